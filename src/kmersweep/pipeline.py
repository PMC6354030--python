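"""End-to-end orchestration of the staged pipeline.

The stages mirror the method's three jobs — (1) per-sample k-mer prefix
histograms, (2) range-partitioned inverted index construction, (3) sweep-line
distance matrix computation — plus optional clustering. Each stage persists
its artifacts so a run is idempotent and resumable: deleting downstream
outputs and re-running recomputes only what is missing.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Sequence

from . import __version__
from .config import RunConfig
from .distance import DistanceMatrix, distance_matrix
from .index import InvertedIndex, META_FILENAME, build_index
from .kmer import KmerCountTable, build_histogram, count_sample, merge_histograms, KmerHistogram
from .partition import compute_partitions
from .postprocess import plot_heatmap, similarity_edges, ward_cluster, write_edges_tsv
from .seqio import SampleRecord, group_samples

logger = logging.getLogger(__name__)


def _md5(path: Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def run_pipeline(
    config: RunConfig,
    samples: Sequence[SampleRecord],
    cluster: bool = False,
    similarity_threshold: float = 0.30,
    resume: bool = True,
) -> dict:
    """Execute histogram -> partition -> index -> distance (-> cluster) stages.

    Returns a dict with the distance matrix and the paths of all artifacts.
    A run manifest (config, input checksums, stage timings, version) is
    written alongside them.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    hist_dir = out / "histograms"
    hist_dir.mkdir(exist_ok=True)
    index_dir = out / "index"
    timings: dict[str, float] = {}

    # ---- stage 1: per-sample prefix histograms (count tables cached) ----
    t0 = time.perf_counter()
    tables: dict[str, KmerCountTable] = {}
    histograms = []
    for s in samples:
        hpath = hist_dir / f"{s.sample_id}.hist.txt"
        if resume and hpath.exists():
            h = KmerHistogram.load(hpath)
            if h.k != config.k:
                h = None
        else:
            h = None
        if h is None:
            table = count_sample(s, config.k, min_freq=config.min_freq)
            tables[s.sample_id] = table
            h = build_histogram(table, config.prefix_len)
            h.save(hpath)
            logger.info(
                "histogram: sample=%s distinct_kmers=%d", s.sample_id, h.total
            )
        histograms.append(h)
    timings["histogram"] = time.perf_counter() - t0

    # ---- stage 2: balanced k-mer range partitions ----
    t0 = time.perf_counter()
    merged_hist = merge_histograms(histograms)
    partitions = compute_partitions(merged_hist, config.effective_partitions)
    for p in partitions:
        logger.info(
            "partition %d: [%s, %s) expected_records=%d",
            p.ordinal, p.lo, p.hi, p.expected_records,
        )
    timings["partition"] = time.perf_counter() - t0

    # ---- stage 3: inverted index ----
    t0 = time.perf_counter()
    index = None
    if resume and (index_dir / META_FILENAME).exists():
        try:
            index = InvertedIndex.load(index_dir)
            if (
                index.k != config.k
                or index.sample_ids != [s.sample_id for s in samples]
                or len(index.partitions) != len(partitions)
            ):
                index = None
        except Exception:
            index = None
    if index is None:
        groups = group_samples(samples, config.group_cap)
        logger.info("index: %d samples in %d staging group(s)", len(samples), len(groups))
        index = build_index(
            groups, config.k, partitions, min_freq=config.min_freq, tables=tables
        )
        index.save(index_dir)
        for chunk in index.chunks:
            logger.info(
                "index chunk %d: records=%d",
                chunk.spec.ordinal, chunk.record_count,
            )
    timings["index"] = time.perf_counter() - t0

    # ---- stage 4: distance matrix ----
    t0 = time.perf_counter()
    matrix_path = out / "distance.tsv"
    matrix = distance_matrix(
        index, scheme=config.weighting, metric=config.metric,
        n_workers=config.n_workers,
    )
    matrix.to_tsv(matrix_path)
    timings["distance"] = time.perf_counter() - t0
    logger.info("distance: metric=%s weighting=%s -> %s",
                config.metric, config.weighting, matrix_path)

    artifacts = {
        "matrix": matrix,
        "matrix_path": matrix_path,
        "index_dir": index_dir,
        "histogram_dir": hist_dir,
    }

    # ---- stage 5 (optional): clustering + edge list + heatmap ----
    if cluster and len(samples) >= 2:
        t0 = time.perf_counter()
        dend = ward_cluster(matrix)
        newick_path = out / "cluster.nwk"
        dend.save_newick(newick_path)
        edges = similarity_edges(matrix, similarity_threshold)
        edges_path = out / "edges.tsv"
        write_edges_tsv(edges, edges_path)
        heatmap_path = out / "heatmap.png"
        plot_heatmap(matrix, heatmap_path, dend)
        timings["cluster"] = time.perf_counter() - t0
        artifacts.update(
            newick_path=newick_path, edges_path=edges_path, heatmap_path=heatmap_path
        )

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "inputs": {s.sample_id: {"path": str(s.path), "md5": _md5(Path(s.path))}
                   for s in samples},
        "timings_sec": {k: round(v, 4) for k, v in timings.items()},
    }
    manifest_path = out / "run_manifest.json"
    with open(manifest_path, "wt", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    artifacts["manifest_path"] = manifest_path
    return artifacts
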