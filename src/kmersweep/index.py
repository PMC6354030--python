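"""The range-partitioned inverted index: canonical k-mer -> per-sample frequencies.

Records are kept in ascending k-mer order inside each chunk, and all k-mers of
chunk n sort before those of chunk n+1, so a lookup routes to the covering
chunk and binary-searches there. Raw frequencies (never weights) are stored,
so any weighting scheme can be applied at distance time.

On disk a chunk is a sorted plain-text file, one record per line::

    <kmer> TAB <sample_id>:<freq>,<sample_id>:<freq>,...

with postings sorted by sample id, plus a JSON ``index.meta`` sidecar holding
the k, sample roster, partition bounds and per-sample totals. The format is
bit-exact and diffable; the index built from any staging grouping of the same
samples is byte-identical after chunk concatenation.
"""
from __future__ import annotations

import json
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .errors import ConfigError, DataError, IndexCorruptionError
from .kmer import (
    KmerCountTable,
    canonical,
    decode_kmer,
    decode_kmer_array,
    encode_kmer,
)
from .partition import PartitionSpec, boundary_kmer_ints, validate_partitions
from .seqio import SampleGroup

META_FILENAME = "index.meta"


@dataclass
class IndexRecord:
    """One k-mer with its posting list of (sample_id, frequency) pairs."""

    kmer: str
    postings: list[tuple[str, int]]


class IndexChunk:
    """Records of one partition, CSR-packed over the global sample roster."""

    def __init__(
        self,
        spec: PartitionSpec,
        k: int,
        sample_ids: Sequence[str],
        kmers: np.ndarray,
        indptr: np.ndarray,
        sample_idx: np.ndarray,
        freqs: np.ndarray,
    ):
        self.spec = spec
        self.k = k
        self.sample_ids = list(sample_ids)
        self.kmers = np.asarray(kmers, dtype=np.int64)
        self.indptr = np.asarray(indptr, dtype=np.int64)
        self.sample_idx = np.asarray(sample_idx, dtype=np.int32)
        self.freqs = np.asarray(freqs, dtype=np.int64)

    @property
    def record_count(self) -> int:
        return int(self.kmers.size)

    def record_at(self, i: int) -> IndexRecord:
        lo, hi = int(self.indptr[i]), int(self.indptr[i + 1])
        postings = sorted(
            (self.sample_ids[self.sample_idx[j]], int(self.freqs[j]))
            for j in range(lo, hi)
        )
        return IndexRecord(decode_kmer(int(self.kmers[i]), self.k), postings)

    def iter_records(self, start: int = 0, stop: int | None = None) -> Iterator[IndexRecord]:
        stop = self.record_count if stop is None else stop
        for i in range(start, stop):
            yield self.record_at(i)


class InvertedIndex:
    """All chunks of one run plus the roster and partition table."""

    def __init__(
        self,
        k: int,
        sample_ids: Sequence[str],
        partitions: Sequence[PartitionSpec],
        chunks: Sequence[IndexChunk],
        prefix_len: int,
        min_freq: int = 1,
        sample_stats: dict | None = None,
    ):
        self.k = k
        self.sample_ids = list(sample_ids)
        self.partitions = list(partitions)
        self.chunks = list(chunks)
        self.prefix_len = prefix_len
        self.min_freq = min_freq
        self.sample_stats = sample_stats or {}

    @property
    def n_records(self) -> int:
        return sum(c.record_count for c in self.chunks)

    # -- queries ---------------------------------------------------------

    def _route(self, kint: int) -> int:
        bounds = boundary_kmer_ints(self.partitions, self.k, self.prefix_len)
        return int(np.searchsorted(bounds, kint, side="right")) - 1

    def lookup(self, kmer: str) -> IndexRecord | None:
        """The unique record for a canonical k-mer, or None if not indexed."""
        if len(kmer) != self.k:
            raise ValueError(f"query length {len(kmer)} != k={self.k}")
        if canonical(kmer) != kmer:
            raise ValueError(f"query k-mer {kmer!r} is not canonical")
        v = encode_kmer(kmer)
        chunk = self.chunks[self._route(v)]
        i = int(np.searchsorted(chunk.kmers, v))
        if i < chunk.record_count and int(chunk.kmers[i]) == v:
            return chunk.record_at(i)
        return None

    def iterate_range(self, lo: str, hi: str | None) -> Iterator[IndexRecord]:
        """Stream records with k-mer in [lo, hi), ascending; bounds may be prefixes."""
        shift_lo = 2 * (self.k - len(lo))
        lo_int = encode_kmer(lo) << shift_lo
        hi_int = None
        if hi is not None:
            hi_int = encode_kmer(hi) << (2 * (self.k - len(hi)))
        for chunk in self.chunks:
            if chunk.record_count == 0:
                continue
            start = int(np.searchsorted(chunk.kmers, lo_int, side="left"))
            stop = chunk.record_count
            if hi_int is not None:
                stop = int(np.searchsorted(chunk.kmers, hi_int, side="left"))
            yield from chunk.iter_records(start, stop)

    def iter_records(self) -> Iterator[IndexRecord]:
        for chunk in self.chunks:
            yield from chunk.iter_records()

    # -- persistence -----------------------------------------------------

    def save(self, directory: str | os.PathLike) -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for chunk in self.chunks:
            path = directory / f"chunk_{chunk.spec.ordinal:04d}.idx"
            _write_chunk(chunk, path)
            paths.append(path)
        meta = {
            "k": self.k,
            "prefix_len": self.prefix_len,
            "min_freq": self.min_freq,
            "sample_ids": self.sample_ids,
            "partitions": [p.to_dict() for p in self.partitions],
            "record_counts": [c.record_count for c in self.chunks],
            "sample_stats": self.sample_stats,
        }
        with open(directory / META_FILENAME, "wt", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return paths

    @classmethod
    def load(cls, directory: str | os.PathLike) -> "InvertedIndex":
        directory = Path(directory)
        with open(directory / META_FILENAME, "rt", encoding="utf-8") as fh:
            meta = json.load(fh)
        partitions = [PartitionSpec.from_dict(d) for d in meta["partitions"]]
        sample_ids = meta["sample_ids"]
        pos = {sid: i for i, sid in enumerate(sample_ids)}
        chunks = []
        for spec, expect in zip(partitions, meta["record_counts"]):
            path = directory / f"chunk_{spec.ordinal:04d}.idx"
            chunk = _read_chunk(path, spec, meta["k"], sample_ids, pos)
            if chunk.record_count != expect:
                raise IndexCorruptionError(
                    f"{path}: {chunk.record_count} records, metadata says {expect}"
                )
            chunks.append(chunk)
        return cls(
            meta["k"],
            sample_ids,
            partitions,
            chunks,
            meta["prefix_len"],
            meta.get("min_freq", 1),
            meta.get("sample_stats"),
        )


def _write_chunk(chunk: IndexChunk, path: Path) -> None:
    kmer_strs = decode_kmer_array(chunk.kmers, chunk.k)
    sids = chunk.sample_ids
    indptr = chunk.indptr
    sidx = chunk.sample_idx.tolist()
    freqs = chunk.freqs.tolist()
    with open(path, "wt", encoding="ascii") as fh:
        lines = []
        for i in range(chunk.record_count):
            lo, hi = indptr[i], indptr[i + 1]
            postings = sorted(
                (sids[sidx[j]], freqs[j]) for j in range(lo, hi)
            )
            lines.append(
                kmer_strs[i].decode("ascii")
                + "\t"
                + ",".join(f"{sid}:{f}" for sid, f in postings)
            )
            if len(lines) >= 65536:
                fh.write("\n".join(lines) + "\n")
                lines = []
        if lines:
            fh.write("\n".join(lines) + "\n")


def _read_chunk(
    path: Path,
    spec: PartitionSpec,
    k: int,
    sample_ids: Sequence[str],
    pos: dict[str, int],
) -> IndexChunk:
    kmers: list[int] = []
    indptr: list[int] = [0]
    sidx: list[int] = []
    freqs: list[int] = []
    with open(path, "rt", encoding="ascii") as fh:
        for line in fh:
            kmer, _, rest = line.rstrip("\n").partition("\t")
            kmers.append(encode_kmer(kmer))
            for part in rest.split(","):
                sid, _, f = part.rpartition(":")
                if sid not in pos:
                    raise IndexCorruptionError(f"{path}: unknown sample id {sid!r}")
                sidx.append(pos[sid])
                freqs.append(int(f))
            indptr.append(len(sidx))
    return IndexChunk(
        spec,
        k,
        sample_ids,
        np.array(kmers, dtype=np.int64),
        np.array(indptr, dtype=np.int64),
        np.array(sidx, dtype=np.int32),
        np.array(freqs, dtype=np.int64),
    )


def build_index(
    groups: Sequence[SampleGroup] | Sequence[KmerCountTable],
    k: int,
    partitions: Sequence[PartitionSpec],
    min_freq: int = 1,
    tables: dict[str, KmerCountTable] | None = None,
    batch_reads: int = 200_000,
) -> InvertedIndex:
    """Build the inverted index from staged sample groups (or count tables).

    Per-group per-sample count tables are merged across groups by k-mer; every
    canonical k-mer surviving ``min_freq`` gets exactly one record in exactly
    one chunk. ``tables`` may supply precomputed count tables by sample id
    (e.g. cached from the histogram stage); missing ones are counted here.
    """
    from .kmer import count_sample  # local import to avoid cycle at module load

    validate_partitions(partitions, _partitions_prefix_len(partitions))
    prefix_len = _partitions_prefix_len(partitions)

    ordered_tables: list[KmerCountTable] = []
    sample_stats: dict[str, dict] = {}
    for g in groups:
        members = g.members if isinstance(g, SampleGroup) else [g]
        for s in members:
            if isinstance(s, KmerCountTable):
                t = s.filtered(min_freq)
            elif tables is not None and s.sample_id in tables:
                t = tables[s.sample_id].filtered(min_freq)
            else:
                t = count_sample(s, k, min_freq=min_freq, batch_reads=batch_reads)
            if t.k != k:
                raise ConfigError(f"count table for {t.sample_id} has k={t.k}, expected {k}")
            ordered_tables.append(t)
            sample_stats[t.sample_id] = {
                "distinct_kmers": t.n_distinct,
                "kmer_total": t.total,
            }

    sample_ids = [t.sample_id for t in ordered_tables]
    if len(set(sample_ids)) != len(sample_ids):
        raise ConfigError("duplicate sample ids across groups")

    bounds = boundary_kmer_ints(partitions, k, prefix_len)
    chunks: list[IndexChunk] = []
    for p_ord, spec in enumerate(partitions):
        lo = bounds[p_ord]
        hi = bounds[p_ord + 1] if p_ord + 1 < len(bounds) else None
        kk_parts, si_parts, fr_parts = [], [], []
        for s_i, t in enumerate(ordered_tables):
            a = int(np.searchsorted(t.kmers, lo, side="left"))
            b = t.kmers.size if hi is None else int(np.searchsorted(t.kmers, hi, side="left"))
            if b > a:
                kk_parts.append(t.kmers[a:b])
                si_parts.append(np.full(b - a, s_i, dtype=np.int32))
                fr_parts.append(t.counts[a:b])
        if not kk_parts:
            empty = np.empty(0, dtype=np.int64)
            chunks.append(
                IndexChunk(spec, k, sample_ids, empty, np.zeros(1, np.int64),
                           np.empty(0, np.int32), empty)
            )
            continue
        kk = np.concatenate(kk_parts)
        si = np.concatenate(si_parts)
        fr = np.concatenate(fr_parts)
        order = np.lexsort((si, kk))
        kk, si, fr = kk[order], si[order], fr[order]
        uniq, first = np.unique(kk, return_index=True)
        indptr = np.append(first, kk.size).astype(np.int64)
        chunks.append(IndexChunk(spec, k, sample_ids, uniq, indptr, si, fr))

    return InvertedIndex(
        k, sample_ids, partitions, chunks, prefix_len, min_freq, sample_stats
    )


def _partitions_prefix_len(partitions: Sequence[PartitionSpec]) -> int:
    return len(partitions[0].lo) if partitions else 0
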