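"""All-vs-all distance matrices from the inverted index.

Each sample s is viewed as a vector v_s over the canonical k-mer space whose
components are weights w_ks derived from the raw frequencies f_ks:

    boolean      w = 1            (presence/absence)
    natural      w = f            (raw frequency)
    logarithmic  w = 1 + ln(f)    (damps highly abundant k-mers)

The cosine distance is 1 - D/(M1*M2) with D the dot product accumulated over
shared k-mers and M_s = sqrt(sum w^2) the vector magnitude; because magnitude
cancels, it normalizes samples of different sequencing depth. Bray-Curtis is
1 - 2*sum(min(w1,w2))/(sum w1 + sum w2) on the weighted vectors, and
Jensen-Shannon is the base-2 divergence of the probability-normalized vectors
p = w / sum(w), bounded in [0, 1].

All pair terms are accumulated by a sweep line: one ordered scan of the index
records, where a record with m postings updates all m(m-1)/2 unordered sample
pairs. Partitions are swept independently (optionally in parallel processes)
and their partial D/M sums merged — an exact algebra, so results never depend
on partition or worker count. Per-pair sums use compensated (Kahan) summation.
"""
from __future__ import annotations

import logging
import math
import os
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, IndexCorruptionError
from .index import IndexChunk, InvertedIndex

logger = logging.getLogger(__name__)

WEIGHTING_SCHEMES = ("boolean", "natural", "logarithmic")
METRICS = ("cosine", "braycurtis", "jensenshannon")


def weight(f: float, scheme: str) -> float:
    """Weight of a k-mer with frequency ``f`` under a weighting scheme."""
    if f < 1:
        raise ValueError(f"k-mer frequency must be >= 1, got {f}")
    if scheme == "natural":
        return float(f)
    if scheme == "logarithmic":
        return 1.0 + math.log(f)
    if scheme == "boolean":
        return 1.0
    raise ConfigError(f"unknown weighting scheme {scheme!r}")


def weight_array(freqs: np.ndarray, scheme: str) -> np.ndarray:
    if freqs.size and freqs.min() < 1:
        raise ValueError("k-mer frequencies must be >= 1")
    if scheme == "natural":
        return freqs.astype(np.float64)
    if scheme == "logarithmic":
        return 1.0 + np.log(freqs.astype(np.float64))
    if scheme == "boolean":
        return np.ones(freqs.shape, dtype=np.float64)
    raise ConfigError(f"unknown weighting scheme {scheme!r}")


@dataclass
class SampleNorms:
    """Per-sample vector summaries: sum w^2 (magnitude squared), sum w, presence."""

    sample_ids: list[str]
    sum_sq_weight: np.ndarray
    sum_weight: np.ndarray
    present_kmers: np.ndarray

    @classmethod
    def zeros(cls, sample_ids: Sequence[str]) -> "SampleNorms":
        n = len(sample_ids)
        return cls(
            list(sample_ids),
            np.zeros(n, dtype=np.float64),
            np.zeros(n, dtype=np.float64),
            np.zeros(n, dtype=np.int64),
        )

    def add(self, other: "SampleNorms") -> None:
        if other.sample_ids != self.sample_ids:
            raise ConfigError("cannot merge norms over different sample rosters")
        self.sum_sq_weight += other.sum_sq_weight
        self.sum_weight += other.sum_weight
        self.present_kmers += other.present_kmers

    @property
    def magnitude(self) -> np.ndarray:
        return np.sqrt(self.sum_sq_weight)


def _chunk_norms(chunk: IndexChunk, scheme: str) -> SampleNorms:
    n = len(chunk.sample_ids)
    w = weight_array(chunk.freqs, scheme)
    return SampleNorms(
        list(chunk.sample_ids),
        np.bincount(chunk.sample_idx, weights=w * w, minlength=n),
        np.bincount(chunk.sample_idx, weights=w, minlength=n),
        np.bincount(chunk.sample_idx, minlength=n).astype(np.int64),
    )


def compute_norms(index: InvertedIndex, scheme: str) -> SampleNorms:
    """Single pass over all records accumulating sum w^2, sum w, presence per sample."""
    norms = SampleNorms.zeros(index.sample_ids)
    for chunk in index.chunks:
        norms.add(_chunk_norms(chunk, scheme))
    return norms


def pair_index_offsets(n: int) -> list[int]:
    """Offsets so the upper-triangle index of (i, j), i<j, is off[i] + j."""
    return [i * n - i * (i + 1) // 2 - i - 1 for i in range(n)]


class PairAccumulator:
    """Partial per-pair sums from one partition sweep, mergeable across partitions.

    ``sums`` holds, per unordered sample pair: the dot product (cosine), the
    running sum of min(w1, w2) (Bray-Curtis), or the shared-support divergence
    partial sum (Jensen-Shannon). For Jensen-Shannon, ``shared_p``/``shared_q``
    additionally track each side's probability mass on shared k-mers so the
    unshared mass can be added at finalization. Each array carries a Kahan
    compensation twin.
    """

    def __init__(self, metric: str, scheme: str, sample_ids: Sequence[str]):
        if metric not in METRICS:
            raise ConfigError(f"unknown metric {metric!r}")
        if scheme not in WEIGHTING_SCHEMES:
            raise ConfigError(f"unknown weighting scheme {scheme!r}")
        self.metric = metric
        self.scheme = scheme
        self.sample_ids = list(sample_ids)
        n = len(self.sample_ids)
        npairs = n * (n - 1) // 2
        self.sums = np.zeros(npairs, dtype=np.float64)
        self._comp = np.zeros(npairs, dtype=np.float64)
        if metric == "jensenshannon":
            self.shared_p = np.zeros(npairs, dtype=np.float64)
            self._comp_p = np.zeros(npairs, dtype=np.float64)
            self.shared_q = np.zeros(npairs, dtype=np.float64)
            self._comp_q = np.zeros(npairs, dtype=np.float64)
        else:
            self.shared_p = self.shared_q = None
        self.norms = SampleNorms.zeros(self.sample_ids)

    def _check_compatible(self, other: "PairAccumulator") -> None:
        if (
            other.metric != self.metric
            or other.scheme != self.scheme
            or other.sample_ids != self.sample_ids
        ):
            raise ConfigError(
                "cannot merge accumulators with different metric/scheme/roster"
            )

    def merge_with(self, other: "PairAccumulator") -> None:
        self._check_compatible(other)
        self.sums += other.sums
        if self.metric == "jensenshannon":
            self.shared_p += other.shared_p
            self.shared_q += other.shared_q
        self.norms.add(other.norms)


def merge_accumulators(parts: Sequence[PairAccumulator]) -> PairAccumulator:
    """Element-wise sums of pair terms and norms, in the given (ordinal) order."""
    if not parts:
        raise ConfigError("cannot merge an empty list of accumulators")
    merged = PairAccumulator(parts[0].metric, parts[0].scheme, parts[0].sample_ids)
    for p in parts:
        merged.merge_with(p)
    return merged


def sweep_partition(
    chunk: IndexChunk,
    scheme: str,
    metric: str,
    totals: np.ndarray | None = None,
) -> PairAccumulator:
    """Sweep one partition's records in k-mer order, accumulating pair terms.

    Each record with m postings updates all m(m-1)/2 unordered pairs: cosine
    adds w_i*w_j, Bray-Curtis adds min(w_i, w_j), Jensen-Shannon adds the
    shared-support divergence term from p = w_i/total_i, q = w_j/total_j (so
    it needs ``totals`` — per-sample sum of weights over ALL partitions — from
    a prior norms pass). Per-partition norms are accumulated in the same scan.
    """
    acc = PairAccumulator(metric, scheme, chunk.sample_ids)
    acc.norms = _chunk_norms(chunk, scheme)
    n = len(chunk.sample_ids)
    if chunk.sample_idx.size and int(chunk.sample_idx.max()) >= n:
        raise IndexCorruptionError("posting refers to an unregistered sample")
    if metric == "jensenshannon":
        if totals is None:
            raise ConfigError(
                "jensenshannon sweep requires complete per-sample weight totals"
            )
        safe = np.where(totals > 0, totals, 1.0)
        vals = (weight_array(chunk.freqs, scheme) / safe[chunk.sample_idx]).tolist()
    else:
        vals = weight_array(chunk.freqs, scheme).tolist()

    indptr = chunk.indptr.tolist()
    sidx = chunk.sample_idx.tolist()
    off = pair_index_offsets(n)
    sums = acc.sums
    comp = acc._comp
    if metric == "jensenshannon":
        sh_p, cp = acc.shared_p, acc._comp_p
        sh_q, cq = acc.shared_q, acc._comp_q
    log2 = math.log2

    for r in range(len(indptr) - 1):
        a, b = indptr[r], indptr[r + 1]
        if b - a < 2:
            continue
        for ii in range(a, b):
            si = sidx[ii]
            wi = vals[ii]
            oi = off[si]
            for jj in range(ii + 1, b):
                sj = sidx[jj]  # si < sj: postings are roster-ordered within a record
                p = oi + sj
                if metric == "cosine":
                    v = wi * vals[jj]
                elif metric == "braycurtis":
                    wj = vals[jj]
                    v = wi if wi < wj else wj
                else:
                    q = vals[jj]
                    m = wi + q
                    v = 0.5 * (wi * log2(2.0 * wi / m) + q * log2(2.0 * q / m))
                    # Kahan updates of the shared probability masses
                    y = wi - cp[p]
                    t = sh_p[p] + y
                    cp[p] = (t - sh_p[p]) - y
                    sh_p[p] = t
                    y = q - cq[p]
                    t = sh_q[p] + y
                    cq[p] = (t - sh_q[p]) - y
                    sh_q[p] = t
                y = v - comp[p]
                t = sums[p] + y
                comp[p] = (t - sums[p]) - y
                sums[p] = t
    return acc


@dataclass
class DistanceMatrix:
    """Symmetric all-vs-all distance matrix with a sample roster."""

    sample_ids: list[str]
    values: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.to_dataframe().to_csv(path, sep="\t", float_format="%.12g")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(c) for c in df.columns], df.to_numpy(dtype=np.float64))

    def get(self, a: str, b: str) -> float:
        i, j = self.sample_ids.index(a), self.sample_ids.index(b)
        return float(self.values[i, j])


def finalize(
    acc: PairAccumulator,
    norms: SampleNorms | None = None,
    metric: str | None = None,
) -> DistanceMatrix:
    """Assemble the distance matrix from merged pair terms and complete norms.

    Empty samples (zero weight total) are at distance 1 from any non-empty
    sample and 0 from another empty one; the diagonal is exactly 0.
    """
    norms = acc.norms if norms is None else norms
    metric = acc.metric if metric is None else metric
    ids = acc.sample_ids
    n = len(ids)
    off = pair_index_offsets(n)
    d = np.zeros((n, n), dtype=np.float64)
    mags = norms.magnitude
    totals = norms.sum_weight
    empty = totals == 0
    if empty.any():
        logger.warning(
            "%d empty sample(s) in distance computation: %s",
            int(empty.sum()),
            [ids[i] for i in np.flatnonzero(empty)],
        )
    for i in range(n):
        for j in range(i + 1, n):
            p = off[i] + j
            if empty[i] or empty[j]:
                val = 0.0 if (empty[i] and empty[j]) else 1.0
            elif metric == "cosine":
                dot = acc.sums[p]
                if dot < -1e-12:
                    raise DataError(f"negative dot product for pair ({ids[i]}, {ids[j]})")
                val = 1.0 - dot / (mags[i] * mags[j])
            elif metric == "braycurtis":
                minsum = acc.sums[p]
                if minsum < -1e-12:
                    raise DataError(f"negative overlap sum for pair ({ids[i]}, {ids[j]})")
                val = 1.0 - 2.0 * minsum / (totals[i] + totals[j])
            else:  # jensenshannon: shared terms + each side's unshared mass / 2
                val = (
                    acc.sums[p]
                    + 0.5 * (1.0 - acc.shared_p[p])
                    + 0.5 * (1.0 - acc.shared_q[p])
                )
            if val < -1e-12 or val > 1.0 + 1e-9:
                raise DataError(
                    f"distance {val} out of range for pair ({ids[i]}, {ids[j]})"
                )
            val = min(max(val, 0.0), 1.0)
            d[i, j] = d[j, i] = val
    return DistanceMatrix(list(ids), d)


def _sweep_task(args) -> PairAccumulator:
    chunk, scheme, metric, totals = args
    return sweep_partition(chunk, scheme, metric, totals)


def distance_matrix(
    index: InvertedIndex,
    scheme: str = "logarithmic",
    metric: str = "cosine",
    n_workers: int = 1,
) -> DistanceMatrix:
    """Orchestrate norms pass, per-partition sweeps, merge, and finalization.

    Partitions are swept by independent workers with no shared mutable state;
    merging the partial accumulators (always in partition-ordinal order) is
    the only synchronization point, so the result is identical for any
    partition or worker count.
    """
    if scheme not in WEIGHTING_SCHEMES:
        raise ConfigError(f"unknown weighting scheme {scheme!r}")
    if metric not in METRICS:
        raise ConfigError(f"unknown metric {metric!r}")
    totals = None
    if metric == "jensenshannon":  # two-pass contract: totals first
        totals = compute_norms(index, scheme).sum_weight
    tasks = [(chunk, scheme, metric, totals) for chunk in index.chunks]
    if n_workers > 1 and len(tasks) > 1:
        with ProcessPoolExecutor(max_workers=n_workers) as pool:
            parts = list(pool.map(_sweep_task, tasks))
    else:
        parts = [_sweep_task(t) for t in tasks]
    merged = merge_accumulators(parts)
    return finalize(merged)
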