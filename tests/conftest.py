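"""Shared fixtures and independent brute-force oracles.

The oracles here re-derive expected results from first principles (dense
dictionaries, explicit formulas, naive scans) without touching the package's
index/sweep machinery, so they stay independent of the code paths they check.
"""
from __future__ import annotations

import math

import numpy as np
import pytest

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def naive_canonical(s: str) -> str:
    rc = "".join(_COMP[c] for c in reversed(s))
    return min(s, rc)


def naive_count(reads: list[str], k: int, min_freq: int = 1) -> dict[str, int]:
    """Dictionary k-mer count: every window, skip windows with non-ACGT."""
    counts: dict[str, int] = {}
    for read in reads:
        read = read.upper()
        for i in range(len(read) - k + 1):
            win = read[i : i + k]
            if any(c not in "ACGT" for c in win):
                continue
            c = naive_canonical(win)
            counts[c] = counts.get(c, 0) + 1
    return {km: n for km, n in counts.items() if n >= min_freq}


def naive_weight(f: int, scheme: str) -> float:
    if scheme == "natural":
        return float(f)
    if scheme == "logarithmic":
        return 1.0 + math.log(f)
    return 1.0


def dense_distance(
    tables: list[dict[str, int]], scheme: str, metric: str
) -> np.ndarray:
    """Dense-vector all-vs-all distances from per-sample count dictionaries."""
    n = len(tables)
    keys = sorted(set().union(*[set(t) for t in tables]) or set())
    vecs = np.zeros((n, len(keys)), dtype=np.float64)
    for i, t in enumerate(tables):
        for j, km in enumerate(keys):
            if km in t:
                vecs[i, j] = naive_weight(t[km], scheme)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vi, vj = vecs[i], vecs[j]
            ti, tj = vi.sum(), vj.sum()
            if ti == 0 or tj == 0:
                val = 0.0 if ti == tj else 1.0
            elif metric == "cosine":
                val = 1.0 - vi @ vj / (np.linalg.norm(vi) * np.linalg.norm(vj))
            elif metric == "braycurtis":
                val = 1.0 - 2.0 * np.minimum(vi, vj).sum() / (ti + tj)
            else:  # jensenshannon divergence, log base 2
                p, q = vi / ti, vj / tj
                m = (p + q) / 2.0
                with np.errstate(divide="ignore", invalid="ignore"):
                    kl_p = np.where(p > 0, p * np.log2(np.where(p > 0, p / m, 1)), 0.0)
                    kl_q = np.where(q > 0, q * np.log2(np.where(q > 0, q / m, 1)), 0.0)
                val = 0.5 * kl_p.sum() + 0.5 * kl_q.sum()
            d[i, j] = d[j, i] = val
    return d


def random_reads(rng: np.random.Generator, n: int, length: int,
                 alphabet: str = "ACGT") -> list[str]:
    letters = list(alphabet)
    return ["".join(rng.choice(letters, size=length)) for _ in range(n)]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)


def build_small_index(tables_by_id: dict[str, dict[str, int]], k: int,
                      n_partitions: int = 1, min_freq: int = 1):
    """Assemble an InvertedIndex from plain dict count tables (test helper)."""
    from kmersweep.index import build_index
    from kmersweep.kmer import KmerCountTable, build_histogram, encode_kmer, merge_histograms
    from kmersweep.partition import compute_partitions

    kw_tables = []
    for sid, t in tables_by_id.items():
        ints = sorted(encode_kmer(km) for km in t)
        counts = [t[km] for km in sorted(t)]
        kw_tables.append(
            KmerCountTable(sid, k, np.array(ints, np.int64), np.array(counts, np.int64))
        )
    hist = merge_histograms([build_histogram(t, 6) for t in kw_tables])
    parts = compute_partitions(hist, n_partitions)
    return build_index(kw_tables, k, parts, min_freq=min_freq)
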