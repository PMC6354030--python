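"""Canonical k-mer extraction, per-sample counting, and prefix histograms.

Counting is strand-independent: every window is replaced by its canonical
form, the lexicographic minimum of the k-mer and its reverse complement under
A<C<G<T. Internally k-mers are packed 2 bits per base into int64 (k <= 31),
an encoding that preserves lexicographic order, so sorted integer arrays and
sorted k-mer strings agree.

The prefix histogram approximates the k-mer distribution by truncating each
distinct k-mer to its first ``prefix_len`` letters (default 6); it is the
input to load-balanced range partitioning.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence, Union

import numpy as np

from .errors import ConfigError, DataError
from .seqio import SampleRecord, read_sequences

BASES = "ACGT"
MAX_K = 31  # 2 bits/base in a signed 64-bit integer

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# byte -> 2-bit code; 255 marks anything outside {A,C,G,T} (case-insensitive)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(BASES.encode("ascii"), dtype=np.uint8)


def reverse_complement(s: str) -> str:
    """Watson-Crick reverse complement of an A/C/G/T string."""
    _validate_acgt(s)
    return s.translate(_COMPLEMENT)[::-1]


def canonical(s: str) -> str:
    """Lexicographic minimum of ``s`` and its reverse complement."""
    rc = reverse_complement(s)
    return s if s <= rc else rc


def _validate_acgt(s: str) -> None:
    for ch in s:
        if ch not in "ACGTacgt":
            raise ValueError(f"non-ACGT character {ch!r} in nucleotide string")


def extract_kmers(seq: str, k: int) -> Iterator[str]:
    """Yield the canonical k-mer of every valid window of ``seq``, in order.

    Windows containing any character outside {A,C,G,T} (e.g. N) are skipped;
    sequences shorter than k yield nothing.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    seq = seq.upper()
    n = len(seq)
    bad_prefix = [0] * (n + 1)  # running count of non-ACGT characters
    for i, ch in enumerate(seq):
        bad_prefix[i + 1] = bad_prefix[i] + (ch not in BASES)
    for start in range(n - k + 1):
        if bad_prefix[start + k] == bad_prefix[start]:
            yield canonical(seq[start : start + k])


def encode_kmer(s: str) -> int:
    """Pack an A/C/G/T string into a 2-bit-per-base integer."""
    v = 0
    for ch in s:
        c = _CODE[ord(ch)]
        if c >= 4:
            raise ValueError(f"non-ACGT character {ch!r} in k-mer")
        v = (v << 2) | int(c)
    return v


def decode_kmer(v: int, k: int) -> str:
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append(BASES[(v >> shift) & 3])
    return "".join(out)


def decode_kmer_array(kmers: np.ndarray, k: int) -> np.ndarray:
    """Vectorized decode of packed k-mers to fixed-width byte strings."""
    n = kmers.shape[0]
    chars = np.empty((n, k), dtype=np.uint8)
    for j in range(k):
        shift = 2 * (k - 1 - j)
        chars[:, j] = _DECODE[(kmers >> shift) & 3]
    return chars.reshape(-1).view(f"S{k}")


def canonical_kmer_ints(seqs: Sequence[str], k: int) -> np.ndarray:
    """Canonical packed k-mers of every valid window across ``seqs``.

    Sequences are joined with an N sentinel so windows never straddle reads.
    Returns an unsorted int64 array, one entry per valid window.
    """
    if k < 1 or k > MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    if not seqs:
        return np.empty(0, dtype=np.int64)
    joined = "N".join(seqs)
    codes = _CODE[np.frombuffer(joined.encode("ascii"), dtype=np.uint8)]
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    bad = codes >= 4
    cs = np.zeros(codes.size + 1, dtype=np.int64)
    np.cumsum(bad, out=cs[1:])
    ok = (cs[k:] - cs[:-k]) == 0
    cc = np.where(bad, 0, codes).astype(np.int64)
    fwd = np.zeros(n, dtype=np.int64)
    rev = np.zeros(n, dtype=np.int64)
    for j in range(k):
        fwd = (fwd << 2) | cc[j : j + n]
        rev |= (3 - cc[j : j + n]) << (2 * j)
    return np.minimum(fwd, rev)[ok]


class KmerCountTable:
    """Canonical k-mer frequencies of one sample, ascending by k-mer.

    Backed by a sorted unique int64 array plus parallel counts; iteration
    order (ascending packed integers) equals ascending lexicographic order
    of the k-mer strings.
    """

    def __init__(self, sample_id: str, k: int, kmers: np.ndarray, counts: np.ndarray):
        self.sample_id = sample_id
        self.k = k
        self.kmers = np.asarray(kmers, dtype=np.int64)
        self.counts = np.asarray(counts, dtype=np.int64)
        if self.kmers.shape != self.counts.shape:
            raise DataError("k-mer and count arrays differ in length")

    @property
    def n_distinct(self) -> int:
        return int(self.kmers.size)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def get(self, kmer: str) -> int:
        v = encode_kmer(kmer)
        i = np.searchsorted(self.kmers, v)
        if i < self.kmers.size and self.kmers[i] == v:
            return int(self.counts[i])
        return 0

    def items(self) -> Iterator[tuple[str, int]]:
        for v, c in zip(self.kmers, self.counts):
            yield decode_kmer(int(v), self.k), int(c)

    def to_dict(self) -> dict[str, int]:
        return dict(self.items())

    def filtered(self, min_freq: int) -> "KmerCountTable":
        if min_freq <= 1:
            return self
        keep = self.counts >= min_freq
        return KmerCountTable(self.sample_id, self.k, self.kmers[keep], self.counts[keep])


ReadSource = Union[SampleRecord, str, os.PathLike, Iterable[str]]


def _iter_read_strings(source: ReadSource) -> Iterator[str]:
    if isinstance(source, SampleRecord):
        for rec in read_sequences(source.path):
            yield rec.sequence
    elif isinstance(source, (str, os.PathLike)):
        for rec in read_sequences(source):
            yield rec.sequence
    else:
        for s in source:
            yield s.upper()


def count_sample(
    source: ReadSource,
    k: int,
    min_freq: int = 1,
    batch_reads: int = 200_000,
    sample_id: str | None = None,
) -> KmerCountTable:
    """Count canonical k-mers over all reads of a sample.

    Reads are processed in batches; per-batch sorted unique runs are merged at
    the end, so the result is identical to counting everything in memory.
    Entries with frequency below ``min_freq`` are dropped.
    """
    if min_freq < 1:
        raise ConfigError(f"min_freq must be >= 1, got {min_freq}")
    if sample_id is None:
        sample_id = source.sample_id if isinstance(source, SampleRecord) else "sample"
    uniq_parts: list[np.ndarray] = []
    count_parts: list[np.ndarray] = []
    batch: list[str] = []

    def flush() -> None:
        if not batch:
            return
        km = canonical_kmer_ints(batch, k)
        batch.clear()
        if km.size:
            u, c = np.unique(km, return_counts=True)
            uniq_parts.append(u)
            count_parts.append(c)

    for seq in _iter_read_strings(source):
        batch.append(seq)
        if len(batch) >= batch_reads:
            flush()
    flush()

    if not uniq_parts:
        return KmerCountTable(sample_id, k, np.empty(0, np.int64), np.empty(0, np.int64))
    if len(uniq_parts) == 1:
        kmers, counts = uniq_parts[0], count_parts[0]
    else:
        allk = np.concatenate(uniq_parts)
        allc = np.concatenate(count_parts)
        kmers, inverse = np.unique(allk, return_inverse=True)
        counts = np.zeros(kmers.size, dtype=np.int64)
        np.add.at(counts, inverse, allc)
    table = KmerCountTable(sample_id, k, kmers, counts)
    return table.filtered(min_freq)


@dataclass
class KmerHistogram:
    """Distinct-k-mer counts per fixed-length prefix (one sample, or merged).

    ``counts[p]`` is the number of distinct canonical k-mers whose first
    ``prefix_len`` letters equal ``p`` — record counts, not frequency mass,
    because partition balancing targets records per partition.
    """

    prefix_len: int
    counts: dict[str, int] = field(default_factory=dict)
    k: int | None = None
    sample_id: str | None = None

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "wt", encoding="ascii") as fh:
            fh.write(
                f"# k={self.k} prefix_len={self.prefix_len} "
                f"sample_id={self.sample_id} total={self.total}\n"
            )
            for p in sorted(self.counts):
                fh.write(f"{p}\t{self.counts[p]}\n")

    @classmethod
    def load(cls, path: str | os.PathLike) -> "KmerHistogram":
        counts: dict[str, int] = {}
        k = None
        prefix_len = None
        sample_id = None
        with open(path, "rt", encoding="ascii") as fh:
            header = fh.readline()
            for tok in header.lstrip("# ").split():
                key, _, val = tok.partition("=")
                if key == "k":
                    k = None if val == "None" else int(val)
                elif key == "prefix_len":
                    prefix_len = int(val)
                elif key == "sample_id":
                    sample_id = None if val == "None" else val
            for line in fh:
                p, c = line.split("\t")
                counts[p] = int(c)
        if prefix_len is None:
            raise DataError(f"{path}: missing prefix_len header")
        return cls(prefix_len=prefix_len, counts=counts, k=k, sample_id=sample_id)


def build_histogram(table: KmerCountTable, prefix_len: int = 6) -> KmerHistogram:
    """Histogram of distinct canonical k-mers by their first min(prefix_len, k) letters."""
    if prefix_len < 1:
        raise ConfigError(f"prefix_len must be >= 1, got {prefix_len}")
    plen = min(prefix_len, table.k)
    shift = 2 * (table.k - plen)
    prefixes = table.kmers >> shift
    u, c = np.unique(prefixes, return_counts=True)
    counts = {decode_kmer(int(p), plen): int(n) for p, n in zip(u, c)}
    return KmerHistogram(prefix_len=plen, counts=counts, k=table.k, sample_id=table.sample_id)


def merge_histograms(histograms: Sequence[KmerHistogram]) -> KmerHistogram:
    """Per-prefix sums across samples; totals add."""
    if not histograms:
        raise ConfigError("cannot merge an empty list of histograms")
    plen = histograms[0].prefix_len
    k = histograms[0].k
    merged: dict[str, int] = {}
    for h in histograms:
        if h.prefix_len != plen:
            raise ConfigError(
                f"histogram prefix_len mismatch: {h.prefix_len} != {plen}"
            )
        for p, c in h.counts.items():
            merged[p] = merged.get(p, 0) + c
    return KmerHistogram(prefix_len=plen, counts=merged, k=k, sample_id=None)
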