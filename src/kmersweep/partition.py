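"""Histogram-balanced range partitioning of the canonical k-mer space.

Partition boundaries live at prefix granularity (the histogram cannot see
finer structure): a k-mer is routed by comparing its first ``prefix_len``
letters against the boundary prefixes. A greedy cumulative walk over the
ascending prefixes cuts each time the cumulative record count reaches the
next multiple of total/n, so every partition carries roughly the same number
of index records. Partitioning never changes results, only parallel staging.
"""
from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigError
from .kmer import BASES, KmerHistogram, encode_kmer


@dataclass(frozen=True)
class PartitionSpec:
    """A half-open k-mer range [lo, hi) assigned to one independent sweep.

    ``lo``/``hi`` are prefix strings; ``hi is None`` is the end-of-space
    sentinel of the last partition.
    """

    ordinal: int
    lo: str
    hi: str | None
    expected_records: int = 0

    def to_dict(self) -> dict:
        return {
            "ordinal": self.ordinal,
            "lo": self.lo,
            "hi": self.hi,
            "expected_records": self.expected_records,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PartitionSpec":
        return cls(d["ordinal"], d["lo"], d["hi"], d.get("expected_records", 0))


def compute_partitions(h: KmerHistogram, n: int) -> list[PartitionSpec]:
    """Split the k-mer space into at most ``n`` balanced half-open ranges.

    A boundary cut is taken at the first prefix whose cumulative distinct-k-mer
    count reaches the next target quantile (deterministic tie-breaking); the
    following observed prefix starts the next partition. Heavily skewed
    prefixes cannot be split below prefix granularity.
    """
    if n < 1:
        raise ConfigError(f"partition count must be >= 1, got {n}")
    plen = h.prefix_len
    first_lo = BASES[0] * plen
    total = h.total
    if n == 1 or total == 0 or len(h.counts) <= 1:
        return [PartitionSpec(0, first_lo, None, total)]

    items = sorted(h.counts.items())
    # segment boundaries: indexes into `items` where a new partition starts
    starts = [0]
    cum = 0
    next_target = 1
    for pos, (_, c) in enumerate(items):
        cum += c
        if pos == len(items) - 1:
            break
        if next_target < n and cum >= next_target * total / n:
            starts.append(pos + 1)
            # skip any targets already passed so no empty partition is made
            while next_target < n and cum >= next_target * total / n:
                next_target += 1
            if next_target >= n:
                break

    specs: list[PartitionSpec] = []
    for i, s in enumerate(starts):
        e = starts[i + 1] if i + 1 < len(starts) else len(items)
        lo = first_lo if i == 0 else items[s][0]
        hi = items[starts[i + 1]][0] if i + 1 < len(starts) else None
        expected = sum(c for _, c in items[s:e])
        specs.append(PartitionSpec(i, lo, hi, expected))
    return specs


def validate_partitions(partitions: Sequence[PartitionSpec], prefix_len: int) -> None:
    """Require that the partitions tile the whole space: no gaps, no overlaps."""
    if not partitions:
        raise ConfigError("empty partition list")
    first_lo = BASES[0] * prefix_len
    if partitions[0].lo != first_lo:
        raise ConfigError(
            f"partitions do not start at the minimal prefix {first_lo!r}"
        )
    for a, b in zip(partitions, partitions[1:]):
        if a.hi != b.lo:
            raise ConfigError(
                f"gapped or overlapping partitions: [{a.lo},{a.hi}) then [{b.lo},{b.hi})"
            )
        if not a.lo < b.lo:
            raise ConfigError("partition bounds not strictly increasing")
    if partitions[-1].hi is not None:
        raise ConfigError("last partition must end at the end-of-space sentinel")


def route_prefix(partitions: Sequence[PartitionSpec], prefix: str) -> int:
    """Ordinal of the partition whose [lo, hi) contains a k-mer prefix."""
    los = [p.lo for p in partitions]
    return bisect_right(los, prefix) - 1


def route_kmer(partitions: Sequence[PartitionSpec], kmer: str, prefix_len: int) -> int:
    return route_prefix(partitions, kmer[: min(prefix_len, len(kmer))])


def boundary_kmer_ints(
    partitions: Sequence[PartitionSpec], k: int, prefix_len: int
) -> np.ndarray:
    """Packed-integer lower bounds of each partition, on the full k-mer scale.

    A prefix bound p maps to encode(p) << 2*(k - plen): the smallest k-mer
    with that prefix. Routing a sorted k-mer array is then a searchsorted.
    """
    plen = min(prefix_len, k)
    shift = 2 * (k - plen)
    return np.array(
        [encode_kmer(p.lo[:plen]) << shift for p in partitions], dtype=np.int64
    )
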