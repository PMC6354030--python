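"""Synthetic staggered mock communities and error-bearing read sets.

The generator emulates defined ("mock") microbial communities whose member
abundances span several orders of magnitude, and draws substitution-error
reads from them, so every pipeline stage can be exercised on data with a
known ground truth. Genomes are i.i.d. random ACGT: at k=21 their k-mer
profiles are near-orthogonal, which keeps community-separation tests sharp.

The classic evaluation series is built by :func:`make_mock_series`:

    mock1  the staggered base community,
    mock2  mock1 with three pairs of abundant members' abundances inverted,
    mock3  mock2 with two further inversions,
    mock4  mock3 spiked with high-abundance genomes absent from the others.

Everything is reproducible from integer seeds; output files are byte-identical
across runs.
"""
from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .errors import ConfigError
from .seqio import SequenceRecord, write_fasta, write_fastq

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class CommunityProfile:
    """A defined community: members with relative abundances plus their genomes."""

    members: list[tuple[str, float]]
    genomes: dict[str, str]

    def __post_init__(self) -> None:
        total = sum(a for _, a in self.members)
        if not self.members or abs(total - 1.0) > 1e-9:
            raise ConfigError(f"member abundances must sum to 1, got {total}")
        for gid, a in self.members:
            if a <= 0:
                raise ConfigError(f"abundance of {gid} must be > 0")
            if gid not in self.genomes:
                raise ConfigError(f"no genome sequence for member {gid}")

    def abundance(self, gid: str) -> float:
        return dict(self.members)[gid]


@dataclass
class ReadSimSpec:
    """Read simulation parameters: a simple uniform-substitution error model."""

    n_reads: int
    read_length: int = 100
    error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 0:
            raise ConfigError("n_reads must be >= 0")
        if not 0.0 <= self.error_rate < 1.0:
            raise ConfigError("error_rate must be in [0, 1)")


def generate_genomes(
    n: int, length: int, seed: int, prefix: str = "genome"
) -> dict[str, str]:
    """``n`` i.i.d. uniform-ACGT genomes of the given length, seed-reproducible."""
    if n < 1:
        raise ConfigError("need at least one genome")
    rng = np.random.default_rng(seed)
    genomes = {}
    for i in range(n):
        arr = _BASES[rng.integers(0, 4, size=length)]
        genomes[f"{prefix}{i:02d}"] = arr.tobytes().decode("ascii")
    return genomes


def staggered_profile(
    genomes: dict[str, str], orders_of_magnitude: float = 6.0, seed: int = 0
) -> CommunityProfile:
    """Log-spaced abundances across the stated number of decades, shuffled by seed.

    Emulates staggered mock designs whose per-organism copy numbers span
    several orders of magnitude (default 6 decades).
    """
    ids = list(genomes)
    if len(ids) < 2:
        raise ConfigError("a staggered profile needs at least 2 genomes")
    rng = np.random.default_rng(seed)
    levels = np.power(10.0, np.linspace(0.0, orders_of_magnitude, len(ids)))
    levels /= levels.sum()
    order = rng.permutation(len(ids))
    members = [(ids[i], float(levels[r])) for r, i in enumerate(order)]
    members = [(gid, a) for gid, a in sorted(members, key=lambda m: ids.index(m[0]))]
    return CommunityProfile(members=members, genomes=dict(genomes))


def perturb_profile(
    p: CommunityProfile,
    swaps: int,
    seed: int,
    candidates: Sequence[str] | None = None,
) -> CommunityProfile:
    """Exchange the abundances of ``swaps`` disjoint member pairs.

    ``candidates`` restricts the drawn members (e.g. to abundant community
    members); the multiset of abundances is always preserved.
    """
    ids = [gid for gid, _ in p.members]
    pool = list(candidates) if candidates is not None else list(ids)
    if swaps * 2 > len(pool):
        raise ConfigError(f"{swaps} swaps need {2 * swaps} members, have {len(pool)}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=2 * swaps, replace=False)
    abund = dict(p.members)
    for t in range(swaps):
        a, b = pool[chosen[2 * t]], pool[chosen[2 * t + 1]]
        abund[a], abund[b] = abund[b], abund[a]
    return CommunityProfile(
        members=[(gid, abund[gid]) for gid in ids], genomes=dict(p.genomes)
    )


def spike_in(
    p: CommunityProfile, new_genomes: dict[str, str], fraction: float
) -> CommunityProfile:
    """Add new members holding total abundance ``fraction`` (split equally),
    rescaling the existing members by 1 - fraction."""
    if not 0.0 < fraction < 1.0:
        raise ConfigError("spike-in fraction must be in (0, 1)")
    for gid in new_genomes:
        if gid in p.genomes:
            raise ConfigError(f"spike-in genome id {gid} already present")
    share = fraction / len(new_genomes)
    members = [(gid, a * (1.0 - fraction)) for gid, a in p.members]
    members += [(gid, share) for gid in new_genomes]
    genomes = dict(p.genomes)
    genomes.update(new_genomes)
    return CommunityProfile(members=members, genomes=genomes)


def _displacement(p: CommunityProfile, ref: CommunityProfile) -> float:
    """Total log10 abundance displacement of p's members relative to ref."""
    ref_ab = dict(ref.members)
    return float(
        sum(abs(np.log10(a) - np.log10(ref_ab[gid])) for gid, a in p.members)
    )


def make_mock_series(
    n_genomes: int = 20,
    genome_length: int = 10_000,
    orders_of_magnitude: float = 6.0,
    seed: int = 0,
    n_abundant: int = 10,
    spike_genomes: int = 2,
    spike_fraction: float = 0.30,
) -> dict[str, CommunityProfile]:
    """Build the mock1-4 community series used in separation experiments.

    Abundance inversions target the ``n_abundant`` most abundant members (the
    altered species are abundant ones by design). mock3's two further
    inversions are drawn from the abundant members mock2 left untouched, so
    its alterations strictly accumulate on top of mock2's — "further
    alterations" must alter further. mock4 spikes in genomes absent from
    every other community.
    """
    if n_abundant < 10:
        raise ConfigError("the mock series needs >= 10 abundant candidates (5 pairs)")
    genomes = generate_genomes(n_genomes, genome_length, seed)
    mock1 = staggered_profile(genomes, orders_of_magnitude, seed)
    top = [
        gid
        for gid, _ in sorted(mock1.members, key=lambda m: -m[1])[:n_abundant]
    ]
    rng = np.random.default_rng(seed + 1)
    mock2_members = [top[i] for i in rng.choice(len(top), size=6, replace=False)]
    mock2 = perturb_profile(mock1, 3, seed + 1, candidates=mock2_members)
    untouched = [gid for gid in top if gid not in mock2_members]
    mock3 = perturb_profile(mock2, 2, seed + 2, candidates=untouched)
    assert _displacement(mock3, mock1) > _displacement(mock2, mock1)
    extra = generate_genomes(spike_genomes, genome_length, seed + 97, prefix="spike")
    mock4 = spike_in(mock3, extra, spike_fraction)
    return {"mock1": mock1, "mock2": mock2, "mock3": mock3, "mock4": mock4}


def simulate_reads(
    p: CommunityProfile, spec: ReadSimSpec, sample_id: str = "sim"
) -> Iterator[SequenceRecord]:
    """Draw reads: genome by abundance, start uniform, strand uniform,
    i.i.d. substitutions at ``error_rate``. Fully reproducible from the seed."""
    rng = np.random.default_rng(spec.seed)
    gids = [gid for gid, _ in p.members]
    abunds = np.array([a for _, a in p.members], dtype=np.float64)
    abunds /= abunds.sum()
    rl = spec.read_length
    for gid in gids:
        if len(p.genomes[gid]) < rl:
            raise ConfigError(
                f"genome {gid} shorter than read length {rl}"
            )
    counts = rng.multinomial(spec.n_reads, abunds)
    comp = {ord("A"): "T", ord("C"): "G", ord("G"): "C", ord("T"): "A"}
    read_no = 0
    for g_i, gid in enumerate(gids):
        genome = p.genomes[gid]
        c = int(counts[g_i])
        if c == 0:
            continue
        starts = rng.integers(0, len(genome) - rl + 1, size=c)
        strands = rng.integers(0, 2, size=c)
        n_errs = rng.binomial(rl, spec.error_rate, size=c)
        for r in range(c):
            s = int(starts[r])
            seq = genome[s : s + rl]
            if strands[r]:
                seq = seq.translate(comp)[::-1]
            ne = int(n_errs[r])
            if ne:
                positions = rng.choice(rl, size=ne, replace=False)
                shifts = rng.integers(1, 4, size=ne)
                chars = list(seq)
                for pos, sh in zip(positions, shifts):
                    chars[pos] = "ACGT"[("ACGT".index(chars[pos]) + int(sh)) % 4]
                seq = "".join(chars)
            yield SequenceRecord(f"{sample_id}_r{read_no:07d} {gid}", seq)
            read_no += 1


def simulate_sample(
    p: CommunityProfile,
    spec: ReadSimSpec,
    out_path: str | os.PathLike,
    sample_id: str = "sim",
    fmt: str = "fasta",
    provenance: bool = True,
) -> Path:
    """Simulate reads to a FASTA/FASTQ file plus a JSON provenance sidecar."""
    out_path = Path(out_path)
    records = simulate_reads(p, spec, sample_id)
    if fmt == "fasta":
        write_fasta(records, out_path)
    elif fmt == "fastq":
        write_fastq(records, out_path)
    else:
        raise ConfigError(f"unknown output format {fmt!r}")
    if provenance:
        prov = {
            "sample_id": sample_id,
            "profile": [[gid, a] for gid, a in p.members],
            "genome_lengths": {gid: len(s) for gid, s in p.genomes.items()},
            "spec": {
                "n_reads": spec.n_reads,
                "read_length": spec.read_length,
                "error_rate": spec.error_rate,
                "seed": spec.seed,
            },
            "format": fmt,
        }
        with open(out_path.with_suffix(out_path.suffix + ".json"), "wt") as fh:
            json.dump(prov, fh, indent=1)
            fh.write("\n")
    return out_path


def duplicate_dataset(
    path: str | os.PathLike, times: int, out_path: str | os.PathLike
) -> Path:
    """Concatenate a read file with itself ``times`` times (dataset duplication)."""
    if times < 1:
        raise ConfigError("duplication factor must be >= 1")
    path, out_path = Path(path), Path(out_path)
    data = path.read_bytes()
    if data and not data.endswith(b"\n"):
        data += b"\n"
    with open(out_path, "wb") as fh:
        for _ in range(times):
            fh.write(data)
    return out_path
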