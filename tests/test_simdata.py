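"""Synthetic mock communities and read simulation."""
from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from kmersweep.errors import ConfigError
from kmersweep.simdata import (
    CommunityProfile,
    ReadSimSpec,
    duplicate_dataset,
    generate_genomes,
    make_mock_series,
    perturb_profile,
    simulate_reads,
    simulate_sample,
    spike_in,
    staggered_profile,
)


class TestGenerateGenomes:
    def test_deterministic_from_seed(self):
        a = generate_genomes(2, 10, seed=42)
        b = generate_genomes(2, 10, seed=42)
        assert a == b
        assert all(len(s) == 10 for s in a.values())
        assert all(set(s) <= set("ACGT") for s in a.values())

    def test_different_seeds_differ(self):
        assert generate_genomes(1, 50, seed=1) != generate_genomes(1, 50, seed=2)

    def test_composition_roughly_uniform(self):
        (seq,) = generate_genomes(1, 40_000, seed=7).values()
        counts = [seq.count(b) for b in "ACGT"]
        assert stats.chisquare(counts).pvalue > 1e-4


class TestProfiles:
    def test_log_spaced_normalization(self):
        genomes = generate_genomes(3, 30, seed=0)
        p = staggered_profile(genomes, orders_of_magnitude=2, seed=0)
        abunds = sorted(a for _, a in p.members)
        assert abunds == pytest.approx([1 / 111, 10 / 111, 100 / 111])
        assert sum(a for _, a in p.members) == pytest.approx(1.0)

    def test_shuffle_only_permutes(self):
        genomes = generate_genomes(5, 30, seed=0)
        p1 = staggered_profile(genomes, 3, seed=1)
        p2 = staggered_profile(genomes, 3, seed=2)
        assert sorted(a for _, a in p1.members) == pytest.approx(
            sorted(a for _, a in p2.members)
        )

    def test_perturb_zero_swaps_is_identity(self):
        genomes = generate_genomes(4, 30, seed=0)
        p = staggered_profile(genomes, 3, seed=0)
        assert perturb_profile(p, 0, seed=5).members == p.members

    def test_perturb_single_pair(self):
        genomes = generate_genomes(2, 30, seed=0)
        p = staggered_profile(genomes, 1, seed=0)
        q = perturb_profile(p, 1, seed=0)
        assert dict(q.members) == {
            gid: dict(p.members)[other]
            for gid, other in zip(dict(p.members), reversed(list(dict(p.members))))
        }

    def test_perturb_preserves_abundance_multiset(self):
        genomes = generate_genomes(10, 30, seed=0)
        p = staggered_profile(genomes, 4, seed=0)
        q = perturb_profile(p, 3, seed=9)
        assert sorted(a for _, a in q.members) == pytest.approx(
            sorted(a for _, a in p.members)
        )

    def test_spike_in_rescales(self):
        genomes = generate_genomes(1, 30, seed=0)
        gid = next(iter(genomes))
        p = CommunityProfile([(gid, 1.0)], genomes)
        new = generate_genomes(1, 30, seed=1, prefix="new")
        q = spike_in(p, new, 0.5)
        assert dict(q.members)[gid] == pytest.approx(0.5)
        assert dict(q.members)["new00"] == pytest.approx(0.5)
        assert sum(a for _, a in q.members) == pytest.approx(1.0)

    def test_spike_in_duplicate_id_rejected(self):
        genomes = generate_genomes(1, 30, seed=0)
        gid = next(iter(genomes))
        p = CommunityProfile([(gid, 1.0)], genomes)
        with pytest.raises(ConfigError):
            spike_in(p, {gid: "ACGT" * 10}, 0.3)

    def test_mock_series_design(self):
        series = make_mock_series(n_genomes=12, genome_length=500, seed=3)
        assert set(series) == {"mock1", "mock2", "mock3", "mock4"}
        m1, m2, m3, m4 = (series[k] for k in ("mock1", "mock2", "mock3", "mock4"))
        # inversions preserve the abundance multiset
        base = sorted(a for _, a in m1.members)
        assert sorted(a for _, a in m2.members) == pytest.approx(base)
        assert sorted(a for _, a in m3.members) == pytest.approx(base)
        # mock4 adds spike genomes absent elsewhere
        extra = set(g for g, _ in m4.members) - set(g for g, _ in m1.members)
        assert len(extra) == 2 and all(g.startswith("spike") for g in extra)
        spike_mass = sum(a for g, a in m4.members if g in extra)
        assert spike_mass == pytest.approx(0.30)


class TestSimulateReads:
    def _profile(self, n=3, length=300, seed=0, decades=1.0):
        genomes = generate_genomes(n, length, seed)
        return staggered_profile(genomes, decades, seed)

    def test_zero_reads_empty(self, tmp_path):
        p = self._profile()
        out = simulate_sample(p, ReadSimSpec(0, 50, 0.0, 1), tmp_path / "x.fasta")
        assert out.read_text() == ""

    def test_errorfree_reads_are_genome_substrings_or_revcomp(self):
        genomes = generate_genomes(1, 80, seed=5)
        gid, seq = next(iter(genomes.items()))
        p = CommunityProfile([(gid, 1.0)], genomes)
        revcomp = "".join(
            {"A": "T", "C": "G", "G": "C", "T": "A"}[c] for c in reversed(seq)
        )
        reads = list(simulate_reads(p, ReadSimSpec(30, 80, 0.0, 2)))
        assert all(r.sequence in (seq, revcomp) for r in reads)
        assert any(r.sequence == seq for r in reads)  # both strands drawn

    def test_read_counts_follow_abundances(self):
        p = self._profile(n=4, length=500, decades=1.0)
        reads = list(simulate_reads(p, ReadSimSpec(10_000, 60, 0.0, 3)))
        counts: dict[str, int] = {}
        for r in reads:  # genome of origin is the record description token
            gid = r.id.split(" ")[-1]
            counts[gid] = counts.get(gid, 0) + 1
        expected = {gid: a * 10_000 for gid, a in p.members}
        chi = stats.chisquare(
            [counts.get(g, 0) for g in expected], list(expected.values())
        )
        assert chi.pvalue > 1e-4

    def test_reproducible_files_byte_identical(self, tmp_path):
        p = self._profile()
        spec = ReadSimSpec(200, 60, 0.02, 11)
        a = simulate_sample(p, spec, tmp_path / "a.fasta")
        b = simulate_sample(p, spec, tmp_path / "b.fasta")
        assert a.read_bytes() == b.read_bytes()

    def test_error_rate_observable(self):
        genomes = generate_genomes(1, 2000, seed=5)
        gid = next(iter(genomes))
        p = CommunityProfile([(gid, 1.0)], genomes)
        reads = list(simulate_reads(p, ReadSimSpec(500, 100, 0.05, 4)))
        genome = genomes[gid]
        mismatches = total = 0
        for r in reads:
            seq = r.sequence
            # anchor by a 20-mer prefix on either strand, then count mismatches
            best = None
            for cand in (seq, "".join({"A": "T", "C": "G", "G": "C", "T": "A"}[c] for c in reversed(seq))):
                i = genome.find(cand[:20])
                if i >= 0 and i + len(cand) <= len(genome):
                    mm = sum(a != b for a, b in zip(cand, genome[i : i + len(cand)]))
                    best = mm if best is None else min(best, mm)
            if best is not None:
                mismatches += best
                total += len(seq)
        assert total > 0
        rate = mismatches / total
        assert 0.02 < rate < 0.09  # around the simulated 5%

    def test_genome_shorter_than_read_rejected(self):
        genomes = generate_genomes(1, 30, seed=0)
        gid = next(iter(genomes))
        p = CommunityProfile([(gid, 1.0)], genomes)
        with pytest.raises(ConfigError):
            list(simulate_reads(p, ReadSimSpec(5, 50, 0.0, 0)))


class TestDuplicateDataset:
    def test_concatenates_times(self, tmp_path):
        src = tmp_path / "a.fasta"
        src.write_text(">r1\nACGT\n")
        out = duplicate_dataset(src, 3, tmp_path / "a3.fasta")
        assert out.read_text() == ">r1\nACGT\n" * 3

    def test_invalid_factor_rejected(self, tmp_path):
        src = tmp_path / "a.fasta"
        src.write_text(">r1\nACGT\n")
        with pytest.raises(ConfigError):
            duplicate_dataset(src, 0, tmp_path / "out.fasta")
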