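"""Weighting, sweep-line accumulation, merge algebra, and finalization."""
from __future__ import annotations

import math

import numpy as np
import pytest

from conftest import build_small_index, dense_distance, naive_count, random_reads
from kmersweep.distance import (
    METRICS,
    WEIGHTING_SCHEMES,
    PairAccumulator,
    compute_norms,
    distance_matrix,
    finalize,
    merge_accumulators,
    sweep_partition,
    weight,
)
from kmersweep.errors import ConfigError


class TestWeight:
    @pytest.mark.parametrize(
        "f,scheme,expected",
        [
            (1, "logarithmic", 1.0),  # 1 + ln 1
            (7, "natural", 7.0),  # w = f
            (5, "boolean", 1.0),
            (math.e, "logarithmic", 2.0),
        ],
    )
    def test_examples(self, f, scheme, expected):
        assert weight(f, scheme) == pytest.approx(expected)

    def test_zero_frequency_rejected(self):
        with pytest.raises(ValueError):
            weight(0, "natural")

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ConfigError):
            weight(1, "tfidf")


class TestNorms:
    def test_single_sample_natural(self):
        idx = build_small_index({"s1": {"ACG": 2, "CGA": 3}}, 3)
        norms = compute_norms(idx, "natural")
        assert norms.sum_sq_weight[0] == pytest.approx(13.0)  # 4 + 9
        assert norms.sum_weight[0] == pytest.approx(5.0)
        assert norms.present_kmers[0] == 2

    def test_empty_index_all_zero(self):
        idx = build_small_index({"s1": {}}, 3)
        norms = compute_norms(idx, "natural")
        assert norms.sum_sq_weight[0] == 0 and norms.present_kmers[0] == 0

    def test_matches_dense_vectors(self, rng):
        tables = {f"s{i}": naive_count(random_reads(rng, 40, 30), 5) for i in range(4)}
        idx = build_small_index(tables, 5, n_partitions=3)
        for scheme in WEIGHTING_SCHEMES:
            norms = compute_norms(idx, scheme)
            for i, (sid, t) in enumerate(tables.items()):
                w = np.array([weight(f, scheme) for f in t.values()])
                assert norms.sum_sq_weight[i] == pytest.approx((w**2).sum(), rel=1e-12)
                assert norms.sum_weight[i] == pytest.approx(w.sum(), rel=1e-12)


class TestSweep:
    def test_single_record_dot_contribution(self):
        idx = build_small_index({"s1": {"ACG": 2}, "s2": {"ACG": 1}}, 3)
        acc = sweep_partition(idx.chunks[0], "natural", "cosine")
        assert acc.sums[0] == pytest.approx(2.0)  # 2*1

    def test_record_updates_exactly_its_sample_pairs(self):
        """A record {<s1,x>,<s2,y>,<s4,z>} updates pairs (s1s2),(s1s4),(s2s4)
        with x*y, x*z, y*z — and no other pair."""
        x, y, z = 3, 5, 7
        idx = build_small_index(
            {"s1": {"ACG": x}, "s2": {"ACG": y}, "s3": {}, "s4": {"ACG": z}}, 3
        )
        acc = sweep_partition(idx.chunks[0], "natural", "cosine")
        ids = idx.sample_ids
        n = len(ids)
        got = {}
        p = 0
        for i in range(n):
            for j in range(i + 1, n):
                got[(ids[i], ids[j])] = acc.sums[p]
                p += 1
        assert got[("s1", "s2")] == pytest.approx(x * y)
        assert got[("s1", "s4")] == pytest.approx(x * z)
        assert got[("s2", "s4")] == pytest.approx(y * z)
        assert got[("s1", "s3")] == got[("s2", "s3")] == got[("s3", "s4")] == 0.0

    def test_accumulated_dots_match_dense_vectors(self, rng):
        tables = {f"s{i}": naive_count(random_reads(rng, 50, 35), 5) for i in range(4)}
        idx = build_small_index(tables, 5)
        acc = sweep_partition(idx.chunks[0], "natural", "cosine")
        keys = sorted(set().union(*tables.values()))
        vecs = np.array(
            [[t.get(km, 0) for km in keys] for t in tables.values()], dtype=float
        )
        p = 0
        for i in range(4):
            for j in range(i + 1, 4):
                assert acc.sums[p] == pytest.approx(vecs[i] @ vecs[j], rel=1e-12)
                p += 1

    def test_jensenshannon_requires_totals(self):
        idx = build_small_index({"s1": {"ACG": 1}, "s2": {"ACG": 1}}, 3)
        with pytest.raises(ConfigError, match="totals"):
            sweep_partition(idx.chunks[0], "natural", "jensenshannon")


class TestMerge:
    def _accs(self, rng, n_partitions):
        tables = {f"s{i}": naive_count(random_reads(rng, 50, 35), 5) for i in range(4)}
        idx = build_small_index(tables, 5, n_partitions=n_partitions)
        return [sweep_partition(c, "natural", "cosine") for c in idx.chunks], idx

    def test_merge_identity_and_commutativity(self, rng):
        accs, _ = self._accs(rng, 2)
        single = merge_accumulators([accs[0]])
        assert np.array_equal(single.sums, accs[0].sums)
        ab = merge_accumulators([accs[0], accs[1]])
        ba = merge_accumulators([accs[1], accs[0]])
        np.testing.assert_allclose(ab.sums, ba.sums, rtol=0, atol=1e-12)

    def test_partitioned_merge_equals_single_sweep(self, rng):
        accs2, idx2 = self._accs(rng, 3)
        merged = merge_accumulators(accs2)
        tables = {
            sid: {r.kmer: dict(r.postings).get(sid) for r in idx2.iter_records()
                  if sid in dict(r.postings)}
            for sid in idx2.sample_ids
        }
        idx1 = build_small_index(tables, 5, n_partitions=1)
        whole = sweep_partition(idx1.chunks[0], "natural", "cosine")
        np.testing.assert_allclose(merged.sums, whole.sums, rtol=0, atol=1e-12)

    def test_mismatched_metric_rejected(self):
        a = PairAccumulator("cosine", "natural", ["s1", "s2"])
        b = PairAccumulator("braycurtis", "natural", ["s1", "s2"])
        with pytest.raises(ConfigError):
            merge_accumulators([a, b])


class TestFinalize:
    @pytest.mark.parametrize("metric", METRICS)
    @pytest.mark.parametrize("scheme", WEIGHTING_SCHEMES)
    def test_identical_tables_distance_zero(self, metric, scheme):
        t = {"ACG": 3, "CGA": 1, "GGG": 7}
        idx = build_small_index({"s1": dict(t), "s2": dict(t)}, 3)
        m = distance_matrix(idx, scheme, metric)
        assert abs(m.get("s1", "s2")) < 1e-9
        assert m.values[0, 0] == 0.0

    @pytest.mark.parametrize("metric", METRICS)
    def test_disjoint_tables_distance_one(self, metric):
        idx = build_small_index({"s1": {"AAA": 2}, "s2": {"CCC": 5}}, 3)
        m = distance_matrix(idx, "natural", metric)
        assert m.get("s1", "s2") == pytest.approx(1.0, abs=1e-12)

    def test_hand_worked_cosine(self):
        # s1=(1,2), s2=(2,1): D=4, M1=M2=sqrt(5), d = 1 - 4/5 = 0.2
        idx = build_small_index(
            {"s1": {"AAA": 1, "CCC": 2}, "s2": {"AAA": 2, "CCC": 1}}, 3
        )
        m = distance_matrix(idx, "natural", "cosine")
        assert m.get("s1", "s2") == pytest.approx(0.2, abs=1e-12)

    @pytest.mark.parametrize("metric", METRICS)
    def test_empty_sample_conventions(self, metric):
        idx = build_small_index(
            {"s1": {"ACG": 2}, "e1": {}, "e2": {}}, 3
        )
        m = distance_matrix(idx, "natural", metric)
        assert m.get("s1", "e1") == 1.0
        assert m.get("e1", "e2") == 0.0
        assert np.all(np.diag(m.values) == 0.0)


class TestPipelineEquivalence:
    """Full index+sweep pipeline vs brute-force dense vectors."""

    @pytest.mark.parametrize("k", [5, 11])
    def test_matches_dense_for_all_scheme_metric_pairs(self, rng, k):
        reads = {f"s{i}": random_reads(rng, 80, 50, "ACGTN") for i in range(4)}
        tables = {sid: naive_count(r, k) for sid, r in reads.items()}
        idx = build_small_index(tables, k, n_partitions=3)
        for scheme in WEIGHTING_SCHEMES:
            for metric in METRICS:
                got = distance_matrix(idx, scheme, metric)
                expected = dense_distance(list(tables.values()), scheme, metric)
                np.testing.assert_allclose(
                    got.values, expected, rtol=0, atol=1e-9,
                    err_msg=f"{scheme}/{metric}",
                )

    def test_cosine_scale_invariance_under_read_duplication(self, rng):
        """Duplicating every read scales the vector but not natural-weight cosine."""
        reads = random_reads(rng, 200, 40)
        other = random_reads(rng, 150, 40)
        t1 = naive_count(reads, 7)
        t1_dup = naive_count(reads * 3, 7)
        t2 = naive_count(other, 7)
        d_orig = distance_matrix(
            build_small_index({"a": t1, "b": t2}, 7), "natural", "cosine"
        ).get("a", "b")
        d_dup = distance_matrix(
            build_small_index({"a": t1_dup, "b": t2}, 7), "natural", "cosine"
        ).get("a", "b")
        assert abs(d_orig - d_dup) < 1e-9

    def test_worker_count_never_changes_result(self, rng):
        tables = {f"s{i}": naive_count(random_reads(rng, 60, 40), 7) for i in range(4)}
        idx = build_small_index(tables, 7, n_partitions=4)
        serial = distance_matrix(idx, "logarithmic", "cosine", n_workers=1)
        parallel = distance_matrix(idx, "logarithmic", "cosine", n_workers=4)
        np.testing.assert_allclose(serial.values, parallel.values, rtol=0, atol=1e-12)

    def test_single_sample_matrix_is_zero(self, rng):
        idx = build_small_index({"only": naive_count(random_reads(rng, 30, 40), 7)}, 7)
        m = distance_matrix(idx, "natural", "cosine")
        assert m.values.shape == (1, 1) and m.values[0, 0] == 0.0


class TestMatrixIO:
    def test_tsv_round_trip(self, tmp_path, rng):
        tables = {f"s{i}": naive_count(random_reads(rng, 40, 40), 7) for i in range(3)}
        m = distance_matrix(build_small_index(tables, 7), "logarithmic", "cosine")
        path = tmp_path / "m.tsv"
        m.to_tsv(path)
        from kmersweep.distance import DistanceMatrix

        back = DistanceMatrix.from_tsv(path)
        assert back.sample_ids == m.sample_ids
        np.testing.assert_allclose(back.values, m.values, rtol=0, atol=1e-10)
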