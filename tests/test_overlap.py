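"""Resampling null for shared candidate genes: enumeration oracles,
analytic mean, empirical p conventions, NS enrichment and the
hypergeometric cross-check."""

import numpy as np
import pytest
from scipy import stats

import convergescan as cs


def two_gene_universe():
    return cs.OrthologUniverse(
        species_ids=("s1", "s2"),
        annotated={"s1": frozenset("ab"), "s2": frozenset("ab")},
    )


class TestResampleOverlap:
    def test_two_species_enumeration(self):
        # both draw 1 of 2 fully shared genes: overlap 1 with prob 1/2
        null = cs.resample_overlap(
            two_gene_universe(), {"s1": 1, "s2": 1}, ("s1", "s2"),
            n_iter=4000, seed=0,
        )
        assert set(np.unique(null)) <= {0, 1}
        assert null.mean() == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(4000))

    def test_zero_size_gives_all_zero(self, small_universe):
        null = cs.resample_overlap(
            small_universe, {"A": 0, "B": 5, "C": 5}, ("A", "B", "C"),
            n_iter=50, seed=1,
        )
        assert (null == 0).all()

    def test_full_draw_recovers_shared_core(self, small_universe):
        sizes = {s: small_universe.size(s) for s in small_universe.species_ids}
        null = cs.resample_overlap(
            small_universe, sizes, small_universe.species_ids, n_iter=20, seed=2
        )
        assert (null == len(small_universe.shared_core)).all()

    def test_null_counts_bounded_by_core(self, small_universe):
        null = cs.resample_overlap(
            small_universe, {"A": 60, "B": 60, "C": 60}, ("A", "B", "C"),
            n_iter=300, seed=3,
        )
        assert null.min() >= 0
        assert null.max() <= len(small_universe.shared_core)

    def test_fixed_seed_bit_identical(self, small_universe):
        a = cs.resample_overlap(small_universe, {"A": 30, "B": 30, "C": 30},
                                ("A", "B", "C"), n_iter=100, seed=42)
        b = cs.resample_overlap(small_universe, {"A": 30, "B": 30, "C": 30},
                                ("A", "B", "C"), n_iter=100, seed=42)
        assert (a == b).all()

    def test_oversized_draw_rejected(self, small_universe):
        with pytest.raises(ValueError):
            cs.resample_overlap(small_universe, {"A": 1000, "B": 5, "C": 5},
                                ("A", "B", "C"), n_iter=10, seed=0)


class TestAnalyticExpectation:
    def test_study_scale_configuration(self):
        exp = cs.expected_overlap_analytic(
            12485, (617, 2894, 5944), (15909, 16088, 16047)
        )
        assert exp == pytest.approx(32.26, abs=0.01)

    def test_full_draw_returns_core(self):
        assert cs.expected_overlap_analytic(7, (10, 12), (10, 12)) == 7.0

    def test_matches_enumeration(self):
        assert cs.expected_overlap_analytic(2, (1, 1), (2, 2)) == pytest.approx(0.5)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            cs.expected_overlap_analytic(1, (0,), (0,))


class TestEmpiricalP:
    def test_sixteen_in_ten_thousand(self):
        null = np.zeros(10000, dtype=int)
        null[:16] = 27
        assert cs.empirical_p(null, 27) == pytest.approx(0.0016)

    def test_extremes_and_monotonicity(self):
        null = np.array([1, 2, 3, 4])
        assert cs.empirical_p(null, 5) == 0.0
        assert cs.empirical_p(null, 1) == 1.0
        assert cs.empirical_p(null, 0) == 1.0
        ps = [cs.empirical_p(null, o) for o in range(6)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestOverRepresentation:
    def test_study_values(self):
        assert cs.over_representation(27, 14.77) == pytest.approx(82.8, abs=0.05)
        assert cs.over_representation(565, 447.3) == pytest.approx(26.3, abs=0.05)

    def test_null_excess_is_zero(self):
        assert cs.over_representation(10, 10.0) == 0.0

    def test_nonpositive_expectation_rejected(self):
        with pytest.raises(ValueError):
            cs.over_representation(3, 0.0)


class TestNsEnrichment:
    def test_enumerated_small_case(self):
        # 2 of 4 universe genes carry NS; draw 2; both NS: p = 1/6
        p = cs.ns_enrichment_test(2, 2, 4, 2, n_iter=30000, seed=5)
        assert p == pytest.approx(1 / 6, abs=0.01)

    def test_whole_universe_draw_is_certain(self):
        assert cs.ns_enrichment_test(10, 6, 10, 6, n_iter=100, seed=0) == 1.0

    def test_study_scale_twi_enrichment_significant(self):
        p = cs.ns_enrichment_test(581, 488, 12485, 8681, n_iter=10000, seed=6)
        assert p < 0.05

    def test_size_violations_rejected(self):
        with pytest.raises(ValueError):
            cs.ns_enrichment_test(3, 4, 10, 5)
        with pytest.raises(ValueError):
            cs.ns_enrichment_test(11, 2, 10, 5)


class TestHypergeomPairwise:
    def test_reduces_to_classical_hypergeometric(self):
        n, k1, k2 = 12, 5, 7
        expected, tail = cs.hypergeom_pairwise(n, k1, k2, n, n)
        assert expected == pytest.approx(k1 * k2 / n)
        for k in range(0, min(k1, k2) + 1):
            assert tail(k) == pytest.approx(
                stats.hypergeom.sf(k - 1, n, k1, k2), abs=1e-10
            )

    def test_two_gene_enumeration(self):
        expected, tail = cs.hypergeom_pairwise(2, 1, 1, 2, 2)
        assert expected == pytest.approx(0.5)
        assert tail(1) == pytest.approx(0.5)
        assert tail(0) == 1.0

    def test_matches_pairwise_resampling(self):
        rng = np.random.default_rng(7)
        for _ in range(3):
            big1, big2 = int(rng.integers(20, 40)), int(rng.integers(20, 40))
            s12 = int(rng.integers(5, min(big1, big2)))
            n1, n2 = int(rng.integers(1, big1)), int(rng.integers(1, big2))
            shared = [f"g{i}" for i in range(s12)]
            uni = cs.OrthologUniverse(
                species_ids=("s1", "s2"),
                annotated={
                    "s1": frozenset(shared + [f"a{i}" for i in range(big1 - s12)]),
                    "s2": frozenset(shared + [f"b{i}" for i in range(big2 - s12)]),
                },
            )
            null = cs.resample_overlap(uni, {"s1": n1, "s2": n2}, ("s1", "s2"),
                                       n_iter=3000, seed=8)
            expected, tail = cs.hypergeom_pairwise(s12, n1, n2, big1, big2)
            se = null.std(ddof=0) / np.sqrt(null.size)
            assert null.mean() == pytest.approx(expected, abs=max(3 * se, 1e-9))
            k = int(np.median(null)) + 1
            assert (null >= k).mean() == pytest.approx(tail(k), abs=0.03)


class TestConvergenceSuite:
    def test_result_count_and_contents(self, small_universe, small_tables, small_config):
        flagged = {
            s: cs.annotate_scan_table(t, small_config.factor_names)
            for s, t in small_tables.items()
        }
        coll = cs.build_candidate_sets(flagged, small_universe, small_config.factor_names)
        results = cs.run_convergence_suite(coll, small_universe, n_iter=200, seed=9)
        # (1 outlier + 2 factors) x (1 triple + 3 pairs)
        assert len(results) == 3 * 4
        for r in results:
            assert 0.0 <= r.empirical_p <= 1.0
            assert min(r.null_counts) <= r.null_mean <= max(r.null_counts)
            if r.over_representation is not None:
                assert r.over_representation == pytest.approx(
                    100 * (r.observed / r.null_mean - 1)
                )

    def test_planted_factor_significant_across_all_species(
        self, small_universe, small_tables, small_config
    ):
        flagged = {
            s: cs.annotate_scan_table(t, small_config.factor_names)
            for s, t in small_tables.items()
        }
        coll = cs.build_candidate_sets(flagged, small_universe, small_config.factor_names)
        results = cs.run_convergence_suite(coll, small_universe, n_iter=400, seed=10)
        by_key = {(r.analysis, r.species_subset): r for r in results}
        planted = by_key[("F1", ("A", "B", "C"))]
        assert planted.observed >= small_config.n_planted_convergent * 0.8
        assert planted.empirical_p < 0.05
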