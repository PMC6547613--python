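"""Overlap statistics: Jaccard, permutation null, exact multi-set test."""

import math

import numpy as np
import pytest
from scipy import stats

from degoverlap import (
    ExperimentDE, GeneUniverse, InvalidArgumentError, MembershipError,
    analytic_null_moments, directional_suite, exact_multiset_test, jaccard,
    make_universe, multiset_intersection_pmf, permutation_overlap,
    triple_overlap, venn_counts,
)
from _oracles import enumerate_intersection_distribution, enumerate_jaccard_moments


class TestJaccard:
    def test_half_overlap(self):
        assert jaccard({"g1", "g2", "g3"}, {"g2", "g3", "g4"}) == 0.5

    def test_identity_and_disjoint(self):
        assert jaccard({"a", "b"}, {"a", "b"}) == 1.0
        assert jaccard({"a"}, {"b"}) == 0.0

    def test_both_empty_is_zero_by_convention(self):
        assert jaccard(set(), set()) == 0.0


class TestAnalyticNullMoments:
    def test_empty_set(self):
        assert analytic_null_moments(0, 5, 10) == (0.0, 0.0)

    def test_full_universe_degenerate(self):
        mean, sd = analytic_null_moments(10, 10, 10)
        assert mean == pytest.approx(1.0) and sd == pytest.approx(0.0)

    def test_matches_full_enumeration(self):
        # every pair of subset placements enumerated: C(10,4)*C(10,5) pairs
        mean, sd = analytic_null_moments(4, 5, 10)
        e_mean, e_sd = enumerate_jaccard_moments(4, 5, 10)
        assert mean == pytest.approx(e_mean, abs=1e-12)
        assert sd == pytest.approx(e_sd, abs=1e-12)


@pytest.fixture(scope="module")
def universe():
    return make_universe(1000, seed=0)


class TestPermutationOverlap:
    def test_identical_sets_minimal_empirical_p(self, universe):
        a = frozenset(list(universe)[:50])
        res = permutation_overlap(a, a, universe, n_perm=10_000, seed=1)
        assert res.jaccard == 1.0
        # no permuted size-50 subset attains J=1 except the one exact set
        assert res.empirical_p == pytest.approx(1 / 10_001)

    def test_degenerate_full_universe(self, universe):
        full = universe.as_set()
        res = permutation_overlap(full, full, universe, n_perm=50, seed=0)
        assert res.null_sd == 0.0
        assert res.null_mean == 1.0 == res.jaccard
        assert math.isnan(res.z_score)
        assert res.empirical_p == 1.0

    def test_null_mean_agrees_with_analytic_moments(self):
        universe = make_universe(20_000, seed=3)
        rng = np.random.default_rng(3)
        ids = np.array(universe.identifiers)
        a = frozenset(rng.choice(ids, 1687, replace=False))
        b = frozenset(rng.choice(ids, 800, replace=False))
        res = permutation_overlap(a, b, universe, n_perm=10_000, seed=5)
        mean, sd = analytic_null_moments(1687, 800, 20_000)
        assert abs(res.null_mean - mean) < 3 * sd / math.sqrt(10_000)

    def test_deterministic_given_seed(self, universe):
        ids = list(universe)
        a, b = set(ids[:100]), set(ids[50:200])
        r1 = permutation_overlap(a, b, universe, n_perm=500, seed=9)
        r2 = permutation_overlap(a, b, universe, n_perm=500, seed=9)
        assert r1 == r2
        r3 = permutation_overlap(a, b, universe, n_perm=500, seed=10)
        assert r3.null_mean != r1.null_mean

    def test_membership_error_lists_offenders(self, universe):
        with pytest.raises(MembershipError, match="NOTGENE"):
            permutation_overlap({"NOTGENE"}, set(), universe)

    def test_empty_focal_set(self, universe):
        b = set(list(universe)[:30])
        res = permutation_overlap(set(), b, universe, n_perm=100, seed=0)
        assert res.jaccard == 0.0 and res.null_sd == 0.0
        assert math.isnan(res.z_score) and res.empirical_p == 1.0

    def test_randomize_both_still_calibrated(self, universe):
        ids = list(universe)
        a, b = set(ids[:80]), set(ids[900:980])
        res = permutation_overlap(a, b, universe, n_perm=2000, seed=4, randomize="both")
        mean, sd = analytic_null_moments(80, 80, 1000)
        assert abs(res.null_mean - mean) < 4 * sd / math.sqrt(2000)

    def test_shared_genes_membership(self, universe):
        ids = list(universe)
        a, b = set(ids[:10]), set(ids[5:15])
        res = permutation_overlap(a, b, universe, n_perm=10, seed=0)
        assert set(res.shared_genes) == a & b
        assert res.intersection_size == 5 and res.union_size == 15


class TestExactMultisetTest:
    def test_k2_matches_enumeration_and_closed_form(self, tiny_universe):
        ids = list(tiny_universe)
        a, b = set(ids[:4]), set(ids[2:7])  # sizes 4, 5; observed = 2
        res = exact_multiset_test([a, b], tiny_universe)
        pmf = enumerate_intersection_distribution([4, 5], 10)
        closed = stats.hypergeom.pmf(np.arange(5), 10, 4, 5)
        assert np.array_equal(res.pmf_support, closed)
        assert res.exact_p == pytest.approx(pmf[2:].sum(), abs=1e-12)

    def test_k2_observed_at_maximum(self, tiny_universe):
        ids = list(tiny_universe)
        a = set(ids[:4])
        b = set(ids[:5])
        res = exact_multiset_test([a, b], tiny_universe)  # observed 4 of max 4
        pmf = enumerate_intersection_distribution([4, 5], 10)
        assert res.exact_p == pytest.approx(pmf[4:].sum(), abs=1e-12)

    @pytest.mark.parametrize("N,sizes", [
        (6, (3, 3, 3)), (7, (3, 5, 2)), (8, (4, 4, 2)), (10, (4, 5, 3)),
        (5, (5, 5, 5)), (6, (0, 3, 2)),
    ])
    def test_k3_pmf_matches_enumeration(self, N, sizes):
        pmf = multiset_intersection_pmf(sizes, N)
        oracle = enumerate_intersection_distribution(list(sizes), N)
        assert np.allclose(pmf, oracle, atol=1e-12)

    def test_k3_all_sets_equal_universe(self):
        u = make_universe(6, 0)
        full = u.as_set()
        res = exact_multiset_test([full, full, full], u)
        assert res.observed == 6
        assert res.exact_p == pytest.approx(1.0)
        assert res.expected == pytest.approx(6.0)

    def test_empty_list_gives_p_one(self, tiny_universe):
        ids = list(tiny_universe)
        res = exact_multiset_test([set(), set(ids[:3]), set(ids[:4])], tiny_universe)
        assert res.observed == 0 and res.exact_p == 1.0

    def test_k1_rejected(self, tiny_universe):
        with pytest.raises(InvalidArgumentError):
            exact_multiset_test([set(list(tiny_universe)[:3])], tiny_universe)

    def test_pmf_normalized_across_configs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            N = int(rng.integers(20, 201))
            k = int(rng.integers(2, 6))
            sizes = rng.integers(0, N + 1, size=k)
            pmf = multiset_intersection_pmf(sizes, N)
            assert abs(pmf.sum() - 1.0) < 1e-9

    def test_monotone_tail_in_observed(self):
        pmf = multiset_intersection_pmf((40, 50, 30), 200)
        tails = pmf[::-1].cumsum()[::-1]
        assert np.all(np.diff(tails) <= 1e-15)

    def test_paper_scale_tail_does_not_underflow(self):
        # triple overlap at study scale: tiny but strictly positive p
        pmf = multiset_intersection_pmf((1687, 800, 1200), 20_000)
        tail = pmf[23:].sum()
        assert 0 < tail < 1
        assert abs(pmf.sum() - 1.0) < 1e-9

    def test_fold_enrichment_and_expected(self, tiny_universe):
        ids = list(tiny_universe)
        res = exact_multiset_test([set(ids[:4]), set(ids[:5])], tiny_universe)
        assert res.expected == pytest.approx(10 * 0.4 * 0.5)
        assert res.fold_enrichment == pytest.approx(4 / 2.0)


def _exp(name, over, under, universe):
    return ExperimentDE(name=name, over=frozenset(over), under=frozenset(under),
                        universe=universe, thresholds=(1.5, 0.05))


class TestDirectionalSuite:
    def test_planted_concordant_overlap_detected(self, universe):
        ids = list(universe)
        shared_o, shared_u = set(ids[:30]), set(ids[30:55])
        a = _exp("a", shared_o | set(ids[100:170]), shared_u | set(ids[200:250]), universe)
        b = _exp("b", shared_o | set(ids[300:350]), shared_u | set(ids[400:440]), universe)
        comp = directional_suite(a, b, universe, n_perm=999, seed=0)
        assert comp.significant[("over", "over")]
        assert comp.significant[("under", "under")]
        assert not comp.significant[("over", "under")]
        assert not comp.significant[("under", "over")]

    def test_empty_direction_handled(self, universe):
        ids = list(universe)
        a = _exp("a", ids[:40], [], universe)
        b = _exp("b", ids[20:60], ids[100:140], universe)
        comp = directional_suite(a, b, universe, n_perm=99, seed=1)
        res = comp.results[("under", "under")]
        assert res.jaccard == 0.0 and math.isnan(res.z_score)
        assert not comp.significant[("under", "under")]

    def test_swap_preserves_concordant_intersections(self, universe):
        ids = list(universe)
        a = _exp("a", ids[:50], ids[60:100], universe)
        b = _exp("b", ids[30:80], ids[90:130], universe)
        ab = directional_suite(a, b, universe, n_perm=99, seed=2)
        ba = directional_suite(b, a, universe, n_perm=99, seed=2)
        for pair in (("over", "over"), ("under", "under")):
            assert (ab.results[pair].intersection_size
                    == ba.results[pair].intersection_size)


class TestTripleOverlap:
    def test_identical_lists(self):
        u = make_universe(100, 0)
        genes = set(list(u)[:10])
        exps = [_exp(n, genes, [], u) for n in "abc"]
        tri = triple_overlap(*exps, direction="over", universe=u)
        assert tri.result.observed == 10
        assert set(tri.shared_genes) == genes
        # p is the minimum attainable over the support
        tails = tri.result.pmf_support[::-1].cumsum()[::-1]
        assert tri.result.exact_p == pytest.approx(tails[-1])

    def test_any_empty_list(self):
        u = make_universe(50, 0)
        exps = [_exp("a", list(u)[:5], [], u), _exp("b", [], [], u),
                _exp("c", list(u)[:5], [], u)]
        tri = triple_overlap(*exps, direction="over", universe=u)
        assert tri.result.observed == 0 and tri.result.exact_p == 1.0
        assert tri.shared_genes == ()


def test_venn_counts_regions():
    sets = {"A": {"1", "2", "3"}, "B": {"2", "3", "4"}, "C": {"3", "5"}}
    table = venn_counts(sets)
    assert len(table) == 7
    lookup = {tuple(r[n] for n in "ABC"): r["count"] for _, r in table.iterrows()}
    assert lookup[(True, True, True)] == 1     # {3}
    assert lookup[(True, True, False)] == 1    # {2}
    assert lookup[(False, False, True)] == 1   # {5}
    assert lookup[(True, False, False)] == 1   # {1}
    assert sum(lookup.values()) == 5
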