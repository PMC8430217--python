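import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import normalized_mutual_info_score

from ssnmtf.io import ComplexCover
from ssnmtf.metrics import (
    EnrichmentQuery,
    count_matched,
    enrichment_proportions,
    evaluate,
    hypergeom_pvalue,
    mmr,
    neighborhood_affinity,
    nmi_cover,
    nmi_partition,
    precision_recall_f1,
    sn_ppv_acc,
)


def exact_hypergeom_tail(t, k, f, q):
    """Upper-tail hypergeometric probability in exact rational arithmetic."""
    total = Fraction(0)
    for x in range(q, f + 1):
        if k - x < 0 or k - x > t - f:
            continue
        total += Fraction(math.comb(f, x) * math.comb(t - f, k - x), math.comb(t, k))
    return total


class TestNeighborhoodAffinity:
    def test_identical_sets_score_one(self):
        assert neighborhood_affinity({"a", "b", "c"}, {"a", "b", "c"}) == 1.0

    def test_half_overlap(self):
        assert neighborhood_affinity({"a", "b"}, {"a", "b", "c", "d"}) == 0.5

    def test_disjoint_sets_score_zero(self):
        assert neighborhood_affinity({"a"}, {"b"}) == 0.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            neighborhood_affinity(set(), {"a"})

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.sets(st.integers(0, 15), min_size=1, max_size=8),
        st.sets(st.integers(0, 15), min_size=1, max_size=8),
    )
    def test_symmetry_and_identity_characterization(self, p, g):
        na = neighborhood_affinity(p, g)
        assert na == neighborhood_affinity(g, p)
        assert 0.0 <= na <= 1.0
        assert (na == 1.0) == (p == g)


class TestPrecisionRecallF1:
    def test_perfect_prediction(self):
        cover = ComplexCover(complexes=[{"a", "b", "c"}, {"d", "e", "f"}])
        assert precision_recall_f1(cover, cover) == (1.0, 1.0, 1.0)

    def test_half_matched(self):
        pred = ComplexCover(complexes=[{"a", "b", "c"}, {"x", "y", "z"}])
        ref = ComplexCover(complexes=[{"a", "b", "c"}, {"q", "r", "s"}])
        assert precision_recall_f1(pred, ref) == (0.5, 0.5, 0.5)

    def test_strict_threshold_all_zero_with_f1_convention(self):
        pred = ComplexCover(complexes=[{"a", "b"}])
        ref = ComplexCover(complexes=[{"a", "b", "c"}])
        p, r, f1 = precision_recall_f1(pred, ref, threshold=1.0)
        assert (p, r, f1) == (0.0, 0.0, 0.0)

    def test_swapping_covers_swaps_precision_and_recall(self, rng):
        pred = ComplexCover(complexes=[{"a", "b", "c"}, {"c", "d", "e"}, {"x", "y"}])
        ref = ComplexCover(complexes=[{"a", "b"}, {"d", "e", "f"}])
        p1, r1, _ = precision_recall_f1(pred, ref)
        p2, r2, _ = precision_recall_f1(ref, pred)
        assert (p1, r1) == (r2, p2)


class TestSnPpvAcc:
    def test_exact_disjoint_match(self):
        cover = ComplexCover(complexes=[{"a", "b", "c"}, {"d", "e", "f"}])
        sn, ppv, acc = sn_ppv_acc(cover, cover)
        assert (sn, ppv, acc) == (1.0, 1.0, 1.0)

    def test_merged_prediction(self):
        pred = ComplexCover(complexes=[{"a", "b", "c", "d"}])
        ref = ComplexCover(complexes=[{"a", "b"}, {"c", "d"}])
        sn, ppv, acc = sn_ppv_acc(pred, ref)
        assert sn == 1.0
        assert ppv == 0.5
        assert acc == pytest.approx(math.sqrt(0.5))

    def test_no_shared_proteins(self):
        pred = ComplexCover(complexes=[{"a", "b"}])
        ref = ComplexCover(complexes=[{"x", "y"}])
        assert sn_ppv_acc(pred, ref) == (0.0, 0.0, 0.0)

    def test_acc_is_geometric_mean(self, rng):
        for _ in range(5):
            pred = ComplexCover(
                complexes=[set(rng.choice(20, size=4, replace=False).tolist()) for _ in range(3)]
            )
            ref = ComplexCover(
                complexes=[set(rng.choice(20, size=5, replace=False).tolist()) for _ in range(3)]
            )
            sn, ppv, acc = sn_ppv_acc(pred, ref)
            assert acc**2 == pytest.approx(sn * ppv, abs=1e-12)
            assert 0 <= sn <= 1 and 0 <= ppv <= 1


class TestMMR:
    def test_perfect_prediction_both_modes(self):
        cover = ComplexCover(complexes=[{"a", "b", "c"}, {"d", "e"}])
        assert mmr(cover, cover) == 1.0
        assert mmr(cover, cover, strict_matching=True) == 1.0

    def test_one_reference_unmatched(self):
        ref = ComplexCover(complexes=[{"a", "b", "c"}, {"d", "e", "f"}])
        pred = ComplexCover(complexes=[{"a", "b", "c"}])
        assert mmr(pred, ref) == 0.5

    def test_strict_mode_never_exceeds_default(self, rng):
        universe = [f"p{i}" for i in range(12)]
        for trial in range(10):
            pred = ComplexCover(
                complexes=[
                    set(rng.choice(universe, size=rng.integers(2, 5), replace=False))
                    for _ in range(rng.integers(1, 5))
                ]
            )
            ref = ComplexCover(
                complexes=[
                    set(rng.choice(universe, size=rng.integers(2, 5), replace=False))
                    for _ in range(rng.integers(1, 5))
                ]
            )
            assert mmr(pred, ref, strict_matching=True) <= mmr(pred, ref) + 1e-12

    def test_strict_mode_equals_exhaustive_assignment(self, rng):
        from ssnmtf.metrics import na_matrix

        universe = [f"p{i}" for i in range(10)]
        for trial in range(5):
            pred = ComplexCover(
                complexes=[
                    set(rng.choice(universe, size=3, replace=False)) for _ in range(3)
                ]
            )
            ref = ComplexCover(
                complexes=[
                    set(rng.choice(universe, size=3, replace=False)) for _ in range(4)
                ]
            )
            na = na_matrix(pred, ref)
            best = 0.0
            n_p, n_r = na.shape
            for perm in itertools.permutations(range(n_r), min(n_p, n_r)):
                best = max(best, sum(na[i, j] for i, j in enumerate(perm)))
            assert mmr(pred, ref, strict_matching=True) == pytest.approx(best / n_r)


class TestNMIPartition:
    def test_identical_partitions(self):
        labels = [0, 0, 1, 1, 2, 2]
        assert nmi_partition(labels, labels) == pytest.approx(1.0)

    def test_single_block_against_anything_is_zero(self):
        assert nmi_partition([0] * 6, [0, 0, 1, 1, 2, 2]) == 0.0

    def test_matches_sklearn_on_random_labelings(self, rng):
        for _ in range(10):
            a = rng.integers(0, 3, size=12)
            b = rng.integers(0, 4, size=12)
            want = normalized_mutual_info_score(a, b)
            assert nmi_partition(a, b) == pytest.approx(want, abs=1e-10)

    def test_label_permutation_invariance(self, rng):
        a = rng.integers(0, 3, size=15)
        b = rng.integers(0, 3, size=15)
        perm = {0: 2, 1: 0, 2: 1}
        assert nmi_partition(a, b) == pytest.approx(
            nmi_partition([perm[x] for x in a], b)
        )

    def test_cover_inputs_with_singleton_padding(self):
        a = [{"x", "y"}, {"z"}]
        b = [{"x", "y"}, {"z"}]
        assert nmi_partition(a, b, universe=["x", "y", "z", "w"]) == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            nmi_partition([], [])


class TestNMICover:
    def test_identical_covers_score_one(self):
        uni = [f"v{i}" for i in range(10)]
        cover = [{"v0", "v1", "v2"}, {"v2", "v3", "v4", "v5"}, {"v6", "v7"}]
        assert nmi_cover(cover, cover, universe=uni) == pytest.approx(1.0)

    def test_degraded_cover_scores_less(self):
        uni = [f"v{i}" for i in range(12)]
        truth = [set(uni[:6]), set(uni[6:])]
        noisy = [set(uni[:4]) | {"v7"}, set(uni[4:6]) | set(uni[8:])]
        score = nmi_cover(noisy, truth, universe=uni)
        assert 0.0 <= score < 1.0

    def test_bounded_and_symmetric(self, rng):
        uni = [f"v{i}" for i in range(10)]
        a = [set(rng.choice(uni, size=4, replace=False)) for _ in range(3)]
        b = [set(rng.choice(uni, size=5, replace=False)) for _ in range(2)]
        s1 = nmi_cover(a, b, universe=uni)
        s2 = nmi_cover(b, a, universe=uni)
        assert s1 == pytest.approx(s2)
        assert 0.0 <= s1 <= 1.0


class TestHypergeometric:
    def test_q_zero_gives_one(self):
        assert hypergeom_pvalue(EnrichmentQuery(t=100, k_c=10, f=5, q=0)) == 1.0

    def test_small_exact_case(self):
        # C(2,2) * C(3,0) / C(5,2) = 1/10
        q = EnrichmentQuery(t=5, k_c=2, f=2, q=2)
        assert hypergeom_pvalue(q) == pytest.approx(0.1)

    @pytest.mark.parametrize(
        "t,k,f,q",
        [(100, 10, 10, 10), (50, 8, 20, 3), (30, 5, 12, 1), (200, 15, 40, 7)],
    )
    def test_matches_exact_rational_sum(self, t, k, f, q):
        got = hypergeom_pvalue(EnrichmentQuery(t=t, k_c=k, f=f, q=q))
        want = float(exact_hypergeom_tail(t, k, f, q))
        assert got == pytest.approx(want, abs=1e-12)

    def test_monotone_nonincreasing_in_q(self):
        vals = [
            hypergeom_pvalue(EnrichmentQuery(t=60, k_c=10, f=25, q=q))
            for q in range(0, 11)
        ]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_invalid_query_rejected(self):
        with pytest.raises(ValueError):
            EnrichmentQuery(t=10, k_c=5, f=3, q=4)


class TestEnrichmentProportions:
    def test_all_insignificant(self):
        out = enrichment_proportions([1.0, 1.0, 1.0], [1e-10, 0.01])
        assert out["cumulative"] == [0.0, 0.0]

    def test_hand_counted_cumulative(self):
        out = enrichment_proportions([1e-12, 1e-5, 0.5], [1e-10, 0.01])
        assert out["cumulative"] == pytest.approx([1 / 3, 2 / 3])
        assert out["interval"] == pytest.approx([1 / 3, 1 / 3])

    def test_unsorted_thresholds_canonicalized(self):
        out = enrichment_proportions([0.005], [0.01, 1e-10])
        assert out["thresholds"] == [1e-10, 0.01]
        assert out["cumulative"] == [0.0, 1.0]


class TestCountMatchedAndReport:
    def test_count_matched_identity(self):
        cover = ComplexCover(complexes=[{"a", "b", "c"}, {"d", "e", "f"}])
        assert count_matched(cover, cover) == 2

    def test_count_matched_disjoint(self):
        a = ComplexCover(complexes=[{"a", "b"}])
        b = ComplexCover(complexes=[{"x", "y"}])
        assert count_matched(a, b) == 0

    def test_count_matched_at_threshold_boundary(self):
        pred = ComplexCover(complexes=[{"a", "b"}])
        ref = ComplexCover(complexes=[{"a", "b", "c", "d"}])
        assert count_matched(pred, ref) == 1  # NA = 0.5 >= 0.25

    def test_report_identities(self):
        pred = ComplexCover(complexes=[{"a", "b", "c"}, {"d", "e", "f"}, {"x", "y", "z"}])
        ref = ComplexCover(complexes=[{"a", "b", "c"}, {"d", "e", "q"}])
        rep = evaluate(pred, ref)
        assert rep.acc**2 == pytest.approx(rep.sn * rep.ppv, abs=1e-12)
        assert rep.n_predicted == 3
        for val in (rep.precision, rep.recall, rep.f1, rep.sn, rep.ppv, rep.acc, rep.mmr):
            assert 0.0 <= val <= 1.0
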