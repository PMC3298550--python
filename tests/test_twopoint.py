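"""Two-point estimation: Kosambi pair, achiasmatic MLE, sex-specific MLE."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tigmap import (GenotypeMatrix, PairCounts, count_pair_classes,
                    estimate_r_achiasmatic, estimate_r_sexspecific, kosambi,
                    kosambi_inverse, pairwise_estimates)
from tigmap.twopoint import CLASS_NAMES, sexspecific_class_probs


# ----------------------------------------------------------------------
# Independent oracles
# ----------------------------------------------------------------------

def achiasmatic_grid_mle(counts: PairCounts, step=1e-4):
    """Grid maximisation of the achiasmatic multinomial likelihood."""
    r = np.arange(step, 0.5, step)
    arr = counts.as_array()
    probs = np.stack([(1 - r) / 4, r / 4, np.zeros_like(r), r / 4,
                      (1 - r) / 2, r / 4, np.zeros_like(r), r / 4,
                      (1 - r) / 4])
    keep = [i for i, name in enumerate(CLASS_NAMES)
            if name not in ("AAbb", "aaBB")]
    ll = (arr[keep, None] * np.log(probs[keep])).sum(axis=0)
    candidates = np.concatenate([[0.0, 0.5], r[[np.argmax(ll)]]])

    def loglik(x):
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.array([(1 - x) / 4, x / 4, 0, x / 4, (1 - x) / 2,
                          x / 4, 0, x / 4, (1 - x) / 4])
            terms = np.where(arr[keep] > 0,
                             arr[keep] * np.log(p[keep]), 0.0)
        return terms.sum()

    return min(candidates, key=lambda x: (-loglik(x), x))


def sexspecific_grid_mle(counts: PairCounts, step=1e-3):
    grid = np.arange(0.0, 0.5 + step / 2, step)
    U, V = np.meshgrid(grid, grid, indexing="ij")
    p = sexspecific_class_probs(U, V)
    arr = counts.as_array()
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(arr == 0, 0.0, arr * np.log(p)).sum(axis=-1)
    i, j = np.unravel_index(np.argmax(ll), ll.shape)
    return min(U[i, j], V[i, j]), max(U[i, j], V[i, j])


# ----------------------------------------------------------------------
# Kosambi map function
# ----------------------------------------------------------------------

class TestKosambi:
    def test_zero(self):
        assert kosambi(0.0) == 0.0
        assert kosambi_inverse(0.0) == 0.0

    def test_known_value(self):
        assert kosambi(0.2) == pytest.approx(21.18, abs=0.01)

    def test_domain_errors(self):
        for bad in (0.5, 0.7, -0.01):
            with pytest.raises(ValueError):
                kosambi(bad)
        with pytest.raises(ValueError):
            kosambi_inverse(-1.0)

    @given(st.floats(min_value=0.0, max_value=0.499))
    def test_round_trip_identity(self, r):
        assert kosambi_inverse(kosambi(r)) == pytest.approx(r, abs=1e-10)

    @given(st.floats(min_value=1e-6, max_value=0.49),
           st.floats(min_value=1e-6, max_value=0.49))
    def test_strictly_increasing_and_convex(self, r1, r2):
        lo, hi = sorted([r1, r2])
        if hi - lo > 1e-12:
            assert kosambi(hi) > kosambi(lo)
            mid = (lo + hi) / 2
            assert kosambi(mid) <= (kosambi(lo) + kosambi(hi)) / 2 + 1e-9


# ----------------------------------------------------------------------
# Pair-class counting
# ----------------------------------------------------------------------

class TestCounting:
    def test_single_individual(self):
        m = GenotypeMatrix(["i", "j"], ["x"], np.array([[0], [1]], dtype=np.int8))
        counts = count_pair_classes(m, "i", "j")
        assert counts.AABb == 1 and counts.n_complete == 1

    def test_all_missing_partner(self):
        m = GenotypeMatrix(["i", "j"], ["x", "y"],
                           np.array([[0, 1], [-1, -1]], dtype=np.int8))
        assert count_pair_classes(m, "i", "j").n_complete == 0

    def test_unknown_marker(self, f2_clean):
        with pytest.raises(KeyError):
            count_pair_classes(f2_clean, "nope", f2_clean.markers[0])

    def test_recount_oracle_on_simulated_matrix(self, f2_clean):
        mi, mj = f2_clean.markers[0], f2_clean.markers[5]
        counts = count_pair_classes(f2_clean, mi, mj)
        gi, gj = f2_clean.row(mi), f2_clean.row(mj)
        n_manual = sum(1 for a, b in zip(gi, gj) if a >= 0 and b >= 0)
        assert counts.n_complete == n_manual


# ----------------------------------------------------------------------
# Achiasmatic estimator
# ----------------------------------------------------------------------

class TestAchiasmaticEstimate:
    def test_closed_form_example(self):
        counts = PairCounts(AABB=20, aabb=20, AaBb=40, AABb=5, AaBB=5,
                            Aabb=5, aaBb=5)
        est = estimate_r_achiasmatic(counts)
        assert est.r_hat == pytest.approx(0.20, abs=1e-12)
        assert est.r_hat == pytest.approx(achiasmatic_grid_mle(counts),
                                          abs=1e-4)
        assert est.lod > 0

    def test_null_expectations_give_half_and_zero_lod(self):
        counts = PairCounts(AABB=10, aabb=10, AaBb=20, AABb=10, AaBB=10,
                            Aabb=10, aaBb=10)
        est = estimate_r_achiasmatic(counts)
        assert est.r_hat == 0.5
        assert est.lod == pytest.approx(0.0, abs=1e-12)

    def test_zero_recombinants(self):
        est = estimate_r_achiasmatic(PairCounts(AABB=25, aabb=25, AaBb=50))
        assert est.r_hat == 0.0

    def test_impossible_classes_excluded_and_reported(self):
        counts = PairCounts(AABB=20, aabb=20, AaBb=40, AABb=10, AAbb=3,
                            aaBB=2)
        est = estimate_r_achiasmatic(counts)
        assert est.n_impossible == 5
        assert est.n == 90
        assert est.r_hat == pytest.approx(10 / 90)

    def test_only_impossible_classes_is_an_error(self):
        with pytest.raises(ValueError):
            estimate_r_achiasmatic(PairCounts(AAbb=3, aaBB=4))

    def test_closed_form_equals_grid_mle_on_random_counts(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            arr = rng.integers(0, 30, size=9)
            counts = PairCounts(**dict(zip(CLASS_NAMES, map(int, arr))))
            if counts.n_complete - counts.n_impossible == 0:
                continue
            est = estimate_r_achiasmatic(counts)
            assert est.r_hat == pytest.approx(achiasmatic_grid_mle(counts),
                                              abs=1.1e-4)

    def test_lod_nonnegative_and_zero_iff_half(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            arr = rng.integers(0, 20, size=9)
            counts = PairCounts(**dict(zip(CLASS_NAMES, map(int, arr))))
            if counts.n_complete - counts.n_impossible == 0:
                continue
            est = estimate_r_achiasmatic(counts)
            assert est.lod >= 0
            if est.r_hat == 0.5:
                assert est.lod == pytest.approx(0.0, abs=1e-9)
            elif est.lod == pytest.approx(0.0, abs=1e-12):
                assert est.r_hat == 0.5


# ----------------------------------------------------------------------
# Sex-specific estimator
# ----------------------------------------------------------------------

class TestSexSpecific:
    def test_no_impossible_classes_pins_female_rate_to_zero(self):
        counts = PairCounts(AABB=20, aabb=20, AaBb=40, AABb=5, AaBB=5,
                            Aabb=5, aaBb=5)
        est = estimate_r_sexspecific(counts)
        oracle = sexspecific_grid_mle(counts)
        assert est.r_f == pytest.approx(0.0, abs=1e-3)
        assert est.r_f == pytest.approx(oracle[0], abs=2e-3)
        achias = estimate_r_achiasmatic(counts)
        assert est.r_m == pytest.approx(achias.r_hat, abs=1e-3)

    def test_impossible_classes_force_high_female_recombination(self):
        counts = PairCounts(AABB=15, aabb=15, AaBb=30, AABb=5, AaBB=5,
                            Aabb=5, aaBb=5, AAbb=10, aaBB=10)
        est = estimate_r_sexspecific(counts)
        oracle = sexspecific_grid_mle(counts)
        assert est.r_f > 0.25
        assert est.r_f == pytest.approx(oracle[0], abs=2e-3)
        assert est.r_m == pytest.approx(oracle[1], abs=2e-3)

    def test_null_expectations_sit_on_the_boundary(self):
        # expectations at r_f = r_m = 0.5: all nine classes per their probs
        probs = sexspecific_class_probs(0.5, 0.5)
        counts = PairCounts(**{name: int(round(160 * p))
                               for name, p in zip(CLASS_NAMES, probs)})
        est = estimate_r_sexspecific(counts)
        assert est.r_f == pytest.approx(0.5, abs=1e-6)
        assert est.r_m == pytest.approx(0.5, abs=1e-6)
        null_ll = float(np.where(counts.as_array() > 0,
                                 counts.as_array() * np.log(probs),
                                 0.0).sum())
        assert est.log_likelihood == pytest.approx(null_ll, abs=1e-9)

    def test_constrained_to_achiasmy_reproduces_achiasmatic_mle(self):
        # on the r_f = 0 edge the likelihood is the achiasmatic one
        counts = PairCounts(AABB=30, aabb=28, AaBb=61, AABb=8, AaBB=7,
                            Aabb=9, aaBb=6)
        grid = np.arange(0, 0.5 + 1e-9, 1e-4)
        p = sexspecific_class_probs(0.0, grid)
        arr = counts.as_array()
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.where(arr == 0, 0.0, arr * np.log(p)).sum(axis=-1)
        edge_mle = grid[np.argmax(ll)]
        assert edge_mle == pytest.approx(
            estimate_r_achiasmatic(counts).r_hat, abs=1e-4)

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            estimate_r_sexspecific(PairCounts())


# ----------------------------------------------------------------------
# Vectorised all-pairs table
# ----------------------------------------------------------------------

class TestPairwiseTable:
    def test_matches_per_pair_estimates(self, f2_clean):
        table = pairwise_estimates(f2_clean)
        rng = np.random.default_rng(3)
        rows = table.iloc[rng.choice(len(table), 50, replace=False)]
        for row in rows.itertuples():
            est = estimate_r_achiasmatic(
                count_pair_classes(f2_clean, row.marker_i, row.marker_j))
            assert row.r_hat == pytest.approx(est.r_hat, abs=1e-12)
            assert row.lod == pytest.approx(est.lod, abs=1e-9)
            assert row.n == est.n
            assert row.n_impossible == est.n_impossible

    def test_covers_all_pairs(self, f2_clean):
        table = pairwise_estimates(f2_clean)
        n = f2_clean.n_markers
        assert len(table) == n * (n - 1) // 2
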