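"""Spatial weights, Moran's I, spatial lag model, and the adjusted ANOVA."""

import math
from itertools import combinations, permutations

import numpy as np
import pytest

from laminapipe import (
    BinProfile,
    ValidationError,
    adjusted_anova,
    chain_weights,
    fit_spatial_lag,
    morans_i,
    simulate_spatial_lag,
    two_way_anova,
)
from laminapipe.spatial import FactorialDesign, _permutation_anova


class TestChainWeights:
    def test_three_bin_chain_rows(self):
        w = chain_weights(3)
        expected = [[0, 1, 0], [0.5, 0, 0.5], [0, 1, 0]]
        assert np.allclose(w.W.toarray(), expected)

    def test_twenty_bin_chain_has_38_links(self):
        w = chain_weights(20)
        assert w.binary.nnz == 38  # 2*(n-1) directed links

    def test_rows_normalized_and_diagonal_zero(self):
        w = chain_weights(7, slices=3)
        dense = w.W.toarray()
        assert np.allclose(dense.sum(axis=1), 1.0)
        assert np.allclose(np.diag(dense), 0.0)
        b = w.binary.toarray()
        assert np.array_equal(b, b.T)

    def test_block_diagonal_across_slices(self):
        w = chain_weights(3, slices=2)
        dense = w.W.toarray()
        assert np.allclose(dense[:3, 3:], 0.0)
        assert np.allclose(dense[3:, :3], 0.0)

    def test_too_few_bins_is_an_error(self):
        with pytest.raises(ValidationError):
            chain_weights(1)


def _projection_f(y, genotype, bin_):
    """Brute-force type-II F statistics via explicit projection matrices."""
    import pandas as pd

    def design(cols):
        mats = [np.ones((len(y), 1))]
        if "g" in cols:
            mats.append(pd.get_dummies(pd.Categorical(genotype), drop_first=True).to_numpy(float))
        if "b" in cols:
            mats.append(pd.get_dummies(pd.Categorical(bin_), drop_first=True).to_numpy(float))
        if "gb" in cols:
            ga = pd.get_dummies(pd.Categorical(genotype), drop_first=True).to_numpy(float)
            gb = pd.get_dummies(pd.Categorical(bin_), drop_first=True).to_numpy(float)
            mats.append(np.einsum("ij,ik->ijk", ga, gb).reshape(len(y), -1))
        X = np.hstack(mats)
        return X @ np.linalg.pinv(X)

    def rss(P):
        r = y - P @ y
        return float(r @ r)

    a = len(set(genotype))
    b = len(set(bin_))
    n = len(y)
    rss_a, rss_b = rss(design(["g"])), rss(design(["b"]))
    rss_add, rss_full = rss(design(["g", "b"])), rss(design(["g", "b", "gb"]))
    df_res = n - a * b
    mse = rss_full / df_res
    return {
        "genotype": ((rss_b - rss_add) / (a - 1)) / mse,
        "bin": ((rss_a - rss_add) / (b - 1)) / mse,
        "interaction": ((rss_add - rss_full) / ((a - 1) * (b - 1))) / mse,
    }


class TestTwoWayAnova:
    def test_matches_projection_oracle_on_toy(self):
        rng = np.random.default_rng(8)
        genotype = np.repeat(["WT", "KO"], 6)
        bin_ = np.tile([1, 2, 3], 4)
        y = rng.normal(size=12) + 2.0 * (bin_ == 2)
        res = two_way_anova(y, genotype, bin_)
        oracle = _projection_f(y, genotype, bin_)
        assert res.F_genotype == pytest.approx(oracle["genotype"])
        assert res.F_bin == pytest.approx(oracle["bin"])
        assert res.F_interaction == pytest.approx(oracle["interaction"])

    def test_engine_agrees_with_statsmodels(self):
        rng = np.random.default_rng(9)
        genotype = np.repeat(["WT", "KO"], 40)
        bin_ = np.tile(np.arange(1, 11), 8)
        y = rng.normal(size=80) + 0.5 * (bin_ > 5)
        res = two_way_anova(y, genotype, bin_)
        eng = FactorialDesign(genotype, bin_).f_stats(y)
        assert eng["genotype"] == pytest.approx(res.F_genotype)
        assert eng["bin"] == pytest.approx(res.F_bin)
        assert eng["interaction"] == pytest.approx(res.F_interaction)

    def test_pure_bin_effect_keeps_genotype_null_calibrated(self):
        rng = np.random.default_rng(10)
        genotype = np.repeat(["WT", "KO"], 30)
        bin_ = np.tile(np.arange(1, 6), 12)
        n_ok = 0
        for _ in range(100):
            y = rng.normal(size=60) + 1.5 * bin_
            n_ok += two_way_anova(y, genotype, bin_).p_genotype > 0.05
        assert n_ok >= 90

    def test_constant_response_is_an_error(self):
        with pytest.raises(ValidationError):
            two_way_anova(
                np.ones(12), np.repeat(["a", "b"], 6), np.tile([1, 2, 3], 4)
            )

    def test_missing_cell_is_an_error(self):
        genotype = ["a", "a", "b", "b"]
        bin_ = [1, 2, 1, 1]  # cell (b, 2) empty
        with pytest.raises(ValidationError, match="empty"):
            two_way_anova([1.0, 2.0, 3.0, 4.0], genotype, bin_)


def _brute_force_moran_p(e, W_dense):
    """Enumerate all n! orderings of the residuals (ties at 1e-9 resolution)."""
    z = np.asarray(e, float) - np.mean(e)
    n = len(z)
    s0 = W_dense.sum()
    denom = z @ z
    i_obs = n / s0 * (z @ W_dense @ z) / denom
    vals = []
    for perm in permutations(z):
        p = np.array(perm)
        vals.append(n / s0 * (p @ W_dense @ p) / denom)
    return float(np.mean(np.round(vals, 9) >= round(i_obs, 9)))


class TestMoransI:
    def test_alternating_chain_hand_value(self):
        res = morans_i([1, -1, 1, -1], chain_weights(4), n_perm=100)
        assert res.I == pytest.approx(-1.0)
        assert res.expected_I == pytest.approx(-1 / 3)

    def test_exhaustive_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for n in (5, 6):
            w = chain_weights(n)
            e = rng.normal(size=n)
            res = morans_i(e, w, n_perm=math.factorial(n))
            assert res.n_perm == "exhaustive"
            assert res.p_value == _brute_force_moran_p(e, w.W.toarray())

    def test_permutation_null_mean_is_analytic_expectation(self):
        # over ALL permutations the mean of I is exactly -1/(n-1)
        rng = np.random.default_rng(12)
        n = 6
        res = morans_i(rng.normal(size=n), chain_weights(n), n_perm=math.factorial(n))
        assert res.null_mean == pytest.approx(-1 / (n - 1))

    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(13)
        w = chain_weights(40)
        rej = 0
        n_sims = 500
        for i in range(n_sims):
            e = rng.normal(size=40)
            rej += morans_i(e, w, n_perm=199, seed=i).p_value < 0.05
        assert 0.03 <= rej / n_sims <= 0.07

    def test_p_invariant_to_affine_transform_of_residuals(self):
        rng = np.random.default_rng(14)
        e = rng.normal(size=25)
        w = chain_weights(25)
        p1 = morans_i(e, w, n_perm=299, seed=5).p_value
        p2 = morans_i(3.0 * e + 7.0, w, n_perm=299, seed=5).p_value
        assert p1 == p2

    def test_constant_residuals_are_an_error(self):
        with pytest.raises(ValidationError):
            morans_i(np.ones(5), chain_weights(5))

    def test_normal_approx_agrees_with_permutation_on_strong_signal(self):
        rng = np.random.default_rng(15)
        smooth = np.cumsum(rng.normal(size=30))
        w = chain_weights(30)
        p_perm = morans_i(smooth, w, n_perm=999, seed=0).p_value
        p_norm = morans_i(smooth, w, method="normal_approx").p_value
        assert p_perm < 0.05 and p_norm < 0.05


class TestSpatialLag:
    def _design(self, n_slices=20, n_bins=20):
        genotype = np.repeat(["WT", "KO"], n_slices // 2 * n_bins)
        bins = np.tile(np.arange(1, n_bins + 1), n_slices)
        return FactorialDesign(genotype, bins).X_full, chain_weights(n_bins, n_slices)

    def test_zero_rho_not_spuriously_detected(self):
        X, w = self._design()
        rng = np.random.default_rng(16)
        beta = rng.normal(size=X.shape[1])
        y = simulate_spatial_lag(X, beta, 0.0, w, rng=np.random.default_rng(0))
        fit = fit_spatial_lag(y, X, w)
        assert abs(fit.rho) < 0.1
        assert fit.loglik >= fit.loglik_at_zero

    def test_rho_recovery_at_point_six(self):
        X, w = self._design()
        rng = np.random.default_rng(17)
        beta = rng.normal(size=X.shape[1])
        est = [
            fit_spatial_lag(
                simulate_spatial_lag(X, beta, 0.6, w, rng=np.random.default_rng(100 + s)),
                X,
                w,
            ).rho
            for s in range(100)
        ]
        assert 0.5 <= np.mean(est) <= 0.7

    def test_dimension_mismatch_is_an_error(self):
        X, w = self._design()
        with pytest.raises(ValidationError):
            fit_spatial_lag(np.ones(10), X, w)


def _profiles_from_matrix(mat, genotypes):
    return [
        BinProfile(f"s{i}", g, row, n_cells=100)
        for i, (row, g) in enumerate(zip(mat, genotypes))
    ]


class TestAdjustedAnova:
    def test_reduces_to_classical_anova_when_gates_pass(self):
        rng = np.random.default_rng(18)
        n_slices, n_bins = 12, 8
        base = np.full(n_bins, 100.0 / n_bins)
        mat = base + rng.normal(0, 0.5, size=(n_slices, n_bins))
        mat = mat / mat.sum(axis=1, keepdims=True) * 100
        genotypes = ["WT"] * 6 + ["KO"] * 6
        profiles = _profiles_from_matrix(mat, genotypes)
        res = adjusted_anova(profiles, seed=1)
        assert res.shapiro_p >= 0.05 and res.moran_p >= 0.05  # seed chosen ok
        assert res.branch == "classical"
        y = mat.ravel()
        g = np.repeat(genotypes, n_bins)
        b = np.tile(np.arange(1, n_bins + 1), n_slices)
        ref = two_way_anova(y, g, b)
        assert res.p_interaction == pytest.approx(ref.p_interaction)
        assert res.F_interaction == pytest.approx(ref.F_interaction)
        assert res.rho is None

    def test_permutation_branch_matches_enumeration_oracle(self):
        # 3+3 slices, 4 bins: all C(6,3)=20 genotype assignments enumerable
        rng = np.random.default_rng(19)
        n_bins = 4
        mat = rng.dirichlet(np.ones(n_bins) * 5, size=6) * 100
        genotypes = ["WT"] * 3 + ["KO"] * 3
        y = mat.ravel()
        g = np.repeat(genotypes, n_bins)
        b = np.tile(np.arange(1, n_bins + 1), 6)
        p_g, p_b, p_i, scheme = _permutation_anova(
            y, g, b, genotypes, n_bins, n_perm=1000, seed=0
        )
        assert scheme == "slice-exhaustive"
        design = FactorialDesign(g, b)
        obs = design.f_stats(y)
        f_int, f_gen = [], []
        for pick in combinations(range(6), 3):
            order = list(pick) + [i for i in range(6) if i not in pick]
            f = design.f_stats(mat[order].ravel())
            f_int.append(f["interaction"])
            f_gen.append(f["genotype"])
        assert p_i == np.mean(np.array(f_int) >= obs["interaction"])
        assert p_g == np.mean(np.array(f_gen) >= obs["genotype"])

    def test_gate_pvalues_reported_for_untaken_branches(self):
        rng = np.random.default_rng(20)
        mat = rng.dirichlet(np.ones(6), size=10) * 100
        profiles = _profiles_from_matrix(mat, ["WT"] * 5 + ["KO"] * 5)
        res = adjusted_anova(profiles, n_perm=199, seed=3)
        for gate in (res.shapiro_p, res.levene_p, res.moran_p):
            assert 0.0 <= gate <= 1.0
        assert res.branch in {
            "classical",
            "permutation",
            "spatial_filtered",
            "spatial_filtered_permutation",
        }

    def test_posthoc_bonferroni_scaling(self):
        rng = np.random.default_rng(21)
        n_bins = 5
        mat = rng.dirichlet(np.ones(n_bins) * 10, size=8) * 100
        profiles = _profiles_from_matrix(mat, ["WT"] * 4 + ["KO"] * 4)
        res = adjusted_anova(profiles, n_perm=199, seed=4)
        ph = res.posthoc
        assert len(ph) == n_bins
        assert np.allclose(
            ph["p_bonferroni"], np.minimum(1.0, ph["p_raw"] * n_bins)
        )

    def test_too_few_slices_is_an_error(self):
        mat = np.full((3, 4), 25.0)
        with pytest.raises(ValidationError):
            adjusted_anova(_profiles_from_matrix(mat, ["WT", "WT", "KO"]))

    def test_reproducible_under_fixed_seed(self):
        rng = np.random.default_rng(22)
        mat = rng.dirichlet(np.ones(10), size=10) * 100
        profiles = _profiles_from_matrix(mat, ["WT"] * 5 + ["KO"] * 5)
        r1 = adjusted_anova(profiles, n_perm=299, seed=7)
        r2 = adjusted_anova(profiles, n_perm=299, seed=7)
        assert r1.p_interaction == r2.p_interaction
        assert r1.branch == r2.branch
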