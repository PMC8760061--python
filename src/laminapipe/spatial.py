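"""Spatially adjusted two-way ANOVA for laminar bin profiles.

Bin percentages along a cortical column are spatially ordered: adjacent bins
share cells' neighborhoods, so ANOVA residuals can be spatially
autocorrelated, violating the independence assumption of the classical
two-way (genotype x bin) ANOVA.  The pipeline here:

1. fits the ordinary factorial model (type-II sums of squares),
2. gates the assumptions — Shapiro-Wilk on residuals, Levene across
   genotype x bin cells, Moran's I on residuals against a chain contiguity
   weights matrix (bin i adjacent to i+/-1 within each slice),
3. if Moran's I is significant, removes the autocorrelation with a
   maximum-likelihood spatial lag model y = rho*W*y + X*beta + eps and
   analyzes the filtered response y - rho_hat*W*y,
4. if residual normality fails, replaces F-test p-values with restricted
   permutation p-values: whole slice profiles are permuted across genotype
   assignments for the genotype and interaction effects (the slice is the
   exchangeable replicate unit; a slice's bin percentages sum to 100 and
   must travel together), and bin values are permuted within each slice for
   the bin main effect,
5. runs Bonferroni-corrected per-bin genotype contrasts as the post hoc.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations, permutations
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import sparse, stats
from scipy.optimize import minimize_scalar
from statsmodels.stats.anova import anova_lm

from .errors import ValidationError
from .laminar import BinProfile

__all__ = [
    "SpatialWeights",
    "MoranResult",
    "SpatialLagFit",
    "AnovaResult",
    "AdjustedAnovaResult",
    "chain_weights",
    "two_way_anova",
    "morans_i",
    "fit_spatial_lag",
    "simulate_spatial_lag",
    "adjusted_anova",
    "FactorialDesign",
]


@dataclass
class SpatialWeights:
    """Row-normalized contiguity weights.

    ``W`` is the row-normalized matrix used in all statistics; ``binary`` is
    the symmetric 0/1 adjacency it was built from.  For block-diagonal chain
    weights the per-block size is retained so eigenvalues can be computed from
    a single block.
    """

    W: sparse.csr_matrix
    binary: sparse.csr_matrix
    scheme: str = "chain_contiguity"
    normalized: bool = True
    block_size: int | None = None
    n_blocks: int = 1
    _eigs: np.ndarray | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.W.shape[0]

    @property
    def s0(self) -> float:
        """Sum of all weights (equals n for a fully row-normalized matrix)."""
        return float(self.W.sum())

    def eigenvalues(self) -> np.ndarray:
        """Real eigenvalues of W (needed for the lag-model log-determinant)."""
        if self._eigs is None:
            if self.block_size is not None:
                block = self.W[: self.block_size, : self.block_size].toarray()
                eigs = np.linalg.eigvals(block)
                eigs = np.tile(np.real(eigs), self.n_blocks)
            else:
                eigs = np.real(np.linalg.eigvals(self.W.toarray()))
            self._eigs = np.sort(eigs)
        return self._eigs


@dataclass(frozen=True)
class MoranResult:
    I: float
    expected_I: float
    p_value: float
    method: str
    n_perm: int | str
    alternative: str = "greater"
    #: mean/sd of I over the permutation draws (diagnostics; the permutation
    #: mean estimates the analytic null expectation -1/(n-1))
    null_mean: float | None = None
    null_sd: float | None = None


@dataclass(frozen=True)
class SpatialLagFit:
    """Maximum-likelihood fit of y = rho*W*y + X*beta + eps."""

    rho: float
    beta: np.ndarray
    sigma2: float
    loglik: float
    loglik_at_zero: float


@dataclass(frozen=True)
class AnovaResult:
    """Type-II two-way factorial ANOVA with residuals for diagnostics."""

    F_genotype: float
    F_bin: float
    F_interaction: float
    p_genotype: float
    p_bin: float
    p_interaction: float
    df: dict[str, float]
    residuals: np.ndarray
    fitted: np.ndarray
    table: pd.DataFrame


@dataclass(frozen=True)
class AdjustedAnovaResult:
    shapiro_p: float
    levene_p: float
    moran_p: float
    moran_I: float
    branch: str
    rho: float | None
    F_genotype: float
    F_bin: float
    F_interaction: float
    p_genotype: float
    p_bin: float
    p_interaction: float
    posthoc: pd.DataFrame | None
    n_perm: int
    seed: int | None
    notes: tuple[str, ...] = ()


def chain_weights(n_bins: int, slices: int = 1) -> SpatialWeights:
    """Chain contiguity weights: bin i adjacent to i+/-1 within each slice.

    Slices are assembled block-diagonally (bins of different columns are not
    neighbors), then each row is divided by its total.
    """
    if n_bins < 2:
        raise ValidationError("chain_weights requires n_bins >= 2")
    if slices < 1:
        raise ValidationError("chain_weights requires slices >= 1")
    off = np.ones(n_bins - 1)
    block = sparse.diags([off, off], offsets=[-1, 1], format="csr")
    binary = sparse.block_diag([block] * slices, format="csr")
    row_sums = np.asarray(binary.sum(axis=1)).ravel()
    inv = np.divide(1.0, row_sums, out=np.zeros_like(row_sums), where=row_sums > 0)
    W = sparse.diags(inv).dot(binary).tocsr()
    return SpatialWeights(
        W=W, binary=binary, block_size=n_bins, n_blocks=slices
    )


class FactorialDesign:
    """Projection engine for the two-factor model, vectorized over responses.

    Precomputes orthonormal bases for the four nested designs (A, B, A+B,
    full) so type-II F statistics can be evaluated for thousands of permuted
    response vectors with a handful of matrix products.
    """

    def __init__(self, genotype: Sequence[str], bin_: Sequence[int]):
        g = pd.Categorical(genotype)
        b = pd.Categorical(bin_)
        counts = pd.crosstab(g, b)
        empty = counts[counts == 0].stack()
        if len(empty):
            cell = empty.index[0]
            raise ValidationError(
                f"design has an empty genotype x bin cell: {cell}; "
                "every combination needs at least one slice"
            )
        n = len(g)
        a_levels, b_levels = len(g.categories), len(b.categories)
        ga = pd.get_dummies(g, drop_first=True).to_numpy(dtype=float)
        gb = pd.get_dummies(b, drop_first=True).to_numpy(dtype=float)
        inter = np.einsum("ij,ik->ijk", ga, gb).reshape(n, -1)
        one = np.ones((n, 1))
        self._q = {
            "a": np.linalg.qr(np.hstack([one, ga]))[0],
            "b": np.linalg.qr(np.hstack([one, gb]))[0],
            "add": np.linalg.qr(np.hstack([one, ga, gb]))[0],
            "full": np.linalg.qr(np.hstack([one, ga, gb, inter]))[0],
        }
        self.X_full = np.hstack([one, ga, gb, inter])
        self.df = {
            "genotype": a_levels - 1,
            "bin": b_levels - 1,
            "interaction": (a_levels - 1) * (b_levels - 1),
            "residual": n - a_levels * b_levels,
        }
        if self.df["residual"] < 1:
            raise ValidationError("no residual degrees of freedom (need replicate slices)")

    def _rss(self, key: str, Y: np.ndarray, y2: np.ndarray) -> np.ndarray:
        q = self._q[key]
        return y2 - ((q.T @ Y) ** 2).sum(axis=0)

    def f_stats(self, Y: np.ndarray) -> dict[str, np.ndarray]:
        """Type-II F statistics for each column of ``Y`` (or a single vector)."""
        Y = np.asarray(Y, dtype=float)
        squeeze = Y.ndim == 1
        if squeeze:
            Y = Y[:, None]
        y2 = (Y * Y).sum(axis=0)
        rss_a = self._rss("a", Y, y2)
        rss_b = self._rss("b", Y, y2)
        rss_add = self._rss("add", Y, y2)
        rss_full = self._rss("full", Y, y2)
        ss = {
            "genotype": np.maximum(rss_b - rss_add, 0.0),
            "bin": np.maximum(rss_a - rss_add, 0.0),
            "interaction": np.maximum(rss_add - rss_full, 0.0),
        }
        mse = rss_full / self.df["residual"]
        out = {}
        for key, val in ss.items():
            f = np.divide(
                val / self.df[key], mse, out=np.full_like(mse, np.nan), where=mse > 0
            )
            out[key] = float(f[0]) if squeeze else f
        return out


def two_way_anova(
    y: Sequence[float], genotype: Sequence[str], bin_: Sequence[int]
) -> AnovaResult:
    """Ordinary two-way factorial ANOVA with type-II sums of squares."""
    y = np.asarray(y, dtype=float)
    df = pd.DataFrame({"y": y, "genotype": genotype, "bin": bin_})
    if df["genotype"].nunique() < 2 or df["bin"].nunique() < 2:
        raise ValidationError("both factors need >= 2 levels")
    FactorialDesign(df["genotype"], df["bin"])  # raises on empty cells
    model = smf.ols("y ~ C(genotype) * C(bin)", data=df).fit()
    resid = np.asarray(model.resid)
    if resid.var() <= np.finfo(float).eps * max(1.0, float(y.var())):
        raise ValidationError("zero residual variance: F statistics are undefined")
    table = anova_lm(model, typ=2)
    get = lambda row: (float(table.loc[row, "F"]), float(table.loc[row, "PR(>F)"]))
    f_g, p_g = get("C(genotype)")
    f_b, p_b = get("C(bin)")
    f_i, p_i = get("C(genotype):C(bin)")
    return AnovaResult(
        F_genotype=f_g,
        F_bin=f_b,
        F_interaction=f_i,
        p_genotype=p_g,
        p_bin=p_b,
        p_interaction=p_i,
        df={
            "genotype": float(table.loc["C(genotype)", "df"]),
            "bin": float(table.loc["C(bin)", "df"]),
            "interaction": float(table.loc["C(genotype):C(bin)", "df"]),
            "residual": float(table.loc["Residual", "df"]),
        },
        residuals=resid,
        fitted=np.asarray(model.fittedvalues),
        table=table,
    )


def morans_i(
    e: Sequence[float],
    weights: SpatialWeights,
    n_perm: int = 999,
    seed: int | None = None,
    alternative: str = "greater",
    method: str = "permutation",
) -> MoranResult:
    """Moran's I of a residual vector against spatial weights.

    I = (n/S0) * z'Wz / z'z with z the mean-centered residuals.  Significance
    by random permutation of the residuals (default), by exhaustive
    enumeration whenever n! <= n_perm, or by the normal approximation under
    the randomization assumption (``method="normal_approx"``).
    """
    e = np.asarray(e, dtype=float)
    n = e.size
    if n != weights.n:
        raise ValidationError(f"residual length {n} != weights dimension {weights.n}")
    z = e - e.mean()
    denom = float(z @ z)
    if denom <= 0:
        raise ValidationError("residuals are constant; Moran's I is undefined")
    W = weights.W
    s0 = weights.s0
    expected = -1.0 / (n - 1)
    i_obs = float(n / s0 * (z @ (W @ z)) / denom)

    if method == "normal_approx":
        p = _moran_normal_p(z, weights, i_obs, expected, alternative)
        return MoranResult(i_obs, expected, p, "normal_approx", 0, alternative)
    if method != "permutation":
        raise ValidationError(f"unknown Moran method {method!r}")

    # tie convention: I values are compared at 1e-9 resolution, so permutations
    # whose I equals I_obs (e.g. the identity, or a chain reversal) land in the
    # tail regardless of floating-point summation order
    def tail_count(i_perm: np.ndarray) -> int:
        ip = np.round(i_perm, 9)
        io = round(i_obs, 9)
        if alternative == "greater":
            return int(np.sum(ip >= io))
        if alternative == "less":
            return int(np.sum(ip <= io))
        if alternative == "two-sided":
            return int(np.sum(np.abs(ip - expected) >= abs(io - expected)))
        raise ValidationError(f"unknown alternative {alternative!r}")

    if math.factorial(n) <= n_perm:
        perms = np.array(list(permutations(z)))
        i_perm = n / s0 * np.einsum("ij,ij->i", perms, perms @ W.T.toarray()) / denom
        count = tail_count(i_perm)
        return MoranResult(
            i_obs, expected, count / math.factorial(n), "permutation",
            "exhaustive", alternative,
            null_mean=float(i_perm.mean()), null_sd=float(i_perm.std(ddof=1)),
        )

    rng = np.random.default_rng(seed)
    P = rng.permuted(np.broadcast_to(z, (n_perm, n)).copy(), axis=1)
    WP = (W @ P.T).T
    i_perm = n / s0 * (P * WP).sum(axis=1) / denom
    count = tail_count(i_perm)
    return MoranResult(
        i_obs, expected, (1 + count) / (n_perm + 1), "permutation", n_perm, alternative,
        null_mean=float(i_perm.mean()), null_sd=float(i_perm.std(ddof=1)),
    )


def _moran_normal_p(
    z: np.ndarray, weights: SpatialWeights, i_obs: float, expected: float, alternative: str
) -> float:
    """Normal approximation under the randomization assumption."""
    W = weights.W.toarray()
    n = z.size
    s0 = W.sum()
    s1 = 0.5 * ((W + W.T) ** 2).sum()
    s2 = ((W.sum(axis=1) + W.sum(axis=0)) ** 2).sum()
    b2 = n * (z**4).sum() / (z**2).sum() ** 2
    num = n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2) - b2 * (
        (n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2
    )
    var = num / ((n - 1) * (n - 2) * (n - 3) * s0**2) - expected**2
    zscore = (i_obs - expected) / math.sqrt(var)
    if alternative == "greater":
        return float(stats.norm.sf(zscore))
    if alternative == "less":
        return float(stats.norm.cdf(zscore))
    return float(2 * stats.norm.sf(abs(zscore)))


def fit_spatial_lag(
    y: Sequence[float], X: np.ndarray, weights: SpatialWeights
) -> SpatialLagFit:
    """Maximum-likelihood spatial lag model y = rho*W*y + X*beta + eps.

    rho is found by maximizing the concentrated log-likelihood
    ll(rho) = -n/2 log(RSS(rho)/n) + sum_i log(1 - rho*lambda_i) + const
    on (1/lambda_min + 1e-6, 1 - 1e-6), with lambda_i the eigenvalues of the
    row-normalized W; beta and sigma2 follow by OLS on y - rho*W*y.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = y.size
    if X.shape[0] != n or weights.n != n:
        raise ValidationError("y, X and W dimensions do not conform")
    Wy = weights.W @ y
    Q, _ = np.linalg.qr(X)
    eigs = weights.eigenvalues()
    lam_min = float(eigs.min())
    lo = (1.0 / lam_min + 1e-6) if lam_min < 0 else -1.0 + 1e-6
    hi = 1.0 - 1e-6

    resid_y = y - Q @ (Q.T @ y)
    resid_wy = Wy - Q @ (Q.T @ Wy)

    def negll(rho: float) -> float:
        r = resid_y - rho * resid_wy
        rss = float(r @ r)
        with np.errstate(invalid="raise"):
            logdet = float(np.log(1.0 - rho * eigs).sum())
        return 0.5 * n * math.log(rss / n) - logdet

    res = minimize_scalar(negll, bounds=(lo, hi), method="bounded")
    if not res.success:
        raise ValidationError(
            f"spatial-lag optimizer failed on bracket ({lo:.4g}, {hi:.4g}): {res.message}"
        )
    rho = float(res.x)

    def full_ll(rho: float) -> tuple[float, np.ndarray, float]:
        yf = y - rho * Wy
        beta, *_ = np.linalg.lstsq(X, yf, rcond=None)
        r = yf - X @ beta
        sigma2 = float(r @ r) / n
        logdet = float(np.log(1.0 - rho * eigs).sum())
        ll = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0) + logdet
        return ll, beta, sigma2

    ll_hat, beta, sigma2 = full_ll(rho)
    ll_zero, _, _ = full_ll(0.0)
    return SpatialLagFit(
        rho=rho, beta=beta, sigma2=sigma2, loglik=ll_hat, loglik_at_zero=ll_zero
    )


def simulate_spatial_lag(
    X: np.ndarray,
    beta: np.ndarray,
    rho: float,
    weights: SpatialWeights,
    sigma: float = 1.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw y = (I - rho*W)^-1 (X*beta + eps), eps ~ N(0, sigma^2 I)."""
    rng = rng or np.random.default_rng()
    n = X.shape[0]
    eps = rng.normal(0.0, sigma, size=n)
    A = sparse.identity(n, format="csc") - rho * weights.W
    return sparse.linalg.spsolve(A.tocsc(), X @ beta + eps)


def _permutation_anova(
    y: np.ndarray,
    genotype: np.ndarray,
    bin_: np.ndarray,
    slice_geno: Sequence[str],
    n_bins: int,
    n_perm: int,
    seed: int,
) -> tuple[float, float, float, str]:
    """Restricted-permutation p-values for the three factorial F tests.

    Genotype and interaction: whole slice profiles are permuted across the
    genotype assignment (slices are the exchangeable replicate unit; one
    slice's bin percentages sum to 100 and must travel together).  With two
    genotypes and C(n_slices, n_a) <= n_perm all distinct assignments are
    enumerated and the p-value is the exact tail fraction; otherwise n_perm
    random slice permutations with the +1 correction.  Bin main effect: bin
    values are permuted within each slice (random, +1 correction).
    """
    design = FactorialDesign(genotype, bin_)
    obs = design.f_stats(y)
    n_slices = len(slice_geno)
    prof = y.reshape(n_slices, n_bins)
    rng = np.random.default_rng(seed)

    levels = sorted(set(slice_geno))
    n_a = sum(g == levels[0] for g in slice_geno)
    exhaustive = (
        len(levels) == 2 and math.comb(n_slices, n_a) <= n_perm
    )
    if exhaustive:
        slot_a = [i for i, g in enumerate(slice_geno) if g == levels[0]]
        slot_b = [i for i, g in enumerate(slice_geno) if g != levels[0]]
        order = np.empty(n_slices, dtype=int)
        cols = []
        for pick in combinations(range(n_slices), n_a):
            rest = [i for i in range(n_slices) if i not in set(pick)]
            order[slot_a] = pick
            order[slot_b] = rest
            cols.append(prof[order].ravel())
        Y = np.array(cols).T
        f_perm = design.f_stats(Y)
        total = Y.shape[1]
        p_g = float((f_perm["genotype"] >= obs["genotype"]).sum()) / total
        p_i = float((f_perm["interaction"] >= obs["interaction"]).sum()) / total
        scheme = "slice-exhaustive"
    else:
        idx = np.argsort(rng.random((n_perm, n_slices)), axis=1)
        Y = prof[idx].reshape(n_perm, -1).T
        f_perm = design.f_stats(Y)
        p_g = (1 + int((f_perm["genotype"] >= obs["genotype"]).sum())) / (n_perm + 1)
        p_i = (1 + int((f_perm["interaction"] >= obs["interaction"]).sum())) / (
            n_perm + 1
        )
        scheme = "slice-level"

    within = rng.permuted(
        np.broadcast_to(prof, (n_perm, n_slices, n_bins)).copy(), axis=2
    )
    f_bin = design.f_stats(within.reshape(n_perm, -1).T)["bin"]
    p_b = (1 + int((f_bin >= obs["bin"]).sum())) / (n_perm + 1)
    return p_g, p_b, p_i, scheme


def adjusted_anova(
    profiles: Sequence[BinProfile],
    alpha_gate: float = 0.05,
    n_perm: int = 5000,
    seed: int | None = None,
    n_moran_perm: int = 999,
    posthoc: bool = True,
) -> AdjustedAnovaResult:
    """Spatially adjusted two-way (genotype x bin) ANOVA over bin profiles.

    Pipeline: stack profiles -> OLS factorial ANOVA -> assumption gates
    (Shapiro-Wilk, Levene, Moran's I with chain contiguity weights) ->
    spatial-lag filtering of the response when Moran's I is significant ->
    permutation p-values (unrestricted response permutation, F statistic)
    when residual normality fails -> Bonferroni per-bin genotype contrasts.
    All gate p-values are reported even for branches not taken.
    """
    if len(profiles) < 4:
        raise ValidationError("need >= 2 genotypes with >= 2 slices each")
    n_bins = profiles[0].n_bins
    if any(p.n_bins != n_bins for p in profiles):
        raise ValidationError("all profiles must have the same number of bins")
    genotypes = sorted({p.genotype for p in profiles})
    if len(genotypes) < 2:
        raise ValidationError("need >= 2 genotypes")
    for g in genotypes:
        if sum(p.genotype == g for p in profiles) < 2:
            raise ValidationError(f"genotype {g!r} has fewer than 2 slices")

    y = np.concatenate([p.percentages for p in profiles])
    genotype = np.repeat([p.genotype for p in profiles], n_bins)
    bin_ = np.tile(np.arange(1, n_bins + 1), len(profiles))

    seeds = np.random.SeedSequence(seed).generate_state(3)
    notes: list[str] = []

    base = two_way_anova(y, genotype, bin_)
    shapiro_p = float(stats.shapiro(base.residuals).pvalue)
    cells = pd.DataFrame({"r": base.residuals, "g": genotype, "b": bin_})
    groups = [grp["r"].to_numpy() for _, grp in cells.groupby(["g", "b"], observed=True)]
    levene_p = float(stats.levene(*groups).pvalue)
    weights = chain_weights(n_bins, slices=len(profiles))
    moran = morans_i(
        base.residuals, weights, n_perm=n_moran_perm, seed=int(seeds[0])
    )

    rho: float | None = None
    y_work = y
    result = base
    spatial = moran.p_value < alpha_gate
    if spatial:
        design = FactorialDesign(genotype, bin_)
        lag = fit_spatial_lag(y, design.X_full, weights)
        rho = lag.rho
        y_work = y - rho * (weights.W @ y)
        result = two_way_anova(y_work, genotype, bin_)
        notes.append("response spatially filtered (y - rho*W*y) before testing")

    permute = shapiro_p < alpha_gate
    p_g, p_b, p_i = result.p_genotype, result.p_bin, result.p_interaction
    if permute:
        slice_geno = [p.genotype for p in profiles]
        p_g, p_b, p_i, scheme = _permutation_anova(
            y_work, genotype, bin_, slice_geno, n_bins, n_perm, int(seeds[1])
        )
        notes.append(f"F-test p-values obtained by {scheme} permutation")

    branch = {
        (False, False): "classical",
        (False, True): "permutation",
        (True, False): "spatial_filtered",
        (True, True): "spatial_filtered_permutation",
    }[(spatial, permute)]

    posthoc_df = None
    if posthoc:
        rows = []
        n_pairs = len(list(combinations(genotypes, 2)))
        n_tests = n_bins * n_pairs
        frame = pd.DataFrame({"y": y_work, "g": genotype, "b": bin_})
        for ga, gb in combinations(genotypes, 2):
            for b in range(1, n_bins + 1):
                va = frame.query("g == @ga and b == @b")["y"].to_numpy()
                vb = frame.query("g == @gb and b == @b")["y"].to_numpy()
                if permute:
                    stat, raw_p = stats.mannwhitneyu(va, vb, alternative="two-sided")
                    test = "mann_whitney"
                else:
                    stat, raw_p = stats.ttest_ind(va, vb)
                    test = "t"
                rows.append(
                    {
                        "bin": b,
                        "genotype_a": ga,
                        "genotype_b": gb,
                        "statistic": float(stat),
                        "p_raw": float(raw_p),
                        "p_bonferroni": min(1.0, float(raw_p) * n_tests),
                        "test": test,
                    }
                )
        posthoc_df = pd.DataFrame(rows)

    return AdjustedAnovaResult(
        shapiro_p=shapiro_p,
        levene_p=levene_p,
        moran_p=moran.p_value,
        moran_I=moran.I,
        branch=branch,
        rho=rho,
        F_genotype=result.F_genotype,
        F_bin=result.F_bin,
        F_interaction=result.F_interaction,
        p_genotype=p_g,
        p_bin=p_b,
        p_interaction=p_i,
        posthoc=posthoc_df,
        n_perm=n_perm if permute else 0,
        seed=seed,
        notes=tuple(notes),
    )
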