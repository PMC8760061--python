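"""Laminar cell-distribution statistics and group comparisons.

The substrate is a cell-position table: one row per cell with its depth in a
cortical column expressed as a fraction of cortical thickness (0 = ventral
boundary, 1 = pial surface) plus slice/animal/genotype labels.  This module
quantifies a column's laminar distribution (20-bin profile, mean laminar
position, kernel density, ECDF) and compares depth samples across genotypes
with a permutation test for medians and the k-sample Anderson-Darling test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "REQUIRED_CELL_COLUMNS",
    "BinProfile",
    "DensityEstimate",
    "GroupComparisonResult",
    "validate_cell_table",
    "normalize_depths",
    "bin_profile",
    "bin_profiles",
    "mean_laminar_position",
    "median_position_test",
    "pairwise_median_tests",
    "depth_density",
    "depth_ecdf",
    "ad_k_sample_test",
]

REQUIRED_CELL_COLUMNS = ("cell_id", "depth_fraction", "slice_id", "animal_id", "genotype")


@dataclass(frozen=True)
class BinProfile:
    """Per-slice 20-bin laminar distribution.

    ``percentages[i]`` is the percentage of the slice's cells whose depth falls
    in bin i+1; bin 1 abuts the ventral boundary and bin ``n_bins`` the pia.
    """

    slice_id: str
    genotype: str
    percentages: np.ndarray
    n_cells: int

    @property
    def n_bins(self) -> int:
        return len(self.percentages)


@dataclass(frozen=True)
class DensityEstimate:
    """Kernel density of depths on [0, 1] with boundary reflection."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    @property
    def mode(self) -> float:
        """Depth of maximal probability density."""
        return float(self.grid[int(np.argmax(self.density))])

    @property
    def peak(self) -> float:
        """Maximal probability density."""
        return float(np.max(self.density))


@dataclass(frozen=True)
class GroupComparisonResult:
    """Outcome of a two-or-more-group distribution comparison."""

    statistic: float
    p_value: float
    n_permutations: int | str
    method: str
    groups: tuple[str, ...] = ()
    notes: tuple[str, ...] = ()


def validate_cell_table(cells: pd.DataFrame) -> pd.DataFrame:
    """Check the cell-table contract; returns the table unchanged."""
    missing = [c for c in REQUIRED_CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise ValidationError(f"cell table is missing required column(s): {missing}")
    depths = cells["depth_fraction"].to_numpy(dtype=float)
    bad = np.flatnonzero((depths < 0) | (depths > 1) | ~np.isfinite(depths))
    if bad.size:
        ids = cells["cell_id"].iloc[bad[:10]].tolist()
        raise ValidationError(
            f"{bad.size} cell(s) have depth_fraction outside [0, 1]; first offenders: {ids}"
        )
    dup = cells.duplicated(subset=["slice_id", "cell_id"])
    if dup.any():
        ids = cells.loc[dup, "cell_id"].iloc[:10].tolist()
        raise ValidationError(f"duplicate cell_id within a slice: {ids}")
    return cells


def normalize_depths(raw_positions: pd.DataFrame) -> pd.DataFrame:
    """Convert per-cell (y_um, column_height_um) into depth fractions.

    Expects columns ``cell_id, y_um, column_height_um, slice_id, animal_id,
    genotype``; returns a validated cell-position table where
    ``depth_fraction = y_um / column_height_um``.
    """
    required = ("cell_id", "y_um", "column_height_um")
    missing = [c for c in required if c not in raw_positions.columns]
    if missing:
        raise ValidationError(f"raw position table is missing column(s): {missing}")
    heights = raw_positions["column_height_um"].to_numpy(dtype=float)
    if (heights <= 0).any():
        raise ValidationError("column_height_um must be > 0 for every cell")
    y = raw_positions["y_um"].to_numpy(dtype=float)
    bad = np.flatnonzero((y < 0) | (y > heights))
    if bad.size:
        ids = raw_positions["cell_id"].iloc[bad[:10]].tolist()
        raise ValidationError(
            f"{bad.size} cell(s) have y_um outside [0, column_height_um]; "
            f"first offenders: {ids}"
        )
    out = raw_positions.copy()
    out["depth_fraction"] = y / heights
    keep = [c for c in REQUIRED_CELL_COLUMNS if c in out.columns]
    return validate_cell_table(out[keep]) if set(keep) == set(REQUIRED_CELL_COLUMNS) else out


def _bin_indices(depths: np.ndarray, n_bins: int) -> np.ndarray:
    """1-based half-open bins [(i-1)/n, i/n); depth 1.0 goes to the last bin."""
    idx = np.floor(depths * n_bins).astype(int) + 1
    return np.minimum(idx, n_bins)


def bin_profile(cells: pd.DataFrame, slice_id: str, n_bins: int = 20) -> BinProfile:
    """Percentage of a slice's cells in each of ``n_bins`` equal depth bins."""
    validate_cell_table(cells)
    sub = cells[cells["slice_id"] == slice_id]
    if sub.empty:
        raise ValidationError(f"slice {slice_id!r} has no cells")
    depths = sub["depth_fraction"].to_numpy(dtype=float)
    idx = _bin_indices(depths, n_bins)
    counts = np.bincount(idx - 1, minlength=n_bins).astype(float)
    genotypes = sub["genotype"].unique()
    return BinProfile(
        slice_id=slice_id,
        genotype=str(genotypes[0]),
        percentages=100.0 * counts / counts.sum(),
        n_cells=int(counts.sum()),
    )


def bin_profiles(cells: pd.DataFrame, n_bins: int = 20) -> list[BinProfile]:
    """One :class:`BinProfile` per slice, in sorted slice order."""
    validate_cell_table(cells)
    return [bin_profile(cells, s, n_bins) for s in sorted(cells["slice_id"].unique())]


def mean_laminar_position(depths: Iterable[float]) -> float:
    """Mean depth as a percentage of cortical thickness."""
    arr = np.asarray(list(depths) if not isinstance(depths, np.ndarray) else depths, dtype=float)
    if arr.size == 0:
        raise ValidationError("mean_laminar_position requires at least one cell")
    return float(100.0 * arr.mean())


def median_position_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    n_perm: int = 10_000,
    seed: int | None = None,
) -> GroupComparisonResult:
    """Two-group permutation test for the difference of medians.

    The statistic is |median(a) - median(b)|.  When the number of distinct
    label assignments C(n_a + n_b, n_a) does not exceed ``n_perm`` the test
    enumerates them all and the p-value is the exact fraction of assignments
    with a statistic at least as large as observed; otherwise ``n_perm``
    random reassignments are drawn and the p-value uses the +1 correction,
    p = (1 + #{|diff| >= obs}) / (n_perm + 1).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be nonempty")
    notes: list[str] = []
    if n_perm < 100:
        notes.append(f"n_perm={n_perm} is below 100; p-value resolution is coarse")
    observed = abs(float(np.median(a)) - float(np.median(b)))
    pooled = np.concatenate([a, b])
    n_total, n_a = pooled.size, a.size

    n_assignments = math.comb(n_total, n_a)
    if n_assignments <= n_perm:
        count = 0
        for pick in combinations(range(n_total), n_a):
            mask = np.zeros(n_total, dtype=bool)
            mask[list(pick)] = True
            diff = abs(float(np.median(pooled[mask])) - float(np.median(pooled[~mask])))
            if diff >= observed:
                count += 1
        return GroupComparisonResult(
            statistic=observed,
            p_value=count / n_assignments,
            n_permutations="exhaustive",
            method="median_permutation",
            groups=("a", "b"),
            notes=tuple(notes),
        )

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        diff = abs(float(np.median(perm[:n_a])) - float(np.median(perm[n_a:])))
        if diff >= observed:
            count += 1
    return GroupComparisonResult(
        statistic=observed,
        p_value=(1 + count) / (n_perm + 1),
        n_permutations=n_perm,
        method="median_permutation",
        groups=("a", "b"),
        notes=tuple(notes),
    )


def pairwise_median_tests(
    groups: dict[str, Sequence[float]],
    n_perm: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """All pairwise median permutation tests, Bonferroni-corrected by pair count."""
    if len(groups) < 2:
        raise ValidationError("pairwise_median_tests requires >= 2 groups")
    names = sorted(groups)
    pairs = list(combinations(names, 2))
    seeds = np.random.SeedSequence(seed).generate_state(len(pairs))
    rows = []
    for (ga, gb), s in zip(pairs, seeds):
        res = median_position_test(groups[ga], groups[gb], n_perm=n_perm, seed=int(s))
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "statistic": res.statistic,
                "p_raw": res.p_value,
                "p_bonferroni": min(1.0, res.p_value * len(pairs)),
                "n_permutations": res.n_permutations,
            }
        )
    return pd.DataFrame(rows)


def depth_density(
    depths: Sequence[float],
    bandwidth: float | str = "auto",
    grid_size: int = 512,
) -> DensityEstimate:
    """Gaussian kernel density of depths on [0, 1] with boundary reflection.

    Mass that a plain Gaussian kernel would spill past 0 or 1 is reflected
    back, so the estimate integrates to ~1 on the support.  ``bandwidth`` is
    either ``"auto"`` (Silverman's rule) or an absolute bandwidth in
    depth-fraction units.
    """
    arr = np.asarray(depths, dtype=float)
    if np.unique(arr).size < 2:
        raise ValidationError(
            "depth_density requires >= 2 distinct depths; for degenerate data "
            "use bin_profile instead"
        )
    n = arr.size
    if bandwidth == "auto":
        sd = arr.std(ddof=1)
        iqr = np.subtract(*np.percentile(arr, [75, 25]))
        scale = min(sd, iqr / 1.349) if iqr > 0 else sd
        h = 0.9 * scale * n ** (-1 / 5)
    else:
        h = float(bandwidth)
        if h <= 0:
            raise ValidationError("bandwidth must be > 0")
    grid = np.linspace(0.0, 1.0, grid_size)
    # reflect at both boundaries: kernel mass from -x and 2-x folds back in
    diffs = grid[:, None] - arr[None, :]
    refl_low = grid[:, None] + arr[None, :]
    refl_high = (2.0 - grid[:, None]) - arr[None, :]
    dens = (
        np.exp(-0.5 * (diffs / h) ** 2)
        + np.exp(-0.5 * (refl_low / h) ** 2)
        + np.exp(-0.5 * (refl_high / h) ** 2)
    ).sum(axis=1) / (n * h * np.sqrt(2 * np.pi))
    return DensityEstimate(grid=grid, density=dens, bandwidth=h)


def depth_ecdf(depths: Sequence[float], x: float | np.ndarray) -> float | np.ndarray:
    """Right-continuous empirical CDF: fraction of depths <= x."""
    arr = np.sort(np.asarray(depths, dtype=float))
    if arr.size == 0:
        raise ValidationError("depth_ecdf requires at least one cell")
    vals = np.searchsorted(arr, np.asarray(x, dtype=float), side="right") / arr.size
    return float(vals) if np.isscalar(x) else vals


def ad_k_sample_test(groups: Sequence[Sequence[float]]) -> GroupComparisonResult:
    """Scholz-Stephens k-sample Anderson-Darling test (midrank version).

    Rank-based, hence invariant under any common strictly monotone transform
    of all the data.  The returned p-value is the standardized approximation,
    clipped by the underlying tables to [0.001, 0.25].
    """
    if len(groups) < 2:
        raise ValidationError("ad_k_sample_test requires >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrays):
        if g.size < 5:
            raise ValidationError(f"group {i} has {g.size} < 5 observations")
    with warnings.catch_warnings():
        # scipy warns when the interpolated p-value hits the table's range cap
        warnings.simplefilter("ignore")
        res = stats.anderson_ksamp(arrays, variant="midrank")
    return GroupComparisonResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_permutations=0,
        method="anderson_darling_k",
        groups=tuple(f"group{i}" for i in range(len(arrays))),
    )
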