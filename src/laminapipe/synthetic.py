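"""Synthetic-data generators for every pipeline stage.

Three generators produce inputs with the statistical structure the downstream
analyses assume:

* :func:`gen_columns` — per-cell normalized depths in cortical columns, as a
  mixture of truncated-Gaussian laminar bands with a genotype-dependent shift
  ``delta`` toward the pial surface and animal/slice random intercepts.
* :func:`gen_gene_universe` — an expressed-gene universe, a disease gene set,
  and a differentially-expressed (DEX) gene list with a planted overlap
  enrichment ``fold``.
* :func:`gen_expression` — a nonnegative RPKM-scale matrix whose genes share a
  module latent factor so that within-module Pearson correlation on
  ``log2(x + 1)`` approximates a target ``within_module_r``.

All generators are pure functions of (config, seed): the same config yields
byte-identical output. With every planted effect at zero they produce data
under the null of every downstream test, which is how the type-I-error
calibrations are run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "LayerSpec",
    "ColumnSimConfig",
    "EnrichmentSimConfig",
    "ExpressionSimConfig",
    "DEFAULT_LAYERS",
    "gen_columns",
    "gen_gene_universe",
    "gen_expression",
]


@dataclass(frozen=True)
class LayerSpec:
    """One laminar band of a cortical column.

    Depths are fractions of cortical thickness: 0 = ventral boundary,
    1 = pial surface.
    """

    name: str
    depth_center: float
    depth_sd: float
    weight: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.depth_center <= 1.0:
            raise ConfigurationError(
                f"layer {self.name!r}: depth_center {self.depth_center} not in [0, 1]"
            )
        if self.depth_sd <= 0:
            raise ConfigurationError(f"layer {self.name!r}: depth_sd must be > 0")
        if self.weight < 0:
            raise ConfigurationError(f"layer {self.name!r}: weight must be >= 0")


#: Default laminar bands, approximating the deep-to-superficial marker bands
#: (L6, L5, L4, L2/3) of a P30 somatosensory column.
DEFAULT_LAYERS: tuple[LayerSpec, ...] = (
    LayerSpec("L6", depth_center=0.20, depth_sd=0.07, weight=0.30),
    LayerSpec("L5", depth_center=0.42, depth_sd=0.06, weight=0.25),
    LayerSpec("L4", depth_center=0.58, depth_sd=0.04, weight=0.20),
    LayerSpec("L2/3", depth_center=0.78, depth_sd=0.07, weight=0.25),
)


@dataclass(frozen=True)
class ColumnSimConfig:
    """Configuration of the layered-column simulator.

    ``genotype_shifts`` maps genotype label to the signed depth-fraction shift
    ``delta`` added to every layer center (positive = toward the pia, the
    over-migration direction).  ``animal_sd`` and ``slice_sd`` are Gaussian
    random-intercept scales on ``delta``, reproducing the slices-within-animals
    replicate hierarchy.
    """

    layers: tuple[LayerSpec, ...] = DEFAULT_LAYERS
    genotype_shifts: dict[str, float] = field(
        default_factory=lambda: {"WT": 0.0, "KO": 0.0}
    )
    n_animals_per_genotype: int = 5
    slices_per_animal: int = 5
    cells_per_slice: int = 150
    animal_sd: float = 0.0
    slice_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.layers:
            raise ConfigurationError("at least one layer is required")
        total = sum(l.weight for l in self.layers)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"layer weights must sum to 1 (got {total:.6g})"
            )
        for name in ("n_animals_per_genotype", "slices_per_animal", "cells_per_slice"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.animal_sd < 0 or self.slice_sd < 0:
            raise ConfigurationError("hierarchical noise scales must be >= 0")
        if not self.genotype_shifts:
            raise ConfigurationError("at least one genotype is required")


@dataclass(frozen=True)
class EnrichmentSimConfig:
    """Universe / disease-set / DEX-list simulator configuration.

    ``fold`` multiplies the chance-expected overlap: the DEX overlap count is
    drawn Binomial(n, min(1, fold * K / N)), giving expected overlap
    ``fold * n * K / N`` exactly.
    """

    universe_size: int
    set_size: int
    dex_size: int
    fold: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        n, k_set, n_dex = self.universe_size, self.set_size, self.dex_size
        if n < 1:
            raise ConfigurationError("universe_size must be >= 1")
        if not 0 <= k_set <= n:
            raise ConfigurationError("set_size must satisfy 0 <= K <= N")
        if not 0 <= n_dex <= n:
            raise ConfigurationError("dex_size must satisfy 0 <= n <= N")
        if self.fold < 0:
            raise ConfigurationError("fold must be >= 0")
        if self.fold * k_set / n > 1 + 1e-12:
            raise ConfigurationError(
                f"fold * K / N = {self.fold * k_set / n:.3g} exceeds 1; "
                "the planted overlap probability is not a probability"
            )


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Factor-model expression simulator configuration.

    Genes sharing a module id load on a common latent factor with loading
    ``sqrt(within_module_r)``, so within-module Pearson correlation of the
    log2-scale values approximates ``within_module_r``; ``noise_sd`` adds
    independent measurement noise on the log2 scale on top of the unit-variance
    signal.
    """

    n_genes: int
    n_samples: int
    module_assignment: dict[str, int] = field(default_factory=dict)
    within_module_r: float = 0.8
    noise_sd: float = 0.1
    seed: int = 0
    base_log2: float = 4.0
    log2_sd: float = 1.5

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ConfigurationError("n_samples must be >= 3")
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if not 0.0 <= self.within_module_r < 1.0:
            raise ConfigurationError("within_module_r must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


def _truncated_normal(
    rng: np.random.Generator, centers: np.ndarray, sds: np.ndarray
) -> np.ndarray:
    """Rejection-sample N(center, sd) truncated to [0, 1], elementwise."""
    out = rng.normal(centers, sds)
    bad = (out < 0.0) | (out > 1.0)
    # worst case (center at a boundary) accepts ~half the draws per round
    while bad.any():
        out[bad] = rng.normal(centers[bad], sds[bad])
        bad = (out < 0.0) | (out > 1.0)
    return out


def gen_columns(config: ColumnSimConfig) -> pd.DataFrame:
    """Simulate per-cell depths for every slice of every animal.

    Returns a cell-position table with columns
    ``cell_id, depth_fraction, slice_id, animal_id, genotype``; every depth
    lies in [0, 1].  Deterministic for a fixed config (seed included).
    """
    rng = np.random.default_rng(config.seed)
    centers = np.array([l.depth_center for l in config.layers])
    sds = np.array([l.depth_sd for l in config.layers])
    weights = np.array([l.weight for l in config.layers])

    frames = []
    for genotype in sorted(config.genotype_shifts):
        delta = config.genotype_shifts[genotype]
        for a in range(config.n_animals_per_genotype):
            animal_id = f"{genotype}_a{a + 1:02d}"
            animal_shift = delta + rng.normal(0.0, config.animal_sd)
            for s in range(config.slices_per_animal):
                slice_id = f"{animal_id}_s{s + 1:02d}"
                shift = animal_shift + rng.normal(0.0, config.slice_sd)
                comp = rng.choice(len(weights), size=config.cells_per_slice, p=weights)
                cell_centers = np.clip(centers[comp] + shift, 0.0, 1.0)
                depths = _truncated_normal(rng, cell_centers, sds[comp])
                frames.append(
                    pd.DataFrame(
                        {
                            "cell_id": [
                                f"{slice_id}_c{i + 1:04d}"
                                for i in range(config.cells_per_slice)
                            ],
                            "depth_fraction": depths,
                            "slice_id": slice_id,
                            "animal_id": animal_id,
                            "genotype": genotype,
                        }
                    )
                )
    return pd.concat(frames, ignore_index=True)


def gen_gene_universe(
    config: EnrichmentSimConfig,
) -> tuple[set[str], set[str], set[str]]:
    """Simulate (universe, disease set, DEX set) with a planted enrichment.

    The overlap count is drawn Binomial(n, min(1, fold*K/N)); overlap members
    are sampled from the disease set and the remaining DEX members from
    outside it, so the expected overlap is exactly ``fold * n * K / N``.
    """
    rng = np.random.default_rng(config.seed)
    n_univ, k_set, n_dex = config.universe_size, config.set_size, config.dex_size
    labels = np.array([f"G{i:06d}" for i in range(n_univ)])

    set_idx = rng.choice(n_univ, size=k_set, replace=False)
    in_set = np.zeros(n_univ, dtype=bool)
    in_set[set_idx] = True
    outside_idx = np.flatnonzero(~in_set)

    p_overlap = min(1.0, config.fold * k_set / n_univ) if n_univ else 0.0
    m = int(rng.binomial(n_dex, p_overlap))
    m = min(m, k_set)
    n_out = n_dex - m
    if n_out > outside_idx.size:
        # degenerate corner: not enough non-set genes; spill back into the set
        spill = n_out - outside_idx.size
        n_out = outside_idx.size
        m = min(m + spill, k_set)
    dex_idx = np.concatenate(
        [
            rng.choice(set_idx, size=m, replace=False),
            rng.choice(outside_idx, size=n_out, replace=False),
        ]
    )
    universe = set(labels)
    disease = set(labels[set_idx])
    dex = set(labels[dex_idx])
    return universe, disease, dex


def gen_expression(config: ExpressionSimConfig) -> pd.DataFrame:
    """Simulate a genes x samples RPKM matrix with module co-expression.

    Log2-scale values are ``base_log2 + log2_sd * z`` where ``z`` mixes a
    per-module latent factor (loading sqrt(r)) with independent noise
    (loading sqrt(1-r)); ``noise_sd`` adds extra independent log2-scale
    noise.  RPKM = max(0, 2**L - 1), so log2(RPKM + 1) recovers L wherever
    L >= 0 (the clip touches <1% of entries at the defaults).
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"gene{i:05d}" for i in range(config.n_genes)]
    r = config.within_module_r

    module_ids = sorted({m for m in config.module_assignment.values()})
    factors = {m: rng.normal(size=config.n_samples) for m in module_ids}

    z = np.empty((config.n_genes, config.n_samples))
    for i, g in enumerate(genes):
        eps = rng.normal(size=config.n_samples)
        m = config.module_assignment.get(g)
        if m is None:
            z[i] = eps
        else:
            z[i] = np.sqrt(r) * factors[m] + np.sqrt(1.0 - r) * eps
    log2_vals = (
        config.base_log2
        + config.log2_sd * z
        + config.noise_sd * rng.normal(size=z.shape)
    )
    rpkm = np.maximum(0.0, np.exp2(log2_vals) - 1.0)
    samples = [f"sample{j:03d}" for j in range(config.n_samples)]
    return pd.DataFrame(rpkm, index=genes, columns=samples)
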