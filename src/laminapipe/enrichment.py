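"""Gene-set overlap enrichment with analytic and resampling nulls.

Given a differentially-expressed (DEX) gene list, an expressed-gene universe
of size N, and a curated gene set occupying K of the N genes, the overlap k
out of the n DEX genes is tested for over-representation three ways:

* binomial: P(X >= k), X ~ Binomial(n, K/N) — sampling with replacement;
* hypergeometric: P(X >= k), X ~ Hypergeom(N, K, n) — without replacement;
* resampling: R random n-subsets of the universe, p with the +1 correction
  (the resampling null is exactly the hypergeometric, so the two converge).

Binomial p-values across the compared sets are Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

__all__ = [
    "GeneSet",
    "OverlapResult",
    "normalize_genes",
    "overlap_percent",
    "binomial_overlap_test",
    "hypergeometric_overlap_test",
    "resampling_null",
    "bh_adjust",
    "enrich_report",
    "dex_accounting",
]


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))


@dataclass(frozen=True)
class OverlapResult:
    set_name: str
    k: int
    n: int
    K: int
    N: int
    percent: float
    p_binomial: float
    p_hypergeometric: float
    p_permutation: float
    q_bh: float
    n_resamples: int
    out_of_universe: int = 0

    @property
    def percent_rounded(self) -> float:
        return round(self.percent, 1)


def normalize_genes(genes: Iterable[str]) -> frozenset[str]:
    """Upper-case and strip identifiers so matching is deterministic."""
    return frozenset(str(g).strip().upper() for g in genes if str(g).strip())


def overlap_percent(k: int, n: int) -> float:
    """100*k/n; callers round to one decimal for reporting."""
    if n <= 0:
        raise ValidationError("overlap_percent requires n > 0")
    if not 0 <= k <= n:
        raise ValidationError("overlap count must satisfy 0 <= k <= n")
    return 100.0 * k / n


def _check_counts(k: int, n: int, K: int, N: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(n, K) + 0):
        if K > N or n > N:
            raise ValidationError("need K <= N and n <= N")
        if k > n:
            raise ValidationError("overlap k cannot exceed DEX size n")


def binomial_overlap_test(k: int, n: int, K: int, N: int) -> float:
    """One-sided enrichment tail P(X >= k), X ~ Binomial(n, K/N)."""
    _check_counts(k, n, K, N)
    if K == 0:
        return 0.0 if k > 0 else 1.0  # impossible under the model when k > 0
    return float(stats.binom.sf(k - 1, n, K / N))


def hypergeometric_overlap_test(k: int, n: int, K: int, N: int) -> float:
    """One-sided enrichment tail P(X >= k), X ~ Hypergeom(N, K, n)."""
    _check_counts(k, n, K, N)
    if K == 0:
        return 0.0 if k > 0 else 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def resampling_null(
    dex_size: int,
    gene_set: GeneSet | frozenset[str],
    universe: Iterable[str],
    k_observed: int,
    R: int = 1000,
    seed: int | None = None,
) -> tuple[float, np.ndarray]:
    """Resampling-validation p-value for an observed overlap.

    Draws R random ``dex_size``-subsets of the universe without replacement,
    counts their overlap with the gene set, and returns
    (p, null_overlaps) with p = (1 + #{overlap >= k_observed}) / (R + 1).
    """
    if R < 1:
        raise ValidationError("resampling_null requires R >= 1")
    members = gene_set.members if isinstance(gene_set, GeneSet) else frozenset(gene_set)
    univ = np.array(sorted(set(universe)))
    n_univ = univ.size
    if dex_size > n_univ:
        raise ValidationError("dex_size exceeds universe size")
    in_set = np.isin(univ, sorted(members))
    rng = np.random.default_rng(seed)
    # vectorized subset draws: argpartition of uniform keys per replicate
    keys = rng.random((R, n_univ))
    picks = np.argpartition(keys, dex_size - 1, axis=1)[:, :dex_size]
    null = in_set[picks].sum(axis=1)
    p = (1 + int((null >= k_observed).sum())) / (R + 1)
    return p, null


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_report(
    dex: GeneSet | Iterable[str],
    sets: Sequence[GeneSet],
    universe: Iterable[str],
    R: int = 1000,
    seed: int | None = None,
) -> list[OverlapResult]:
    """One :class:`OverlapResult` per gene set, BH-adjusted across sets.

    Identifiers are normalized (upper-cased, stripped); set members outside
    the universe are dropped from the computation but counted in
    ``out_of_universe``.  The BH adjustment is applied to the binomial
    p-values, the primary test.
    """
    universe_n = normalize_genes(universe)
    if not universe_n:
        raise ValidationError("universe is empty")
    dex_members = dex.members if isinstance(dex, GeneSet) else frozenset(dex)
    dex_n = normalize_genes(dex_members) & universe_n
    if not dex_n:
        raise ValidationError("DEX list is empty after intersection with the universe")

    n = len(dex_n)
    N = len(universe_n)
    seeds = np.random.SeedSequence(seed).generate_state(max(1, len(sets)))
    results = []
    for i, gs in enumerate(sets):
        members_norm = normalize_genes(gs.members)
        in_univ = members_norm & universe_n
        k = len(dex_n & in_univ)
        K = len(in_univ)
        p_perm, _ = resampling_null(
            n, in_univ, universe_n, k, R=R, seed=int(seeds[i])
        )
        results.append(
            OverlapResult(
                set_name=gs.name,
                k=k,
                n=n,
                K=K,
                N=N,
                percent=overlap_percent(k, n),
                p_binomial=binomial_overlap_test(k, n, K, N),
                p_hypergeometric=hypergeometric_overlap_test(k, n, K, N),
                p_permutation=p_perm,
                q_bh=np.nan,
                n_resamples=R,
                out_of_universe=len(members_norm - universe_n),
            )
        )
    qs = bh_adjust([r.p_binomial for r in results])
    return [
        OverlapResult(**{**r.__dict__, "q_bh": float(q)}) for r, q in zip(results, qs)
    ]


def dex_accounting(
    n_down: int, n_up: int, n_generic: int | None = None
) -> dict[str, int]:
    """Bookkeeping of a DEX gene list: totals and layer-enriched remainder."""
    if n_down < 0 or n_up < 0:
        raise ValidationError("counts must be >= 0")
    out = {"n_down": n_down, "n_up": n_up, "n_total": n_down + n_up}
    if n_generic is not None:
        if n_generic > out["n_total"]:
            raise ValidationError("generic genes cannot exceed the DEX total")
        out["n_generic"] = n_generic
        out["n_layer_enriched"] = out["n_total"] - n_generic
    return out
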