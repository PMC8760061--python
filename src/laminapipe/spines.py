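"""Dendritic-spine turnover rates from longitudinal two-photon counts.

For each imaged dendritic segment with ``n_day0`` spines at the first
session, ``n_gained`` and ``n_lost`` over the interval:

    formation_pct   = 100 * n_gained / n_day0
    elimination_pct = 100 * n_lost   / n_day0
    net_addition_pct = formation_pct - elimination_pct

Group comparisons aggregate segments to animal means first (animals, not
segments, are the replicate unit), then run a two-tailed t-test or a
Mann-Whitney test depending on a Shapiro-Wilk normality gate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = ["SpineSurvey", "TurnoverRates", "GroupTurnoverResult", "turnover_rates", "group_turnover"]


@dataclass(frozen=True)
class SpineSurvey:
    segment_id: str
    animal_id: str
    genotype: str
    n_day0: int
    n_gained: int
    n_lost: int
    interval_days: float = 3.0

    def __post_init__(self) -> None:
        if min(self.n_day0, self.n_gained, self.n_lost) < 0:
            raise ValidationError("spine counts must be >= 0")
        if self.n_lost > self.n_day0:
            raise ValidationError(
                f"segment {self.segment_id!r}: cannot lose more spines "
                f"({self.n_lost}) than present at day 0 ({self.n_day0})"
            )


@dataclass(frozen=True)
class TurnoverRates:
    formation_pct: float
    elimination_pct: float
    net_addition_pct: float


@dataclass(frozen=True)
class GroupTurnoverResult:
    rate: str
    groups: tuple[str, str]
    means: tuple[float, float]
    statistic: float
    p_value: float
    test: str
    n_animals: tuple[int, int]


def turnover_rates(s: SpineSurvey) -> TurnoverRates:
    """Per-interval formation/elimination/net-addition percentages."""
    if s.n_day0 == 0:
        raise ValidationError(f"segment {s.segment_id!r} has no day-0 spines")
    formation = 100.0 * s.n_gained / s.n_day0
    elimination = 100.0 * s.n_lost / s.n_day0
    return TurnoverRates(formation, elimination, formation - elimination)


def animal_means(surveys: Sequence[SpineSurvey]) -> pd.DataFrame:
    """Mean rates per animal (segments averaged within animal)."""
    rows = []
    for s in surveys:
        r = turnover_rates(s)
        rows.append(
            {
                "animal_id": s.animal_id,
                "genotype": s.genotype,
                "formation_pct": r.formation_pct,
                "elimination_pct": r.elimination_pct,
                "net_addition_pct": r.net_addition_pct,
            }
        )
    df = pd.DataFrame(rows)
    return df.groupby(["genotype", "animal_id"], as_index=False).mean(numeric_only=True)


def group_turnover(
    surveys: Sequence[SpineSurvey],
    rates: Sequence[str] = ("formation_pct", "elimination_pct", "net_addition_pct"),
    alpha_normality: float = 0.05,
) -> list[GroupTurnoverResult]:
    """Animal-level two-group comparison of turnover rates.

    Uses a two-tailed t-test when both groups pass Shapiro-Wilk normality
    (or are too small for it to apply), Mann-Whitney otherwise.
    """
    if not surveys:
        raise ValidationError("no surveys provided")
    per_animal = animal_means(surveys)
    genotypes = sorted(per_animal["genotype"].unique())
    if len(genotypes) != 2:
        raise ValidationError(f"group_turnover needs exactly 2 genotypes, got {genotypes}")
    ga, gb = genotypes
    out = []
    for rate in rates:
        va = per_animal.loc[per_animal["genotype"] == ga, rate].to_numpy()
        vb = per_animal.loc[per_animal["genotype"] == gb, rate].to_numpy()
        if min(va.size, vb.size) < 2:
            raise ValidationError("each genotype needs >= 2 animals")
        normal = True
        for v in (va, vb):
            if v.size >= 3 and np.ptp(v) > 0:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # near-identical data
                    if stats.shapiro(v).pvalue < alpha_normality:
                        normal = False
        if normal:
            stat, p = stats.ttest_ind(va, vb)
            test = "t"
        else:
            stat, p = stats.mannwhitneyu(va, vb, alternative="two-sided")
            test = "mann_whitney"
        out.append(
            GroupTurnoverResult(
                rate=rate,
                groups=(ga, gb),
                means=(float(va.mean()), float(vb.mean())),
                statistic=float(stat),
                p_value=float(p),
                test=test,
                n_animals=(va.size, vb.size),
            )
        )
    return out
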