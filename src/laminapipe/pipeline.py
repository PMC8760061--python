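"""End-to-end pipeline runner: simulate -> laminar -> spatial-anova ->
enrich -> network -> turnover, with a RunRecord tracing every seed and
branch decision."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np

from . import __version__
from . import io as lio
from .enrichment import GeneSet, enrich_report
from .errors import ConfigurationError
from .laminar import ad_k_sample_test, bin_profiles, mean_laminar_position, median_position_test
from .network import degree_table, edge_weight_scaling, log_transform, pearson_network
from .spatial import adjusted_anova
from .spines import group_turnover
from .synthetic import (
    ColumnSimConfig,
    EnrichmentSimConfig,
    ExpressionSimConfig,
    gen_columns,
    gen_expression,
    gen_gene_universe,
)

__all__ = ["PipelineConfig", "RunRecord", "run_pipeline", "ALL_STAGES"]

ALL_STAGES = ("simulate", "laminar", "spatial-anova", "enrich", "network", "turnover")


@dataclass
class PipelineConfig:
    """Stage selection, inputs, seeds, and test parameters for one run."""

    out_dir: str
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    n_perm: int = 5000
    n_resamples: int = 1000
    alpha_gate: float = 0.05
    n_bins: int = 20
    network_threshold: float = 0.7
    # inputs; when None the simulate stage must provide them
    cell_table: str | None = None
    gmt: str | None = None
    dex_list: str | None = None
    universe: str | None = None
    expression: str | None = None
    spines: str | None = None
    genotype_shift: float = 0.05

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stage(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


@dataclass
class RunRecord:
    config: dict[str, Any]
    config_hash: str
    version: str
    stages_run: list[str] = field(default_factory=list)
    branches: dict[str, Any] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> RunRecord:
    """Execute the requested stages in order; outputs land in ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    record = RunRecord(
        config=dataclasses.asdict(config),
        config_hash=_config_hash(config),
        version=__version__,
    )
    seeds = np.random.SeedSequence(config.seed).generate_state(8)

    cells = spine_surveys = expression = None
    gene_sets = dex = universe = None

    if "simulate" in config.stages:
        col_cfg = ColumnSimConfig(
            genotype_shifts={"WT": 0.0, "KO": config.genotype_shift},
            seed=int(seeds[0]),
        )
        cells = gen_columns(col_cfg)
        lio.write_cell_table(cells, out / "cells.csv")

        enr_cfg = EnrichmentSimConfig(
            universe_size=12000, set_size=1200, dex_size=250, fold=2.0,
            seed=int(seeds[1]),
        )
        univ, disease, dex_set = gen_gene_universe(enr_cfg)
        universe, dex = univ, dex_set
        gene_sets = [GeneSet("disease_set", frozenset(disease))]
        lio.write_gene_list(universe, out / "universe.tsv")
        lio.write_gene_list(dex, out / "dex.tsv")
        lio.write_gmt(gene_sets, out / "sets.gmt")

        genes = [f"gene{i:05d}" for i in range(60)]
        modules = {g: 1 for g in genes[:20]}
        expr_cfg = ExpressionSimConfig(
            n_genes=60, n_samples=40, module_assignment=modules,
            within_module_r=0.8, seed=int(seeds[2]),
        )
        expression = gen_expression(expr_cfg)
        lio.write_expression(expression, out / "expression.tsv")

        rng = np.random.default_rng(int(seeds[3]))
        from .spines import SpineSurvey

        spine_surveys = []
        for genotype, net_gain, n_animals in (("WT", 0.0, 8), ("KO", 6.0, 6)):
            for a in range(n_animals):
                animal = f"{genotype}_a{a + 1}"
                for s in range(5):
                    n0 = int(rng.integers(30, 60))
                    gained = max(0, int(rng.poisson(n0 * (0.08 + net_gain / 100))))
                    lost = min(n0, int(rng.poisson(n0 * 0.08)))
                    spine_surveys.append(
                        SpineSurvey(f"{animal}_seg{s}", animal, genotype, n0, gained, lost)
                    )
        lio.write_spines(spine_surveys, out / "spines.csv")
        record.stages_run.append("simulate")

    if "laminar" in config.stages:
        if cells is None:
            if config.cell_table is None:
                raise ConfigurationError("laminar stage needs a cell table")
            cells = lio.read_cell_table(config.cell_table)
        profiles = bin_profiles(cells, n_bins=config.n_bins)
        lio.write_bin_profiles(profiles, out / "bin_profiles.tsv")
        by_geno = {
            g: grp["depth_fraction"].to_numpy()
            for g, grp in cells.groupby("genotype")
        }
        genos = sorted(by_geno)
        summary: dict[str, Any] = {
            "mean_laminar_position_pct": {
                g: mean_laminar_position(v) for g, v in by_geno.items()
            }
        }
        if len(genos) == 2:
            med = median_position_test(
                by_geno[genos[0]], by_geno[genos[1]],
                n_perm=config.n_perm, seed=int(seeds[4]),
            )
            ad = ad_k_sample_test([by_geno[g] for g in genos])
            summary["median_permutation"] = dataclasses.asdict(med)
            summary["anderson_darling"] = dataclasses.asdict(ad)
        lio.write_json(summary, out / "laminar_summary.json")
        record.stages_run.append("laminar")

    if "spatial-anova" in config.stages:
        profiles = lio.read_bin_profiles(out / "bin_profiles.tsv")
        res = adjusted_anova(
            profiles,
            alpha_gate=config.alpha_gate,
            n_perm=config.n_perm,
            seed=int(seeds[5]),
        )
        record.branches["spatial_anova"] = res.branch
        payload = dataclasses.asdict(res)
        payload["posthoc"] = res.posthoc
        lio.write_json(payload, out / "spatial_anova.json")
        record.stages_run.append("spatial-anova")

    if "enrich" in config.stages:
        if gene_sets is None:
            if not (config.gmt and config.dex_list and config.universe):
                raise ConfigurationError("enrich stage needs --gmt, --dex and --universe")
            gene_sets = lio.read_gmt(config.gmt)
            dex = lio.read_gene_list(config.dex_list)
            universe = lio.read_gene_list(config.universe)
        results = enrich_report(
            dex, gene_sets, universe, R=config.n_resamples, seed=int(seeds[6])
        )
        lio.write_json([dataclasses.asdict(r) for r in results], out / "enrichment.json")
        record.stages_run.append("enrich")

    if "network" in config.stages:
        if expression is None:
            if config.expression is None:
                raise ConfigurationError("network stage needs an expression matrix")
            expression = lio.read_expression(config.expression)
        net = pearson_network(log_transform(expression), threshold=config.network_threshold)
        degree_table(net).to_csv(out / "degree.tsv", sep="\t")
        edge_weight_scaling(net).to_csv(out / "edges.tsv", sep="\t", index=False)
        record.branches["network_dropped_zero_variance"] = len(net.dropped_zero_variance)
        record.stages_run.append("network")

    if "turnover" in config.stages:
        if spine_surveys is None:
            if config.spines is None:
                raise ConfigurationError("turnover stage needs a spine-count table")
            spine_surveys = lio.read_spines(config.spines)
        comparisons = group_turnover(spine_surveys)
        lio.write_json([dataclasses.asdict(c) for c in comparisons], out / "turnover.json")
        record.stages_run.append("turnover")

    lio.write_json(dataclasses.asdict(record), out / "run_record.json")
    return record
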