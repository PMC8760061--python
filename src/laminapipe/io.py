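"""File formats: cell tables (CSV), bin profiles (TSV), GMT gene sets,
expression matrices (TSV), spine counts (CSV), result JSON, and the
blind/unblind relabeling used to mask genotypes during scoring.

Dialects are fixed: UTF-8, header row required, '.' decimal separator.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .enrichment import GeneSet
from .laminar import REQUIRED_CELL_COLUMNS, BinProfile, validate_cell_table
from .spines import SpineSurvey

__all__ = [
    "read_cell_table",
    "write_cell_table",
    "read_bin_profiles",
    "write_bin_profiles",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "write_gene_list",
    "read_expression",
    "write_expression",
    "read_spines",
    "write_spines",
    "write_json",
    "blind_labels",
    "unblind",
]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s): {missing}")


def _read_table(path: str | Path, sep: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    df = pd.read_csv(path, sep=sep)
    if df.empty and df.columns.empty:
        raise ValidationError(f"{path}: file is empty")
    return df


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-cell position CSV."""
    path = Path(path)
    df = _read_table(path, sep=",")
    _require_columns(df, REQUIRED_CELL_COLUMNS, path)
    depths = pd.to_numeric(df["depth_fraction"], errors="coerce")
    bad = np.flatnonzero(~np.isfinite(depths) | (depths < 0) | (depths > 1))
    if bad.size:
        # +2: header line plus 1-based numbering
        lines = (bad[:10] + 2).tolist()
        raise ValidationError(
            f"{path}: {bad.size} row(s) with depth_fraction outside [0, 1] "
            f"(file lines {lines})"
        )
    df["depth_fraction"] = depths
    return validate_cell_table(df)


def write_cell_table(cells: pd.DataFrame, path: str | Path) -> None:
    validate_cell_table(cells)
    cells.to_csv(path, index=False)


def write_bin_profiles(profiles: Sequence[BinProfile], path: str | Path) -> None:
    """TSV: slice_id, genotype, bin_01..bin_NN, n_cells."""
    if not profiles:
        raise ValidationError("no profiles to write")
    n_bins = profiles[0].n_bins
    rows = []
    for p in profiles:
        row: dict[str, Any] = {"slice_id": p.slice_id, "genotype": p.genotype}
        row.update({f"bin_{i + 1:02d}": p.percentages[i] for i in range(n_bins)})
        row["n_cells"] = p.n_cells
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_bin_profiles(path: str | Path) -> list[BinProfile]:
    path = Path(path)
    df = _read_table(path, sep="\t")
    _require_columns(df, ["slice_id", "genotype", "n_cells"], path)
    bin_cols = sorted(c for c in df.columns if c.startswith("bin_"))
    if not bin_cols:
        raise ValidationError(f"{path}: no bin_XX columns found")
    out = []
    for _, row in df.iterrows():
        out.append(
            BinProfile(
                slice_id=str(row["slice_id"]),
                genotype=str(row["genotype"]),
                percentages=row[bin_cols].to_numpy(dtype=float),
                n_cells=int(row["n_cells"]),
            )
        )
    return out


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Standard GMT: per line, set name, description, then tab-separated members.

    Duplicate members within a line are deduplicated with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    sets = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(
                f"{path}:{lineno}: GMT line needs name, description and >= 1 member"
            )
        name, _desc, *members = parts
        members = [m for m in members if m.strip()]
        unique = list(dict.fromkeys(members))
        if len(unique) < len(members):
            warnings.warn(
                f"{path}:{lineno}: {len(members) - len(unique)} duplicate member(s) "
                f"in set {name!r} were deduplicated",
                stacklevel=2,
            )
        sets.append(GeneSet(name=name, members=frozenset(unique)))
    if not sets:
        raise ValidationError(f"{path}: file is empty")
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    lines = [
        "\t".join([gs.name, "na", *sorted(gs.members)]) for gs in sets
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_gene_list(path: str | Path) -> frozenset[str]:
    """One-column TSV of gene identifiers (header optional: 'gene')."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    lines = [l.strip() for l in path.read_text(encoding="utf-8").splitlines() if l.strip()]
    if lines and lines[0].lower() == "gene":
        lines = lines[1:]
    if not lines:
        raise ValidationError(f"{path}: no genes found")
    return frozenset(lines)


def write_gene_list(genes: Sequence[str] | frozenset[str], path: str | Path) -> None:
    Path(path).write_text(
        "gene\n" + "\n".join(sorted(genes)) + "\n", encoding="utf-8"
    )


def read_expression(path: str | Path) -> pd.DataFrame:
    """TSV, gene rows x sample columns, first column = gene id."""
    path = Path(path)
    df = _read_table(path, sep="\t")
    df = df.set_index(df.columns[0])
    vals = df.apply(pd.to_numeric, errors="coerce")
    if vals.isna().any().any():
        raise ValidationError(f"{path}: non-numeric or missing expression values")
    if (vals.to_numpy() < 0).any():
        raise ValidationError(f"{path}: negative expression values")
    vals.index.name = None
    return vals


def write_expression(x: pd.DataFrame, path: str | Path) -> None:
    x.to_csv(path, sep="\t", index_label="gene")


SPINE_COLUMNS = (
    "segment_id",
    "animal_id",
    "genotype",
    "n_day0",
    "n_gained",
    "n_lost",
    "interval_days",
)


def read_spines(path: str | Path) -> list[SpineSurvey]:
    path = Path(path)
    df = _read_table(path, sep=",")
    _require_columns(df, SPINE_COLUMNS[:-1], path)
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                SpineSurvey(
                    segment_id=str(row["segment_id"]),
                    animal_id=str(row["animal_id"]),
                    genotype=str(row["genotype"]),
                    n_day0=int(row["n_day0"]),
                    n_gained=int(row["n_gained"]),
                    n_lost=int(row["n_lost"]),
                    interval_days=float(row.get("interval_days", 3.0)),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}: line {i + 2}: {exc}") from exc
    return out


def write_spines(surveys: Sequence[SpineSurvey], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(s) for s in surveys]).to_csv(path, index=False)


class _JsonEncoder(json.JSONEncoder):
    def default(self, o: Any) -> Any:
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        return super().default(o)


def write_json(obj: Any, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, cls=_JsonEncoder) + "\n",
        encoding="utf-8",
    )


def blind_labels(
    table: pd.DataFrame, seed: int | None = None, column: str = "genotype"
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Replace genotype labels by random codes; returns (table, key).

    The key maps code -> original label and is what :func:`unblind` consumes.
    The same seed yields the same coding.
    """
    if column not in table.columns:
        raise ValidationError(f"column {column!r} not present")
    rng = np.random.default_rng(seed)
    labels = sorted(table[column].astype(str).unique())
    codes = [f"group_{c}" for c in rng.permutation(len(labels))]
    forward = dict(zip(labels, codes))
    out = table.copy()
    out[column] = out[column].astype(str).map(forward)
    return out, {code: label for label, code in forward.items()}


def unblind(
    table: pd.DataFrame, key: dict[str, str], column: str = "genotype"
) -> pd.DataFrame:
    """Restore original labels from a blinding key."""
    if column not in table.columns:
        raise ValidationError(f"column {column!r} not present")
    present = set(table[column].astype(str).unique())
    unknown = present - set(key)
    if unknown:
        raise ValidationError(f"blinding key does not cover label(s): {sorted(unknown)}")
    out = table.copy()
    out[column] = out[column].astype(str).map(key)
    return out
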