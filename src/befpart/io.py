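"""CSV interchange: commented headers, schema validation, config loading.

All tables travel as UTF-8, comma-delimited CSV with a mandatory header row
and "." as decimal separator.  Files written by the package carry leading
comment lines (prefixed ``#``) recording the tool version, the seed and a
hash of the configuration, so every artifact is traceable to the run that
produced it; readers skip those lines.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "Violation",
    "SCHEMAS",
    "write_table",
    "read_table",
    "validate_schema",
    "has_errors",
    "load_config_file",
    "config_hash",
]


class SchemaError(ValueError):
    """A table failed schema validation where conformance is required."""


@dataclass(frozen=True)
class Violation:
    severity: str  # "error" | "warning"
    row: int | None
    column: str | None
    message: str


@dataclass(frozen=True)
class _Col:
    name: str
    kind: str  # "str" | "int" | "float"
    min: float | None = None
    min_exclusive: bool = False
    allowed: tuple | None = None
    nullable: bool = False
    unique: bool = False


# Unknown columns yield warnings, never errors (forward compatibility).
SCHEMAS: dict[str, tuple[_Col, ...]] = {
    "design": (
        _Col("pot_id", "str", unique=True),
        _Col("richness", "int", min=1),
        _Col("species_list", "str"),
        _Col("drought", "int", allowed=(0, 1)),
        _Col("biochar", "int", allowed=(0, 1)),
        _Col("replicate", "int", min=1),
    ),
    "individuals": (
        _Col("pot_id", "str"),
        _Col("species", "str"),
        _Col("height_cm", "float", min=0, min_exclusive=True, nullable=True),
        _Col("leaf_area_mm2", "float", min=0, min_exclusive=True, nullable=True),
        _Col("leaf_dry_mass_mg", "float", min=0, min_exclusive=True, nullable=True),
        _Col("root_length_cm", "float", min=0, min_exclusive=True, nullable=True),
        _Col("root_dry_mass_g", "float", min=0, min_exclusive=True, nullable=True),
        _Col("shoot_dry_mass_g", "float", min=0, min_exclusive=True, nullable=True),
    ),
    "pots": (
        _Col("pot_id", "str"),
        _Col("species", "str"),
        _Col("biomass_g", "float", min=0),
    ),
    "effects": (
        _Col("pot_id", "str", unique=True),
        _Col("drought", "int", allowed=(0, 1)),
        _Col("biochar", "int", allowed=(0, 1)),
        _Col("richness", "int", min=2),
        _Col("expected_biomass_g", "float", min=0, min_exclusive=True),
        _Col("observed_biomass_g", "float", min=0),
        _Col("nbe_g", "float"),
        _Col("ce_g", "float"),
        _Col("se_g", "float"),
        _Col("additivity_residual_g", "float"),
    ),
}


def config_hash(meta: dict) -> str:
    """Short stable hash of a configuration mapping."""
    canon = json.dumps(meta, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def write_table(
    df: pd.DataFrame, path, *, seed: int | None = None, meta: dict | None = None
) -> None:
    """Write a CSV with provenance header comments."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(f"# befpart v{__version__}\n")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        if meta is not None:
            fh.write(f"# config_hash={config_hash(meta)}\n")
        df.to_csv(fh, index=False)


def read_table(path, schema: str | None = None) -> pd.DataFrame:
    """Read a befpart CSV (skipping ``#`` comments), optionally enforcing a schema."""
    path = Path(path)
    if not path.exists():
        raise OSError(f"no such file: {path}")
    df = pd.read_csv(path, comment="#")
    if schema is not None:
        report = validate_schema(df, schema, source=str(path))
        if has_errors(report):
            first = next(v for v in report if v.severity == "error")
            raise SchemaError(
                f"{path}: schema '{schema}' violated — {first.message}"
                + (f" (row {first.row})" if first.row is not None else "")
            )
    return df


def has_errors(report: list[Violation]) -> bool:
    return any(v.severity == "error" for v in report)


def validate_schema(
    table: pd.DataFrame | str | Path, schema_name: str, source: str = ""
) -> list[Violation]:
    """Validate a table against a named schema.

    Returns the full list of violations; errors mark non-conformance,
    warnings (e.g. unknown columns) do not.  Row indices are 0-based data
    rows (header and comment lines excluded).
    """
    if schema_name not in SCHEMAS:
        raise ValueError(
            f"unknown schema {schema_name!r}; choose from {sorted(SCHEMAS)}"
        )
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, comment="#")
    cols = SCHEMAS[schema_name]
    report: list[Violation] = []

    known = {c.name for c in cols}
    for extra in table.columns:
        if extra not in known:
            report.append(
                Violation("warning", None, extra, f"unknown column {extra!r} ignored")
            )
    for col in cols:
        if col.name not in table.columns:
            report.append(
                Violation("error", None, col.name, f"missing column {col.name!r}")
            )
            continue
        series = table[col.name]
        if col.kind == "str":
            empty = series.isna() | (series.astype(str).str.len() == 0)
            for row in np.flatnonzero(empty.to_numpy()):
                report.append(
                    Violation("error", int(row), col.name, f"empty {col.name!r}")
                )
            if col.unique and series.duplicated().any():
                for row in np.flatnonzero(series.duplicated().to_numpy()):
                    report.append(
                        Violation(
                            "error", int(row), col.name,
                            f"duplicate {col.name!r}: {series.iloc[row]!r}",
                        )
                    )
            continue
        numeric = pd.to_numeric(series, errors="coerce")
        bad_parse = numeric.isna() & series.notna()
        for row in np.flatnonzero(bad_parse.to_numpy()):
            report.append(
                Violation(
                    "error", int(row), col.name,
                    f"non-numeric value {series.iloc[row]!r} in {col.name!r}",
                )
            )
        missing = numeric.isna() & series.isna()
        if not col.nullable:
            for row in np.flatnonzero(missing.to_numpy()):
                report.append(
                    Violation("error", int(row), col.name, f"missing {col.name!r}")
                )
        vals = numeric.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if col.kind == "int":
                noninteger = ~np.isnan(vals) & (vals != np.floor(vals))
                for row in np.flatnonzero(noninteger):
                    report.append(
                        Violation(
                            "error", int(row), col.name,
                            f"non-integer value {vals[row]!r} in {col.name!r}",
                        )
                    )
            if col.allowed is not None:
                outside = ~np.isnan(vals) & ~np.isin(vals, col.allowed)
                for row in np.flatnonzero(outside):
                    report.append(
                        Violation(
                            "error", int(row), col.name,
                            f"value {vals[row]!r} not in {col.allowed} for {col.name!r}",
                        )
                    )
            if col.min is not None:
                below = ~np.isnan(vals) & (
                    (vals <= col.min) if col.min_exclusive else (vals < col.min)
                )
                for row in np.flatnonzero(below):
                    bound = ">" if col.min_exclusive else ">="
                    report.append(
                        Violation(
                            "error", int(row), col.name,
                            f"{col.name!r} must be {bound} {col.min}, got {vals[row]!r}",
                        )
                    )
        if col.unique and series.duplicated().any():
            for row in np.flatnonzero(series.duplicated().to_numpy()):
                report.append(
                    Violation(
                        "error", int(row), col.name,
                        f"duplicate {col.name!r}: {series.iloc[row]!r}",
                    )
                )
    if report:
        logger.info(
            "schema %s%s: %d finding(s)",
            schema_name,
            f" [{source}]" if source else "",
            len(report),
        )
    return report


def load_config_file(path) -> dict:
    """Load a YAML or JSON configuration, auto-detected by extension."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
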