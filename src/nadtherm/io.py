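"""Reading and writing the package's tabular interfaces.

The thermolysis measurement table is a strict four-column TSV
(``compound``, ``temperature_C``, ``rate_pct_per_min``, ``sd_pct_per_min``);
temperatures are stored in Celsius as printed and converted to kelvin when
typed measurements are materialized.  Model configurations are YAML files
mirroring :func:`nadtherm.network.default_config`.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigurationError
from .thermolysis import RateMeasurement

__all__ = [
    "RATE_TABLE_COLUMNS",
    "fixture_path",
    "read_rate_table",
    "write_rate_table",
    "to_measurements",
    "load_model_config",
    "save_model_config",
    "write_results",
]

RATE_TABLE_COLUMNS = ("compound", "temperature_C", "rate_pct_per_min", "sd_pct_per_min")


def fixture_path() -> Path:
    """Path of the bundled thermolysis measurement table."""
    return Path(importlib.resources.files("nadtherm") / "data" / "table1_thermolysis.tsv")


def read_rate_table(path) -> pd.DataFrame:
    """Read a thermolysis rate table, strictly validating the schema.

    Unknown or missing columns are rejected; non-numeric or negative values
    are reported with their (1-based, header-inclusive) line number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if tuple(df.columns) != RATE_TABLE_COLUMNS:
        missing = set(RATE_TABLE_COLUMNS) - set(df.columns)
        extra = set(df.columns) - set(RATE_TABLE_COLUMNS)
        raise ConfigurationError(
            f"rate table {path}: expected columns {list(RATE_TABLE_COLUMNS)}"
            + (f"; missing {sorted(missing)}" if missing else "")
            + (f"; unknown {sorted(extra)}" if extra else "")
        )
    out = df.copy()
    for col in RATE_TABLE_COLUMNS[1:]:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() | (values < 0)
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ConfigurationError(
                f"rate table {path}, line {line}: invalid {col} value {df[col][bad.idxmax()]!r}"
            )
        out[col] = values.astype(float)
    return out


def write_rate_table(df: pd.DataFrame, path) -> None:
    """Write a rate table in the fixture schema (round-trip stable)."""
    if tuple(df.columns) != RATE_TABLE_COLUMNS:
        raise ConfigurationError(f"rate table must have columns {list(RATE_TABLE_COLUMNS)}")
    df.to_csv(path, sep="\t", index=False)


def to_measurements(df: pd.DataFrame) -> list[RateMeasurement]:
    """Materialize typed measurements, converting Celsius to kelvin."""
    return [
        RateMeasurement(
            compound=row.compound,
            temperature=float(row.temperature_C) + 273.15,
            rate=float(row.rate_pct_per_min),
            rate_sd=float(row.sd_pct_per_min),
        )
        for row in df.itertuples(index=False)
    ]


def load_model_config(path) -> dict:
    """Load and validate a YAML model configuration."""
    from .network import validate_config

    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigurationError(f"model config {path} must be a mapping")
    validate_config(config)
    return config


def save_model_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def write_results(out_dir, tables: dict[str, pd.DataFrame]) -> dict[str, Path]:
    """Write named tidy tables as TSV under ``out_dir``; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, table in tables.items():
        p = out_dir / f"{name}.tsv"
        table.to_csv(p, sep="\t", index=False)
        paths[name] = p
    return paths
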