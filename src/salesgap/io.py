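"""Panel I/O, deflation and per-capita transforms, and run configuration.

The canonical panel representation is a long-format table with one row per
(province, year): ``province, year, sales_pc, price, gdp_pc`` and an
optional ``pop18`` adult-population column.  Monetary columns are expected
in real terms; :func:`deflate` converts nominal series with a CPI series
and a base year (the study convention is base 2016).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

logger = logging.getLogger("salesgap")

PANEL_COLUMNS = ["province", "year", "sales_pc", "price", "gdp_pc"]
OPTIONAL_COLUMNS = ["pop18"]

__all__ = [
    "PANEL_COLUMNS",
    "ModelSettings",
    "RunConfig",
    "deflate",
    "load_run_config",
    "per_capita",
    "read_panel",
    "validate_panel",
    "write_panel",
]


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Validate the panel contract; returns the frame (column-pruned)."""
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise ValueError(f"panel is missing required columns: {missing}")
    extras = [c for c in panel.columns if c not in PANEL_COLUMNS + OPTIONAL_COLUMNS]
    if extras:
        logger.info("ignoring extra panel columns: %s", extras)
    keep = [c for c in PANEL_COLUMNS + OPTIONAL_COLUMNS if c in panel.columns]
    panel = panel[keep]

    dup = panel.duplicated(subset=["province", "year"])
    if dup.any():
        offenders = panel.loc[dup, ["province", "year"]].to_records(index=False).tolist()
        raise ValueError(f"duplicate (province, year) rows: {offenders}")
    for col in ("sales_pc", "price", "gdp_pc"):
        bad = panel.index[~(panel[col] > 0) | ~pd.notna(panel[col])]
        if len(bad):
            raise ValueError(
                f"column {col!r} must be strictly positive; offending rows: {list(bad[:10])}"
            )
    if panel["province"].nunique() < 3:
        raise ValueError("panel must contain at least 3 provinces")
    return panel


def read_panel(path) -> pd.DataFrame:
    """Read and validate a long-format panel CSV (tolerant of extra columns)."""
    try:
        raw = pd.read_csv(path)
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"could not parse panel CSV {path}: {exc}") from exc
    return validate_panel(raw)


def write_panel(panel: pd.DataFrame, path) -> None:
    validate_panel(panel).to_csv(path, index=False)


def deflate(nominal: pd.Series, cpi: pd.Series, base_year: int) -> pd.Series:
    """Convert a nominal series (indexed by year) to real terms.

    real(y) = nominal(y) * CPI(base_year) / CPI(y).
    """
    if base_year not in cpi.index:
        raise ValueError(f"CPI series does not cover the base year {base_year}")
    if not cpi[base_year] > 0:
        raise ValueError(f"CPI at base year {base_year} must be > 0")
    missing = sorted(set(nominal.index) - set(cpi.index))
    if missing:
        raise ValueError(f"CPI series missing years: {missing}")
    return nominal * cpi[base_year] / cpi.reindex(nominal.index)


def per_capita(total: pd.Series, pop18: pd.Series) -> pd.Series:
    """Elementwise division by the adult population (units become per-adult)."""
    if (pop18 <= 0).any():
        raise ValueError("pop18 must be strictly positive")
    return total / pop18


@dataclass
class ModelSettings:
    family: str = "linear_qr"
    n_trees: int = 500
    min_leaf: int = 5
    max_features: int | float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("linear_qr", "qrf"):
            raise ValueError(
                f"unknown model family {self.family!r}; expected 'linear_qr' or 'qrf'"
            )


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (YAML-loadable)."""

    seed: int = 0
    t: float = 10.0
    model: ModelSettings = field(default_factory=ModelSettings)
    panel_path: str | None = None       # None -> generate synthetically
    truth_path: str | None = None
    output_dir: str = "salesgap_out"
    synthetic: dict = field(default_factory=dict)   # SyntheticConfig overrides
    grouping: dict[str, list[str]] = field(default_factory=dict)  # group -> provinces
    log_log: bool = False
    denominator: str = "anomalous"      # national-average convention
    deflation: dict | None = None       # {cpi: path, base_year: int, columns: [...]}

    def __post_init__(self) -> None:
        if not 0 < self.t < 50:
            raise ValueError(f"t must lie in (0, 50) percent, got {self.t}")
        if self.denominator not in ("anomalous", "all"):
            raise ValueError(f"denominator must be 'anomalous' or 'all', got {self.denominator!r}")


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "seed" not in raw:
        raise ValueError("config must set an explicit seed")
    model = ModelSettings(**raw.pop("model", {}))
    return RunConfig(model=model, **raw)
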