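"""Anomaly quantification: UAR/LAR ratios, national aggregation, and the
cross-border / tourism decomposition.

The upper anomaly ratio UAR = (y - p_u)/p_u measures sales in excess of the
upper prediction bound; the lower anomaly ratio LAR = (y - p_l)/p_l is
negative when sales fall short of the lower bound.  National series average
the ratios per year over the anomalous provinces (summaries report |LAR|),
and the per-year average UAR splits exactly into per-group components by
province grouping.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("salesgap")

__all__ = [
    "aggregate_national",
    "compute_lar",
    "compute_uar",
    "decompose_uar",
    "grouping_from_truth",
    "quantify_anomalies",
    "recovery_report",
]


def compute_uar(observed, p_u):
    """(observed - p_u) / p_u; positive exactly when observed > p_u."""
    p_u = np.asarray(p_u, dtype=float)
    if np.any(p_u <= 0):
        raise ValueError("upper bound p_u must be strictly positive")
    out = (np.asarray(observed, dtype=float) - p_u) / p_u
    return float(out) if out.ndim == 0 else out


def compute_lar(observed, p_l):
    """(observed - p_l) / p_l; negative exactly when observed < p_l."""
    p_l = np.asarray(p_l, dtype=float)
    if np.any(p_l <= 0):
        raise ValueError("lower bound p_l must be strictly positive")
    out = (np.asarray(observed, dtype=float) - p_l) / p_l
    return float(out) if out.ndim == 0 else out


def quantify_anomalies(classified: pd.DataFrame) -> pd.DataFrame:
    """Per-record anomaly table: province, year, status, ratio.

    The ratio is the UAR for upper records, the LAR for lower records and
    NaN for normal ones (sign correctness enforced by construction).
    """
    out = classified[["province", "year", "status"]].copy()
    ratio = np.full(len(out), np.nan)
    up = classified["status"].to_numpy() == "upper"
    lo = classified["status"].to_numpy() == "lower"
    if up.any():
        ratio[up] = compute_uar(
            classified.loc[up, "observed"], classified.loc[up, "p_u"]
        )
    if lo.any():
        ratio[lo] = compute_lar(
            classified.loc[lo, "observed"], classified.loc[lo, "p_l"]
        )
    out["ratio"] = ratio
    return out


def aggregate_national(
    records: pd.DataFrame, denominator: str = "anomalous"
) -> pd.DataFrame:
    """Per-year national series: avg_uar, avg_abslar, n_upper, n_lower.

    ``denominator='anomalous'`` averages over the anomalous provinces only
    (a year with none contributes 0); ``'all'`` divides by all provinces
    observed that year.
    """
    if records.empty:
        raise ValueError("records must cover at least one year")
    if denominator not in ("anomalous", "all"):
        raise ValueError(f"denominator must be 'anomalous' or 'all', got {denominator!r}")

    rows = []
    for year, grp in records.groupby("year", sort=True):
        upper = grp.loc[grp["status"] == "upper", "ratio"]
        lower = grp.loc[grp["status"] == "lower", "ratio"]
        n = len(grp) if denominator == "all" else None
        rows.append(
            {
                "year": year,
                "avg_uar": _mean_ratio(upper.to_numpy(), n),
                "avg_abslar": _mean_ratio(np.abs(lower.to_numpy()), n),
                "n_upper": len(upper),
                "n_lower": len(lower),
            }
        )
    return pd.DataFrame(rows)


def _mean_ratio(values: np.ndarray, n_all: int | None) -> float:
    if values.size == 0:
        return 0.0
    return float(values.sum() / n_all) if n_all else float(values.mean())


def decompose_uar(
    records: pd.DataFrame, grouping: Mapping[str, str]
) -> pd.DataFrame:
    """Split the per-year average UAR into province-group components.

    component_g = (sum of UAR over upper records in group g) / n_upper, so
    the components sum back to avg_uar exactly.  ``grouping`` maps province
    -> group label; every province in ``records`` must be covered.
    """
    missing = sorted(set(records["province"]) - set(grouping))
    if missing:
        raise ValueError(f"provinces missing from grouping: {missing}")
    groups = sorted(set(grouping.values()))

    rows = []
    for year, grp in records.groupby("year", sort=True):
        upper = grp[grp["status"] == "upper"]
        n_upper = len(upper)
        row = {"year": year}
        for g in groups:
            members = upper["province"].map(grouping) == g
            total = upper.loc[members, "ratio"].sum()
            row[f"uar_{g}"] = float(total / n_upper) if n_upper else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def grouping_from_truth(
    truth: pd.DataFrame, provinces=None, default: str = "other"
) -> dict[str, str]:
    """Derive a province -> group map from ground truth group labels."""
    mapping: dict[str, str] = {}
    labeled = truth[truth["group_label"].astype(str) != ""]
    for prov, grp in labeled.groupby("province"):
        mapping[prov] = grp["group_label"].iloc[0]
    for prov in provinces if provinces is not None else truth["province"].unique():
        mapping.setdefault(prov, default)
    return mapping


def recovery_report(records: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Score detected anomalies against the generator's ground truth.

    Per direction: precision, recall (per province-year cell), the RMSE of
    the estimated ratio against the injected effect (multiplier - 1) on
    correctly detected cells, and the mean |ratio| on those cells.
    """
    merged = records.merge(
        truth, on=["province", "year"], how="outer", indicator=True, validate="one_to_one"
    )
    if (merged["_merge"] != "both").any():
        raise ValueError("records and ground truth do not share identical (province, year) keys")

    report: dict[str, dict] = {}
    for direction, label in (("upper", "upper"), ("lower", "lower")):
        flagged = merged["status"] == direction
        true = merged["true_label"] == label
        tp = flagged & true
        n_flagged, n_true = int(flagged.sum()), int(true.sum())
        precision = float(tp.sum() / n_flagged) if n_flagged else float("nan")
        if not n_flagged:
            logger.info("no %s flags raised; precision undefined", direction)
        recall = float(tp.sum() / n_true) if n_true else float("nan")
        est = merged.loc[tp, "ratio"].to_numpy(float)
        injected = merged.loc[tp, "true_multiplier"].to_numpy(float) - 1.0
        rmse = float(np.sqrt(np.mean((est - injected) ** 2))) if tp.any() else float("nan")
        report[direction] = {
            "precision": precision,
            "recall": recall,
            "n_true": n_true,
            "n_flagged": n_flagged,
            "magnitude_rmse": rmse,
            "mean_abs_ratio": float(np.mean(np.abs(est))) if tp.any() else float("nan"),
        }
    return report
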