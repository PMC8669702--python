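"""End-to-end orchestration: generate/read -> intervals -> anomalies -> evaluate.

Writes all stage outputs (CSV/JSON) plus a run manifest with the config
hash, seed and package version; identical configs reproduce identical
artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .anomalies import (
    aggregate_national,
    decompose_uar,
    grouping_from_truth,
    quantify_anomalies,
    recovery_report,
)
from .evaluation import interval_metrics, point_metrics
from .intervals import IntervalConfig, build_lopo_intervals, classify_intervals
from .io import RunConfig, read_panel, validate_panel
from .synthetic import default_config, generate_panel

logger = logging.getLogger("salesgap")

__all__ = ["run_pipeline"]


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


def _grouping(config: RunConfig, panel: pd.DataFrame, truth) -> dict[str, str]:
    if config.grouping:
        mapping = {p: g for g, provs in config.grouping.items() for p in provs}
        for prov in panel["province"].unique():
            mapping.setdefault(prov, "other")
        return mapping
    if truth is not None and "group_label" in truth.columns:
        return grouping_from_truth(truth, provinces=panel["province"].unique())
    return {p: "other" for p in panel["province"].unique()}


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages; returns the output directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    t0 = time.time()
    if config.panel_path is not None:
        logger.info("reading panel from %s", config.panel_path)
        panel = read_panel(config.panel_path)
        truth = pd.read_csv(config.truth_path) if config.truth_path else None
    else:
        logger.info("generating synthetic panel")
        syn = default_config(seed=config.seed, **config.synthetic)
        panel, truth = generate_panel(syn)
    panel = validate_panel(panel)

    icfg = IntervalConfig(
        t=config.t, model=config.model, log_log=config.log_log, seed=config.seed
    )
    logger.info("building LOPO intervals (model=%s, t=%g)", config.model.family, config.t)
    intervals = classify_intervals(build_lopo_intervals(panel, icfg))
    intervals.to_csv(out / "intervals.csv", index=False)

    records = quantify_anomalies(intervals)
    records.to_csv(out / "anomalies.csv", index=False)

    national = aggregate_national(records, denominator=config.denominator)
    components = decompose_uar(records, _grouping(config, panel, truth))
    national = national.merge(components, on="year")
    national.to_csv(out / "national_series.csv", index=False)

    evaluation = {
        "model": config.model.family,
        "t": config.t,
        "split": "lopo",
        "point": point_metrics(intervals["q50"], intervals["observed"]),
        "interval": interval_metrics(intervals, t=config.t),
    }
    (out / "evaluation.json").write_text(json.dumps(evaluation, indent=2) + "\n")

    if truth is not None:
        recovery = recovery_report(records, truth)
        (out / "recovery.json").write_text(json.dumps(recovery, indent=2) + "\n")

    manifest = {
        "config": dataclasses.asdict(config),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "outputs": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
        "runtime_s": round(time.time() - t0, 3),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    logger.info("pipeline finished in %.1fs -> %s", manifest["runtime_s"], out)
    return out
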