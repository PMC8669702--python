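"""Leave-one-province-out prediction intervals and anomaly classification.

For each province, quantile models at the symmetric levels t/100, 0.5 and
(100-t)/100 are fitted on every other province's records and evaluated on
the held-out province, so each interval is out-of-sample for the province
it describes.  An observation is anomalous when it falls strictly outside
its interval: below the conditional t-quantile (lower) or above the
(100-t)-quantile (upper).  By the symmetric construction the nominal
probability of falling inside the default t=10 interval is
0.9 - 0.1 = 0.8.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ModelSettings, validate_panel
from .quantile_models import LinearQuantileRegression, QuantileRegressionForest

logger = logging.getLogger("salesgap")

FEATURES = ["price", "gdp_pc"]

__all__ = [
    "FEATURES",
    "IntervalConfig",
    "build_lopo_intervals",
    "classify_anomaly",
    "classify_intervals",
    "province_seed",
]


@dataclass
class IntervalConfig:
    """t is the symmetric quantile level in percent: bounds at t/100 and
    (100 - t)/100.  ``log_log`` fits log-response on log-features
    (constant-elasticity form) and exponentiates the predicted bounds."""

    t: float = 10.0
    model: ModelSettings = field(default_factory=ModelSettings)
    log_log: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.t < 50:
            raise ValueError(f"t must lie in (0, 50) percent, got {self.t}")

    @property
    def alphas(self) -> list[float]:
        return [self.t / 100.0, 0.5, 1.0 - self.t / 100.0]


def province_seed(master_seed: int, province: str) -> int:
    """Child seed for one province's fit, invariant to iteration order."""
    return (master_seed * 1_000_003 + zlib.crc32(str(province).encode())) % (2**31)


def _make_model(config: IntervalConfig, seed: int):
    if config.model.family == "linear_qr":
        return LinearQuantileRegression()
    if config.model.family == "qrf":
        return QuantileRegressionForest(
            n_trees=config.model.n_trees,
            min_leaf=config.model.min_leaf,
            max_features=config.model.max_features,
            seed=seed,
        )
    raise ValueError(f"unknown model family {config.model.family!r}")


def build_lopo_intervals(panel: pd.DataFrame, config: IntervalConfig) -> pd.DataFrame:
    """One prediction interval per (province, year), built leave-one-province-out.

    Returns a frame ``province, year, p_l, q50, p_u, observed`` with
    p_l <= q50 <= p_u (non-crossing enforced by per-row sorting).
    """
    panel = validate_panel(panel)
    # canonical row order: results must not depend on input ordering
    panel = panel.sort_values(["province", "year"], kind="stable").reset_index(drop=True)
    alphas = config.alphas

    pieces = []
    for prov in sorted(panel["province"].unique()):
        test = panel[panel["province"] == prov]
        train = panel[panel["province"] != prov]
        if test.empty:
            logger.warning("province %s has no records; skipped", prov)
            continue

        X_train = train[FEATURES].to_numpy(float)
        y_train = train["sales_pc"].to_numpy(float)
        X_test = test[FEATURES].to_numpy(float)
        if config.log_log:
            X_train, y_train, X_test = np.log(X_train), np.log(y_train), np.log(X_test)

        model = _make_model(config, province_seed(config.seed, prov))
        model.fit(X_train, y_train, feature_names=FEATURES)
        q = model.predict_quantiles(X_test, alphas)
        if config.log_log:
            q = np.exp(q)
        if not np.isfinite(q).all():
            raise RuntimeError(f"non-finite interval predicted for province {prov}")

        pieces.append(
            pd.DataFrame(
                {
                    "province": prov,
                    "year": test["year"].to_numpy(),
                    "p_l": q[:, 0],
                    "q50": q[:, 1],
                    "p_u": q[:, 2],
                    "observed": test["sales_pc"].to_numpy(float),
                }
            )
        )
    return pd.concat(pieces, ignore_index=True)


def classify_anomaly(interval) -> str:
    """Anomaly status of one interval record (mapping with p_l, p_u, observed).

    ``lower`` iff observed < p_l, ``upper`` iff observed > p_u, else
    ``none``; boundary equality counts as normal.
    """
    obs, p_l, p_u = interval["observed"], interval["p_l"], interval["p_u"]
    if not p_l <= p_u:
        raise ValueError(f"invalid interval: p_l={p_l} > p_u={p_u}")
    if obs < p_l:
        return "lower"
    if obs > p_u:
        return "upper"
    return "none"


def classify_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Vectorized classification; returns a copy with a ``status`` column."""
    out = intervals.copy()
    obs = out["observed"].to_numpy()
    out["status"] = np.where(
        obs < out["p_l"].to_numpy(),
        "lower",
        np.where(obs > out["p_u"].to_numpy(), "upper", "none"),
    )
    return out
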