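"""Point- and interval-prediction quality metrics.

Point metrics score the conditional-median prediction (MAE, RMSE, MAPE,
R^2); interval metrics score the prediction band: PICP (coverage), MPIW
(mean width), PINAW (width normalized by the observed response range) and
the Winkler interval score at nominal level 1 - 2t/100, which adds a
2/alpha-scaled penalty for every violation distance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import (
    mean_absolute_error,
    mean_absolute_percentage_error,
    mean_squared_error,
    r2_score,
)

__all__ = ["interval_metrics", "point_metrics"]


def point_metrics(predicted_median, observed) -> dict[str, float]:
    """MAE, RMSE, MAPE (%) and R^2 of median predictions vs observations."""
    pred = np.asarray(predicted_median, dtype=float).ravel()
    obs = np.asarray(observed, dtype=float).ravel()
    if pred.shape != obs.shape:
        raise ValueError(f"length mismatch: {pred.shape[0]} predictions vs {obs.shape[0]} observations")
    if pred.size < 2:
        raise ValueError("need at least 2 observations")
    if np.any(obs == 0):
        raise ValueError("observed values must be nonzero for MAPE")
    return {
        "mae": float(mean_absolute_error(obs, pred)),
        "rmse": float(np.sqrt(mean_squared_error(obs, pred))),
        "mape": float(100.0 * mean_absolute_percentage_error(obs, pred)),
        "r2": float(r2_score(obs, pred)),
    }


def interval_metrics(intervals: pd.DataFrame, t: float = 10.0) -> dict[str, float]:
    """PICP, MPIW, PINAW and mean Winkler score of a set of intervals.

    ``intervals`` needs columns p_l, p_u, observed; ``t`` is the symmetric
    quantile level in percent, so the nominal coverage is 1 - 2t/100 and
    the Winkler miss rate alpha = 2t/100.
    """
    if len(intervals) == 0:
        raise ValueError("need at least one interval")
    p_l = intervals["p_l"].to_numpy(float)
    p_u = intervals["p_u"].to_numpy(float)
    obs = intervals["observed"].to_numpy(float)
    if np.any(p_l > p_u):
        raise ValueError("intervals must satisfy p_l <= p_u")

    width = p_u - p_l
    inside = (obs >= p_l) & (obs <= p_u)
    obs_range = obs.max() - obs.min()

    alpha = 2.0 * t / 100.0
    winkler = width.copy()
    below, above = obs < p_l, obs > p_u
    winkler[below] += (2.0 / alpha) * (p_l[below] - obs[below])
    winkler[above] += (2.0 / alpha) * (obs[above] - p_u[above])

    return {
        "picp": float(inside.mean()),
        "mpiw": float(width.mean()),
        "pinaw": float(width.mean() / obs_range) if obs_range > 0 else float("nan"),
        "winkler": float(winkler.mean()),
    }
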