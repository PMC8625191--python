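"""External-validation error metrics.

Relative prediction error per observation, relative bias (accuracy) and
relative root-mean-square error (precision):

    rPE_i  = (C_P,i - C_O,i) / C_O,i
    rBias  = 100% * mean(rPE)
    rRMSE  = 100% * sqrt(mean(rPE^2))

where C_O are observed and C_P model-predicted concentrations.  Both
summary metrics are scale-free: rescaling observed and predicted by a
common factor (a unit change) leaves them unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PredictionPerformance", "rpe", "rbias", "rrmse", "validate"]


@dataclass
class PredictionPerformance:
    """Summary of a model-vs-observation comparison."""

    rbias: float  # %
    rrmse: float  # %
    n: int
    rpe: np.ndarray  # per-observation relative prediction errors
    excluded_ids: list = field(default_factory=list)


def _check_pair(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError(f"length mismatch: {obs.shape} vs {pred.shape}")
    if obs.size == 0:
        raise ValueError("need at least one observation")
    if np.any(obs <= 0):
        raise ValueError("observed concentrations must be positive")
    return obs, pred


def rpe(observed, predicted) -> np.ndarray:
    """Relative prediction error (C_P - C_O) / C_O, elementwise."""
    obs, pred = _check_pair(observed, predicted)
    return (pred - obs) / obs


def rbias(observed, predicted) -> float:
    """Relative bias in percent: 100 * mean(rPE)."""
    return 100.0 * float(np.mean(rpe(observed, predicted)))


def rrmse(observed, predicted) -> float:
    """Relative RMSE in percent: 100 * sqrt(mean(rPE^2))."""
    return 100.0 * float(np.sqrt(np.mean(rpe(observed, predicted) ** 2)))


def performance(observed, predicted, excluded_ids=None) -> PredictionPerformance:
    """Bundle rPE/rBias/rRMSE for one observation set."""
    errors = rpe(observed, predicted)
    return PredictionPerformance(
        rbias=100.0 * float(np.mean(errors)),
        rrmse=100.0 * float(np.sqrt(np.mean(errors**2))),
        n=int(errors.size),
        rpe=errors,
        excluded_ids=list(excluded_ids or []),
    )


def validate(
    observed: pd.DataFrame,
    predicted_col: str = "pred",
    observed_col: str = "concentration",
    subject_col: str = "subject_id",
    exclusion_ids: list | None = None,
) -> dict[str, PredictionPerformance]:
    """Validation metrics with and without listed subject exclusions.

    ``observed`` is a long table of validation observations with a column of
    model predictions.  Returns ``{"all": ..., "excluded": ...}``; the second
    entry is present only when exclusions are given.  Exclusions that match
    no subject raise a warning rather than an error.
    """
    exclusion_ids = list(exclusion_ids or [])
    out = {
        "all": performance(observed[observed_col], observed[predicted_col])
    }
    if exclusion_ids:
        present = set(observed[subject_col])
        missing = [i for i in exclusion_ids if i not in present]
        if missing:
            warnings.warn(
                f"exclusion ids not found in dataset: {missing}", stacklevel=2
            )
        kept = observed[~observed[subject_col].isin(exclusion_ids)]
        out["excluded"] = performance(
            kept[observed_col], kept[predicted_col], excluded_ids=exclusion_ids
        )
    return out
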