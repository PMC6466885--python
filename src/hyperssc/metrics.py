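"""Chemometric model-evaluation statistics: RMSE, R2, RPD, bias, slope, growth rate.

Conventions used throughout (each is the standard chemometric choice, but
none is universal, so they are stated explicitly):

* R2 is the squared Pearson correlation between reference and predicted
  values (``definition="pearson"``); the 1 - SS_res/SS_tot variant is
  available behind ``definition="ss"``.
* RPD divides the *reference* set's sample standard deviation (n-1
  denominator) by the prediction RMSE; RPD > 3 is the usual screening
  threshold for usable fruit-quality models.
* bias = mean(predicted - reference); slope regresses predicted on
  reference by default (``direction="pred_on_ref"``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RegressionMetrics",
    "rmse",
    "rpd",
    "rpd_from_sd",
    "r_squared",
    "bias_slope",
    "growth_rate",
    "evaluate",
    "metrics_table",
]


@dataclass
class RegressionMetrics:
    """Evaluation summary for one model on one data set."""

    r2: float
    rmse: float
    rpd: float
    bias: float
    slope: float
    n: int


def _check_pair(y_ref, y_pred) -> tuple[np.ndarray, np.ndarray]:
    y_ref = np.asarray(y_ref, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_ref.size != y_pred.size:
        raise ValueError(f"length mismatch: {y_ref.size} reference vs {y_pred.size} predicted")
    if y_ref.size == 0:
        raise ValueError("empty vectors")
    return y_ref, y_pred


def rmse(y_ref, y_pred) -> float:
    """Root-mean-square error sqrt(mean((pred - ref)^2)), in % SSC."""
    y_ref, y_pred = _check_pair(y_ref, y_pred)
    return float(np.sqrt(np.mean((y_pred - y_ref) ** 2)))


def rpd(y_ref, rmse_val: float) -> float:
    """Residual predictive deviation: sd(y_ref) / RMSE (sd with n-1 denominator)."""
    y_ref = np.asarray(y_ref, dtype=float).ravel()
    if y_ref.size < 2:
        raise ValueError("RPD needs at least two reference values")
    if rmse_val <= 0:
        raise ValueError("RPD undefined for zero (or negative) RMSE")
    return float(np.std(y_ref, ddof=1) / rmse_val)


def rpd_from_sd(sd: float, rmse_val: float) -> float:
    """RPD from an already-computed reference-set standard deviation."""
    if sd <= 0:
        raise ValueError("standard deviation must be positive")
    if rmse_val <= 0:
        raise ValueError("RPD undefined for zero (or negative) RMSE")
    return sd / rmse_val


def r_squared(y_ref, y_pred, definition: str = "pearson") -> float:
    """Determination coefficient between reference and predicted values."""
    y_ref, y_pred = _check_pair(y_ref, y_pred)
    if y_ref.size < 2:
        raise ValueError("R2 needs at least two samples")
    if definition == "pearson":
        sr, sp = y_ref.std(), y_pred.std()
        if sr == 0 or sp == 0:
            raise ValueError("R2 undefined: a vector has zero variance")
        r = np.mean((y_ref - y_ref.mean()) * (y_pred - y_pred.mean())) / (sr * sp)
        return float(r**2)
    if definition == "ss":
        ss_tot = np.sum((y_ref - y_ref.mean()) ** 2)
        if ss_tot == 0:
            raise ValueError("R2 undefined: reference has zero variance")
        return float(1.0 - np.sum((y_pred - y_ref) ** 2) / ss_tot)
    raise ValueError(f"unknown R2 definition {definition!r}")


def bias_slope(y_ref, y_pred, direction: str = "pred_on_ref") -> tuple[float, float]:
    """Mean prediction bias (% SSC) and least-squares slope (unitless)."""
    y_ref, y_pred = _check_pair(y_ref, y_pred)
    if y_ref.size < 2:
        raise ValueError("bias/slope need at least two samples")
    bias = float(np.mean(y_pred - y_ref))
    x, y = (y_ref, y_pred) if direction == "pred_on_ref" else (y_pred, y_ref)
    varx = np.var(x)
    if varx == 0:
        raise ValueError("slope undefined: regressor has zero variance")
    slope = float(np.mean((x - x.mean()) * (y - y.mean())) / varx)
    return bias, slope


def growth_rate(mean_prev: float, mean_next: float) -> float:
    """Relative change between consecutive stage means, in percent."""
    if mean_prev <= 0:
        raise ValueError("growth rate needs a positive previous-stage mean")
    return (mean_next - mean_prev) / mean_prev * 100.0


def evaluate(y_ref, y_pred) -> RegressionMetrics:
    """All evaluation statistics for one prediction vector."""
    e = rmse(y_ref, y_pred)
    bias, slope = bias_slope(y_ref, y_pred)
    return RegressionMetrics(
        r2=r_squared(y_ref, y_pred),
        rmse=e,
        rpd=rpd(y_ref, e),
        bias=bias,
        slope=slope,
        n=int(np.asarray(y_ref).size),
    )


def metrics_table(rows: dict) -> pd.DataFrame:
    """Assemble a results table in the conventional column order.

    ``rows`` maps a label (e.g. set name) to a dict with keys among
    gamma, sigma2, r2_cal, rmsec, r2_pred, rmsep, slope, bias, rpd.
    """
    cols = ["gamma", "sigma2", "r2_cal", "rmsec", "r2_pred", "rmsep", "slope", "bias", "rpd"]
    df = pd.DataFrame.from_dict(rows, orient="index")
    return df.reindex(columns=cols)
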