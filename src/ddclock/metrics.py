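"""Evaluation metrics and age-acceleration utilities."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ClockMetrics:
    """Agreement between predicted and chronological age.

    ``r`` is NaN (and ``r_defined`` False) when either vector has zero
    variance — e.g. a constant predictor, or a cohort with a single age.
    R² is 1 − SS_res/SS_tot and may be negative out of sample.
    """

    r: float
    r2: float
    mae: float
    rmse: float
    n: int

    @property
    def r_defined(self) -> bool:
        return not math.isnan(self.r)

    def as_dict(self) -> dict:
        return {"r": self.r, "r2": self.r2, "mae": self.mae, "rmse": self.rmse, "n": self.n}


def evaluate_predictions(age: np.ndarray, predicted: np.ndarray) -> ClockMetrics:
    """Compute r, R², MAE and RMSE between predicted and true ages."""
    age = np.asarray(age, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if age.size == 0 or age.size != predicted.size:
        raise ValueError("need matching non-empty age/prediction vectors")
    err = predicted - age
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    ss_tot = float(np.sum((age - age.mean()) ** 2))
    if ss_tot == 0:
        r2 = math.nan
    else:
        r2 = 1.0 - float(np.sum(err**2)) / ss_tot
    if age.size < 2 or np.std(age) == 0 or np.std(predicted) == 0:
        r = math.nan
    else:
        r = float(stats.pearsonr(age, predicted)[0])
    return ClockMetrics(r=r, r2=r2, mae=mae, rmse=rmse, n=age.size)


def age_acceleration(
    age: np.ndarray, predicted: np.ndarray, mode: str = "relative"
) -> np.ndarray:
    """Per-sample age acceleration, in years.

    absolute: predicted − chronological age.
    relative: residual of predicted age regressed (OLS) on chronological
    age within the given samples — removes regression-to-the-mean slope
    bias, so relative accelerations sum to zero by construction.
    """
    age = np.asarray(age, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if age.size == 0 or age.size != predicted.size:
        raise ValueError("need matching non-empty age/prediction vectors")
    if mode == "absolute":
        return predicted - age
    if mode == "relative":
        if age.size < 3:
            raise ValueError("relative acceleration needs at least 3 samples")
        design = np.column_stack([np.ones(age.size), age])
        coef, *_ = np.linalg.lstsq(design, predicted, rcond=None)
        return predicted - design @ coef
    raise ValueError("mode must be 'absolute' or 'relative'")
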