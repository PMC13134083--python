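"""Klemera-Doubal biological-age regression (KDR).

Each marker x_j is regressed on chronological age (CA) in the training
cohort, x_j = q_j + k_j * CA + noise with residual SD s_j. The
biological-age estimate inverts every marker's regression and combines
the per-marker age estimates with inverse-variance weights:

    BA_E  = sum_j (x_j - q_j) * k_j / s_j^2  /  sum_j (k_j / s_j)^2

The "EC" variant additionally treats chronological age as one more
noisy marker of biological age, with SD s_BA (the spread of true
biological age around chronological age in the population):

    BA_EC = [ sum_j (x_j - q_j) * k_j / s_j^2 + CA / s_BA^2 ]
            / [ sum_j (k_j / s_j)^2 + 1 / s_BA^2 ]

so BA_EC -> BA_E as s_BA -> inf and BA_EC -> CA as s_BA -> 0. s_BA is
estimated from the training spread of BA_E - CA minus the propagated
marker-noise variance of BA_E (which is 1 / sum_j (k_j / s_j)^2),
floored at a small positive constant.

The EC variant therefore *requires* chronological age at prediction
time; BA_E does not.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

#: Positivity floor for the biological-age SD, in years.
S_BA_FLOOR = 0.5

#: Floor for per-marker residual SDs (guards exact, noise-free markers).
S_J_FLOOR = 1e-8


class UninformativeMarkerError(ValueError):
    """A marker's regression slope on age is exactly zero."""


def _ols_on_age(x: np.ndarray, age: np.ndarray) -> tuple[float, float, float]:
    """Least-squares fit x = q + k*age; returns (q, k, residual SD)."""
    n = age.size
    design = np.column_stack([np.ones(n), age])
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    q, k = float(coef[0]), float(coef[1])
    resid = x - (q + k * age)
    dof = max(n - 2, 1)
    s = float(np.sqrt(resid @ resid / dof))
    return q, k, s


class KlemeraDoubalRegressor(BaseEstimator, RegressorMixin):
    """Klemera-Doubal biological-age estimator over CpG markers.

    Parameters
    ----------
    variant : {"BA_EC", "BA_E"}, default "BA_EC"
        BA_EC shrinks toward chronological age and requires it at
        prediction time; BA_E is age-blind.
    s_ba_floor : float
        Lower bound on the estimated s_BA, in years.

    Attributes
    ----------
    q_, k_, s_ : pandas.Series
        Per-marker intercept, slope (marker units per year) and residual
        SD from the training regressions.
    s_ba_ : float
        Estimated SD of biological-age deviation, in years.
    """

    def __init__(self, variant: str = "BA_EC", s_ba_floor: float = S_BA_FLOOR):
        self.variant = variant
        self.s_ba_floor = s_ba_floor

    def fit(self, X: pd.DataFrame, y) -> "KlemeraDoubalRegressor":
        if self.variant not in ("BA_E", "BA_EC"):
            raise ValueError("variant must be 'BA_E' or 'BA_EC'")
        X = self._as_frame(X)
        age = np.asarray(y, dtype=float)
        if age.size != len(X):
            raise ValueError("X and y disagree on sample count")
        q, k, s = {}, {}, {}
        for col in X.columns:
            qj, kj, sj = _ols_on_age(X[col].to_numpy(dtype=float), age)
            if abs(kj) < 1e-12:  # numerically zero slope
                raise UninformativeMarkerError(
                    f"marker {col!r} has zero slope on age; drop it from the panel"
                )
            q[col], k[col], s[col] = qj, kj, max(sj, S_J_FLOOR)
        self.q_ = pd.Series(q)
        self.k_ = pd.Series(k)
        self.s_ = pd.Series(s)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]

        # s_BA: training variance of BA_E - CA minus the propagated
        # marker-noise variance of the BA_E estimator, floored.
        ba_e = self._ba_e(X)
        noise_var = 1.0 / float(np.sum((self.k_ / self.s_) ** 2))
        excess = float(np.var(ba_e - age, ddof=1)) - noise_var
        self.s_ba_ = max(self.s_ba_floor, np.sqrt(max(excess, 0.0)))
        return self

    def _ba_e(self, X: pd.DataFrame) -> np.ndarray:
        num = np.zeros(len(X))
        for col in self.feature_names_in_:
            x = X[col].to_numpy(dtype=float)
            num += (x - self.q_[col]) * self.k_[col] / self.s_[col] ** 2
        denom = float(np.sum((self.k_ / self.s_) ** 2))
        return num / denom

    def predict(self, X: pd.DataFrame, chronological_age=None) -> np.ndarray:
        """Predict biological age in years.

        ``chronological_age`` (array, years) is mandatory for the BA_EC
        variant and ignored by BA_E.
        """
        check_is_fitted(self, "q_")
        X = self._as_frame(X)
        missing = [c for c in self.feature_names_in_ if c not in X.columns]
        if missing:
            raise ValueError(f"missing marker columns: {missing}")
        if self.variant == "BA_E":
            return self._ba_e(X)
        if chronological_age is None:
            raise ValueError(
                "variant='BA_EC' requires chronological_age at prediction time "
                "(use variant='BA_E' for age-blind prediction)"
            )
        ca = np.asarray(chronological_age, dtype=float)
        if ca.ndim == 0:
            ca = np.full(len(X), float(ca))
        num = np.zeros(len(X))
        for col in self.feature_names_in_:
            x = X[col].to_numpy(dtype=float)
            num += (x - self.q_[col]) * self.k_[col] / self.s_[col] ** 2
        denom = float(np.sum((self.k_ / self.s_) ** 2))
        return (num + ca / self.s_ba_**2) / (denom + 1.0 / self.s_ba_**2)

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        raise TypeError("expected a DataFrame of marker columns")

    def get_state(self) -> dict:
        check_is_fitted(self, "q_")
        return {
            "variant": self.variant,
            "s_ba_floor": self.s_ba_floor,
            "q": {k: float(v) for k, v in self.q_.items()},
            "k": {k: float(v) for k, v in self.k_.items()},
            "s": {k: float(v) for k, v in self.s_.items()},
            "s_ba": float(self.s_ba_),
        }

    @classmethod
    def from_state(cls, state: dict) -> "KlemeraDoubalRegressor":
        obj = cls(variant=state["variant"], s_ba_floor=state["s_ba_floor"])
        obj.q_ = pd.Series(state["q"])
        obj.k_ = pd.Series(state["k"])
        obj.s_ = pd.Series(state["s"])
        obj.s_ba_ = state["s_ba"]
        obj.feature_names_in_ = np.asarray(list(state["q"]), dtype=object)
        obj.n_features_in_ = len(state["q"])
        return obj
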