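"""Training-set preprocessing for the clock stage.

Three of the six CpGs (ELOVL2, EDARADD, CCDC102B) drift nonlinearly with
age, which hurts models that assume linearity. The preprocessor fixes
this with a per-CpG monotone transform chosen from a small fixed
candidate family — identity, log(beta + eps), logit on clipped beta, and
a couple of power maps — by maximizing |Pearson r| between the
transformed marker and age on the *training* data. Identity is always a
candidate, so transformation can never reduce training |r|.

All six markers are then standardized (training mean and SD, divisor
n − 1). Everything is fitted on training data only; applying the fitted
state to new samples never touches their statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

#: Clipping/offset constant shared by the log and logit candidates.
TRANSFORM_EPS = 0.01

#: CpGs considered for a nonlinearity-correcting transform by default.
DEFAULT_TRANSFORM_CPGS: tuple[str, ...] = ("CCDC102B", "EDARADD", "ELOVL2")


def _candidate_maps(eps: float) -> dict[str, callable]:
    def _logit(x: np.ndarray) -> np.ndarray:
        xc = np.clip(x, eps, 1 - eps)
        return np.log(xc / (1 - xc))

    return {
        "identity": lambda x: np.asarray(x, dtype=float),
        "log": lambda x: np.log(np.asarray(x, dtype=float) + eps),
        "logit": _logit,
        "sqrt": lambda x: np.sqrt(np.clip(x, 0.0, None)),
        "square": lambda x: np.square(np.asarray(x, dtype=float)),
    }


class MethylationPreprocessor(BaseEstimator, TransformerMixin):
    """Monotone per-CpG transforms plus standardization.

    Parameters
    ----------
    apply_transform : bool, default True
        When False ("raw" mode) only standardization is fitted and the
        transform for every column is the identity.
    transform_cpgs : tuple of str
        Columns eligible for a non-identity transform (intersected with
        the columns actually present).
    eps : float
        Offset/clip constant for the log and logit candidates.

    Attributes
    ----------
    transform_names_ : dict
        Chosen candidate per column ("identity" for non-eligible ones).
    mean_, scale_ : pandas.Series
        Post-transform standardization state (training mean, SD with
        divisor n − 1).
    """

    def __init__(
        self,
        apply_transform: bool = True,
        transform_cpgs: tuple[str, ...] = DEFAULT_TRANSFORM_CPGS,
        eps: float = TRANSFORM_EPS,
    ):
        self.apply_transform = apply_transform
        self.transform_cpgs = transform_cpgs
        self.eps = eps

    def fit(self, X: pd.DataFrame, y=None) -> "MethylationPreprocessor":
        X = self._check_frame(X)
        if self.apply_transform and y is None:
            raise ValueError("transform=True requires ages y to rank candidates")
        candidates = _candidate_maps(self.eps)
        names: dict[str, str] = {}
        for col in X.columns:
            x = X[col].to_numpy(dtype=float)
            if np.ptp(x) == 0:
                raise ValueError(f"zero-variance CpG column {col!r}")
            if not self.apply_transform or col not in self.transform_cpgs:
                names[col] = "identity"
                continue
            age = np.asarray(y, dtype=float)
            best_name, best_r = "identity", -np.inf
            for name, fn in candidates.items():
                tx = fn(x)
                if np.ptp(tx) == 0 or not np.all(np.isfinite(tx)):
                    continue
                r = abs(stats.pearsonr(tx, age)[0])
                if r > best_r + 1e-12:  # strict improvement; identity wins ties
                    best_name, best_r = name, r
            names[col] = best_name
        self.transform_names_ = names
        transformed = self._apply_transforms(X)
        self.mean_ = transformed.mean()
        self.scale_ = transformed.std(ddof=1)
        if (self.scale_ <= 0).any():
            bad = self.scale_.index[self.scale_ <= 0].tolist()
            raise ValueError(f"zero variance after transform: {bad}")
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "mean_")
        X = self._check_frame(X)
        missing = [c for c in self.feature_names_in_ if c not in X.columns]
        if missing:
            raise ValueError(f"missing CpG columns: {missing}")
        X = X[list(self.feature_names_in_)]
        return (self._apply_transforms(X) - self.mean_) / self.scale_

    def _apply_transforms(self, X: pd.DataFrame) -> pd.DataFrame:
        candidates = _candidate_maps(self.eps)
        out = {}
        for col in X.columns:
            fn = candidates[self.transform_names_[col]]
            out[col] = fn(X[col].to_numpy(dtype=float))
        return pd.DataFrame(out, index=X.index)

    @staticmethod
    def _check_frame(X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("expected a DataFrame of CpG beta columns")
        if X.empty:
            raise ValueError("empty input")
        return X

    def get_state(self) -> dict:
        """JSON-serializable fitted state."""
        check_is_fitted(self, "mean_")
        return {
            "apply_transform": self.apply_transform,
            "transform_cpgs": list(self.transform_cpgs),
            "eps": self.eps,
            "transform_names": dict(self.transform_names_),
            "mean": {k: float(v) for k, v in self.mean_.items()},
            "scale": {k: float(v) for k, v in self.scale_.items()},
        }

    @classmethod
    def from_state(cls, state: dict) -> "MethylationPreprocessor":
        obj = cls(
            apply_transform=state["apply_transform"],
            transform_cpgs=tuple(state["transform_cpgs"]),
            eps=state["eps"],
        )
        obj.transform_names_ = dict(state["transform_names"])
        obj.mean_ = pd.Series(state["mean"])
        obj.scale_ = pd.Series(state["scale"])
        obj.feature_names_in_ = np.asarray(list(state["mean"]), dtype=object)
        obj.n_features_in_ = len(state["mean"])
        return obj
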