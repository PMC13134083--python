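"""Six-CpG epigenetic clocks: model families, evaluation, subset search.

Five model families predict chronological age from the CpG panel:

* ``enr`` — elastic net (mixed L1/L2 linear model),
* ``gbr`` — gradient-boosted regression trees,
* ``svml`` / ``svmr`` — support vector regression, linear / RBF kernel,
* ``kdr`` — the Klemera-Doubal estimator (see :mod:`ddclock.kdr`).

Hyperparameters of the sklearn families are chosen by 5-fold
cross-validation on the training set only (unshuffled folds, so fits are
deterministic under the seed). Every clock carries its own fitted
:class:`~ddclock.preprocess.MethylationPreprocessor`, serializes to a
versioned JSON document, and reloads with bit-identical predictions.
"""

from __future__ import annotations

import base64
import itertools
import json
import pickle

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import ElasticNetCV
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.svm import SVR
from sklearn.utils.validation import check_is_fitted

from .droplets import CPGS
from .kdr import KlemeraDoubalRegressor
from .metrics import ClockMetrics, age_acceleration, evaluate_predictions
from .preprocess import MethylationPreprocessor
from .simulate_cohort import AGE_COLUMN

FAMILIES: tuple[str, ...] = ("enr", "gbr", "svml", "svmr", "kdr")

MODEL_FORMAT_VERSION = 1


def _make_family_model(family: str, seed: int):
    cv = KFold(n_splits=5)
    if family == "enr":
        # alpha grid extends low enough that a noiseless linear signal is
        # recovered to numerical precision.
        return ElasticNetCV(
            l1_ratio=[0.1, 0.5, 0.7, 0.9, 0.95, 1.0],
            alphas=np.logspace(-8, 1.5, 60),
            cv=cv,
            max_iter=50_000,
            tol=1e-10,
            random_state=seed,
        )
    if family == "gbr":
        return GridSearchCV(
            GradientBoostingRegressor(n_estimators=300, random_state=seed),
            {"learning_rate": [0.05, 0.1], "max_depth": [2, 3]},
            cv=cv,
            scoring="neg_mean_absolute_error",
        )
    if family == "svml":
        return GridSearchCV(
            SVR(kernel="linear"),
            {"C": [0.1, 1.0, 10.0, 100.0], "epsilon": [0.1, 1.0]},
            cv=cv,
            scoring="neg_mean_absolute_error",
        )
    if family == "svmr":
        return GridSearchCV(
            SVR(kernel="rbf"),
            {"C": [1.0, 10.0, 100.0, 1000.0], "gamma": ["scale"], "epsilon": [0.1, 1.0]},
            cv=cv,
            scoring="neg_mean_absolute_error",
        )
    if family == "kdr":
        return KlemeraDoubalRegressor()
    raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")


class EpigeneticClock(BaseEstimator, RegressorMixin):
    """Age-prediction clock over a CpG subset.

    Parameters
    ----------
    family : str
        One of ``enr``, ``gbr``, ``svml``, ``svmr``, ``kdr``.
    cpg_subset : tuple of str or None
        Panel columns to use (None = all six assay CpGs present).
    transform : bool
        Apply the nonlinearity-correcting transforms before
        standardization ("transformed" mode) or standardize raw betas.
    kdr_variant : str
        Passed to the KDR family; ``BA_EC`` requires chronological age at
        prediction time.
    seed : int
        Controls hyperparameter search and any stochastic fitting.
    """

    def __init__(
        self,
        family: str = "kdr",
        cpg_subset: tuple[str, ...] | None = None,
        transform: bool = True,
        kdr_variant: str = "BA_EC",
        seed: int = 0,
    ):
        self.family = family
        self.cpg_subset = cpg_subset
        self.transform = transform
        self.kdr_variant = kdr_variant
        self.seed = seed

    # -- fitting -----------------------------------------------------------

    def fit(self, X: pd.DataFrame, y=None) -> "EpigeneticClock":
        """Fit on a cohort table (CpG columns; ages in ``y`` or an 'age' column)."""
        if y is None:
            if AGE_COLUMN not in X.columns:
                raise ValueError("need ages: pass y or include an 'age' column")
            y = X[AGE_COLUMN]
        age = np.asarray(y, dtype=float)
        subset = self._resolve_subset(X)
        if not (2 <= len(subset) <= 6):
            raise ValueError(f"cpg_subset must have 2-6 CpGs, got {len(subset)}")
        missing = [c for c in subset if c not in X.columns]
        if missing:
            raise ValueError(f"cohort lacks CpG columns: {missing}")

        self.preprocessor_ = MethylationPreprocessor(apply_transform=self.transform)
        Z = self.preprocessor_.fit(X[list(subset)], age).transform(X[list(subset)])
        model = _make_family_model(self.family, self.seed)
        if self.family == "kdr":
            model = KlemeraDoubalRegressor(variant=self.kdr_variant)
            model.fit(Z, age)
        else:
            model.fit(Z.to_numpy(), age)
        self.model_ = model
        self.cpg_subset_ = tuple(subset)
        return self

    def _resolve_subset(self, X: pd.DataFrame) -> tuple[str, ...]:
        if self.cpg_subset is not None:
            return tuple(self.cpg_subset)
        return tuple(c for c in CPGS if c in X.columns)

    # -- prediction --------------------------------------------------------

    def predict(self, X: pd.DataFrame, chronological_age=None) -> np.ndarray:
        """Predict ages (years). KDR/BA_EC needs chronological age, either
        via ``chronological_age`` or an 'age' column in ``X``."""
        check_is_fitted(self, "model_")
        Z = self.preprocessor_.transform(X[list(self.cpg_subset_)])
        if isinstance(self.model_, KlemeraDoubalRegressor):
            if (
                chronological_age is None
                and self.model_.variant == "BA_EC"
                and AGE_COLUMN in X.columns
            ):
                chronological_age = X[AGE_COLUMN].to_numpy(dtype=float)
            return self.model_.predict(Z, chronological_age=chronological_age)
        return self.model_.predict(Z.to_numpy())

    # -- persistence -------------------------------------------------------

    def to_json(self) -> str:
        """Serialize the fitted clock to a versioned JSON document."""
        check_is_fitted(self, "model_")
        doc = {
            "format_version": MODEL_FORMAT_VERSION,
            "family": self.family,
            "cpg_subset": list(self.cpg_subset_),
            "transform": self.transform,
            "kdr_variant": self.kdr_variant,
            "seed": self.seed,
            "preprocessor": self.preprocessor_.get_state(),
        }
        if isinstance(self.model_, KlemeraDoubalRegressor):
            doc["kdr"] = self.model_.get_state()
        elif isinstance(self.model_, ElasticNetCV):
            doc["linear"] = {
                "coef": [float(c) for c in self.model_.coef_],
                "intercept": float(self.model_.intercept_),
                "alpha": float(self.model_.alpha_),
                "l1_ratio": float(self.model_.l1_ratio_),
            }
        else:
            # tree/kernel models: embed the fitted best estimator so
            # reloads are bit-identical (the surrounding CV search object
            # carries timing data and is not reproducible byte-for-byte).
            fitted = self.model_
            if isinstance(fitted, GridSearchCV):
                doc["best_params"] = fitted.best_params_
                fitted = fitted.best_estimator_
            blob = pickle.dumps(fitted)
            doc["sklearn_blob"] = base64.b64encode(blob).decode("ascii")
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "EpigeneticClock":
        doc = json.loads(text)
        if doc.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format: {doc.get('format_version')}")
        clock = cls(
            family=doc["family"],
            cpg_subset=tuple(doc["cpg_subset"]),
            transform=doc["transform"],
            kdr_variant=doc["kdr_variant"],
            seed=doc["seed"],
        )
        clock.preprocessor_ = MethylationPreprocessor.from_state(doc["preprocessor"])
        clock.cpg_subset_ = tuple(doc["cpg_subset"])
        if "kdr" in doc:
            clock.model_ = KlemeraDoubalRegressor.from_state(doc["kdr"])
        elif "linear" in doc:
            clock.model_ = _FrozenLinear(
                np.asarray(doc["linear"]["coef"], dtype=float),
                doc["linear"]["intercept"],
            )
        else:
            clock.model_ = pickle.loads(base64.b64decode(doc["sklearn_blob"]))
        return clock


class _FrozenLinear:
    """Reloaded linear model: coefficients only, no refitting."""

    def __init__(self, coef: np.ndarray, intercept: float):
        self.coef_ = coef
        self.intercept_ = intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_


# -- module-level conveniences (thin wrappers over the estimator) ----------


def fit_clock(
    family: str,
    train: pd.DataFrame,
    cpg_subset: tuple[str, ...] | None = None,
    transform: bool = True,
    seed: int = 0,
    kdr_variant: str = "BA_EC",
) -> EpigeneticClock:
    """Fit one clock on a cohort table (must contain an 'age' column)."""
    return EpigeneticClock(
        family=family,
        cpg_subset=cpg_subset,
        transform=transform,
        kdr_variant=kdr_variant,
        seed=seed,
    ).fit(train)


def evaluate(clock: EpigeneticClock, data: pd.DataFrame) -> ClockMetrics:
    """Evaluate a fitted clock against the cohort's chronological ages."""
    if data.empty:
        raise ValueError("empty evaluation cohort")
    predicted = clock.predict(data)
    return evaluate_predictions(data[AGE_COLUMN].to_numpy(dtype=float), predicted)


def clock_age_acceleration(
    clock: EpigeneticClock, data: pd.DataFrame, mode: str = "relative"
) -> np.ndarray:
    """Per-sample age acceleration (years) of a fitted clock on a cohort."""
    predicted = clock.predict(data)
    return age_acceleration(data[AGE_COLUMN].to_numpy(dtype=float), predicted, mode=mode)


def subset_search(
    families,
    train: pd.DataFrame,
    test: pd.DataFrame,
    transform: bool = True,
    seed: int = 0,
    sizes: tuple[int, ...] = (2, 3, 4, 5, 6),
    cpgs: tuple[str, ...] = CPGS,
    kdr_variant: str = "BA_EC",
) -> pd.DataFrame:
    """Fit every CpG combination of the given sizes for every family.

    With all six CpGs and sizes 2-6 that is 57 combinations per family.
    Each row reports training and testing metrics; per-fit failures are
    flagged in the ``status`` column rather than aborting the search.
    Rows are ranked by test MAE, ties broken by (fewer CpGs,
    lexicographic subset).
    """
    if isinstance(families, str):
        families = [families]
    rows = []
    for family in families:
        for size in sizes:
            for combo in itertools.combinations(sorted(cpgs), size):
                row: dict = {
                    "family": family,
                    "cpg_subset": ",".join(combo),
                    "n_cpgs": size,
                    "status": "ok",
                }
                try:
                    clock = fit_clock(
                        family,
                        train,
                        cpg_subset=combo,
                        transform=transform,
                        seed=seed,
                        kdr_variant=kdr_variant,
                    )
                    for name, data in (("train", train), ("test", test)):
                        m = evaluate(clock, data)
                        row.update(
                            {
                                f"{name}_r": m.r,
                                f"{name}_r2": m.r2,
                                f"{name}_mae": m.mae,
                                f"{name}_rmse": m.rmse,
                            }
                        )
                except Exception as exc:  # noqa: BLE001 — flagged, not fatal
                    row["status"] = f"error: {exc}"
                rows.append(row)
    table = pd.DataFrame(rows)
    if "test_mae" not in table.columns:
        return table
    table = table.sort_values(
        by=["test_mae", "n_cpgs", "cpg_subset"],
        na_position="last",
        kind="mergesort",
    ).reset_index(drop=True)
    return table
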