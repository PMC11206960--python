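"""QSPR regressors and the SVM-RF-GBM stacking ensemble.

Five base learners are supported — multiple linear regression (mlr),
partial least squares (pls), RBF-kernel support vector regression
(svm_rbf), random forest (rf) and gradient boosting (gbm) — with defaults
fixed to the reference model settings: PLS ncomp = 11; SVM sigma = 0.015
(the kernlab rbfdot parameterization exp(-sigma ||x-y||^2), i.e. the RBF
gamma), C = 2, epsilon = 0.1; RF mtry = 18 with 500 trees; GBM 100 trees
of depth 16, shrinkage 0.1, minimum 10 observations per terminal node.

The stacking ensemble fits a linear meta-model by least squares on
out-of-fold base predictions (avoiding resubstitution leakage), then
refits the three bases on the full training set.

Reported R^2 is the squared Pearson correlation of observed and predicted
values, not 1 - SS_res/SS_tot.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import RepeatedKFold
from sklearn.svm import SVR

__all__ = [
    "MODEL_KINDS",
    "PAPER_HYPERPARAMS",
    "ModelSpec",
    "TrainedModel",
    "StackingEnsemble",
    "Metrics",
    "CVConfig",
    "train_model",
    "predict",
    "evaluate",
    "cross_validate",
    "tune_model",
    "train_ensemble",
]

MODEL_KINDS = ("mlr", "pls", "svm_rbf", "rf", "gbm")

PAPER_HYPERPARAMS: dict[str, dict] = {
    "mlr": {},
    "pls": {"ncomp": 11},
    "svm_rbf": {"sigma": 0.015, "C": 2.0, "epsilon": 0.1},
    "rf": {"mtry": 18, "n_trees": 500},
    "gbm": {"n_trees": 100, "interaction_depth": 16, "shrinkage": 0.1, "min_node_obs": 10},
}


@dataclass
class ModelSpec:
    kind: str
    hyperparams: dict = field(default_factory=dict)
    seed: Optional[int] = None

    def resolved_hyperparams(self) -> dict:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}; expected one of {MODEL_KINDS}")
        params = dict(PAPER_HYPERPARAMS[self.kind])
        unknown = set(self.hyperparams) - set(params)
        if unknown and self.kind != "mlr":
            raise ValueError(f"unknown hyperparameters for {self.kind}: {sorted(unknown)}")
        if unknown:
            raise ValueError(f"mlr takes no hyperparameters, got {sorted(unknown)}")
        params.update(self.hyperparams)
        return params


def _build_estimator(spec: ModelSpec, n_features: int, n_samples: int):
    hp = spec.resolved_hyperparams()
    seed = spec.seed
    if spec.kind == "mlr":
        return LinearRegression()
    if spec.kind == "pls":
        ncomp = int(hp["ncomp"])
        if ncomp > n_features:
            raise ValueError(f"ncomp = {ncomp} exceeds the {n_features} available features")
        return PLSRegression(n_components=ncomp, scale=False)
    if spec.kind == "svm_rbf":
        return SVR(kernel="rbf", gamma=hp["sigma"], C=hp["C"], epsilon=hp["epsilon"])
    if spec.kind == "rf":
        mtry = int(hp["mtry"])
        if mtry > n_features:
            raise ValueError(f"mtry = {mtry} exceeds the {n_features} available features")
        return RandomForestRegressor(
            n_estimators=int(hp["n_trees"]), max_features=mtry, random_state=seed
        )
    if spec.kind == "gbm":
        return GradientBoostingRegressor(
            n_estimators=int(hp["n_trees"]),
            max_depth=int(hp["interaction_depth"]),
            learning_rate=hp["shrinkage"],
            min_samples_leaf=int(hp["min_node_obs"]),
            random_state=seed,
        )
    raise ValueError(f"unknown model kind {spec.kind!r}")


def _as_frame(X) -> pd.DataFrame:
    return X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))


@dataclass
class TrainedModel:
    """A fitted regressor plus the column names it was trained on."""

    spec: ModelSpec
    estimator: object
    columns: list[str]

    def predict(self, X) -> np.ndarray:
        X = _as_frame(X)
        missing = [c for c in self.columns if c not in X.columns]
        if missing:
            raise KeyError(f"matrix lacks model columns: {missing}")
        pred = self.estimator.predict(np.asarray(X[self.columns], dtype=float))
        return np.asarray(pred, dtype=float).ravel()


def train_model(spec: ModelSpec, X, y) -> TrainedModel:
    """Fit one regressor; unspecified hyperparameters take the reference defaults."""
    X = _as_frame(X)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("training requires at least 2 samples")
    if X.shape[0] != len(y):
        raise ValueError("X and y must have the same number of rows")
    est = _build_estimator(spec, n_features=X.shape[1], n_samples=X.shape[0])
    est.fit(np.asarray(X, dtype=float), y)
    return TrainedModel(spec=spec, estimator=est, columns=list(X.columns))


def predict(model, X) -> np.ndarray:
    """Predict log Papp; the column order of X is irrelevant."""
    return model.predict(X)


@dataclass
class Metrics:
    """RMSE (log Papp units) and R^2 (squared Pearson correlation).

    ``r2`` is None — with ``r2_undefined`` set — when either vector has
    zero variance.
    """

    rmse: float
    r2: Optional[float]
    r2_undefined: bool = False


def evaluate(y, y_hat) -> Metrics:
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size < 2:
        raise ValueError("evaluate requires two equal-length vectors of size >= 2")
    rmse = float(np.sqrt(np.mean((y - y_hat) ** 2)))
    if np.std(y) == 0 or np.std(y_hat) == 0:
        warnings.warn("zero variance in observed or predicted values; R^2 undefined")
        return Metrics(rmse=rmse, r2=None, r2_undefined=True)
    r = stats.pearsonr(y, y_hat).statistic
    return Metrics(rmse=rmse, r2=float(r * r))


@dataclass
class CVConfig:
    folds: int = 5
    repeats: int = 5
    seed: Optional[int] = None


def _mean_metrics(per_fold: list[Metrics]) -> Metrics:
    rmse = float(np.mean([m.rmse for m in per_fold]))
    r2s = [m.r2 for m in per_fold if m.r2 is not None]
    if r2s:
        return Metrics(rmse=rmse, r2=float(np.mean(r2s)), r2_undefined=len(r2s) < len(per_fold))
    return Metrics(rmse=rmse, r2=None, r2_undefined=True)


def _cv_splits(n: int, cv: CVConfig):
    if cv.folds < 2:
        raise ValueError("cross-validation requires at least 2 folds")
    if cv.folds > n:
        raise ValueError(f"folds = {cv.folds} exceeds the {n} available rows")
    rkf = RepeatedKFold(n_splits=cv.folds, n_repeats=cv.repeats, random_state=cv.seed)
    return rkf.split(np.arange(n))


def cross_validate(spec: ModelSpec, X, y, cv: CVConfig) -> Metrics:
    """Repeated k-fold CV metrics, averaged over folds x repeats."""
    X = _as_frame(X)
    y = np.asarray(y, dtype=float)
    per_fold = []
    for train_idx, test_idx in _cv_splits(len(y), cv):
        model = train_model(spec, X.iloc[train_idx], y[train_idx])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            per_fold.append(evaluate(y[test_idx], model.predict(X.iloc[test_idx])))
    return _mean_metrics(per_fold)


def tune_model(kind: str, grid: Sequence[dict], X, y, cv: CVConfig, seed: Optional[int] = None) -> ModelSpec:
    """Return the grid point with minimum mean CV RMSE (ties: first in grid order)."""
    grid = list(grid)
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    best_spec, best_rmse = None, math.inf
    for point in grid:
        spec = ModelSpec(kind=kind, hyperparams=dict(point), seed=seed)
        rmse = cross_validate(spec, X, y, cv).rmse
        if rmse < best_rmse:
            best_spec, best_rmse = spec, rmse
    return best_spec


DEFAULT_BASE_KINDS = ("svm_rbf", "rf", "gbm")


class StackingEnsemble(BaseEstimator, RegressorMixin):
    """SVM-RF-GBM stacking: linear meta-model on out-of-fold base predictions.

    The meta-coefficients (intercept + one weight per base) are fitted by
    least squares of y on base predictions gathered out-of-fold with
    repeated k-fold CV; the bases are then refitted on the full training
    set. Degenerate (collinear or constant) base predictions fall back to
    the minimum-norm least-squares solution and set ``degenerate_``.

    Parameters
    ----------
    base_specs : three ModelSpec (default: svm_rbf, rf, gbm with the
        reference hyperparameters, mtry/ncomp clamped by the caller).
    cv : CVConfig controlling the out-of-fold prediction folds.
    """

    def __init__(self, base_specs: Optional[Sequence[ModelSpec]] = None, cv: Optional[CVConfig] = None):
        self.base_specs = base_specs
        self.cv = cv

    def _specs(self) -> list[ModelSpec]:
        if self.base_specs is None:
            return [ModelSpec(kind=k) for k in DEFAULT_BASE_KINDS]
        return list(self.base_specs)

    def fit(self, X, y) -> "StackingEnsemble":
        X = _as_frame(X)
        y = np.asarray(y, dtype=float)
        specs = self._specs()
        cv = self.cv or CVConfig(folds=5, repeats=1, seed=0)
        n = len(y)
        oof = np.zeros((n, len(specs)))
        counts = np.zeros(n)
        for train_idx, test_idx in _cv_splits(n, cv):
            for j, spec in enumerate(specs):
                m = train_model(spec, X.iloc[train_idx], y[train_idx])
                oof[test_idx, j] += m.predict(X.iloc[test_idx])
            counts[test_idx] += 1
        oof /= counts[:, None]
        A = np.column_stack([np.ones(n), oof])
        coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
        self.degenerate_ = rank < A.shape[1]
        if self.degenerate_:
            warnings.warn("degenerate base predictions; minimum-norm meta-coefficients used")
        self.intercept_ = float(coef[0])
        self.weights_ = coef[1:].copy()
        self.base_models_ = [train_model(spec, X, y) for spec in specs]
        self.columns_ = list(X.columns)
        self.oof_predictions_ = oof
        return self

    def base_predictions(self, X) -> np.ndarray:
        return np.column_stack([m.predict(X) for m in self.base_models_])

    def predict(self, X) -> np.ndarray:
        P = self.base_predictions(X)
        return self.intercept_ + P @ self.weights_

    @property
    def meta_coefficients(self) -> np.ndarray:
        return np.concatenate([[self.intercept_], self.weights_])


def train_ensemble(
    X,
    y,
    base_specs: Optional[Sequence[ModelSpec]] = None,
    cv: Optional[CVConfig] = None,
) -> StackingEnsemble:
    """Fit the SVM-RF-GBM stacking ensemble."""
    return StackingEnsemble(base_specs=base_specs, cv=cv).fit(X, y)


def cross_validate_ensemble(X, y, base_specs, cv_outer: CVConfig, cv_inner: Optional[CVConfig] = None) -> Metrics:
    """Repeated k-fold CV of the full stacking procedure (meta-fit inside each fold)."""
    X = _as_frame(X)
    y = np.asarray(y, dtype=float)
    inner = cv_inner or CVConfig(folds=cv_outer.folds, repeats=1, seed=cv_outer.seed)
    per_fold = []
    for train_idx, test_idx in _cv_splits(len(y), cv_outer):
        ens = StackingEnsemble(base_specs=base_specs, cv=inner).fit(X.iloc[train_idx], y[train_idx])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            per_fold.append(evaluate(y[test_idx], ens.predict(X.iloc[test_idx])))
    return _mean_metrics(per_fold)
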