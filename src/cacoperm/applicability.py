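"""Leverage-based applicability domain (AD) for QSPR models.

The AD is defined by the hat matrix of the intercept-augmented training
design: H = X (X'X)^-1 X'. A sample's leverage is the corresponding
diagonal entry; for a new row u it is h = u' (X'X)^-1 u. Samples with
leverage above the warning leverage h* = 3(p+1)/n, or with standardized
residual outside +/-3, lie outside the domain (Williams plot convention).

The inverse Gram matrix is computed with a pseudo-inverse so that
collinear designs (possible after descriptor selection) degrade gracefully
instead of failing.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = ["LeverageAD", "fit_ad", "leverage", "standardized_residuals", "williams_data"]

ArrayLike = Union[np.ndarray, pd.DataFrame]


def _as_matrix(X: ArrayLike, columns: Optional[Sequence[str]] = None) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        if columns is not None:
            missing = [c for c in columns if c not in X.columns]
            if missing:
                raise KeyError(f"matrix lacks required predictor columns: {missing}")
            X = X[list(columns)]
        return np.asarray(X, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    return X


class LeverageAD(BaseEstimator):
    """Hat-matrix / leverage applicability-domain model.

    Fitted attributes
    -----------------
    inv_gram_ : (p+1, p+1) pseudo-inverse of the intercept-augmented
        training Gram matrix X'X.
    h_star_ : warning leverage, 3(p+1)/n.
    n_train_, p_ : training size and predictor count.
    residual_scale_ : sample standard deviation (ddof=1) of the supplied
        training residuals, log Papp units.
    training_leverages_ : hat diagonal of the training design.
    column_names_ : predictor names when fitted on a DataFrame.
    """

    def fit(self, X: ArrayLike, residuals: Optional[Sequence[float]] = None) -> "LeverageAD":
        self.column_names_ = list(X.columns) if isinstance(X, pd.DataFrame) else None
        M = _as_matrix(X)
        n, p = M.shape
        if n == 0 or p == 0:
            raise ValueError("cannot fit an applicability domain on an empty matrix")
        A = np.column_stack([np.ones(n), M])
        self.inv_gram_ = np.linalg.pinv(A.T @ A)
        self.n_train_ = n
        self.p_ = p
        self.h_star_ = 3 * (p + 1) / n
        self.training_leverages_ = np.einsum("ij,jk,ik->i", A, self.inv_gram_, A)
        if residuals is not None:
            r = np.asarray(residuals, dtype=float)
            if r.shape[0] != n:
                raise ValueError("residual vector length must match the training matrix")
            self.residual_scale_ = float(np.std(r, ddof=1)) if n > 1 else 0.0
        else:
            self.residual_scale_ = float("nan")
        return self

    def leverage(self, X: ArrayLike) -> np.ndarray:
        """Leverage h = u' (X'X)^-1 u for each (intercept-augmented) row u."""
        M = _as_matrix(X, self.column_names_)
        if M.shape[1] != self.p_:
            raise ValueError(f"expected {self.p_} predictors, got {M.shape[1]}")
        U = np.column_stack([np.ones(M.shape[0]), M])
        return np.einsum("ij,jk,ik->i", U, self.inv_gram_, U)

    def standardized_residuals(self, y: Sequence[float], y_hat: Sequence[float]) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        y_hat = np.asarray(y_hat, dtype=float)
        if y.shape != y_hat.shape:
            raise ValueError("y and y_hat must have equal length")
        if not np.isfinite(self.residual_scale_) or self.residual_scale_ <= 0:
            raise ValueError("residual scale is zero or undefined; cannot standardize")
        return (y - y_hat) / self.residual_scale_

    def williams_data(
        self,
        X: ArrayLike,
        y: Sequence[float],
        y_hat: Sequence[float],
        set_label: str = "train",
        ids: Optional[Sequence[str]] = None,
    ) -> pd.DataFrame:
        """Williams-plot table: id, leverage, std_residual, set, outlier.

        A point is an outlier when leverage > h* or |std residual| > 3.
        """
        h = self.leverage(X)
        sr = self.standardized_residuals(y, y_hat)
        if ids is None:
            ids = list(X.index) if isinstance(X, pd.DataFrame) else list(range(len(h)))
        out = pd.DataFrame(
            {
                "id": list(ids),
                "leverage": h,
                "std_residual": sr,
                "set": set_label,
                "outlier": (h > self.h_star_) | (np.abs(sr) > 3.0),
            }
        )
        return out


def fit_ad(X_train: ArrayLike, residuals: Optional[Sequence[float]] = None) -> LeverageAD:
    """Fit the leverage applicability domain on the training design."""
    return LeverageAD().fit(X_train, residuals)


def leverage(ad: LeverageAD, X_new: ArrayLike) -> np.ndarray:
    return ad.leverage(X_new)


def standardized_residuals(ad: LeverageAD, y, y_hat) -> np.ndarray:
    return ad.standardized_residuals(y, y_hat)


def williams_data(ad: LeverageAD, X, y, y_hat, set_label: str = "train", ids=None) -> pd.DataFrame:
    return ad.williams_data(X, y, y_hat, set_label=set_label, ids=ids)
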