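"""Descriptor preprocessing and dataset splitting.

The preprocessing chain is fitted on the training matrix only and applied
unchanged to any other matrix (test set, new compounds): median imputation,
near-zero-variance removal, pairwise |r| correlation filtering (default
cutoff 0.70), then centering and unit-variance scaling with the training
statistics. The 80:20 split is stratified on response quantile bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "DescriptorPreprocessor",
    "SplitResult",
    "near_zero_variance",
    "correlation_filter",
    "fit_preprocess",
    "apply_preprocess",
    "split_dataset",
]


def near_zero_variance(
    m: pd.DataFrame, freq_cut: float = 19.0, unique_cut: float = 10.0
) -> list[str]:
    """Columns with (near-)zero variance, caret-style.

    A column is flagged when it has a single distinct value, or when the
    frequency ratio of its two most common values exceeds ``freq_cut`` and
    its distinct-value percentage is below ``unique_cut``.
    """
    flagged = []
    n = len(m)
    for col in m.columns:
        counts = m[col].dropna().value_counts()
        if len(counts) <= 1:
            flagged.append(col)
            continue
        freq_ratio = counts.iloc[0] / counts.iloc[1]
        pct_unique = 100.0 * len(counts) / n
        if freq_ratio > freq_cut and pct_unique < unique_cut:
            flagged.append(col)
    return flagged


def correlation_filter(m: pd.DataFrame, threshold: float = 0.70) -> list[str]:
    """Greedy pairwise-correlation filter; returns the kept column names.

    While any pair of surviving columns has |r| > threshold: take the pair
    with the largest |r| and drop the member with the larger mean absolute
    correlation against all remaining columns; on a tie, drop the column
    that comes later in input order. Requires a complete matrix with no
    zero-variance columns.
    """
    if m.isna().any().any():
        raise ValueError("correlation_filter requires a complete matrix (impute first)")
    if len(m) < 2:
        raise ValueError("correlation_filter requires at least 2 rows")
    values = np.asarray(m, dtype=float)
    sds = values.std(axis=0, ddof=1)
    zero_var = [c for c, s in zip(m.columns, sds) if s == 0]
    if zero_var:
        raise ValueError(f"zero-variance columns present (remove first): {zero_var}")
    p = values.shape[1]
    if p < 2:
        return list(m.columns)
    R = np.abs(np.corrcoef(values, rowvar=False))
    R = (R + R.T) / 2  # enforce exact symmetry so ties are detected as ties
    np.fill_diagonal(R, 0.0)
    alive = np.ones(p, dtype=bool)
    while alive.sum() > 1:
        idx = np.flatnonzero(alive)
        sub = R[np.ix_(idx, idx)]
        flat = np.argmax(sub)  # first occurrence in row-major order on ties
        i_sub, j_sub = divmod(flat, len(idx))
        if sub[i_sub, j_sub] <= threshold:
            break
        i, j = idx[i_sub], idx[j_sub]
        # mean |r| of each pair member against the other remaining columns
        mean_i = R[i, idx[idx != i]].mean()
        mean_j = R[j, idx[idx != j]].mean()
        if mean_i > mean_j:
            victim = i
        elif mean_j > mean_i:
            victim = j
        else:
            victim = max(i, j)  # tie: drop the later column in input order
        alive[victim] = False
    return [c for c, a in zip(m.columns, alive) if a]


class DescriptorPreprocessor(BaseEstimator, TransformerMixin):
    """Median imputation -> NZV removal -> correlation filter -> center/scale.

    All statistics are learned in :meth:`fit` (training matrix only) and
    reused verbatim by :meth:`transform` on any matrix containing the kept
    columns. Columns whose median is undefined (all values missing) are
    dropped at fit time.

    Parameters
    ----------
    corr_threshold : |r| cutoff of the pairwise correlation filter.
    freq_cut, unique_cut : near-zero-variance parameters (frequency ratio
        of the two most common values; distinct-value percentage).
    """

    def __init__(self, corr_threshold: float = 0.70, freq_cut: float = 19.0, unique_cut: float = 10.0):
        self.corr_threshold = corr_threshold
        self.freq_cut = freq_cut
        self.unique_cut = unique_cut

    def fit(self, X: pd.DataFrame, y=None) -> "DescriptorPreprocessor":
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(X)
        if X.shape[0] < 2 or X.shape[1] < 1:
            raise ValueError("preprocessing requires at least 2 rows and 1 column")
        if not (0 < self.corr_threshold <= 1):
            raise ValueError("corr_threshold must lie in (0, 1]")
        X = X.astype(float)
        X = X.dropna(axis=1, how="all")  # median undefined -> drop
        self.medians_ = X.median(axis=0, skipna=True).to_dict()
        imputed = X.fillna(pd.Series(self.medians_))
        nzv = set(near_zero_variance(imputed, self.freq_cut, self.unique_cut))
        imputed = imputed[[c for c in imputed.columns if c not in nzv]]
        kept = correlation_filter(imputed, self.corr_threshold) if imputed.shape[1] else []
        self.kept_columns_ = list(kept)
        retained = imputed[self.kept_columns_]
        self.centers_ = retained.mean(axis=0).to_dict()
        scales = retained.std(axis=0, ddof=1)
        if (scales <= 0).any():
            raise ValueError("zero-variance column survived filtering; cannot scale")
        self.scales_ = scales.to_dict()
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(X)
        missing = [c for c in self.kept_columns_ if c not in X.columns]
        if missing:
            raise KeyError(f"matrix lacks required columns: {missing}")
        out = X[self.kept_columns_].astype(float).copy()
        for col in self.kept_columns_:
            out[col] = (out[col].fillna(self.medians_[col]) - self.centers_[col]) / self.scales_[col]
        return out

    def to_dict(self) -> dict:
        return {
            "corr_threshold": self.corr_threshold,
            "freq_cut": self.freq_cut,
            "unique_cut": self.unique_cut,
            "medians": self.medians_,
            "kept_columns": self.kept_columns_,
            "centers": self.centers_,
            "scales": self.scales_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DescriptorPreprocessor":
        model = cls(d["corr_threshold"], d["freq_cut"], d["unique_cut"])
        model.medians_ = dict(d["medians"])
        model.kept_columns_ = list(d["kept_columns"])
        model.centers_ = dict(d["centers"])
        model.scales_ = dict(d["scales"])
        return model


def fit_preprocess(
    train: pd.DataFrame,
    corr_threshold: float = 0.70,
    freq_cut: float = 19.0,
    unique_cut: float = 10.0,
) -> DescriptorPreprocessor:
    return DescriptorPreprocessor(corr_threshold, freq_cut, unique_cut).fit(train)


def apply_preprocess(model: DescriptorPreprocessor, m: pd.DataFrame) -> pd.DataFrame:
    return model.transform(m)


@dataclass
class SplitResult:
    train_ids: list
    test_ids: list


def split_dataset(
    ids: Sequence,
    response: Sequence[float],
    ratio: float = 0.8,
    n_bins: int = 5,
    seed: Optional[int] = None,
) -> SplitResult:
    """Stratified train/test split on response quantile bins.

    Within each bin, round(ratio * bin size) ids are drawn without
    replacement into the training set. Both sets are guaranteed non-empty.
    """
    ids = list(ids)
    y = np.asarray(response, dtype=float)
    if len(ids) != len(y):
        raise ValueError("ids and response must have equal length")
    if not (0 < ratio < 1):
        raise ValueError("ratio must lie strictly between 0 and 1")
    if len(ids) < n_bins:
        raise ValueError("need at least n_bins compounds to stratify")
    rng = np.random.default_rng(seed)
    bins = pd.qcut(y, q=n_bins, labels=False, duplicates="drop")
    train_idx: list[int] = []
    test_idx: list[int] = []
    for b in np.unique(bins):
        members = np.flatnonzero(bins == b)
        members = members[rng.permutation(len(members))]
        n_train = int(np.floor(ratio * len(members) + 0.5))
        train_idx.extend(members[:n_train])
        test_idx.extend(members[n_train:])
    if not test_idx:
        test_idx.append(train_idx.pop())
    if not train_idx:
        train_idx.append(test_idx.pop())
    train_idx.sort()
    test_idx.sort()
    return SplitResult(train_ids=[ids[i] for i in train_idx], test_ids=[ids[i] for i in test_idx])
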