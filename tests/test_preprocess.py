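"""Preprocessing chain, correlation filter and the stratified split."""

import numpy as np
import pandas as pd
import pytest

from cacoperm import (
    DescriptorPreprocessor,
    correlation_filter,
    fit_preprocess,
    near_zero_variance,
    split_dataset,
)


def oracle_correlation_filter(m: pd.DataFrame, threshold: float) -> list[str]:
    """Independent literal application of the documented removal rule."""
    cols = list(m.columns)
    while len(cols) > 1:
        corr = m[cols].corr().abs()
        best_pair, best_r = None, threshold
        for i, a in enumerate(cols):
            for b in cols[i + 1:]:
                if corr.loc[a, b] > best_r:
                    best_pair, best_r = (a, b), corr.loc[a, b]
        if best_pair is None:
            break
        a, b = best_pair
        mean_a = np.mean([corr.loc[a, c] for c in cols if c != a])
        mean_b = np.mean([corr.loc[b, c] for c in cols if c != b])
        if mean_a > mean_b:
            victim = a
        elif mean_b > mean_a:
            victim = b
        else:
            victim = a if list(m.columns).index(a) > list(m.columns).index(b) else b
        cols.remove(victim)
    return cols


def exact_correlation_frame(R: np.ndarray, n: int = 24, seed: int = 0) -> pd.DataFrame:
    """Data whose sample correlation matrix equals R exactly."""
    rng = np.random.default_rng(seed)
    p = R.shape[0]
    Z = rng.standard_normal((n, p))
    Z -= Z.mean(axis=0)
    Q, _ = np.linalg.qr(Z)
    L = np.linalg.cholesky(R)
    X = Q[:, :p] @ L.T
    return pd.DataFrame(X, columns=[chr(ord("A") + i) for i in range(p)])


class TestCorrelationFilter:
    def test_below_threshold_all_kept(self, rng):
        m = pd.DataFrame(rng.standard_normal((200, 5)), columns=list("abcde"))
        assert correlation_filter(m, 0.70) == list("abcde")

    def test_duplicated_column_one_removed(self, rng):
        x = rng.standard_normal(50)
        m = pd.DataFrame({"a": x, "b": rng.standard_normal(50), "a2": x})
        kept = correlation_filter(m, 0.70)
        assert len(kept) == 2 and "b" in kept

    def test_three_column_worked_example(self):
        # |r|: (A,B)=0.9, (A,C)=0.8, (B,C)=0.5 (the largest pair plus one
        # sub-threshold pair; note r_BC is constrained to >= 0.458 once
        # r_AB=0.9 and r_AC=0.8, so it cannot be made arbitrarily small).
        # A has the larger mean absolute correlation (0.85 vs 0.70), so A
        # is removed; B and C survive at |r| = 0.5.
        R = np.array([[1.0, 0.9, 0.8], [0.9, 1.0, 0.5], [0.8, 0.5, 1.0]])
        m = exact_correlation_frame(R)
        corr = m.corr().to_numpy()
        assert np.allclose(np.abs(corr), np.abs(R), atol=1e-10)
        kept = correlation_filter(m, 0.70)
        assert kept == ["B", "C"]
        assert kept == oracle_correlation_filter(m, 0.70)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(3, 9))
        base = rng.standard_normal((40, p))
        # plant correlated pairs
        for j in range(1, p, 2):
            base[:, j] = base[:, j - 1] * rng.choice([-1, 1]) + rng.normal(
                0, rng.uniform(0.05, 1.5), 40
            )
        m = pd.DataFrame(base, columns=[f"v{i}" for i in range(p)])
        kept = correlation_filter(m, 0.70)
        assert kept == oracle_correlation_filter(m, 0.70)
        survivors = m[kept].corr().abs().to_numpy()
        np.fill_diagonal(survivors, 0)
        assert survivors.max(initial=0) <= 0.70 + 1e-12

    def test_zero_variance_rejected(self, rng):
        m = pd.DataFrame({"a": rng.standard_normal(20), "b": np.ones(20)})
        with pytest.raises(ValueError, match="zero-variance"):
            correlation_filter(m, 0.7)

    def test_missing_values_rejected(self, rng):
        m = pd.DataFrame({"a": rng.standard_normal(20), "b": rng.standard_normal(20)})
        m.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            correlation_filter(m, 0.7)


class TestPreprocessor:
    def test_median_imputation(self):
        m = pd.DataFrame({"a": [1.0, 2.0, np.nan, 4.0], "b": [0.0, 1.0, 2.0, 3.0]})
        model = fit_preprocess(m, corr_threshold=1.0)
        assert model.medians_["a"] == 2.0
        out = model.transform(m)
        # the imputed cell equals (median - mean)/sd of the imputed column
        imputed = m["a"].fillna(2.0)
        expected = (2.0 - imputed.mean()) / imputed.std(ddof=1)
        assert out.loc[2, "a"] == pytest.approx(expected, abs=1e-12)

    def test_constant_column_removed(self, rng):
        m = pd.DataFrame({"a": rng.standard_normal(30), "k": np.full(30, 7.0)})
        model = fit_preprocess(m)
        assert model.kept_columns_ == ["a"]

    def test_duplicated_informative_column_one_survives(self, rng):
        x = rng.standard_normal(40)
        m = pd.DataFrame({"a": x, "a2": x.copy(), "b": rng.standard_normal(40)})
        model = fit_preprocess(m)
        assert sorted(model.kept_columns_)[-1] == "b"
        assert len([c for c in model.kept_columns_ if c.startswith("a")]) == 1

    def test_training_matrix_standardized(self, small_dataset):
        _, matrix, _, _ = small_dataset
        model = fit_preprocess(matrix)
        out = model.transform(matrix)
        assert out.mean().abs().max() < 1e-10
        assert (out.std(ddof=1) - 1).abs().max() < 1e-10

    def test_new_row_at_training_medians(self, rng):
        m = pd.DataFrame(rng.lognormal(size=(50, 3)), columns=list("abc"))
        model = fit_preprocess(m)
        new = pd.DataFrame([{c: model.medians_[c] for c in "abc"}])
        out = model.transform(new)
        for c in model.kept_columns_:
            expected = (model.medians_[c] - model.centers_[c]) / model.scales_[c]
            assert out.iloc[0][c] == pytest.approx(expected, abs=1e-12)

    def test_apply_is_deterministic(self, small_dataset):
        _, matrix, _, _ = small_dataset
        model = fit_preprocess(matrix)
        pd.testing.assert_frame_equal(model.transform(matrix), model.transform(matrix))

    def test_missing_required_column_named(self, small_dataset):
        _, matrix, _, _ = small_dataset
        model = fit_preprocess(matrix)
        dropped = model.kept_columns_[0]
        with pytest.raises(KeyError, match=dropped):
            model.transform(matrix.drop(columns=[dropped]))

    def test_round_trip_serialization(self, small_dataset):
        _, matrix, _, _ = small_dataset
        model = fit_preprocess(matrix)
        clone = DescriptorPreprocessor.from_dict(model.to_dict())
        pd.testing.assert_frame_equal(model.transform(matrix), clone.transform(matrix))

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            fit_preprocess(pd.DataFrame({"a": [1.0]}))


def test_near_zero_variance_flags_spiked_column(rng):
    col = np.zeros(200)
    col[:3] = 1.0
    m = pd.DataFrame({"spiked": col, "cont": rng.standard_normal(200)})
    assert near_zero_variance(m) == ["spiked"]


class TestSplit:
    def test_single_bin_80_20(self):
        split = split_dataset(list("abcdefghij"), np.arange(10.0), ratio=0.8, n_bins=1, seed=0)
        assert len(split.train_ids) == 8 and len(split.test_ids) == 2

    def test_same_seed_identical(self, rng):
        y = rng.normal(size=60)
        ids = [f"m{i}" for i in range(60)]
        a = split_dataset(ids, y, seed=5)
        b = split_dataset(ids, y, seed=5)
        assert a.train_ids == b.train_ids and a.test_ids == b.test_ids

    def test_partition(self, rng):
        y = rng.normal(size=57)
        ids = list(range(57))
        split = split_dataset(ids, y, seed=1)
        assert sorted(split.train_ids + split.test_ids) == ids
        assert not set(split.train_ids) & set(split.test_ids)

    def test_per_bin_train_fraction(self, rng):
        y = rng.normal(size=1000)
        ids = list(range(1000))
        split = split_dataset(ids, y, ratio=0.8, n_bins=5, seed=2)
        bins = pd.qcut(y, 5, labels=False)
        for b in range(5):
            members = {i for i in ids if bins[i] == b}
            n_train = len(members & set(split.train_ids))
            assert abs(n_train - 0.8 * len(members)) <= 1

    def test_bad_ratio_rejected(self):
        with pytest.raises(ValueError):
            split_dataset([1, 2, 3, 4, 5], [1, 2, 3, 4, 5], ratio=1.2, n_bins=1)
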