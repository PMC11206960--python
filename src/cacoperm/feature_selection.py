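"""Descriptor selection: recursive feature elimination (RFE) with a
random-forest ranker, then genetic-algorithm (GA) refinement of the RFE
survivors. Both stages score candidate subsets by cross-validated RMSE.

RFE evaluates a grid of subset sizes (default 1-200) under repeated
k-fold resampling: within each resample, a forest fitted on all
candidates is ranked by permutation importance scored on the held-out
fold, and nested subsets of the ranking are refitted and scored
out-of-fold. The winning size is the one with minimum mean RMSE; the
final subset is the top-k ranking of a forest refitted on all rows.

The GA searches bit-string chromosomes over the candidate columns with
tournament selection (size 2), uniform crossover (probability 0.8),
per-bit mutation (probability 0.1) and no elitism; fitness is the mean
k-fold CV RMSE of a random forest on the active subset, and the result is
the best chromosome ever evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.model_selection import KFold, RepeatedKFold

__all__ = [
    "RFEConfig",
    "GAConfig",
    "SelectionResult",
    "RFESelector",
    "GASelector",
    "rfe_select",
    "ga_select",
]


@dataclass
class RFEConfig:
    subset_sizes: Sequence[int] = tuple(range(1, 201))
    cv_folds: int = 5
    cv_repeats: int = 20
    n_estimators: int = 500
    perm_repeats: int = 3
    seed: Optional[int] = None


@dataclass
class GAConfig:
    max_generations: int = 100
    population_size: int = 50
    crossover_prob: float = 0.8
    mutation_prob: float = 0.1
    elitism: int = 0
    cv_folds: int = 5
    n_estimators: int = 100
    seed: Optional[int] = None


@dataclass
class SelectionResult:
    selected_columns: list[str]
    score_trace: dict
    best_score: float

    def to_dict(self) -> dict:
        return {
            "selected_columns": self.selected_columns,
            "score_trace": {str(k): v for k, v in self.score_trace.items()},
            "best_score": self.best_score,
        }


def _rmse(y, y_hat) -> float:
    return float(np.sqrt(np.mean((np.asarray(y) - np.asarray(y_hat)) ** 2)))


def _ranker(n_estimators: int, seed: int) -> RandomForestRegressor:
    # mtry = p/3, the customary regression-forest default
    return RandomForestRegressor(n_estimators=n_estimators, max_features=1 / 3, random_state=seed)


class RFESelector(BaseEstimator):
    """Recursive feature elimination over a size grid, forest-ranked.

    Fitted attributes: ``selected_columns_``, ``best_size_``,
    ``best_score_`` and ``score_trace_`` (size -> mean held-out RMSE).
    """

    def __init__(
        self,
        subset_sizes: Sequence[int] = tuple(range(1, 201)),
        cv_folds: int = 5,
        cv_repeats: int = 20,
        n_estimators: int = 500,
        perm_repeats: int = 3,
        random_state: Optional[int] = None,
    ):
        self.subset_sizes = subset_sizes
        self.cv_folds = cv_folds
        self.cv_repeats = cv_repeats
        self.n_estimators = n_estimators
        self.perm_repeats = perm_repeats
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y) -> "RFESelector":
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        if X.isna().any().any():
            raise ValueError("RFE requires a complete (preprocessed) matrix")
        n, p = X.shape
        if n < self.cv_folds:
            raise ValueError("fewer rows than CV folds")
        sizes = sorted(set(int(s) for s in self.subset_sizes))
        if not sizes or sizes[0] < 1:
            raise ValueError("subset sizes must be positive")
        if sizes[-1] > p:
            raise ValueError(f"requested size {sizes[-1]} exceeds the {p} candidate columns")
        ss = np.random.SeedSequence(self.random_state)
        cv_seed, rank_seed, perm_seed, final_seed = [
            int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
        ]
        Xv = np.asarray(X, dtype=float)
        cols = np.array(X.columns)
        rkf = RepeatedKFold(n_splits=self.cv_folds, n_repeats=self.cv_repeats, random_state=cv_seed)
        errors = {s: [] for s in sizes}
        for split_no, (tr, te) in enumerate(rkf.split(Xv)):
            rf = _ranker(self.n_estimators, rank_seed + split_no)
            rf.fit(Xv[tr], y[tr])
            imp = permutation_importance(
                rf, Xv[te], y[te], n_repeats=self.perm_repeats, random_state=perm_seed
            ).importances_mean
            order = np.argsort(-imp, kind="stable")
            for s in sizes:
                sel = order[:s]
                rf_s = _ranker(self.n_estimators, rank_seed + split_no)
                rf_s.fit(Xv[tr][:, sel], y[tr])
                errors[s].append(_rmse(y[te], rf_s.predict(Xv[te][:, sel])))
        self.score_trace_ = {s: float(np.mean(errors[s])) for s in sizes}
        self.best_size_ = min(sizes, key=lambda s: (self.score_trace_[s], s))
        self.best_score_ = self.score_trace_[self.best_size_]
        rf_full = _ranker(self.n_estimators, final_seed)
        rf_full.fit(Xv, y)
        imp_full = permutation_importance(
            rf_full, Xv, y, n_repeats=max(self.perm_repeats, 5), random_state=perm_seed
        ).importances_mean
        order_full = np.argsort(-imp_full, kind="stable")
        self.selected_columns_ = list(cols[order_full[: self.best_size_]])
        self.ranking_ = list(cols[order_full])
        return self

    def get_support(self) -> list[str]:
        return list(self.selected_columns_)


class GASelector(BaseEstimator):
    """Genetic-algorithm subset search over candidate columns.

    Fitted attributes: ``selected_columns_`` (best chromosome ever
    evaluated), ``best_score_`` (its mean CV RMSE) and ``score_trace_``
    (generation -> best fitness in that generation's population; entry 0
    is the random initial population).
    """

    def __init__(
        self,
        max_generations: int = 100,
        population_size: int = 50,
        crossover_prob: float = 0.8,
        mutation_prob: float = 0.1,
        elitism: int = 0,
        cv_folds: int = 5,
        n_estimators: int = 100,
        random_state: Optional[int] = None,
    ):
        self.max_generations = max_generations
        self.population_size = population_size
        self.crossover_prob = crossover_prob
        self.mutation_prob = mutation_prob
        self.elitism = elitism
        self.cv_folds = cv_folds
        self.n_estimators = n_estimators
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y) -> "GASelector":
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        if p == 0:
            raise ValueError("empty candidate set")
        if not (0 <= self.crossover_prob <= 1 and 0 <= self.mutation_prob <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.population_size < 2:
            raise ValueError("population size must be at least 2")
        ss = np.random.SeedSequence(self.random_state)
        ga_seed, cv_seed, rf_seed = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
        rng = np.random.default_rng(ga_seed)
        Xv = np.asarray(X, dtype=float)
        cols = np.array(X.columns)
        folds = list(KFold(self.cv_folds, shuffle=True, random_state=cv_seed).split(Xv))
        cache: dict[bytes, float] = {}

        def fitness(mask: np.ndarray) -> float:
            if not mask.any():
                return np.inf  # empty subset: worst possible fitness
            key = mask.tobytes()
            if key not in cache:
                sub = Xv[:, mask]
                errs = []
                for tr, te in folds:
                    rf = _ranker(self.n_estimators, rf_seed)
                    rf.fit(sub[tr], y[tr])
                    errs.append(_rmse(y[te], rf.predict(sub[te])))
                cache[key] = float(np.mean(errs))
            return cache[key]

        pop = rng.random((self.population_size, p)) < 0.5
        fits = np.array([fitness(ind) for ind in pop])
        best_idx = int(np.argmin(fits))
        best_mask, best_fit = pop[best_idx].copy(), float(fits[best_idx])
        trace = [float(fits.min())]

        def tournament() -> np.ndarray:
            i, j = rng.integers(0, self.population_size, size=2)
            return pop[i] if fits[i] <= fits[j] else pop[j]

        for _gen in range(self.max_generations):
            elite_order = np.argsort(fits, kind="stable")[: self.elitism]
            new_pop = [pop[i].copy() for i in elite_order]
            while len(new_pop) < self.population_size:
                p1, p2 = tournament().copy(), tournament().copy()
                if rng.random() < self.crossover_prob:
                    swap = rng.random(p) < 0.5
                    p1[swap], p2[swap] = p2[swap], p1[swap].copy()
                for child in (p1, p2):
                    flips = rng.random(p) < self.mutation_prob
                    child[flips] = ~child[flips]
                new_pop.append(p1)
                if len(new_pop) < self.population_size:
                    new_pop.append(p2)
            pop = np.array(new_pop)
            fits = np.array([fitness(ind) for ind in pop])
            gen_best = int(np.argmin(fits))
            if fits[gen_best] < best_fit:
                best_mask, best_fit = pop[gen_best].copy(), float(fits[gen_best])
            trace.append(float(fits.min()))

        self.selected_columns_ = list(cols[best_mask])
        self.best_score_ = best_fit
        self.score_trace_ = {g: v for g, v in enumerate(trace)}
        return self

    def get_support(self) -> list[str]:
        return list(self.selected_columns_)


def rfe_select(X: pd.DataFrame, y, cfg: Optional[RFEConfig] = None) -> SelectionResult:
    """RFE over the configured size grid; see :class:`RFESelector`."""
    cfg = cfg or RFEConfig()
    sel = RFESelector(
        subset_sizes=cfg.subset_sizes,
        cv_folds=cfg.cv_folds,
        cv_repeats=cfg.cv_repeats,
        n_estimators=cfg.n_estimators,
        perm_repeats=cfg.perm_repeats,
        random_state=cfg.seed,
    ).fit(X, y)
    return SelectionResult(sel.selected_columns_, sel.score_trace_, sel.best_score_)


def ga_select(X: pd.DataFrame, y, cfg: Optional[GAConfig] = None) -> SelectionResult:
    """GA refinement over candidate columns; see :class:`GASelector`."""
    cfg = cfg or GAConfig()
    sel = GASelector(
        max_generations=cfg.max_generations,
        population_size=cfg.population_size,
        crossover_prob=cfg.crossover_prob,
        mutation_prob=cfg.mutation_prob,
        elitism=cfg.elitism,
        cv_folds=cfg.cv_folds,
        n_estimators=cfg.n_estimators,
        random_state=cfg.seed,
    ).fit(X, y)
    return SelectionResult(sel.selected_columns_, sel.score_trace_, sel.best_score_)
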