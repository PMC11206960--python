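"""End-to-end orchestration: training runs, prediction runs with
applicability-domain screening, and PCA reporting.

A training run executes split -> preprocessing (training rows only) ->
RFE -> GA -> five regressors + stacking ensemble -> train/CV/test metrics
-> leverage applicability domain on the selected, preprocessed training
design. Every stochastic stage draws its seed from the single run seed,
so identical configs give byte-identical metrics tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import joblib
import numpy as np
import pandas as pd
import yaml
from sklearn.decomposition import PCA

from .applicability import LeverageAD
from .druglikeness import classify_permeability, dls_all, ro5_compliant, veber_compliant
from .feature_selection import GAConfig, RFEConfig, SelectionResult, ga_select, rfe_select
from .models import (
    CVConfig,
    ModelSpec,
    PAPER_HYPERPARAMS,
    StackingEnsemble,
    cross_validate,
    cross_validate_ensemble,
    evaluate,
    train_ensemble,
    train_model,
)
from .preprocess import DescriptorPreprocessor, split_dataset
from .synthetic import SyntheticSpec, generate_qspr_dataset
from . import dataio

__all__ = ["RunConfig", "RunBundle", "run_training", "run_prediction", "pca_projection"]

logger = logging.getLogger("cacoperm")

MODEL_LABELS = {"mlr": "MLR", "pls": "PLS", "svm_rbf": "SVM", "rf": "RF", "gbm": "GBM"}
ENSEMBLE_LABEL = "SVM-RF-GBM"
METRIC_COLUMNS = ["RMSE_Train", "R2_Train", "RMSE_CV", "R2_CV", "RMSE_Test", "R2_Test"]


@dataclass
class RunConfig:
    """Configuration of one training run.

    Either ``synthetic`` or both ``compound_table`` and
    ``descriptor_matrix`` must be given. Hyperparameters default to the
    reference settings; ``model_overrides`` maps a model kind to a
    hyperparameter dict.
    """

    seed: int = 0
    synthetic: Optional[SyntheticSpec] = None
    compound_table: Optional[str] = None
    descriptor_matrix: Optional[str] = None
    split_ratio: float = 0.8
    split_bins: int = 5
    corr_threshold: float = 0.70
    rfe: RFEConfig = field(default_factory=RFEConfig)
    ga: GAConfig = field(default_factory=GAConfig)
    cv: CVConfig = field(default_factory=lambda: CVConfig(folds=5, repeats=5))
    model_overrides: dict = field(default_factory=dict)
    fit_ad: bool = True
    outdir: Optional[str] = None

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "synthetic" in d and d["synthetic"] is not None:
            syn = dict(d["synthetic"])
            if "response_range" in syn:
                syn["response_range"] = tuple(syn["response_range"])
            d["synthetic"] = SyntheticSpec(**syn)
        if "rfe" in d and isinstance(d["rfe"], dict):
            rfe = dict(d["rfe"])
            if "subset_sizes" in rfe:
                rfe["subset_sizes"] = tuple(rfe["subset_sizes"])
            d["rfe"] = RFEConfig(**rfe)
        if "ga" in d and isinstance(d["ga"], dict):
            d["ga"] = GAConfig(**d["ga"])
        if "cv" in d and isinstance(d["cv"], dict):
            d["cv"] = CVConfig(**d["cv"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def content_hash(self) -> str:
        def default(o):
            return vars(o) if hasattr(o, "__dict__") else str(o)

        blob = json.dumps(vars(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class RunBundle:
    """All artifacts of a training run."""

    config: RunConfig
    preprocessor: DescriptorPreprocessor
    rfe_result: SelectionResult
    ga_result: SelectionResult
    selected_columns: list[str]
    models: dict
    ensemble: StackingEnsemble
    metrics_table: pd.DataFrame
    ad: Optional[LeverageAD]
    williams: Optional[pd.DataFrame]
    train_ids: list
    test_ids: list
    manifest: dict

    def save(self, outdir) -> None:
        """Serialize: JSON manifest + CSV tables + model blob."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.metrics_table.to_csv(out / "metrics.csv")
        if self.williams is not None:
            self.williams.to_csv(out / "williams.csv", index=False)
        with open(out / "preprocess.json", "w", encoding="utf-8") as fh:
            json.dump(self.preprocessor.to_dict(), fh, indent=1)
        with open(out / "selection.json", "w", encoding="utf-8") as fh:
            json.dump(
                {"rfe": self.rfe_result.to_dict(), "ga": self.ga_result.to_dict(),
                 "selected_columns": self.selected_columns},
                fh, indent=1,
            )
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(self.manifest, fh, indent=1)
        joblib.dump(
            {"models": self.models, "ensemble": self.ensemble, "ad": self.ad,
             "preprocessor": self.preprocessor, "selected_columns": self.selected_columns,
             "train_ids": self.train_ids, "test_ids": self.test_ids},
            out / "models.joblib",
        )

    @classmethod
    def load_models(cls, outdir) -> dict:
        return joblib.load(Path(outdir) / "models.joblib")


def _derive_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _load_inputs(config: RunConfig):
    if config.synthetic is not None:
        matrix, response, _truth = generate_qspr_dataset(config.synthetic)
        return matrix, response
    if not (config.compound_table and config.descriptor_matrix):
        raise ValueError("config needs either a synthetic spec or input file paths")
    records = dataio.read_compound_table(config.compound_table)
    matrix = dataio.read_descriptor_matrix(config.descriptor_matrix)
    response = pd.Series(
        {r.id: r.log_papp for r in records if r.log_papp is not None}, name="log_papp"
    )
    if response.empty:
        raise ValueError("input table carries no measured log Papp responses")
    common = [i for i in matrix.index if i in response.index]
    return matrix.loc[common], response.loc[common]


def _model_specs(config: RunConfig, n_features: int, seeds: list[int]) -> dict[str, ModelSpec]:
    specs = {}
    for kind, seed in zip(MODEL_LABELS, seeds):
        hp = dict(PAPER_HYPERPARAMS[kind])
        if kind == "rf":
            hp["mtry"] = min(hp["mtry"], n_features)
        if kind == "pls":
            hp["ncomp"] = min(hp["ncomp"], n_features)
        hp.update(config.model_overrides.get(kind, {}))
        specs[kind] = ModelSpec(kind=kind, hyperparams=hp, seed=seed)
    return specs


def _metric_row(train_m, cv_m, test_m) -> list:
    def r2(m):
        return np.nan if m.r2 is None else m.r2

    return [train_m.rmse, r2(train_m), cv_m.rmse, r2(cv_m), test_m.rmse, r2(test_m)]


def run_training(config: RunConfig) -> RunBundle:
    """Execute a full training run; see the module docstring for stages."""
    t0 = time.perf_counter()
    (split_seed, rfe_seed, ga_seed, cv_seed, ens_seed, *model_seeds) = _derive_seeds(config.seed, 10)

    matrix, response = _load_inputs(config)
    logger.info("inputs: %d compounds x %d descriptors", *matrix.shape)

    def stage(name):
        logger.info("stage %s done at %.1fs (seed %d)", name, time.perf_counter() - t0, config.seed)

    split = split_dataset(
        list(matrix.index), response.to_numpy(), ratio=config.split_ratio,
        n_bins=config.split_bins, seed=split_seed,
    )
    X_train_raw, X_test_raw = matrix.loc[split.train_ids], matrix.loc[split.test_ids]
    y_train = response.loc[split.train_ids].to_numpy()
    y_test = response.loc[split.test_ids].to_numpy()
    stage("split")

    prep = DescriptorPreprocessor(corr_threshold=config.corr_threshold).fit(X_train_raw)
    X_train = prep.transform(X_train_raw)
    X_test = prep.transform(X_test_raw)
    stage("preprocess")

    rfe_cfg = RFEConfig(**{**vars(config.rfe), "seed": config.rfe.seed if config.rfe.seed is not None else rfe_seed})
    rfe_cfg.subset_sizes = [s for s in rfe_cfg.subset_sizes if s <= X_train.shape[1]]
    rfe_result = rfe_select(X_train, y_train, rfe_cfg)
    stage("rfe")

    ga_cfg = GAConfig(**{**vars(config.ga), "seed": config.ga.seed if config.ga.seed is not None else ga_seed})
    ga_result = ga_select(X_train[rfe_result.selected_columns], y_train, ga_cfg)
    selected = list(ga_result.selected_columns)
    stage("ga")

    Xs_train, Xs_test = X_train[selected], X_test[selected]
    specs = _model_specs(config, len(selected), model_seeds)
    cv = CVConfig(folds=config.cv.folds, repeats=config.cv.repeats,
                  seed=config.cv.seed if config.cv.seed is not None else cv_seed)

    models, rows, index = {}, [], []
    for kind, spec in specs.items():
        m = train_model(spec, Xs_train, y_train)
        models[kind] = m
        rows.append(_metric_row(
            evaluate(y_train, m.predict(Xs_train)),
            cross_validate(spec, Xs_train, y_train, cv),
            evaluate(y_test, m.predict(Xs_test)),
        ))
        index.append(MODEL_LABELS[kind])
    stage("base models")

    base_specs = [specs[k] for k in ("svm_rbf", "rf", "gbm")]
    inner_cv = CVConfig(folds=cv.folds, repeats=1, seed=ens_seed)
    ensemble = train_ensemble(Xs_train, y_train, base_specs=base_specs, cv=inner_cv)
    rows.append(_metric_row(
        evaluate(y_train, ensemble.predict(Xs_train)),
        cross_validate_ensemble(Xs_train, y_train, base_specs, cv, inner_cv),
        evaluate(y_test, ensemble.predict(Xs_test)),
    ))
    index.append(ENSEMBLE_LABEL)
    stage("ensemble")

    metrics_table = pd.DataFrame(rows, index=pd.Index(index, name="Model"), columns=METRIC_COLUMNS)

    ad = williams = None
    if config.fit_ad:
        residuals = y_train - ensemble.predict(Xs_train)
        ad = LeverageAD().fit(Xs_train, residuals)
        williams = pd.concat(
            [
                ad.williams_data(Xs_train, y_train, ensemble.predict(Xs_train), "train"),
                ad.williams_data(Xs_test, y_test, ensemble.predict(Xs_test), "test"),
            ],
            ignore_index=True,
        )
        stage("applicability domain")

    manifest = {
        "package_version": "0.1.0",
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "n_train": len(split.train_ids),
        "n_test": len(split.test_ids),
        "n_selected": len(selected),
        "h_star": None if ad is None else ad.h_star_,
        "runtime_s": round(time.perf_counter() - t0, 2),
    }
    bundle = RunBundle(
        config=config, preprocessor=prep, rfe_result=rfe_result, ga_result=ga_result,
        selected_columns=selected, models=models, ensemble=ensemble,
        metrics_table=metrics_table, ad=ad, williams=williams,
        train_ids=split.train_ids, test_ids=split.test_ids, manifest=manifest,
    )
    if config.outdir:
        bundle.save(config.outdir)
    return bundle


def run_prediction(
    bundle: RunBundle,
    new_compounds: pd.DataFrame,
    properties: Optional[pd.DataFrame] = None,
) -> tuple[pd.DataFrame, dict]:
    """Predict log Papp for new compounds with AD screening.

    Returns a per-compound report (prediction, leverage, AD flag,
    permeability class withheld for outside-AD compounds, plus
    Ro5/Veber/DLS columns when a property table is supplied) and a summary
    of counts by class and AD status.
    """
    X = bundle.preprocessor.transform(new_compounds)[bundle.selected_columns]
    pred = bundle.ensemble.predict(X)
    if bundle.ad is None:
        raise ValueError("bundle has no fitted applicability domain")
    lev = bundle.ad.leverage(X)
    inside = lev <= bundle.ad.h_star_
    classes = [classify_permeability(p) if ok else None for p, ok in zip(pred, inside)]
    report = pd.DataFrame(
        {
            "id": list(new_compounds.index),
            "predicted_log_papp": pred,
            "leverage": lev,
            "inside_ad": inside,
            "permeability_class": classes,
        }
    ).set_index("id")
    if properties is not None:
        from .druglikeness import PropertyProfile

        prof_cols = [f.name for f in PropertyProfile.__dataclass_fields__.values() if f.name != "id"]
        for cid in report.index:
            if cid not in properties.index:
                continue
            row = properties.loc[cid]
            prof = PropertyProfile(id=str(cid), **{c: row[c] for c in prof_cols if c in row.index})
            ro5_ok, _ = ro5_compliant(prof)
            veber_ok, _ = veber_compliant(prof)
            dls = dls_all(prof)
            report.loc[cid, "ro5_compliant"] = ro5_ok
            report.loc[cid, "veber_compliant"] = veber_ok
            for name, score in dls.scores.items():
                report.loc[cid, name] = score
            report.loc[cid, "DLS_cons"] = dls.consensus
    summary = {
        "n_total": int(len(report)),
        "n_inside_ad": int(inside.sum()),
        "n_outside_ad": int((~inside).sum()),
        "class_counts": {
            label: int(sum(c == label for c in classes)) for label in ("high", "medium", "low")
        },
        "h_star": bundle.ad.h_star_,
    }
    return report, summary


def pca_projection(X: pd.DataFrame, k: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Scores of centered data on the top-k principal components.

    Component signs follow the convention that each component's
    largest-magnitude loading is positive, so results are reproducible
    without a seed.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
    if X.isna().any().any():
        raise ValueError("PCA requires a complete matrix")
    n, p = X.shape
    if k > min(n - 1, p):
        raise ValueError(f"k = {k} exceeds min(rows-1, cols) = {min(n - 1, p)}")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(np.asarray(X, dtype=float))
    for j in range(k):
        lead = np.argmax(np.abs(pca.components_[j]))
        if pca.components_[j, lead] < 0:
            scores[:, j] *= -1
    frame = pd.DataFrame(scores, index=X.index, columns=[f"PC{j + 1}" for j in range(k)])
    return frame, pca.explained_variance_ratio_.copy()
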