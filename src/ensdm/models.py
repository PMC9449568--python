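"""The five base learners and the resampling harness that trains them.

All algorithms sit behind one contract — fit on a :class:`FeatureTable`,
emit per-row presence probabilities — so the ensemble layer never needs to
know which backend produced a score. The five members are the classic
presence/absence SDM set: multivariate adaptive regression splines (MARS),
boosted regression trees (BRT), a multilayer perceptron (MLP), random
forest (RF) and a support vector machine (SVM).

Hyperparameters are fixed, sensible defaults (500 trees for the forests and
boosters, RBF kernel with the scale heuristic for the SVM, one hidden layer
sized to the feature count for the MLP), all overridable per
:class:`AlgorithmSpec` and recorded on the fitted model. Reproducibility
beats tuning here: every fit is deterministic given its configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from ._mars import MARSClassifier
from .predictors import FeatureTable

__all__ = [
    "ALGORITHM_IDS",
    "AlgorithmSpec",
    "FittedModel",
    "CVRecord",
    "fit_model",
    "predict_proba",
    "cross_validate",
    "default_specs",
]

ALGORITHM_IDS = ("MARS", "BRT", "MLP", "RF", "SVM")


@dataclass(frozen=True)
class AlgorithmSpec:
    """Identifier + hyperparameters + seed for one base learner."""

    algorithm_id: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm_id not in ALGORITHM_IDS:
            raise ValueError(
                f"unknown algorithm {self.algorithm_id!r}; expected one of {ALGORITHM_IDS}"
            )


def default_specs(seed: int = 0) -> list[AlgorithmSpec]:
    """One spec per supported algorithm, seeded from a master seed."""
    return [AlgorithmSpec(aid, seed=seed + i) for i, aid in enumerate(ALGORITHM_IDS)]


@dataclass
class FittedModel:
    """A trained probabilistic classifier bound to its feature schema."""

    spec: AlgorithmSpec
    feature_names: list[str]
    fitted_state: object
    training_rows: int

    def predict_proba(self, rows: pd.DataFrame | FeatureTable) -> np.ndarray:
        return predict_proba(self, rows)


def _build_estimator(spec: AlgorithmSpec, n_features: int):
    hp = dict(spec.hyperparameters)
    seed = spec.seed
    if spec.algorithm_id == "RF":
        params = {"n_estimators": 500, "random_state": seed, "n_jobs": 1}
        params.update(hp)
        return RandomForestClassifier(**params)
    if spec.algorithm_id == "BRT":
        params = {"n_estimators": 500, "learning_rate": 0.05, "max_depth": 3,
                  "random_state": seed}
        params.update(hp)
        return GradientBoostingClassifier(**params)
    if spec.algorithm_id == "SVM":
        params = {"kernel": "rbf", "gamma": "scale", "C": 1.0,
                  "probability": True, "random_state": seed}
        params.update(hp)
        return Pipeline([("scale", StandardScaler()), ("svm", SVC(**params))])
    if spec.algorithm_id == "MLP":
        params = {"hidden_layer_sizes": (max(n_features, 2),),
                  "max_iter": 1000, "random_state": seed}
        params.update(hp)
        return Pipeline([("scale", StandardScaler()), ("mlp", MLPClassifier(**params))])
    if spec.algorithm_id == "MARS":
        return MARSClassifier(**hp)
    raise ValueError(spec.algorithm_id)  # unreachable: spec validates


def fit_model(spec: AlgorithmSpec, table: FeatureTable) -> FittedModel:
    """Train one base learner on a feature table with both classes present."""
    classes = np.unique(table.labels)
    if len(classes) < 2:
        raise ValueError(
            f"training table has a single class ({classes.tolist()}); need both"
        )
    est = _build_estimator(spec, n_features=len(table.names))
    est.fit(table.features.to_numpy(dtype=float), table.labels)
    return FittedModel(
        spec=spec,
        feature_names=table.names,
        fitted_state=est,
        training_rows=len(table),
    )


def predict_proba(model: FittedModel, rows: pd.DataFrame | FeatureTable) -> np.ndarray:
    """Presence probability per row; the column schema must match exactly.

    Columns are matched by name *and* order — no silent reordering.
    """
    if isinstance(rows, FeatureTable):
        rows = rows.features
    if isinstance(rows, pd.DataFrame):
        if list(rows.columns) != model.feature_names:
            raise ValueError(
                f"feature columns {list(rows.columns)} do not match the model "
                f"schema {model.feature_names}"
            )
        X = rows.to_numpy(dtype=float)
    else:
        X = np.asarray(rows, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(model.feature_names):
            raise ValueError(
                f"expected {len(model.feature_names)} feature columns, got {X.shape}"
            )
    proba = model.fitted_state.predict_proba(X)
    classes = list(model.fitted_state.classes_) if hasattr(model.fitted_state, "classes_") \
        else list(model.fitted_state[-1].classes_)
    p1 = proba[:, classes.index(1)]
    return np.clip(p1, 0.0, 1.0)


@dataclass
class CVRecord:
    """Held-out scores for one algorithm in one fold of one run."""

    algorithm_id: str
    run: int
    fold: int
    test_index: np.ndarray
    scores: np.ndarray
    labels: np.ndarray


def _derive_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s % (2**31 - 1)) for s in ss.generate_state(n)]


def cross_validate(
    table: FeatureTable,
    specs: Sequence[AlgorithmSpec],
    k: int = 4,
    runs: int = 10,
    seed: int = 0,
    scheme: str = "kfold",
    test_fraction: float = 0.3,
) -> list[CVRecord]:
    """Repeated stratified resampling of every algorithm.

    ``scheme="kfold"`` (default): for each of ``runs`` repetitions a fresh
    seeded stratified k-fold partition is drawn and every row is scored
    exactly once per run by a model not trained on it.
    ``scheme="split"``: each run is a single stratified train/test split
    (default 70/30), reported as fold 0.
    """
    if scheme not in ("kfold", "split"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if scheme == "kfold" and k < 2:
        raise ValueError("k must be >= 2")
    y = table.labels
    counts = np.bincount(y, minlength=2)
    if counts.min() < (k if scheme == "kfold" else 2):
        raise ValueError(
            f"class counts {counts.tolist()} too small to stratify into {k} folds"
        )
    X = table.features
    run_seeds = _derive_seeds(seed, runs)
    records: list[CVRecord] = []
    for run, run_seed in enumerate(run_seeds):
        if scheme == "kfold":
            splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=run_seed)
            splits = list(splitter.split(X, y))
        else:
            tr, te = train_test_split(
                np.arange(len(y)), test_size=test_fraction,
                stratify=y, random_state=run_seed,
            )
            splits = [(tr, te)]
        for fold, (train_idx, test_idx) in enumerate(splits):
            assert len(np.intersect1d(train_idx, test_idx)) == 0  # no leakage
            train = FeatureTable(X.iloc[train_idx], y[train_idx])
            test_rows = X.iloc[test_idx]
            for spec in specs:
                model = fit_model(spec, train)
                scores = predict_proba(model, test_rows)
                records.append(
                    CVRecord(
                        algorithm_id=spec.algorithm_id,
                        run=run,
                        fold=fold,
                        test_index=np.asarray(test_idx),
                        scores=scores,
                        labels=y[test_idx],
                    )
                )
    return records
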