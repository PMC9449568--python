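"""Skill-weighted model averaging, raster prediction and variable importance.

The ensemble is a convex combination of the member probabilities: member i
gets weight proportional to max(metric_i − floor, 0), where the floor strips
no-skill models (0.5 for AUC, 0 for TSS), and the weights are normalised to
sum to one. If every member is at or below the floor the ensemble falls back
to uniform weights with a warning.

Variable importance follows the permutation-correlation recipe: a
predictor's contribution is 100 × (1 − Pearson r) between ensemble
predictions on the intact table and on a copy with that column shuffled,
averaged over repeats. Contributions are independent per variable and do
not sum to 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import EvaluationResult
from .geodata_io import PredictorStack, RasterGrid
from .models import FittedModel, predict_proba
from .predictors import FeatureTable

__all__ = [
    "EnsembleModel",
    "ImportanceTable",
    "build_ensemble",
    "ensemble_predict_points",
    "ensemble_predict_raster",
    "ensemble_holdout_scores",
    "variable_importance",
]

_METRIC_FLOORS = {"AUC": 0.5, "TSS": 0.0}


@dataclass
class EnsembleModel:
    """Fitted members with their evaluations and normalised weights."""

    members: list[FittedModel]
    evaluations: list[EvaluationResult]
    weights: np.ndarray
    weighting_metric: str

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.members) != len(self.weights):
            raise ValueError("one weight per member required")
        if (self.weights < 0).any():
            raise ValueError("weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")

    @property
    def feature_names(self) -> list[str]:
        return self.members[0].feature_names


@dataclass
class ImportanceTable:
    """Per-variable percentage contributions (not constrained to sum to 100)."""

    contributions: pd.Series  # index = variable name, values = percent
    method_tag: str = "permutation (1 - Pearson r), x100"

    def ranked(self) -> pd.Series:
        return self.contributions.sort_values(ascending=False)

    def to_frame(self) -> pd.DataFrame:
        df = self.ranked().to_frame("contribution_pct")
        df["method"] = self.method_tag
        return df


def build_ensemble(
    members: list[FittedModel],
    evaluations: list[EvaluationResult],
    metric: str = "AUC",
) -> EnsembleModel:
    """Weight members by skill above the no-skill floor.

    ``metric`` is "AUC" (floor 0.5), "TSS" (floor 0) or "uniform".
    """
    if len(members) != len(evaluations):
        raise ValueError(
            f"{len(members)} members but {len(evaluations)} evaluations"
        )
    if not members:
        raise ValueError("ensemble needs at least one member")
    by_algo = {e.algorithm_id: e for e in evaluations}
    ordered = []
    for m in members:
        if m.spec.algorithm_id not in by_algo:
            raise ValueError(f"no evaluation for member {m.spec.algorithm_id!r}")
        ordered.append(by_algo[m.spec.algorithm_id])
    schemas = {tuple(m.feature_names) for m in members}
    if len(schemas) > 1:
        raise ValueError("members disagree on feature schema")
    if metric == "uniform":
        raw = np.ones(len(members))
    elif metric in _METRIC_FLOORS:
        floor = _METRIC_FLOORS[metric]
        vals = np.array(
            [e.auc if metric == "AUC" else e.tss for e in ordered], dtype=float
        )
        raw = np.maximum(vals - floor, 0.0)
    else:
        raise ValueError(f"unknown weighting metric {metric!r}")
    if raw.sum() == 0:
        warnings.warn(
            "all members at or below the no-skill floor; falling back to uniform weights",
            stacklevel=2,
        )
        raw = np.ones(len(members))
    return EnsembleModel(
        members=list(members),
        evaluations=ordered,
        weights=raw / raw.sum(),
        weighting_metric=metric,
    )


def ensemble_predict_points(
    model: EnsembleModel, rows: pd.DataFrame | FeatureTable
) -> np.ndarray:
    """Weighted-average presence probability per row."""
    if isinstance(rows, FeatureTable):
        rows = rows.features
    out = np.zeros(len(rows), dtype=float)
    for w, member in zip(model.weights, model.members):
        out += w * predict_proba(member, rows)
    return out


def ensemble_predict_raster(
    model: EnsembleModel, stack: PredictorStack, block_rows: int = 256
) -> RasterGrid:
    """Score every valid cell of a co-registered stack.

    The stack may carry extra layers; only the model's features are read.
    Output mask is the union of the input layer masks; prediction is
    block-wise over raster rows to bound memory (block size does not change
    the result).
    """
    names = model.feature_names
    missing = [n for n in names if n not in stack.layers]
    if missing:
        raise ValueError(f"stack is missing model features: {', '.join(missing)}")
    sub = stack.subset(names)
    mask = sub.combined_mask()
    nrows, ncols = sub.shape
    out = np.full((nrows, ncols), np.nan)
    arr = sub.as_array(names)  # (layer, row, col)
    for r0 in range(0, nrows, block_rows):
        r1 = min(r0 + block_rows, nrows)
        block_mask = mask[r0:r1]
        if block_mask.all():
            continue
        rr, cc = np.nonzero(~block_mask)
        X = pd.DataFrame(
            {n: arr[i, r0:r1][rr, cc] for i, n in enumerate(names)}
        )
        out[r0 + rr, cc] = ensemble_predict_points(model, X)
    return RasterGrid(out, sub.transform, sub.crs_tag, mask)


def ensemble_holdout_scores(
    records, weights_by_algorithm: dict[str, float]
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Weighted-average held-out scores per cross-validation replicate.

    All algorithms in one (run, fold) replicate score the same test rows, so
    their probability vectors combine exactly like the fitted ensemble's.
    Returns one (scores, labels) pair per replicate.
    """
    by_rep: dict[tuple[int, int], list] = {}
    for rec in records:
        by_rep.setdefault((rec.run, rec.fold), []).append(rec)
    out = []
    for key in sorted(by_rep):
        recs = by_rep[key]
        ref = recs[0]
        total_w = 0.0
        scores = np.zeros_like(ref.scores)
        for rec in recs:
            if not np.array_equal(rec.test_index, ref.test_index):
                raise ValueError(f"replicate {key}: algorithms saw different folds")
            w = weights_by_algorithm.get(rec.algorithm_id, 0.0)
            scores += w * rec.scores
            total_w += w
        if total_w == 0:
            raise ValueError("all algorithms have zero weight")
        out.append((scores / total_w, ref.labels))
    return out


def variable_importance(
    model: EnsembleModel,
    table: FeatureTable | pd.DataFrame,
    repeats: int = 5,
    seed: int = 0,
) -> ImportanceTable:
    """Permutation importance of each predictor on the ensemble output.

    importance_j = mean over repeats of 100 x (1 - r(p_intact, p_permuted_j)),
    floored at zero. An unused predictor leaves predictions unchanged
    (r = 1, importance 0). Degenerate constant predictions score 0 with a
    warning.
    """
    X = table.features if isinstance(table, FeatureTable) else table
    if len(X) < 3:
        raise ValueError("need at least 3 rows for permutation importance")
    rng = np.random.default_rng(seed)
    base = ensemble_predict_points(model, X)
    base_sd = base.std()
    contributions = {}
    for name in X.columns:
        vals = []
        for _ in range(repeats):
            perm = X.copy()
            perm[name] = rng.permutation(perm[name].to_numpy())
            p = ensemble_predict_points(model, perm)
            if base_sd == 0 or p.std() == 0:
                warnings.warn(
                    "zero-variance predictions; correlation undefined, importance 0",
                    stacklevel=2,
                )
                vals.append(0.0)
                continue
            r = np.corrcoef(base, p)[0, 1]
            vals.append(max(1.0 - r, 0.0) * 100.0)
        contributions[name] = float(np.mean(vals))
    return ImportanceTable(pd.Series(contributions))
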