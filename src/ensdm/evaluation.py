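"""Model skill statistics: AUC, the true skill statistic, and their tables.

AUC is computed by the exact rank (Mann–Whitney) formulation with ties
counted one half — identical to the trapezoidal area under the empirical ROC
curve. TSS(t) = sensitivity(t) + specificity(t) − 1 is maximised over every
observed score plus {0, 1}, predicting presence when score ≥ t; the smallest
maximising threshold is reported. Both are implemented here directly (they
are the quantities under test), with brute-force oracles in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .models import CVRecord

__all__ = [
    "AUC_BANDS",
    "TSS_BANDS",
    "EvaluationResult",
    "auc",
    "tss",
    "evaluate_records",
    "performance_table",
    "classify_performance",
]

#: Grade bands, half-open [lower, upper), top band closed at the metric max.
AUC_BANDS = {
    "fail": (0.0, 0.6),
    "poor": (0.6, 0.7),
    "fair": (0.7, 0.8),
    "good": (0.8, 0.9),
    "excellent": (0.9, 1.0),
}
TSS_BANDS = {
    "fail": (-1.0, 0.2),
    "poor": (0.2, 0.4),
    "fair": (0.4, 0.6),
    "good": (0.6, 0.8),
    "excellent": (0.8, 1.0),
}


@dataclass
class EvaluationResult:
    """Aggregated skill of one algorithm over evaluation replicates."""

    algorithm_id: str
    auc: float
    tss: float
    tss_threshold: float
    n_replicates: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError(f"AUC out of [0, 1]: {self.auc}")
        if not (-1.0 <= self.tss <= 1.0):
            raise ValueError(f"TSS out of [-1, 1]: {self.tss}")


def _check_two_classes(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    pos = labels == 1
    neg = labels == 0
    if not pos.any() or not neg.any():
        raise ValueError("both classes must be present to evaluate")
    return pos, neg


def auc(scores: Iterable[float], labels: Iterable[int]) -> float:
    """Probability that a random presence outscores a random absence.

    Rank-based Mann–Whitney formulation; tied scores count one half.
    """
    scores = np.asarray(list(scores) if not isinstance(scores, np.ndarray) else scores, dtype=float)
    labels = np.asarray(list(labels) if not isinstance(labels, np.ndarray) else labels)
    pos, neg = _check_two_classes(labels)
    n1, n0 = int(pos.sum()), int(neg.sum())
    ranks = rankdata(scores)  # average rank on ties = half-credit per tied pair
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def tss(scores: Iterable[float], labels: Iterable[int]) -> tuple[float, float]:
    """Maximum true skill statistic and the smallest achieving threshold.

    Predictions are positive iff score >= t; t ranges over the observed
    scores plus {0, 1}.
    """
    scores = np.asarray(list(scores) if not isinstance(scores, np.ndarray) else scores, dtype=float)
    labels = np.asarray(list(labels) if not isinstance(labels, np.ndarray) else labels)
    pos, neg = _check_two_classes(labels)
    n1, n0 = int(pos.sum()), int(neg.sum())
    thresholds = np.unique(np.concatenate([scores, [0.0, 1.0]]))
    pred = scores[None, :] >= thresholds[:, None]  # (t, row)
    sens = (pred & pos[None, :]).sum(axis=1) / n1
    spec = (~pred & neg[None, :]).sum(axis=1) / n0
    values = sens + spec - 1.0
    best = values.max()
    t_best = thresholds[values == best].min()
    return float(best), float(t_best)


def evaluate_records(records: Iterable[CVRecord]) -> list[EvaluationResult]:
    """Mean AUC/TSS per algorithm over all (run, fold) replicates."""
    by_algo: dict[str, list[CVRecord]] = {}
    for rec in records:
        by_algo.setdefault(rec.algorithm_id, []).append(rec)
    results = []
    for algo, recs in by_algo.items():
        aucs, tsss, thrs = [], [], []
        for rec in recs:
            aucs.append(auc(rec.scores, rec.labels))
            t_val, t_thr = tss(rec.scores, rec.labels)
            tsss.append(t_val)
            thrs.append(t_thr)
        results.append(
            EvaluationResult(
                algorithm_id=algo,
                auc=float(np.mean(aucs)),
                tss=float(np.mean(tsss)),
                tss_threshold=float(np.mean(thrs)),
                n_replicates=len(recs),
            )
        )
    return results


def performance_table(
    results: Iterable[EvaluationResult] | Mapping[str, tuple[float, float]],
    decimals: int = 2,
) -> pd.DataFrame:
    """Per-algorithm mean AUC/TSS plus an unweighted grand-mean row.

    Accepts either :class:`EvaluationResult` objects or a mapping
    ``{algorithm: (auc, tss)}``. Values are rendered to ``decimals`` places;
    the grand mean is the unweighted mean over algorithms, as printed.
    """
    if isinstance(results, Mapping):
        rows = {a: {"AUC": v[0], "TSS": v[1], "n_replicates": 1}
                for a, v in results.items()}
    else:
        rows = {
            r.algorithm_id: {"AUC": r.auc, "TSS": r.tss, "n_replicates": r.n_replicates}
            for r in results
        }
    if not rows:
        raise ValueError("no evaluation results to tabulate")
    df = pd.DataFrame.from_dict(rows, orient="index")
    mean_row = pd.DataFrame(
        {"AUC": [df["AUC"].mean()], "TSS": [df["TSS"].mean()],
         "n_replicates": [df["n_replicates"].sum()]},
        index=["Mean value"],
    )
    out = pd.concat([df, mean_row])
    out["AUC"] = out["AUC"].round(decimals)
    out["TSS"] = out["TSS"].round(decimals)
    out["n_replicates"] = out["n_replicates"].astype(int)
    return out


def _band_of(value: float, bands: Mapping[str, tuple[float, float]]) -> str:
    labels = list(bands)
    lo_all = bands[labels[0]][0]
    hi_all = bands[labels[-1]][1]
    if not (lo_all <= value <= hi_all):
        raise ValueError(f"metric value {value} outside [{lo_all}, {hi_all}]")
    for label, (lo, hi) in bands.items():
        if lo <= value < hi:
            return label
    return labels[-1]  # top band closed at the maximum


def classify_performance(
    auc_value: float,
    tss_value: float,
    auc_bands: Mapping[str, tuple[float, float]] = AUC_BANDS,
    tss_bands: Mapping[str, tuple[float, float]] = TSS_BANDS,
) -> dict[str, str]:
    """Grade both metrics on half-open bands (top band closed)."""
    return {
        "auc": _band_of(auc_value, auc_bands),
        "tss": _band_of(tss_value, tss_bands),
    }
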