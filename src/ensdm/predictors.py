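"""Point extraction and the two-stage collinearity screen.

Collinear predictors destabilise distribution models, so before fitting the
predictor set goes through (1) a greedy pairwise Pearson screen that removes
one member of every pair with |r| above a threshold (default 0.7), and (2) a
stepwise variance-inflation-factor (VIF) pass that iteratively removes the
predictor with the largest VIF until all remaining VIFs fall below a
threshold (default 10). Both stages are deterministic given column order and
record every removal for auditing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geodata_io import OccurrenceSet, PredictorStack

__all__ = [
    "FeatureTable",
    "ScreenReport",
    "extract_features",
    "pearson_screen",
    "vif",
    "vifstep",
    "screen_predictors",
]

logger = logging.getLogger(__name__)

#: VIF reported for a perfectly collinear column instead of infinity.
VIF_CAP = 1.0 / np.finfo(float).eps


@dataclass
class FeatureTable:
    """Per-occurrence predictor values with a 0/1 label per row."""

    features: pd.DataFrame
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.features = self.features.reset_index(drop=True)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels must have equal length")
        if self.features.isna().any().any():
            raise ValueError("feature table contains missing values")
        if len(self.labels) and not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0 or 1")

    @property
    def names(self) -> list[str]:
        return list(self.features.columns)

    def __len__(self) -> int:
        return len(self.features)

    def subset(self, names: list[str]) -> "FeatureTable":
        return FeatureTable(self.features[names], self.labels)


@dataclass
class ScreenReport:
    """Audit trail of the collinearity screen."""

    retained: list[str]
    dropped_by_correlation: list[tuple[str, str, float]] = field(default_factory=list)
    dropped_by_vif: list[tuple[str, float]] = field(default_factory=list)
    r_threshold: float = 0.7
    vif_threshold: float = 10.0

    @property
    def dropped(self) -> list[str]:
        return [n for n, _, _ in self.dropped_by_correlation] + [
            n for n, _ in self.dropped_by_vif
        ]

    def to_dict(self) -> dict:
        return {
            "retained": self.retained,
            "dropped_by_correlation": [
                {"name": n, "partner": p, "r": r}
                for n, p, r in self.dropped_by_correlation
            ],
            "dropped_by_vif": [
                {"name": n, "vif_at_removal": v} for n, v in self.dropped_by_vif
            ],
            "r_threshold": self.r_threshold,
            "vif_threshold": self.vif_threshold,
        }


def extract_features(stack: PredictorStack, points: OccurrenceSet) -> FeatureTable:
    """Read each layer at each point's containing cell.

    Row order preserves point order. A point outside the extent or on a
    nodata cell is an error naming the point index (clean upstream first).
    """
    mask = stack.combined_mask()
    transform = stack.transform
    shape = stack.shape
    rows = np.empty(len(points), dtype=int)
    cols = np.empty(len(points), dtype=int)
    for i, (lon, lat) in enumerate(zip(points.lon, points.lat)):
        try:
            r, c = transform.cell_of(lon, lat, shape)
        except ValueError as exc:
            raise ValueError(f"point {i}: {exc}") from None
        if mask[r, c]:
            raise ValueError(f"point {i} (lon={lon}, lat={lat}) falls on a nodata cell")
        rows[i], cols[i] = r, c
    data = {name: stack[name].values[rows, cols] for name in stack.names}
    return FeatureTable(pd.DataFrame(data), points.labels)


def _correlation_matrix(X: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson r; zero-variance columns get r = 0 against others."""
    sd = X.std(ddof=0)
    degenerate = sd[sd == 0].index.tolist()
    if degenerate:
        logger.warning(
            "zero-variance columns treated as uncorrelated: %s", ", ".join(degenerate)
        )
    corr = X.corr().fillna(0.0)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def pearson_screen(
    table: FeatureTable | pd.DataFrame, threshold: float = 0.7
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Greedy pairwise correlation elimination.

    While any pair exceeds |r| > threshold, drop the member of the
    worst-offending pair with the larger mean |r| against all remaining
    variables (ties go to the later column). Returns (retained, dropped)
    where dropped entries are (name, partner, r at removal).
    """
    X = table.features if isinstance(table, FeatureTable) else table
    if X.shape[1] == 0:
        return [], []
    if len(X) < 3:
        raise ValueError("need at least 3 rows to estimate correlations")
    remaining = list(X.columns)
    dropped: list[tuple[str, str, float]] = []
    while len(remaining) > 1:
        corr = _correlation_matrix(X[remaining]).abs()
        tri = corr.where(np.triu(np.ones(corr.shape, dtype=bool), k=1))
        worst = tri.stack().idxmax()
        r_worst = float(tri.stack().max())
        if r_worst <= threshold:
            break
        a, b = worst
        mean_abs = (corr.sum(axis=0) - 1.0) / (len(remaining) - 1)
        # drop the member more correlated with everything else; ties -> later column
        if mean_abs[a] > mean_abs[b]:
            victim, partner = a, b
        elif mean_abs[b] > mean_abs[a]:
            victim, partner = b, a
        else:
            victim, partner = (b, a) if remaining.index(b) > remaining.index(a) else (a, b)
        dropped.append((victim, partner, r_worst))
        remaining.remove(victim)
    return remaining, dropped


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per column: 1 / (1 - R^2_j).

    R^2_j comes from an ordinary least-squares regression of column j on all
    other columns plus an intercept. Perfect collinearity is reported as the
    finite cap ``VIF_CAP`` rather than infinity.
    """
    names = list(X.columns)
    if len(names) < 2:
        return pd.Series(1.0, index=names, dtype=float)
    A = X.to_numpy(dtype=float)
    n = A.shape[0]
    if n < len(names) + 1:
        raise ValueError(
            f"need at least {len(names) + 1} rows for {len(names)} columns"
        )
    out = {}
    for j, name in enumerate(names):
        y = A[:, j]
        others = np.delete(A, j, axis=1)
        design = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        sst = np.sum((y - y.mean()) ** 2)
        if sst == 0:
            out[name] = 1.0  # constant column explains nothing, is explained by nothing
            continue
        r2 = 1.0 - np.sum(resid**2) / sst
        if r2 >= 1.0 - 1.0 / VIF_CAP:
            logger.warning("column %r is perfectly collinear; VIF capped", name)
            out[name] = VIF_CAP
        else:
            out[name] = max(1.0 / (1.0 - r2), 1.0)
    return pd.Series(out, dtype=float)


def vifstep(
    table: FeatureTable | pd.DataFrame, vif_threshold: float = 10.0
) -> ScreenReport:
    """Stepwise VIF elimination.

    Iteratively removes the column with the largest VIF while that VIF
    exceeds the threshold (ties go to the later column); every removal is
    recorded with the VIF at removal time.
    """
    X = table.features if isinstance(table, FeatureTable) else table
    remaining = list(X.columns)
    dropped: list[tuple[str, float]] = []
    while len(remaining) >= 2:
        v = vif(X[remaining])
        vmax = v.max()
        if vmax <= vif_threshold:
            break
        # ties -> later column order
        worst_candidates = [n for n in remaining if v[n] == vmax]
        victim = worst_candidates[-1]
        dropped.append((victim, float(vmax)))
        remaining.remove(victim)
    return ScreenReport(
        retained=remaining, dropped_by_vif=dropped, vif_threshold=vif_threshold
    )


def screen_predictors(
    table: FeatureTable,
    r_threshold: float = 0.7,
    vif_threshold: float = 10.0,
) -> ScreenReport:
    """Full two-stage screen: Pearson pairwise first, then stepwise VIF."""
    retained, dropped_r = pearson_screen(table, threshold=r_threshold)
    report = vifstep(table.subset(retained), vif_threshold=vif_threshold)
    report.dropped_by_correlation = dropped_r
    report.r_threshold = r_threshold
    logger.info(
        "screen_predictors: %d -> %d variables (%d by |r|>%g, %d by VIF>%g)",
        len(table.names), len(report.retained),
        len(dropped_r), r_threshold, len(report.dropped_by_vif), vif_threshold,
    )
    return report
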