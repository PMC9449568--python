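"""Suitability classification, area accounting and range-change analysis.

Continuous habitat suitability in [0, 1] is discretised into four classes —
not suitable [0, 0.25), low [0.25, 0.5), moderate [0.5, 0.75) and high
[0.75, 1] — with half-open bins (top bin closed) so every value lands in
exactly one class. Per-class areas are reported as percentages of the valid
(non-nodata) cells; the change rate between a current and a future area is

    AC = (Af - Ac) / Ac * 100

(positive = expansion, negative = contraction). Overlaying a binarised
current and future map yields the four change categories: stable
unsuitable, gain (newly suitable), stable suitable, and loss (vulnerable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geodata_io import RasterGrid

__all__ = [
    "DEFAULT_SCHEME",
    "CHANGE_CODES",
    "ClassificationScheme",
    "AreaSummary",
    "ChangeRateResult",
    "ChangeMap",
    "classify",
    "area_summary",
    "total_suitable",
    "change_map",
    "change_rate",
    "change_rate_result",
    "scenario_report",
]

#: Integer codes of the change-map categories.
CHANGE_CODES = {
    "stable_unsuitable": 0,
    "gain": 1,
    "stable_suitable": 2,
    "loss": 3,
}


@dataclass(frozen=True)
class ClassificationScheme:
    """Ordered, contiguous suitability bins covering [0, 1]."""

    bins: tuple[tuple[str, float, float], ...] = (
        ("not", 0.0, 0.25),
        ("low", 0.25, 0.5),
        ("moderate", 0.5, 0.75),
        ("high", 0.75, 1.0),
    )

    def __post_init__(self) -> None:
        if not self.bins:
            raise ValueError("scheme needs at least one bin")
        if self.bins[0][1] != 0.0 or self.bins[-1][2] != 1.0:
            raise ValueError("bins must cover [0, 1]")
        for (_, _, hi), (_, lo2, _) in zip(self.bins, self.bins[1:]):
            if hi != lo2:
                raise ValueError("bins must be contiguous and non-overlapping")

    @property
    def labels(self) -> list[str]:
        return [label for label, _, _ in self.bins]

    @property
    def edges(self) -> np.ndarray:
        return np.array([lo for _, lo, _ in self.bins] + [self.bins[-1][2]])

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown class label {label!r}") from None


DEFAULT_SCHEME = ClassificationScheme()


@dataclass
class AreaSummary:
    """Per-class percentage of the valid area under one scenario."""

    percentages: dict[str, float]
    scenario_tag: tuple[str, str] = ("current", "")
    n_valid_cells: int = 0
    area_weighting: str = "cell-count"

    def __post_init__(self) -> None:
        total = sum(self.percentages.values())
        if self.percentages and abs(total - 100.0) > 1e-9:
            raise ValueError(f"class percentages sum to {total}, not 100")


@dataclass
class ChangeRateResult:
    """Eq.-style change-rate bookkeeping between a current and future area."""

    Ac: float
    Af: float
    AC: float
    Acf: float | None = None  # overlap area, reported but not used in AC


@dataclass
class ChangeMap:
    """Four-category change raster plus the rule that produced it."""

    raster: RasterGrid
    binarization_rule: str
    counts: dict[str, int] = field(default_factory=dict)


def classify(
    suitability: RasterGrid, scheme: ClassificationScheme = DEFAULT_SCHEME
) -> RasterGrid:
    """Bin a [0, 1] suitability map into integer class codes.

    Values marginally outside [0, 1] are clamped with a warning; anything
    further out is rejected. Bins are half-open [lo, hi), top bin closed.
    """
    vals = suitability.values.copy()
    valid = ~suitability.nodata_mask
    v = vals[valid]
    if v.size and ((v < -0.01).any() or (v > 1.01).any()):
        raise ValueError("suitability values far outside [0, 1]")
    if v.size and ((v < 0).any() or (v > 1).any()):
        warnings.warn("suitability marginally outside [0, 1]; clamping", stacklevel=2)
        vals[valid] = np.clip(v, 0.0, 1.0)
    edges = scheme.edges
    codes = np.digitize(vals, edges[1:-1], right=False).astype(float)
    codes[vals == 1.0] = len(scheme.bins) - 1  # closed top bin
    codes[~valid] = np.nan
    return RasterGrid(
        codes, suitability.transform, suitability.crs_tag, suitability.nodata_mask.copy()
    )


def area_summary(
    classified: RasterGrid,
    scenario_tag: tuple[str, str] = ("current", ""),
    scheme: ClassificationScheme = DEFAULT_SCHEME,
    latitude_weighted: bool = False,
) -> AreaSummary:
    """Percentage of valid area in each suitability class.

    Default is the simple cell fraction; ``latitude_weighted=True`` weights
    each cell by the cosine of its centre latitude (geographic grids have
    smaller cells toward the poles).
    """
    valid = ~classified.nodata_mask
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("raster has no valid cells")
    codes = classified.values
    if latitude_weighted:
        _, lats = classified.transform.cell_centers(classified.shape)
        w_row = np.cos(np.radians(lats))
        weights = np.broadcast_to(w_row[:, None], classified.shape)
    else:
        weights = np.ones(classified.shape)
    total_w = weights[valid].sum()
    pct = {}
    for i, label in enumerate(scheme.labels):
        sel = valid & (codes == i)
        pct[label] = float(100.0 * weights[sel].sum() / total_w)
    return AreaSummary(
        percentages=pct,
        scenario_tag=scenario_tag,
        n_valid_cells=n_valid,
        area_weighting="cos-latitude" if latitude_weighted else "cell-count",
    )


def total_suitable(
    summary: AreaSummary, scheme: ClassificationScheme = DEFAULT_SCHEME,
    suitable_floor: str = "low",
) -> float:
    """Sum of class percentages from ``suitable_floor`` upward (low+moderate+high)."""
    floor_idx = scheme.index_of(suitable_floor)
    return float(
        sum(summary.percentages[label] for label in scheme.labels[floor_idx:])
    )


def _binarize(classified: RasterGrid, floor_idx: int) -> np.ndarray:
    return classified.values >= floor_idx


def change_map(
    current: RasterGrid,
    future: RasterGrid,
    suitable_floor: str = "low",
    scheme: ClassificationScheme = DEFAULT_SCHEME,
) -> ChangeMap:
    """Overlay binarised current/future class maps into four categories.

    A cell is "suitable" iff its class is at or above ``suitable_floor``.
    Categories: both unsuitable -> stable_unsuitable; unsuitable->suitable
    -> gain; both suitable -> stable_suitable; suitable->unsuitable -> loss.
    The output mask is the union of the input masks.
    """
    current.require_coregistered(future, "change_map")
    floor_idx = scheme.index_of(suitable_floor)
    mask = current.nodata_mask | future.nodata_mask
    cur = _binarize(current, floor_idx)
    fut = _binarize(future, floor_idx)
    codes = np.full(current.shape, np.nan)
    valid = ~mask
    codes[valid & ~cur & ~fut] = CHANGE_CODES["stable_unsuitable"]
    codes[valid & ~cur & fut] = CHANGE_CODES["gain"]
    codes[valid & cur & fut] = CHANGE_CODES["stable_suitable"]
    codes[valid & cur & ~fut] = CHANGE_CODES["loss"]
    counts = {
        name: int((codes[valid] == code).sum()) for name, code in CHANGE_CODES.items()
    }
    rule = f"suitable iff class >= {suitable_floor!r} (code {floor_idx})"
    return ChangeMap(
        raster=RasterGrid(codes, current.transform, current.crs_tag, mask),
        binarization_rule=rule,
        counts=counts,
    )


def change_rate(Ac: float, Af: float) -> float:
    """Habitat change rate (%): (Af - Ac) / Ac * 100. Undefined for Ac = 0."""
    if Ac == 0:
        raise ZeroDivisionError("change rate undefined for a zero current area")
    return (Af - Ac) / Ac * 100.0


def change_rate_result(
    current_summary: AreaSummary,
    future_summary: AreaSummary,
    cmap: ChangeMap | None = None,
    scheme: ClassificationScheme = DEFAULT_SCHEME,
    suitable_floor: str = "low",
) -> ChangeRateResult:
    """Change rate of the total suitable area, with the overlap area reported.

    Acf (suitable in both periods) comes from the change map's
    stable_suitable fraction when a map is supplied.
    """
    Ac = total_suitable(current_summary, scheme, suitable_floor)
    Af = total_suitable(future_summary, scheme, suitable_floor)
    Acf = None
    if cmap is not None:
        n_valid = sum(cmap.counts.values())
        if n_valid:
            Acf = 100.0 * cmap.counts["stable_suitable"] / n_valid
    return ChangeRateResult(Ac=Ac, Af=Af, AC=change_rate(Ac, Af), Acf=Acf)


def scenario_report(
    current_summary: AreaSummary,
    future_summaries: dict[tuple[str, str], AreaSummary],
    scheme: ClassificationScheme = DEFAULT_SCHEME,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Class-percentage grid and per-class change-rate grid over scenarios.

    Returns ``(areas, rates)``: ``areas`` has one row per scenario (current
    first) and one column per class; ``rates`` has one row per future
    scenario with the per-class change rate against the current row,
    computed from the full-precision class percentages.
    """
    if not future_summaries:
        raise ValueError("no future scenarios supplied")
    labels = scheme.labels
    rows = {("current", ""): [current_summary.percentages[c] for c in labels]}
    for tag, summ in future_summaries.items():
        rows[tag] = [summ.percentages[c] for c in labels]
    areas = pd.DataFrame.from_dict(rows, orient="index", columns=labels)
    areas.index = pd.MultiIndex.from_tuples(areas.index, names=["period", "scenario"])

    rate_rows = {}
    for tag, summ in future_summaries.items():
        rate_rows[tag] = [
            change_rate(current_summary.percentages[c], summ.percentages[c])
            if current_summary.percentages[c] != 0 else np.nan
            for c in labels
        ]
    rates = pd.DataFrame.from_dict(rate_rows, orient="index", columns=labels)
    rates.index = pd.MultiIndex.from_tuples(rates.index, names=["period", "scenario"])
    return areas, rates
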