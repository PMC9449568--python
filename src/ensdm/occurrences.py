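"""Presence cleaning and spatially constrained pseudo-absence sampling.

Presence records are thinned to one per analysis-grid cell and background
(pseudo-absence) points are drawn uniformly over valid cell centres, subject
to a minimum great-circle distance from every presence (the classic
buffer-exclusion rule, default 5 km). Distances use the haversine formula on
a sphere of mean Earth radius 6371.0088 km.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geodata_io import OccurrenceSet, PredictorStack

__all__ = [
    "EARTH_RADIUS_KM",
    "SamplingConfig",
    "haversine_km",
    "deduplicate",
    "generate_pseudo_absences",
]

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class SamplingConfig:
    """Pseudo-absence sampling settings.

    Defaults mirror a common protocol: 2000 background points, none closer
    than 5 km to any presence.
    """

    n_pseudo_absence: int = 2000
    min_distance_km: float = 5.0
    seed: int = 0
    max_attempts: int | None = None  # None -> 100 * n_pseudo_absence

    def __post_init__(self) -> None:
        if self.n_pseudo_absence < 0:
            raise ValueError("n_pseudo_absence must be >= 0")
        if self.min_distance_km < 0:
            raise ValueError("min_distance_km must be >= 0")
        if self.max_attempts is not None and self.max_attempts < self.n_pseudo_absence:
            raise ValueError("max_attempts must be >= n_pseudo_absence")

    @property
    def attempts_budget(self) -> int:
        if self.max_attempts is None:
            return max(100 * self.n_pseudo_absence, 1000)
        return self.max_attempts


def haversine_km(a, b) -> float:
    """Great-circle distance in km between two (lon, lat) points (degrees).

    Accepts scalars or broadcastable arrays; symmetric and non-negative.
    """
    lon1, lat1 = np.radians(np.asarray(a, dtype=float)).T if np.ndim(a) > 1 else np.radians(np.asarray(a, dtype=float))
    lon2, lat2 = np.radians(np.asarray(b, dtype=float)).T if np.ndim(b) > 1 else np.radians(np.asarray(b, dtype=float))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    return float(d) if np.ndim(d) == 0 else d


def _pairwise_km(lons1, lats1, lons2, lats2) -> np.ndarray:
    """(n1, n2) matrix of haversine distances."""
    lon1 = np.radians(np.asarray(lons1, float))[:, None]
    lat1 = np.radians(np.asarray(lats1, float))[:, None]
    lon2 = np.radians(np.asarray(lons2, float))[None, :]
    lat2 = np.radians(np.asarray(lats2, float))[None, :]
    h = (
        np.sin((lat2 - lat1) / 2.0) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def deduplicate(points: OccurrenceSet, stack: PredictorStack) -> OccurrenceSet:
    """Thin records to at most one per grid cell (first by input order).

    Records outside the stack extent or on nodata cells are removed; all
    removal counts are logged.
    """
    if len(stack) == 0:
        raise ValueError("empty predictor stack")
    mask = stack.combined_mask()
    transform = stack.transform
    shape = stack.shape
    keep: list[int] = []
    seen: set[tuple[int, int]] = set()
    n_outside = n_nodata = n_dup = 0
    df = points.records
    for i, (lon, lat) in enumerate(zip(df["lon"], df["lat"])):
        try:
            cell = transform.cell_of(lon, lat, shape)
        except ValueError:
            n_outside += 1
            continue
        if mask[cell]:
            n_nodata += 1
            continue
        if cell in seen:
            n_dup += 1
            continue
        seen.add(cell)
        keep.append(i)
    logger.info(
        "deduplicate: kept %d of %d (%d outside extent, %d on nodata, %d duplicate-cell)",
        len(keep), len(df), n_outside, n_nodata, n_dup,
    )
    return OccurrenceSet(df.iloc[keep])


def generate_pseudo_absences(
    presences: OccurrenceSet,
    stack: PredictorStack,
    cfg: SamplingConfig,
) -> OccurrenceSet:
    """Draw label-0 background points on valid cell centres.

    Points are sampled uniformly without replacement over the cell centres of
    the analysis grid, rejecting any centre closer than
    ``cfg.min_distance_km`` (haversine) to any presence. Deterministic for a
    fixed seed. Raises if the candidate pool cannot supply
    ``cfg.n_pseudo_absence`` points within the attempts budget.
    """
    if len(presences) == 0:
        raise ValueError("presences must be non-empty")
    if len(stack) == 0:
        raise ValueError("empty predictor stack")
    mask = stack.combined_mask()
    rows, cols = np.nonzero(~mask)
    if rows.size == 0:
        raise ValueError("stack has no valid cells")
    lons, lats = stack.transform.cell_centers(stack.shape)
    cand_lon = lons[cols]
    cand_lat = lats[rows]

    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(rows.size)

    pres_lon = presences.presences().lon
    pres_lat = presences.presences().lat

    chosen: list[int] = []
    attempts = 0
    budget = cfg.attempts_budget
    # test candidates in seeded random order = uniform sampling w/o replacement
    for start in range(0, order.size, 4096):
        if len(chosen) >= cfg.n_pseudo_absence or attempts >= budget:
            break
        block = order[start : start + 4096]
        block = block[: max(budget - attempts, 0)]
        attempts += block.size
        d = _pairwise_km(cand_lon[block], cand_lat[block], pres_lon, pres_lat)
        ok = d.min(axis=1) >= cfg.min_distance_km
        for idx in block[ok]:
            chosen.append(int(idx))
            if len(chosen) == cfg.n_pseudo_absence:
                break
    if len(chosen) < cfg.n_pseudo_absence:
        raise RuntimeError(
            f"could only place {len(chosen)} of {cfg.n_pseudo_absence} pseudo-absences "
            f"after {attempts} attempts (extent too small or exclusion buffer too large)"
        )
    chosen_arr = np.array(chosen[: cfg.n_pseudo_absence], dtype=int)
    return OccurrenceSet.from_arrays(
        cand_lon[chosen_arr], cand_lat[chosen_arr], label=0, source="pseudo-absence"
    )
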