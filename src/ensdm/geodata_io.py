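"""Grid data model and geospatial/tabular I/O.

Everything downstream works on three containers defined here:

* :class:`RasterGrid` — a single georeferenced 2-D layer with a nodata mask,
  the atom of all map arithmetic;
* :class:`PredictorStack` — an ordered, co-registered set of named layers
  (the bioclimatic/topographic predictors);
* :class:`OccurrenceSet` — labelled point records (presence = 1,
  pseudo-absence = 0) in geographic lon/lat.

All coordinates are geographic WGS84 (``EPSG:4326``); there is deliberately
no reprojection or resampling anywhere — co-registration is a hard
precondition and violations raise, because silent resampling is a classic
source of wrong suitability maps.

Rasters are stored as plain single-band north-up GeoTIFFs (via
:mod:`tifffile` plus the standard GeoTIFF tags); occurrences as headed CSV.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "WGS84",
    "NODATA_SENTINEL",
    "GridTransform",
    "RasterGrid",
    "PredictorStack",
    "OccurrenceSet",
    "read_raster",
    "write_raster",
    "read_occurrences",
    "write_occurrences",
    "align_stack",
]

logger = logging.getLogger(__name__)

WGS84 = "EPSG:4326"

#: Nodata sentinel declared in written GeoTIFF metadata (GDAL convention).
NODATA_SENTINEL = -9999.0

# GeoTIFF tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113


@dataclass(frozen=True)
class GridTransform:
    """Affine georeference of a north-up grid.

    ``west``/``north`` are the outer corner of cell (0, 0); ``dx`` is the
    cell width (> 0) and ``dy`` the row step, negative by the north-up
    convention (row 0 is the northernmost row).
    """

    west: float
    north: float
    dx: float
    dy: float

    @property
    def north_up(self) -> bool:
        return self.dx > 0 and self.dy < 0

    def cell_of(self, lon: float, lat: float, shape: tuple[int, int]) -> tuple[int, int]:
        """Map a point to its containing (row, col), or raise ``ValueError``.

        Cells are half-open ``[west, east) x (south, north]`` so that a point
        on a shared edge belongs to exactly one cell.
        """
        nrows, ncols = shape
        h = -self.dy

        def snap(u: float) -> float:
            # points numerically on a cell edge get the exact edge value so
            # the half-open convention, not rounding noise, decides ownership
            r = round(u)
            return float(r) if abs(u - r) < 1e-9 else u

        col = math.floor(snap((lon - self.west) / self.dx))
        # row r spans (north-(r+1)h, north-r*h]; floor lands boundary
        # latitudes in the cell whose (inclusive) top edge they sit on
        row = math.floor(snap((self.north - lat) / h))
        if not (0 <= row < nrows and 0 <= col < ncols):
            raise ValueError(
                f"point (lon={lon}, lat={lat}) falls outside the grid extent"
            )
        return row, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        lon = self.west + (col + 0.5) * self.dx
        lat = self.north + (row + 0.5) * self.dy
        return lon, lat

    def cell_centers(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Lon and lat coordinate arrays of all cell centres (1-D each)."""
        nrows, ncols = shape
        lons = self.west + (np.arange(ncols) + 0.5) * self.dx
        lats = self.north + (np.arange(nrows) + 0.5) * self.dy
        return lons, lats


@dataclass
class RasterGrid:
    """One georeferenced 2-D layer of values with a nodata mask.

    ``nodata_mask`` is True where the cell carries no data; ``values`` at
    masked cells are unspecified and must never enter map arithmetic.
    """

    values: np.ndarray
    transform: GridTransform
    crs_tag: str = WGS84
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {self.values.shape}")
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.values)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise ValueError(
                f"mask shape {self.nodata_mask.shape} != values shape {self.values.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_valid(self) -> int:
        return int((~self.nodata_mask).sum())

    def valid_values(self) -> np.ndarray:
        return self.values[~self.nodata_mask]

    def is_coregistered(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and self.transform == other.transform
            and self.crs_tag == other.crs_tag
        )

    def require_coregistered(self, other: "RasterGrid", what: str = "operation") -> None:
        if not self.is_coregistered(other):
            raise ValueError(
                f"{what} requires co-registered grids: "
                f"{self.shape}/{self.transform} vs {other.shape}/{other.transform}"
            )

    def copy(self) -> "RasterGrid":
        return RasterGrid(
            self.values.copy(), self.transform, self.crs_tag, self.nodata_mask.copy()
        )


@dataclass
class PredictorStack:
    """Named, co-registered set of :class:`RasterGrid` layers."""

    layers: dict[str, RasterGrid]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("a PredictorStack needs at least one layer")
        names = list(self.layers)
        ref = self.layers[names[0]]
        bad = [n for n in names[1:] if not ref.is_coregistered(self.layers[n])]
        if bad:
            raise ValueError(
                f"layers not co-registered with {names[0]!r}: {', '.join(bad)}"
            )

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def shape(self) -> tuple[int, int]:
        return self.first.shape

    @property
    def transform(self) -> GridTransform:
        return self.first.transform

    @property
    def crs_tag(self) -> str:
        return self.first.crs_tag

    @property
    def first(self) -> RasterGrid:
        return next(iter(self.layers.values()))

    def __len__(self) -> int:
        return len(self.layers)

    def __getitem__(self, name: str) -> RasterGrid:
        return self.layers[name]

    def combined_mask(self) -> np.ndarray:
        """Union of all layer nodata masks (True = unusable cell)."""
        mask = np.zeros(self.shape, dtype=bool)
        for grid in self.layers.values():
            mask |= grid.nodata_mask
        return mask

    def as_array(self, names: Sequence[str] | None = None) -> np.ndarray:
        """(n_layers, rows, cols) array in the requested layer order."""
        names = list(names) if names is not None else self.names
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"stack is missing layers: {', '.join(missing)}")
        return np.stack([self.layers[n].values for n in names])

    def subset(self, names: Sequence[str]) -> "PredictorStack":
        return PredictorStack(
            {n: self.layers[n] for n in names},
            {n: self.provenance.get(n, "") for n in names},
        )


@dataclass
class OccurrenceSet:
    """Labelled point records: presence (label 1) or pseudo-absence (0)."""

    records: pd.DataFrame

    COLUMNS = ("lon", "lat", "label", "source")

    def __post_init__(self) -> None:
        df = self.records.reset_index(drop=True).copy()
        for col in ("lon", "lat", "label"):
            if col not in df.columns:
                raise ValueError(f"occurrence table lacks required column {col!r}")
        if "source" not in df.columns:
            df["source"] = ""
        df["lon"] = df["lon"].astype(float)
        df["lat"] = df["lat"].astype(float)
        df["label"] = df["label"].astype(int)
        if len(df) and not df["label"].isin((0, 1)).all():
            raise ValueError("labels must be 0 or 1")
        if len(df):
            out = (df["lon"].abs() > 180) | (df["lat"].abs() > 90)
            if out.any():
                raise ValueError(f"{int(out.sum())} records outside lon/lat range")
        self.records = df[list(self.COLUMNS)]

    @classmethod
    def from_arrays(
        cls,
        lon: Iterable[float],
        lat: Iterable[float],
        label: Iterable[int] | int = 1,
        source: str = "",
    ) -> "OccurrenceSet":
        lon = np.asarray(list(lon), dtype=float)
        lat = np.asarray(list(lat), dtype=float)
        if np.isscalar(label) or isinstance(label, int):
            label = np.full(lon.shape, int(label))
        return cls(
            pd.DataFrame(
                {"lon": lon, "lat": lat, "label": np.asarray(list(label)), "source": source}
            )
        )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def lon(self) -> np.ndarray:
        return self.records["lon"].to_numpy()

    @property
    def lat(self) -> np.ndarray:
        return self.records["lat"].to_numpy()

    @property
    def labels(self) -> np.ndarray:
        return self.records["label"].to_numpy()

    def presences(self) -> "OccurrenceSet":
        return OccurrenceSet(self.records[self.records["label"] == 1])

    def absences(self) -> "OccurrenceSet":
        return OccurrenceSet(self.records[self.records["label"] == 0])

    def concat(self, other: "OccurrenceSet") -> "OccurrenceSet":
        return OccurrenceSet(
            pd.concat([self.records, other.records], ignore_index=True)
        )


# ---------------------------------------------------------------------------
# raster I/O


def read_raster(path: str | Path) -> RasterGrid:
    """Read a single-band, georeferenced, north-up GeoTIFF.

    Cells equal to the declared nodata sentinel (GDAL_NODATA tag) or
    non-finite become masked.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster file not found: {path}")
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) != 1:
            raise ValueError(
                f"{path}: multi-band/multi-page TIFF without a band selector"
            )
        page = tif.pages[0]
        scale = page.tags.get(_TAG_PIXEL_SCALE)
        tiepoint = page.tags.get(_TAG_TIEPOINT)
        if scale is None or tiepoint is None:
            raise ValueError(f"{path}: missing GeoTIFF georeference tags")
        sx, sy = float(scale.value[0]), float(scale.value[1])
        i, j, _, x, y, _ = (float(v) for v in tiepoint.value[:6])
        # tiepoint maps raster (i, j) to model (x, y); recover the corner
        west = x - i * sx
        north = y + j * sy
        transform = GridTransform(west=west, north=north, dx=sx, dy=-sy)
        nodata = None
        nd_tag = page.tags.get(_TAG_GDAL_NODATA)
        if nd_tag is not None:
            nodata = float(str(nd_tag.value))
        values = tif.asarray().astype(np.float64)
    mask = ~np.isfinite(values)
    if nodata is not None:
        mask |= values == nodata
    values = np.where(mask, np.nan, values)
    return RasterGrid(values, transform, WGS84, mask)


def write_raster(grid: RasterGrid, path: str | Path) -> None:
    """Write a :class:`RasterGrid` as a single-band WGS84 GeoTIFF.

    Masked cells are stored as the declared nodata sentinel; values
    round-trip bit-exactly (float64 storage) through :func:`read_raster`.
    """
    path = Path(path)
    t = grid.transform
    if not t.north_up:
        raise ValueError(
            f"write_raster requires a north-up transform (dx>0, dy<0), got {t}"
        )
    data = np.where(grid.nodata_mask, NODATA_SENTINEL, grid.values).astype(np.float64)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (t.dx, -t.dy, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.west, t.north, 0.0)),
        # GeographicTypeGeoKey 2048 = 4326 (WGS84), raster pixel-is-area
        (_TAG_GEO_KEYS, "H", 16, (1, 1, 0, 3, 1024, 0, 1, 2, 1025, 0, 1, 1, 2048, 0, 1, 4326)),
        (_TAG_GDAL_NODATA, "s", 0, str(int(NODATA_SENTINEL))),
    ]
    tifffile.imwrite(path, data, extratags=extratags)


# ---------------------------------------------------------------------------
# occurrence I/O


def read_occurrences(
    path: str | Path,
    lon_col: str = "lon",
    lat_col: str = "lat",
    label_col: str | None = "label",
    source_col: str | None = "source",
) -> OccurrenceSet:
    """Read occurrence points from a headed delimited table.

    Rows with unparsable or out-of-range coordinates are dropped and the
    count logged. If ``label_col`` is absent from the file (or None) all
    records are presences.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"occurrence file not found: {path}")
    df = pd.read_csv(path)
    for col in (lon_col, lat_col):
        if col not in df.columns:
            raise ValueError(
                f"{path}: column {col!r} not found (has: {', '.join(df.columns)})"
            )
    lon = pd.to_numeric(df[lon_col], errors="coerce")
    lat = pd.to_numeric(df[lat_col], errors="coerce")
    ok = lon.notna() & lat.notna() & (lon.abs() <= 180) & (lat.abs() <= 90)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("read_occurrences: dropped %d invalid rows from %s", n_dropped, path)
    if label_col is not None and label_col in df.columns:
        label = pd.to_numeric(df[label_col], errors="coerce").fillna(1).astype(int)
    else:
        label = pd.Series(1, index=df.index)
    if source_col is not None and source_col in df.columns:
        source = df[source_col].fillna("").astype(str)
    else:
        source = pd.Series("", index=df.index)
    out = pd.DataFrame(
        {"lon": lon[ok], "lat": lat[ok], "label": label[ok], "source": source[ok]}
    )
    return OccurrenceSet(out)


def write_occurrences(points: OccurrenceSet, path: str | Path) -> None:
    points.records.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# stack assembly


def align_stack(
    layers: Sequence[RasterGrid] | Mapping[str, RasterGrid],
    names: Sequence[str] | None = None,
    provenance: Mapping[str, str] | None = None,
) -> PredictorStack:
    """Assemble co-registered layers into a :class:`PredictorStack`.

    There is no resampling: any shape/transform/CRS mismatch is an error
    naming the offending layers.
    """
    if isinstance(layers, Mapping):
        named = dict(layers)
    else:
        if names is None or len(names) != len(layers):
            raise ValueError("names must be given, one per layer")
        named = {}
        for name, grid in zip(names, layers):
            if name in named:
                raise ValueError(f"duplicate layer name: {name!r}")
            named[name] = grid
    if not named:
        raise ValueError("align_stack needs at least one layer")
    ref_name = next(iter(named))
    ref = named[ref_name]
    bad = [n for n, g in named.items() if not ref.is_coregistered(g)]
    if bad:
        raise ValueError(
            f"layers not co-registered with {ref_name!r} "
            f"(shape {ref.shape}, {ref.transform}): {', '.join(bad)}"
        )
    return PredictorStack(named, dict(provenance or {}))
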