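"""Virtual-species world generator.

Real suitability maps cannot be validated — nobody knows the true niche — so
the pipeline is exercised on a simulated world where the truth is known:

* climate-like predictor layers = seeded white noise smoothed to a chosen
  autocorrelation length and standardised (mean 0, sd 1) over valid cells;
* deliberately collinear duplicates (parent + small noise, pairwise
  r >= 0.95) to give the collinearity screen something to remove;
* a virtual species whose true suitability is a logistic function of the
  signal layers (optionally with quadratic niche curvature);
* presences drawn without replacement over cells with probability
  proportional to true suitability (a species is recorded at most once per
  cell, mirroring the one-per-cell dedup upstream);
* future scenarios as additive mean shifts of named layers — the minimal
  mechanism that yields a nontrivial, analytically known change map.

What this world does *not* emulate: climate physics, spatial sampling bias,
dispersal limitation, observation error. A green end-to-end test therefore
establishes statistical correctness of the pipeline, not ecological realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .geodata_io import GridTransform, OccurrenceSet, PredictorStack, RasterGrid, WGS84

__all__ = [
    "WorldConfig",
    "VirtualSpecies",
    "ScenarioShift",
    "make_climate_stack",
    "true_suitability",
    "sample_presences",
    "apply_shift",
    "default_species",
]

#: 5 arc-minutes in degrees — the working resolution of the real analysis.
FIVE_ARCMIN = 1.0 / 12.0


@dataclass(frozen=True)
class WorldConfig:
    """Shape and content of the synthetic predictor world.

    Defaults give a 100x100 grid at 5-arc-min resolution with 2 signal
    layers (the true niche axes), 4 decoys and 1 collinear copy of the
    first signal layer.
    """

    nrows: int = 100
    ncols: int = 100
    west: float = 25.0
    north: float = 5.0
    cell_size: float = FIVE_ARCMIN
    n_signal_layers: int = 2
    n_decoy_layers: int = 4
    n_collinear_copies: int = 1
    autocorr_length: float = 5.0
    collinear_noise_sd: float = 0.2  # parent + N(0, sd) -> r ~ 0.98
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nrows < 2 or self.ncols < 2:
            raise ValueError("grid must be at least 2x2")
        if self.n_signal_layers < 1:
            raise ValueError("need at least one signal layer")
        if self.autocorr_length < 0:
            raise ValueError("autocorr_length must be >= 0")

    @property
    def transform(self) -> GridTransform:
        return GridTransform(self.west, self.north, self.cell_size, -self.cell_size)

    @property
    def signal_names(self) -> list[str]:
        return [f"signal{i + 1}" for i in range(self.n_signal_layers)]

    @property
    def decoy_names(self) -> list[str]:
        return [f"decoy{i + 1}" for i in range(self.n_decoy_layers)]

    @property
    def collinear_names(self) -> list[str]:
        # copies duplicate the signal layers cyclically
        return [
            f"{self.signal_names[i % self.n_signal_layers]}_dup{i // self.n_signal_layers + 1}"
            for i in range(self.n_collinear_copies)
        ]


@dataclass(frozen=True)
class VirtualSpecies:
    """True niche: logistic(beta0 + sum beta_j x_j + sum gamma_j x_j^2)."""

    beta0: float = 0.0
    betas: dict[str, float] = field(default_factory=dict)
    quadratic_terms: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class ScenarioShift:
    """Additive per-layer deltas standing in for a future climate scenario."""

    deltas: dict[str, float]
    tag: tuple[str, str] = ("2050", "shift")


def default_species(cfg: WorldConfig) -> VirtualSpecies:
    """A species responding to the signal layers only.

    A strong positive response to signal1 with niche curvature and a negative
    response to signal2. The intercept and slopes are set so that roughly a
    third of the landscape is suitable (p >= 0.25) — a compact, strongly
    climate-limited range comparable to a real dryland specialist, which
    makes presences clearly separable from uniform background points.
    """
    names = cfg.signal_names
    betas = {}
    for i, n in enumerate(names):
        betas[n] = 4.0 if i % 2 == 0 else -3.0
    quads = {names[0]: -2.0}
    return VirtualSpecies(beta0=-2.0, betas=betas, quadratic_terms=quads)


def _smooth_field(rng: np.random.Generator, shape, autocorr_length: float) -> np.ndarray:
    field_ = rng.standard_normal(shape)
    if autocorr_length > 0:
        field_ = gaussian_filter(field_, sigma=autocorr_length, mode="reflect")
    field_ -= field_.mean()
    sd = field_.std()
    if sd > 0:
        field_ /= sd
    return field_


def make_climate_stack(cfg: WorldConfig) -> PredictorStack:
    """Generate the standardised predictor stack described by ``cfg``."""
    rng = np.random.default_rng(cfg.seed)
    shape = (cfg.nrows, cfg.ncols)
    transform = cfg.transform
    layers: dict[str, RasterGrid] = {}
    provenance: dict[str, str] = {}

    for name in cfg.signal_names + cfg.decoy_names:
        vals = _smooth_field(rng, shape, cfg.autocorr_length)
        layers[name] = RasterGrid(vals, transform, WGS84, np.zeros(shape, bool))
        provenance[name] = "synthetic autocorrelated field"

    for i, name in enumerate(cfg.collinear_names):
        parent = cfg.signal_names[i % cfg.n_signal_layers]
        vals = layers[parent].values + cfg.collinear_noise_sd * rng.standard_normal(shape)
        vals = (vals - vals.mean()) / vals.std()
        layers[name] = RasterGrid(vals, transform, WGS84, np.zeros(shape, bool))
        provenance[name] = f"collinear copy of {parent}"

    return PredictorStack(layers, provenance)


def true_suitability(species: VirtualSpecies, stack: PredictorStack) -> RasterGrid:
    """Cell-wise logistic suitability of the virtual species; values in (0, 1)."""
    for name in list(species.betas) + list(species.quadratic_terms):
        if name not in stack.layers:
            raise KeyError(f"species references missing layer {name!r}")
    eta = np.full(stack.shape, species.beta0, dtype=float)
    for name, beta in species.betas.items():
        eta += beta * stack[name].values
    for name, gamma in species.quadratic_terms.items():
        eta += gamma * stack[name].values ** 2
    p = 1.0 / (1.0 + np.exp(-eta))
    mask = stack.combined_mask()
    p = np.where(mask, np.nan, p)
    return RasterGrid(p, stack.transform, stack.crs_tag, mask)


def sample_presences(truth: RasterGrid, n: int, seed: int = 0) -> OccurrenceSet:
    """Draw n presence cells, probability proportional to true suitability.

    Without replacement; presence points sit at cell centres.
    """
    valid = ~truth.nodata_mask
    rows, cols = np.nonzero(valid)
    if n > rows.size:
        raise ValueError(f"cannot draw {n} presences from {rows.size} valid cells")
    w = truth.values[rows, cols].astype(float)
    if (w < 0).any():
        raise ValueError("suitability weights must be non-negative")
    if w.sum() == 0:
        raise ValueError("all suitability weights are zero")
    rng = np.random.default_rng(seed)
    idx = rng.choice(rows.size, size=n, replace=False, p=w / w.sum())
    lons, lats = truth.transform.cell_centers(truth.shape)
    return OccurrenceSet.from_arrays(
        lons[cols[idx]], lats[rows[idx]], label=1, source="virtual-species"
    )


def apply_shift(stack: PredictorStack, shift: ScenarioShift) -> PredictorStack:
    """Additively shift named layers; untouched layers are shared unchanged."""
    unknown = [n for n in shift.deltas if n not in stack.layers]
    if unknown:
        raise KeyError(f"shift references missing layers: {', '.join(unknown)}")
    layers: dict[str, RasterGrid] = {}
    for name, grid in stack.layers.items():
        if name in shift.deltas:
            layers[name] = RasterGrid(
                grid.values + shift.deltas[name],
                grid.transform,
                grid.crs_tag,
                grid.nodata_mask.copy(),
            )
        else:
            layers[name] = grid
    return PredictorStack(layers, dict(stack.provenance))
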