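"""Seeded synthetic landscapes, epoch sequences and driving factors.

Real inputs to the analysis — multi-epoch categorical land-use maps, a
relief raster and a stack of continuous driving factors — are emulated
here with known ground truth so that every downstream stage can be tested
end to end: landscapes are spatially autocorrelated (Gaussian-filtered
noise), epochs evolve under a known row-stochastic class-transition matrix
(optionally with neighborhood-biased allocation of the conversions), and
the factor stack carries genuine class signal (e.g. night light bright over
construction) for the suitability network to learn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import (
    ARABLE,
    CONSTRUCTION,
    GRASSLAND,
    LAND_USE_CODES,
    UNUSED,
    WATER,
    WOODLAND,
    BinaryMask,
    ContinuousGrid,
    LandUseGrid,
    euclidean_distance_field,
)

#: Default class shares of the generated study area: a peri-urban mosaic —
#: large arable and woodland fractions, a construction core, scattered water.
DEFAULT_FRACTIONS = {
    ARABLE: 0.30,
    WOODLAND: 0.30,
    GRASSLAND: 0.10,
    WATER: 0.10,
    CONSTRUCTION: 0.15,
    UNUSED: 0.05,
}

FACTOR_NAMES = (
    "elevation",
    "slope",
    "relief",
    "dist_river",
    "dist_road",
    "dist_railway",
    "dist_residential",
    "night_light",
    "pop_density",
)


@dataclass
class LandscapeSpec:
    shape: tuple[int, int] = (200, 200)
    cell_size: float = 30.0
    class_fractions: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_FRACTIONS)
    )
    autocorrelation_range: float = 18.0  # cells; Gaussian filter sigma
    seed: int = 0

    def __post_init__(self) -> None:
        fr = np.array(list(self.class_fractions.values()), dtype=float)
        if (fr < 0).any():
            raise ValueError("class fractions must be non-negative")
        if abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1")
        if self.shape[0] <= 0 or self.shape[1] <= 0:
            raise ValueError("shape must be positive")


@dataclass
class EvolutionSpec:
    transition_matrix: np.ndarray
    steps: int = 1
    spatial_kernel_size: int = 5  # odd; <=1 disables neighborhood bias (i.i.d.)
    seed: int = 0

    def __post_init__(self) -> None:
        m = np.asarray(self.transition_matrix, dtype=float)
        if m.shape != (6, 6):
            raise ValueError("transition matrix must be 6x6 over the class legend")
        if (m < 0).any() or (m > 1).any():
            raise ValueError("transition probabilities must lie in [0, 1]")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        self.transition_matrix = m


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Unit-variance Gaussian-filtered white noise."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
    sd = f.std()
    return f / sd if sd > 0 else f


def _normalize(v: np.ndarray) -> np.ndarray:
    lo, hi = float(v.min()), float(v.max())
    if hi - lo < 1e-12:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def generate_landscape(spec: LandscapeSpec) -> LandUseGrid:
    """Autocorrelated categorical landscape with calibrated class shares.

    One smooth latent field per class; cells take the argmax class after an
    iterative bias calibration that drives realized shares to the targets
    (within ±2 % of cells). Deterministic for a given spec.
    """
    rng = np.random.default_rng(spec.seed)
    classes = [c for c in LAND_USE_CODES if spec.class_fractions.get(c, 0.0) > 0]
    targets = np.array([spec.class_fractions[c] for c in classes])
    if len(classes) == 1:
        codes = np.full(spec.shape, classes[0], dtype=np.int64)
        return LandUseGrid(spec.cell_size, (0.0, 0.0), codes)
    fields = np.stack(
        [_smooth_field(rng, spec.shape, spec.autocorrelation_range) for _ in classes]
    )
    n = spec.shape[0] * spec.shape[1]
    bias = np.zeros(len(classes))
    for _ in range(300):
        assign = np.argmax(fields + bias[:, None, None], axis=0)
        shares = np.bincount(assign.ravel(), minlength=len(classes)) / n
        err = targets - shares
        if np.abs(err).max() < 0.002:
            break
        bias += 1.5 * err
    codes = np.zeros(spec.shape, dtype=np.int64)
    for k, c in enumerate(classes):
        codes[assign == k] = c
    return LandUseGrid(spec.cell_size, (0.0, 0.0), codes)


def evolve_landscape(
    initial: LandUseGrid, evo: EvolutionSpec
) -> list[LandUseGrid]:
    """Evolve a landscape ``evo.steps`` times under the transition matrix.

    With ``spatial_kernel_size > 1`` the conversion mass of each row is
    redistributed toward classes already present in the cell's window, so
    new construction (say) accretes onto existing construction; the stay
    probability of every class is preserved exactly, so with the kernel
    disabled the empirical cell-level transition frequencies converge to
    the matrix entries.
    """
    rng = np.random.default_rng(evo.seed)
    M = evo.transition_matrix
    out = []
    current = initial.codes.copy()
    valid = initial.valid_mask()
    for _ in range(evo.steps):
        nxt = current.copy()
        idx = current - 1  # class index 0..5 on valid cells
        if evo.spatial_kernel_size > 1:
            k = evo.spatial_kernel_size
            probs = np.zeros(current.shape + (6,))
            neigh = np.empty_like(probs)
            for j in range(6):
                ind = (current == j + 1).astype(float)
                neigh[..., j] = ndimage.uniform_filter(ind, size=k, mode="constant")
            row = M[np.clip(idx, 0, 5)]  # (r, c, 6)
            off = row.copy()
            rows_i = np.clip(idx, 0, 5)
            stay = np.take_along_axis(row, rows_i[..., None], axis=-1)[..., 0]
            np.put_along_axis(off, rows_i[..., None], 0.0, axis=-1)
            weighted = off * (0.05 + neigh)
            denom = weighted.sum(axis=-1)
            scale = np.where(denom > 0, (1.0 - stay) / np.where(denom > 0, denom, 1), 0)
            probs = weighted * scale[..., None]
            np.put_along_axis(probs, rows_i[..., None], stay[..., None], axis=-1)
        else:
            probs = M[np.clip(idx, 0, 5)]
        cum = np.cumsum(probs, axis=-1)
        u = rng.random(current.shape)
        drawn = np.minimum((u[..., None] > cum).sum(axis=-1), 5)  # drawn class index
        nxt[valid] = drawn[valid] + 1
        current = nxt
        out.append(
            LandUseGrid(
                initial.cell_size,
                initial.origin,
                current.copy(),
                nodata=initial.nodata,
            )
        )
    return out


def generate_relief(elevation: ContinuousGrid, window: int = 3) -> ContinuousGrid:
    """Focal range (max − min of elevation in the window) per cell."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    hi = ndimage.maximum_filter(elevation.values, size=window, mode="nearest")
    lo = ndimage.minimum_filter(elevation.values, size=window, mode="nearest")
    return ContinuousGrid(elevation.cell_size, elevation.origin, hi - lo)


def _polyline_mask(rng: np.random.Generator, shape) -> np.ndarray:
    """A 1-cell-wide wavy line across the grid (synthetic road/rail)."""
    rows, cols = shape
    mask = np.zeros(shape, dtype=bool)
    r0 = rng.uniform(0.2, 0.8) * rows
    amp = rng.uniform(0.05, 0.2) * rows
    phase = rng.uniform(0, 2 * np.pi)
    for c in range(cols):
        r = int(round(r0 + amp * np.sin(2 * np.pi * c / cols + phase)))
        if 0 <= r < rows:
            mask[r, c] = True
    if rng.random() < 0.5:
        mask = mask.T if rows == cols else mask
    return mask


def generate_factors(
    landuse: LandUseGrid, seed: int = 0
) -> dict[str, ContinuousGrid]:
    """Nine driving-factor layers, all normalized to [0, 1].

    Elevation is a smooth field raised under woodland (hills carry forest);
    slope and relief derive from it; the four distance layers are Euclidean
    distance fields to synthetic river / road / railway / residential masks
    (river = the water class, residential = the construction class, so the
    distances genuinely co-vary with the land-use pattern); night light and
    population density are smoothed construction indicators plus noise, so
    they correlate positively with construction occurrence.
    """
    rng = np.random.default_rng(seed)
    shape = landuse.shape
    cs, org = landuse.cell_size, landuse.origin

    wood = (landuse.codes == WOODLAND).astype(float)
    constr = (landuse.codes == CONSTRUCTION).astype(float)
    water = landuse.codes == WATER

    base = _smooth_field(rng, shape, 12.0)
    elev = base + 1.5 * ndimage.gaussian_filter(wood, 6.0, mode="nearest")
    gy, gx = np.gradient(elev)
    slope = np.hypot(gx, gy)

    elev_grid = ContinuousGrid(cs, org, elev)
    relief = generate_relief(
        ContinuousGrid(cs, org, 100.0 * _normalize(elev)), window=3
    )

    def dist_layer(bits: np.ndarray) -> ContinuousGrid:
        if not bits.any():  # degenerate landscape: drop a single anchor cell
            bits = np.zeros(shape, dtype=bool)
            bits[shape[0] // 2, shape[1] // 2] = True
        d = euclidean_distance_field(BinaryMask(cs, org, bits))
        return d

    river = dist_layer(water)
    road = dist_layer(_polyline_mask(rng, shape))
    railway = dist_layer(_polyline_mask(rng, shape))
    residential = dist_layer(constr > 0)

    light = ndimage.gaussian_filter(constr, 4.0, mode="nearest")
    light = light + 0.05 * rng.standard_normal(shape)
    dens = ndimage.gaussian_filter(constr, 8.0, mode="nearest")
    dens = dens + 0.05 * rng.standard_normal(shape)

    layers = {
        "elevation": elev,
        "slope": slope,
        "relief": relief.values,
        "dist_river": river.values,
        "dist_road": road.values,
        "dist_railway": railway.values,
        "dist_residential": residential.values,
        "night_light": light,
        "pop_density": dens,
    }
    return {
        name: ContinuousGrid(cs, org, _normalize(vals))
        for name, vals in layers.items()
    }
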