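"""Urban-expansion analytics and simulation validation.

Expansion of a land class (construction, in the study design) is measured
per period by the annual increase index AI = (A_end − A_start)/d, in
km²/yr, and the average annual growth rate
AGR = 100·((A_end/A_start)^(1/d) − 1) in %/yr — absolute versus compound
expansion speed. Zonal breakdowns use four quadrants split at the class's
center of gravity and concentric distance rings (5 km bands by default).

Simulation accuracy against an observed map uses a seeded cell sample,
the confusion matrix, overall accuracy (trace share) and Cohen's kappa
(p_o − p_e)/(1 − p_e) with chance agreement p_e from the marginal
products; per-class accuracy is the recall of each observed class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import LAND_USE_CODES, LandUseGrid

QUADRANTS = ("NE", "NW", "SW", "SE")
OUTSIDE_RING = -1


def compute_ai(a_start: float, a_end: float, d: float) -> float:
    """Annual increase index, km²/yr."""
    if d <= 0:
        raise ValueError("period length must be positive")
    return (a_end - a_start) / d


def compute_agr(a_start: float, a_end: float, d: float) -> float:
    """Average annual growth rate, percent per year."""
    if d <= 0 or a_start <= 0:
        raise ValueError("need positive period length and starting area")
    return 100.0 * ((a_end / a_start) ** (1.0 / d) - 1.0)


def center_of_gravity(lu: LandUseGrid, cls: int) -> tuple[float, float]:
    """Unweighted mean map coordinate of the class's cell centers."""
    sel = (lu.codes == cls) & lu.valid_mask()
    if not sel.any():
        raise ValueError(f"class {cls} absent from the grid")
    x, y = lu.cell_centers()
    return float(x[sel].mean()), float(y[sel].mean())


@dataclass
class Zoning:
    labels: np.ndarray  # quadrant index 0..3 or ring index (OUTSIDE_RING = beyond)
    names: dict[int, str]
    center: tuple[float, float]
    cell_size: float

    def zones(self) -> list[int]:
        return [z for z in self.names if z != OUTSIDE_RING]


def make_zonings(
    lu: LandUseGrid,
    center: tuple[float, float],
    n_rings: int = 12,
    ring_width_m: float = 5000.0,
) -> tuple[Zoning, Zoning]:
    """Quadrant and ring zonings around a center point.

    Quadrants split at the N–S / E–W axes through the center; cells exactly
    on an axis join the counter-clockwise-first quadrant (NE gets x ≥ cx,
    y ≥ cy; NW gets x < cx, y ≥ cy; SW x < cx, y < cy; SE x ≥ cx, y < cy).
    Ring k covers radii [k·w, (k+1)·w); cells beyond the last ring are
    labeled OUTSIDE_RING and excluded from ring tables.
    """
    x, y = lu.cell_centers()
    cx, cy = center
    east, north = x >= cx, y >= cy
    quad = np.where(
        north, np.where(east, 0, 1), np.where(east, 3, 2)
    )
    qz = Zoning(quad, dict(enumerate(QUADRANTS)), center, lu.cell_size)
    r = np.hypot(x - cx, y - cy)
    ring = np.floor(r / ring_width_m).astype(int)
    ring[ring >= n_rings] = OUTSIDE_RING
    names = {
        k: f"{k * ring_width_m / 1000:g}-{(k + 1) * ring_width_m / 1000:g} km"
        for k in range(n_rings)
    }
    names[OUTSIDE_RING] = "outside"
    rz = Zoning(ring, names, center, lu.cell_size)
    return qz, rz


def zonal_series(
    grids: dict[str, LandUseGrid],
    zoning: Zoning,
    cls: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-zone class area/proportion per epoch, AI/AGR per epoch pair.

    Returns ``(levels, changes)``: one row per zone × epoch, and one row
    per zone × consecutive epoch pair.

    ``grids`` maps epoch labels (ordered) to land-use grids sharing one
    frame. Epoch labels that parse as numbers set the period lengths;
    otherwise consecutive epochs are treated as one year apart.
    """
    epochs = list(grids)
    rows = []
    cell_km2 = next(iter(grids.values())).cell_area_km2
    for zone in zoning.zones():
        in_zone = zoning.labels == zone
        for ep in epochs:
            lu = grids[ep]
            valid = lu.valid_mask() & in_zone
            zone_km2 = valid.sum() * cell_km2
            area = np.sum(lu.codes[valid] == cls) * cell_km2
            rows.append(
                {
                    "zone": zoning.names[zone],
                    "epoch": ep,
                    "area_km2": area,
                    "zone_area_km2": zone_km2,
                    "proportion_pct": 100.0 * area / zone_km2 if zone_km2 else 0.0,
                }
            )
    table = pd.DataFrame(rows)
    pairs = []
    for e0, e1 in zip(epochs, epochs[1:]):
        try:
            d = float(e1) - float(e0)
        except ValueError:
            d = 1.0
        for zone in zoning.zones():
            name = zoning.names[zone]
            a0 = float(
                table.query("zone == @name and epoch == @e0").area_km2.iloc[0]
            )
            a1 = float(
                table.query("zone == @name and epoch == @e1").area_km2.iloc[0]
            )
            pairs.append(
                {
                    "zone": name,
                    "period": f"{e0}-{e1}",
                    "a_start_km2": a0,
                    "a_end_km2": a1,
                    "d_years": d,
                    "ai_km2_per_yr": compute_ai(a0, a1, d),
                    "agr_pct": compute_agr(a0, a1, d) if a0 > 0 else np.nan,
                }
            )
    changes = pd.DataFrame(
        pairs,
        columns=[
            "zone", "period", "a_start_km2", "a_end_km2",
            "d_years", "ai_km2_per_yr", "agr_pct",
        ],
    )
    return table, changes


@dataclass
class ValidationReport:
    kappa: float
    overall_accuracy: float
    per_class_accuracy: dict[int, float]
    confusion: np.ndarray  # rows = actual, cols = simulated
    sample_fraction: float
    seed: int


def kappa_validate(
    actual: LandUseGrid,
    simulated: LandUseGrid,
    fraction: float = 0.1,
    seed: int = 0,
) -> ValidationReport:
    """Chance-corrected agreement on a seeded sample of valid cells."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if not actual.same_frame(simulated):
        raise ValueError("grids must share a frame")
    valid = np.flatnonzero(
        (actual.valid_mask() & simulated.valid_mask()).ravel()
    )
    rng = np.random.default_rng(seed)
    n = max(1, int(round(fraction * len(valid))))
    pick = rng.choice(valid, size=n, replace=False) if n < len(valid) else valid
    a = actual.codes.ravel()[pick] - 1
    s = simulated.codes.ravel()[pick] - 1
    k = len(LAND_USE_CODES)
    conf = np.zeros((k, k))
    np.add.at(conf, (a, s), 1.0)
    total = conf.sum()
    p_o = np.trace(conf) / total
    p_e = float(np.sum(conf.sum(axis=1) * conf.sum(axis=0)) / total**2)
    kappa = (p_o - p_e) / (1 - p_e) if p_e < 1 else 1.0
    rowsum = conf.sum(axis=1)
    per_class = {
        c: float(conf[i, i] / rowsum[i]) if rowsum[i] else np.nan
        for i, c in enumerate(LAND_USE_CODES)
    }
    return ValidationReport(
        float(kappa), float(p_o), per_class, conf, fraction, seed
    )
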