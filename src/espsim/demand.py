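"""Markov-chain land demand: transition estimation and projection.

The per-class demand at a horizon year comes from a first-order Markov
chain: the transition matrix is the observed cell-level cross-tabulation
between two epochs, and demands are the base-epoch class counts propagated
by the matrix raised to horizon/interval. Non-integer exponents use the
real fractional matrix power (eigendecomposition); if that root carries
negative entries — fractional roots of stochastic matrices need not be
stochastic — the projection falls back to exact integer-step powers with
linear interpolation of the counts between surrounding steps.

Demands are expressed in cells and rounded by largest-remainder
apportionment so they always sum to the total number of valid cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import fractional_matrix_power

from .grids import LAND_USE_CODES, LandUseGrid

K = len(LAND_USE_CODES)


@dataclass
class TransitionMatrix:
    matrix: np.ndarray  # K x K row-stochastic
    interval_years: float

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (K, K):
            raise ValueError(f"transition matrix must be {K}x{K}")
        if (m < -1e-12).any():
            raise ValueError("transition probabilities must be non-negative")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("rows must sum to 1")
        if self.interval_years <= 0:
            raise ValueError("interval_years must be positive")
        self.matrix = m


@dataclass
class DemandVector:
    counts: np.ndarray  # per-class cell counts, ordered by LAND_USE_CODES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if (self.counts < 0).any():
            raise ValueError("demands must be non-negative")

    def as_dict(self) -> dict[int, int]:
        return {c: int(n) for c, n in zip(LAND_USE_CODES, self.counts)}

    def total(self) -> int:
        return int(self.counts.sum())


def estimate_transition_matrix(
    lu_t1: LandUseGrid, lu_t2: LandUseGrid, interval_years: float = 1.0
) -> TransitionMatrix:
    """Observed cell-level transition frequencies between two epochs.

    Entry (i, j) = count(class i at t1 and j at t2) / count(class i at t1);
    classes absent at t1 get an identity row.
    """
    if not lu_t1.same_frame(lu_t2):
        raise ValueError("epoch grids must share a frame")
    valid = lu_t1.valid_mask() & lu_t2.valid_mask()
    i = lu_t1.codes[valid] - 1
    j = lu_t2.codes[valid] - 1
    counts = np.zeros((K, K))
    np.add.at(counts, (i, j), 1.0)
    rowsum = counts.sum(axis=1)
    m = np.eye(K)
    nz = rowsum > 0
    m[nz] = counts[nz] / rowsum[nz, None]
    return TransitionMatrix(m, interval_years)


def _largest_remainder(fractional: np.ndarray, total: int) -> np.ndarray:
    floors = np.floor(fractional).astype(int)
    short = total - floors.sum()
    order = np.argsort(-(fractional - floors))
    floors[order[:short]] += 1
    return floors


def project_demand(
    tm: TransitionMatrix, base: LandUseGrid, horizon_years: float
) -> DemandVector:
    """Per-class cell demands ``horizon_years`` after the base epoch."""
    if horizon_years <= 0:
        raise ValueError("horizon_years must be positive")
    counts0 = np.array(
        [base.class_counts()[c] for c in LAND_USE_CODES], dtype=float
    )
    total = int(counts0.sum())
    power = horizon_years / tm.interval_years
    target = None
    if abs(power - round(power)) < 1e-9:
        target = counts0 @ np.linalg.matrix_power(tm.matrix, int(round(power)))
    else:
        mp = fractional_matrix_power(tm.matrix, power)
        if np.isrealobj(mp) or np.allclose(mp.imag, 0, atol=1e-9):
            mp = np.real(mp)
            if (mp >= -1e-9).all():
                mp = np.clip(mp, 0, None)
                mp /= mp.sum(axis=1, keepdims=True)
                target = counts0 @ mp
        if target is None:
            lo = int(np.floor(power))
            frac = power - lo
            c_lo = counts0 @ np.linalg.matrix_power(tm.matrix, lo)
            c_hi = c_lo @ tm.matrix
            target = (1 - frac) * c_lo + frac * c_hi
    return DemandVector(_largest_remainder(target, total))
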