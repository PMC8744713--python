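"""ANN-CA allocation: suitability, neighborhood, inertia, roulette.

The future-land-use engine works in two stages. A single-hidden-layer
feed-forward network is fitted on a seeded sample of cells (driving-factor
vector → observed class) and produces a per-class occurrence-probability
stack. Allocation then iterates a cellular-automaton sweep: every
convertible cell gets a joint score per class —

    suitability × neighborhood effect × class inertia × transfer permission

— a candidate class is drawn for each cell by roulette (probability
proportional to the score), and the conversion is committed only while it
moves both class budgets toward the demand vector (target class still
under-supplied, source class over-supplied). Restricted cells and
forbidden transfers never change. The adaptive inertia coefficient of a
class grows when its residual demand worsens between sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.neural_network import MLPClassifier

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
)

K = len(LAND_USE_CODES)

#: Neighborhood weights per class (arable, woodland, grassland, water,
#: construction, unused).
NEIGHBORHOOD_WEIGHTS = {
    ARABLE: 0.1,
    WOODLAND: 0.23,
    GRASSLAND: 0.35,
    WATER: 0.5,
    CONSTRUCTION: 1.0,
    UNUSED: 0.4,
}

#: 0/1 transfer permissions, rows = from, cols = to, class order 1..6.
#: Natural development: most conversions allowed; water accepts only from
#: arable/water/unused rows per the scenario design; unused land may not be
#: created from arable/woodland/construction.
TRANSFER_NATURAL = np.array(
    [
        [1, 1, 1, 1, 1, 0],  # arable
        [1, 1, 1, 0, 1, 0],  # woodland
        [1, 1, 1, 0, 1, 1],  # grassland
        [1, 1, 1, 1, 1, 1],  # water
        [1, 1, 1, 0, 1, 0],  # construction
        [1, 1, 1, 1, 1, 1],  # unused
    ]
)

#: Ecological security: additionally forbids woodland → arable/construction
#: and grassland → arable.
TRANSFER_ECOLOGICAL = np.array(
    [
        [1, 1, 1, 1, 1, 0],
        [0, 1, 1, 0, 0, 0],
        [0, 1, 1, 0, 1, 1],
        [1, 1, 1, 1, 1, 1],
        [1, 1, 1, 0, 1, 0],
        [1, 1, 1, 1, 1, 1],
    ]
)


@dataclass
class SuitabilityStack:
    probs: np.ndarray  # (rows, cols, K), rows sum to 1 on valid cells
    sample_fraction: float
    seed: int
    hidden_units: int

    def __post_init__(self) -> None:
        if self.probs.ndim != 3 or self.probs.shape[2] != K:
            raise ValueError(f"suitability stack must be (r, c, {K})")


@dataclass
class ScenarioConfig:
    name: str = "natural"
    transfer_matrix: np.ndarray = field(
        default_factory=lambda: TRANSFER_NATURAL.copy()
    )
    restricted: BinaryMask | None = None
    neighborhood_weights: dict[int, float] = field(
        default_factory=lambda: dict(NEIGHBORHOOD_WEIGHTS)
    )
    window: int = 3
    neighborhood_floor: float = 1e-3
    max_iterations: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.transfer_matrix)
        if t.shape != (K, K) or not np.isin(t, (0, 1)).all():
            raise ValueError("transfer matrix must be a 6x6 0/1 table")
        if not (np.diag(t) == 1).all():
            raise ValueError("transfer matrix diagonal must be 1 (self-transfer)")
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be a positive odd integer")
        if any(w <= 0 for w in self.neighborhood_weights.values()):
            raise ValueError("neighborhood weights must be positive")
        self.transfer_matrix = t.astype(float)


# ---------------------------------------------------------------------------
# Suitability


def sample_training(
    lu: LandUseGrid,
    factors: dict[str, ContinuousGrid],
    fraction: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform seeded sample of valid cells: (factor matrix X, labels y)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    valid = np.flatnonzero(lu.valid_mask().ravel())
    rng = np.random.default_rng(seed)
    n = max(1, int(round(fraction * len(valid))))
    pick = rng.choice(valid, size=n, replace=False) if n < len(valid) else valid
    stack = np.stack([f.values.ravel() for f in factors.values()], axis=1)
    return stack[pick], lu.codes.ravel()[pick]


def fit_suitability(
    X: np.ndarray, y: np.ndarray, hidden_units: int = 12, seed: int = 0
) -> MLPClassifier:
    """Single-hidden-layer network with softmax output over the classes."""
    if len(np.unique(y)) < 2:
        raise ValueError("training sample contains a single class")
    model = MLPClassifier(
        hidden_layer_sizes=(hidden_units,),
        max_iter=600,
        random_state=seed,
        learning_rate_init=0.01,
    )
    model.fit(X, y)
    return model


def predict_suitability(
    model: MLPClassifier,
    factors: dict[str, ContinuousGrid],
    sample_fraction: float = 0.05,
    seed: int = 0,
) -> SuitabilityStack:
    first = next(iter(factors.values()))
    shape = first.shape
    stack = np.stack([f.values.ravel() for f in factors.values()], axis=1)
    proba = model.predict_proba(stack)
    full = np.zeros((stack.shape[0], K))
    for col, cls in enumerate(model.classes_):
        full[:, int(cls) - 1] = proba[:, col]
    full /= full.sum(axis=1, keepdims=True)
    hidden = model.hidden_layer_sizes
    hidden_units = hidden[0] if isinstance(hidden, (tuple, list)) else int(hidden)
    return SuitabilityStack(
        full.reshape(shape + (K,)), sample_fraction, seed, hidden_units
    )


# ---------------------------------------------------------------------------
# CA components


def neighborhood_effect(
    codes: np.ndarray, cls: int, window: int = 3, weight: float = 1.0
) -> np.ndarray:
    """Weighted fraction of class ``cls`` in the window, center excluded."""
    ind = (codes == cls).astype(float)
    total = ndimage.uniform_filter(ind, size=window, mode="constant") * window**2
    frac = (total - ind) / (window**2 - 1)
    return weight * frac


def update_inertia(inertia: float, d_prev1: float, d_prev2: float) -> float:
    """Adaptive inertia: grow when the residual demand of a class worsens.

    ``d_prev1`` is the residual (demand − count) after the last sweep,
    ``d_prev2`` after the sweep before it.
    """
    if abs(d_prev1) <= abs(d_prev2):
        return inertia
    if d_prev1 < d_prev2 < 0:
        return inertia * (d_prev2 / d_prev1)
    if 0 < d_prev2 < d_prev1:
        return inertia * (d_prev1 / d_prev2)
    return inertia


def combined_probability(
    suit: float,
    neigh: float,
    inertia: float,
    transfer_allowed: bool,
    restricted: bool = False,
    floor: float = 0.0,
) -> float:
    """Joint score of one (cell, class) pair; 0 when the move is barred."""
    if restricted or not transfer_allowed:
        return 0.0
    return suit * max(neigh, floor) * inertia


@dataclass
class AllocationResult:
    landuse: LandUseGrid
    residuals: np.ndarray  # demand - counts per class at exit
    iterations: int
    converged: bool


def allocate(
    base: LandUseGrid,
    suitability: SuitabilityStack,
    demand,
    scenario: ScenarioConfig,
    tolerance: int = 0,
) -> AllocationResult:
    """Roulette-wheel spatial allocation of the demand vector.

    Each sweep scores every convertible cell, draws one candidate class per
    cell by roulette, then visits the proposals in seeded random order and
    commits each conversion only while the target class is still
    under-supplied and the source class over-supplied — so class counts
    converge monotonically to the demands. Sweeps stop when every residual
    is within ``tolerance`` cells or after ``max_iterations``.

    Because commits never overshoot the demands, the residual of a class
    can plateau rather than worsen, which the adaptive inertia rule does
    not react to; a competition-escalation factor therefore doubles the
    roulette weight of any still-under-supplied class after each sweep
    that brings it no conversions (and resets once its demand is met), so
    rare-but-allowed conversions are eventually drawn wherever they are
    feasible. Classes whose demand is already met are excluded from the
    draw (a proposal toward them could never commit).
    """
    rng = np.random.default_rng(scenario.seed)
    codes = base.codes.copy()
    valid = base.valid_mask()
    restricted = (
        scenario.restricted.bits
        if scenario.restricted is not None
        else np.zeros_like(valid)
    )
    convertible = valid & ~restricted
    target = np.asarray(demand.counts, dtype=int)
    counts = np.array([np.sum(codes[valid] == c) for c in LAND_USE_CODES])
    if target.sum() != counts.sum():
        raise ValueError("demand must sum to the number of valid cells")
    weights = np.array([scenario.neighborhood_weights[c] for c in LAND_USE_CODES])
    inertia = np.ones(K)
    boost = np.ones(K)
    D = target - counts
    d_hist = [D.copy(), D.copy()]
    it = 0
    zero_streak = 0
    for it in range(1, scenario.max_iterations + 1):
        if np.abs(D).max() <= tolerance:
            break
        for k in range(K):
            inertia[k] = update_inertia(inertia[k], d_hist[-1][k], d_hist[-2][k])
        # Joint score stack for this sweep.
        neigh = np.stack(
            [
                neighborhood_effect(
                    codes, c, scenario.window, weights[i]
                ).clip(min=scenario.neighborhood_floor * weights[i])
                for i, c in enumerate(LAND_USE_CODES)
            ],
            axis=-1,
        )
        score = suitability.probs * neigh * (inertia * boost)
        idx = np.clip(codes - 1, 0, K - 1)
        score *= scenario.transfer_matrix[idx]
        # Drop classes whose demand is met from the draw, but keep each
        # cell's own class so staying put remains the default outcome.
        self_score = np.take_along_axis(score, idx[..., None], axis=-1)
        score = np.where((D > 0)[None, None, :], score, 0.0)
        np.put_along_axis(score, idx[..., None], self_score, axis=-1)
        # Only cells of over-supplied classes can legally convert.
        cand = convertible & (D[idx] < 0)
        flat = np.flatnonzero(cand.ravel())
        if len(flat) == 0:
            break
        s = score.reshape(-1, K)[flat]
        rowsum = s.sum(axis=1)
        ok = rowsum > 0
        flat, s, rowsum = flat[ok], s[ok], rowsum[ok]
        if len(flat) == 0:
            break
        u = rng.random(len(flat)) * rowsum
        drawn = (np.cumsum(s, axis=1) < u[:, None]).sum(axis=1)
        drawn = np.minimum(drawn, K - 1)
        cur = codes.ravel()[flat] - 1
        moving = drawn != cur
        order = rng.permutation(np.flatnonzero(moving))
        committed = 0
        gained = np.zeros(K, dtype=int)
        for m in order:
            src, tgt = cur[m], drawn[m]
            if D[tgt] > 0 and D[src] < 0:
                codes.ravel()[flat[m]] = tgt + 1
                D[tgt] -= 1
                D[src] += 1
                gained[tgt] += 1
                committed += 1
        stalled = (D > 0) & (gained == 0)
        boost[stalled] = np.minimum(boost[stalled] * 2.0, 1e12)
        boost[D <= 0] = 1.0
        d_hist.append(D.copy())
        # A roulette sweep can commit nothing by chance; only give up after
        # a sustained stall (likely infeasible under the constraints).
        zero_streak = zero_streak + 1 if committed == 0 else 0
        if zero_streak >= 60:  # past any escalation ramp: infeasible
            break
    out = LandUseGrid(
        base.cell_size, base.origin, codes, nodata=base.nodata
    )
    return AllocationResult(
        out, D.copy(), it, bool(np.abs(D).max() <= tolerance)
    )


def simulate_scenario(
    base: LandUseGrid,
    factors: dict[str, ContinuousGrid],
    demand,
    scenario: ScenarioConfig,
    sample_fraction: float = 0.05,
    hidden_units: int = 12,
    tolerance: int = 0,
) -> AllocationResult:
    """Demand → suitability → allocation for one named scenario."""
    X, y = sample_training(base, factors, sample_fraction, scenario.seed)
    model = fit_suitability(X, y, hidden_units, scenario.seed)
    suit = predict_suitability(model, factors, sample_fraction, scenario.seed)
    return allocate(base, suit, demand, scenario, tolerance)
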