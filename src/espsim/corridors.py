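"""Resistance surface, least-cost corridors, gravity model and ESP assembly.

The movement-resistance surface combines a land-use score (woodland and
water 1 … construction 100) with a topographic-relief score (flat terrain
resists dispersal of forest species most: <8 m relief scores 90, >50 m
scores 1), weighted 0.7 / 0.3. Minimum cumulative resistance (MCR) from
the sources is the least over 8-connected paths of Σ step_length ×
step_resistance, with step resistance the mean of the two endpoint cells
and step length cell_size (orthogonal) or cell_size·√2 (diagonal).

Corridor importance follows a gravity model
G = [ln(Sᵢ)/Pᵢ]·[ln(Sⱼ)/Pⱼ]·(L_max/Lᵢⱼ)², with Sᵢ the patch area (hm²),
Pᵢ its mean resistance, Lᵢⱼ the corridor's cumulative resistance and
L_max the maximum over all corridors. Touching patches (Lᵢⱼ = 0) get
G = +inf and are always retained.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
from dataclasses import dataclass, field
from scipy import ndimage, sparse
from scipy.sparse.csgraph import dijkstra

from .grids import (
    ARABLE,
    CONSTRUCTION,
    GRASSLAND,
    UNUSED,
    WATER,
    WOODLAND,
    BinaryMask,
    ContinuousGrid,
    LandUseGrid,
)
from .patches import Patch, PatchSet, label_mask

#: Land-use resistance scores.
LAND_USE_SCORES = {
    WOODLAND: 1.0,
    WATER: 1.0,
    GRASSLAND: 30.0,
    ARABLE: 50.0,
    UNUSED: 90.0,
    CONSTRUCTION: 100.0,
}

#: Relief-score bins: [0,8) -> 90, [8,17) -> 70, [17,27) -> 50,
#: [27,37) -> 30, [37,50) -> 10, [50,inf) -> 1 (left-closed bins).
RELIEF_EDGES = (8.0, 17.0, 27.0, 37.0, 50.0)
RELIEF_SCORES = (90.0, 70.0, 50.0, 30.0, 10.0, 1.0)

W_LAND_USE = 0.7
W_RELIEF = 0.3


@dataclass
class ResistanceSurface:
    values: np.ndarray
    lu_score: np.ndarray
    relief_score: np.ndarray
    weights: tuple[float, float]
    cell_size: float
    origin: tuple[float, float]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def as_grid(self) -> ContinuousGrid:
        return ContinuousGrid(self.cell_size, self.origin, self.values)


def build_resistance(
    landuse: LandUseGrid,
    relief: ContinuousGrid,
    w_lu: float = W_LAND_USE,
    w_relief: float = W_RELIEF,
) -> ResistanceSurface:
    if not landuse.same_frame(relief):
        raise ValueError("land use and relief grids must share a frame")
    lu_score = np.full(landuse.shape, np.nan)
    for code, score in LAND_USE_SCORES.items():
        lu_score[landuse.codes == code] = score
    invalid = np.isnan(lu_score) & landuse.valid_mask()
    if invalid.any():
        raise ValueError("undeclared land-use code in resistance scoring")
    bins = np.digitize(relief.values, RELIEF_EDGES, right=False)
    relief_score = np.asarray(RELIEF_SCORES)[bins]
    values = w_lu * lu_score + w_relief * relief_score
    values[~landuse.valid_mask()] = np.nan
    return ResistanceSurface(
        values, lu_score, relief_score, (w_lu, w_relief),
        landuse.cell_size, landuse.origin,
    )


# ---------------------------------------------------------------------------
# Cost distance on the 8-connected lattice

_SHIFTS = [(0, 1, 1.0), (1, 0, 1.0), (1, 1, np.sqrt(2)), (1, -1, np.sqrt(2))]


def _lattice_graph(res: ResistanceSurface) -> sparse.csr_matrix:
    r = res.values
    rows, cols = r.shape
    n = rows * cols
    idx = np.arange(n).reshape(rows, cols)
    data, ii, jj = [], [], []
    for dr, dc, f in _SHIFTS:
        r0, r1 = max(0, -dr), rows - max(0, dr)
        c0, c1 = max(0, -dc), cols - max(0, dc)
        if r1 <= r0 or c1 <= c0:
            continue
        a = idx[r0:r1, c0:c1].ravel()
        b = idx[r0 + dr: r1 + dr, c0 + dc: c1 + dc].ravel()
        w = 0.5 * (r.ravel()[a] + r.ravel()[b]) * f * res.cell_size
        ok = np.isfinite(w)
        ii.append(a[ok])
        jj.append(b[ok])
        data.append(w[ok])
    return sparse.csr_matrix(
        (np.concatenate(data), (np.concatenate(ii), np.concatenate(jj))),
        shape=(n, n),
    )


def _from_super_source(
    g: sparse.csr_matrix, src: np.ndarray, predecessors: bool = False
):
    """Dijkstra from a zero-cost virtual node wired to ``src`` cells."""
    n = g.shape[0]
    super_row = sparse.csr_matrix(
        (np.full(len(src), 1e-12), (np.zeros(len(src), dtype=int), src)),
        shape=(1, n),
    )
    aug = sparse.vstack(
        [
            sparse.hstack([g, sparse.csr_matrix((n, 1))]),
            sparse.hstack([super_row, sparse.csr_matrix((1, 1))]),
        ]
    ).tocsr()
    return dijkstra(
        aug, directed=False, indices=n, return_predecessors=predecessors
    )


def cost_distance(res: ResistanceSurface, sources: BinaryMask) -> ContinuousGrid:
    """Minimum cumulative resistance from the nearest source cell."""
    if not sources.bits.any():
        raise ValueError("cost distance requires at least one source cell")
    g = _lattice_graph(res)
    src = np.flatnonzero(sources.bits.ravel())
    dist = _from_super_source(g, src)
    out = dist[: g.shape[0]].reshape(res.shape)
    out[sources.bits] = 0.0
    return ContinuousGrid(res.cell_size, res.origin, out)


@dataclass
class CorridorPath:
    i: int
    j: int
    cells: np.ndarray  # (n, 2) row/col polyline
    cost: float  # cumulative resistance L_ij
    length_m: float  # spatial path length
    gravity: float = np.nan


def least_cost_path(
    res: ResistanceSurface, patch_i: Patch, patch_j: Patch
) -> CorridorPath:
    """Minimal-cumulative-cost path between two patches (boundary to boundary)."""
    paths = corridors_from(res, patch_i, [patch_j])
    if not paths:
        raise ValueError(f"no finite path between patches {patch_i.id} and {patch_j.id}")
    return paths[0]


def corridors_from(
    res: ResistanceSurface, patch_i: Patch, others: list[Patch]
) -> list[CorridorPath]:
    """Least-cost paths from one patch to each of several others with a
    single shortest-path solve (multi-source over patch_i's boundary)."""
    g = _lattice_graph(res)
    n = g.shape[0]
    cols = res.shape[1]
    src = patch_i.boundary[:, 0] * cols + patch_i.boundary[:, 1]
    dist, pred = _from_super_source(g, src, predecessors=True)
    out = []
    for other in others:
        tgt_nodes = other.boundary[:, 0] * cols + other.boundary[:, 1]
        d = dist[tgt_nodes]
        if not np.isfinite(d).any():
            continue
        best = tgt_nodes[int(np.argmin(d))]
        nodes = [best]
        while pred[nodes[-1]] >= 0 and pred[nodes[-1]] != n:
            nodes.append(pred[nodes[-1]])
        cells = np.array([(v // cols, v % cols) for v in reversed(nodes)])
        steps = np.abs(np.diff(cells, axis=0))
        length = float(
            np.sum(np.where(steps.sum(axis=1) == 2, np.sqrt(2), 1.0) * res.cell_size)
        ) if len(cells) > 1 else 0.0
        out.append(
            CorridorPath(patch_i.id, other.id, cells, float(d.min()), length)
        )
    return out


def all_corridors(res: ResistanceSurface, sources: PatchSet) -> list[CorridorPath]:
    """Least-cost corridor for every unordered pair of source patches."""
    plist = list(sources)
    paths = []
    for a in range(len(plist)):
        paths.extend(corridors_from(res, plist[a], plist[a + 1:]))
    return paths


# ---------------------------------------------------------------------------
# Gravity model


def gravity_interaction(
    s_i: float, s_j: float, p_i: float, p_j: float, l_ij: float, l_max: float
) -> float:
    """G = [ln(Sᵢ)/Pᵢ]·[ln(Sⱼ)/Pⱼ]·(L_max/Lᵢⱼ)²; +inf for touching patches."""
    if s_i <= 0 or s_j <= 0:
        raise ValueError("patch areas must be positive")
    if l_ij == 0:
        return float("inf")
    return (np.log(s_i) / p_i) * (np.log(s_j) / p_j) * (l_max / l_ij) ** 2


@dataclass
class GravityMatrix:
    paths: list[CorridorPath]
    patch_resistance: dict[int, float]
    patch_area_hm2: dict[int, float]
    l_max: float

    def as_records(self) -> list[dict]:
        return [
            {"i": p.i, "j": p.j, "L": p.cost, "length_m": p.length_m, "G": p.gravity}
            for p in self.paths
        ]


def gravity_matrix(
    paths: list[CorridorPath], sources: PatchSet, res: ResistanceSurface
) -> GravityMatrix:
    p_res = {
        p.id: float(np.nanmean(res.values[p.cells[:, 0], p.cells[:, 1]]))
        for p in sources
    }
    areas = {p.id: p.area_hm2 for p in sources}
    finite = [p.cost for p in paths if p.cost > 0]
    l_max = max(finite) if finite else 1.0
    for p in paths:
        p.gravity = gravity_interaction(
            areas[p.i], areas[p.j], p_res[p.i], p_res[p.j], p.cost, l_max
        )
    return GravityMatrix(paths, p_res, areas, l_max)


def select_corridors(
    gm: GravityMatrix,
    rule: str = "top_k",
    k: int | None = None,
    g_min: float | None = None,
) -> list[CorridorPath]:
    """Retain corridors by gravity rank, always keeping a spanning set.

    ``top_k`` keeps the k highest-G corridors; ``threshold`` keeps those
    with G >= g_min. A maximum-G spanning forest over the sources is added
    in either case so no source is isolated.
    """
    ranked = sorted(gm.paths, key=lambda p: -p.gravity)
    if rule == "top_k":
        kk = len(ranked) if k is None else k
        chosen = ranked[:kk]
    elif rule == "threshold":
        if g_min is None:
            raise ValueError("threshold rule requires g_min")
        chosen = [p for p in ranked if p.gravity >= g_min]
    else:
        raise ValueError(f"unknown corridor selection rule {rule!r}")
    g = nx.Graph()
    for p in gm.paths:
        w = p.gravity if np.isfinite(p.gravity) else 1e30
        g.add_edge(p.i, p.j, weight=-w, path=p)
    spanning = {
        (min(u, v), max(u, v))
        for u, v, _ in nx.minimum_spanning_edges(g, data=True)
    } if g.number_of_edges() else set()
    keep = {(min(p.i, p.j), max(p.i, p.j)) for p in chosen} | spanning
    return [p for p in gm.paths if (min(p.i, p.j), max(p.i, p.j)) in keep]


# ---------------------------------------------------------------------------
# Buffers, rivers, nodes, assembly


def buffer_paths(
    paths: list[CorridorPath],
    radius_m: float,
    like: ResistanceSurface | ContinuousGrid,
) -> BinaryMask:
    """Cells whose center lies within ``radius_m`` of any path cell center."""
    bits = np.zeros(like.shape, dtype=bool)
    for p in paths:
        bits[p.cells[:, 0], p.cells[:, 1]] = True
    mask = BinaryMask(like.cell_size, like.origin, bits)
    if radius_m <= 0 or not bits.any():
        return mask
    dist = ndimage.distance_transform_edt(~bits) * like.cell_size
    return BinaryMask(like.cell_size, like.origin, dist <= radius_m)


def component_length_width(cells: np.ndarray, cell_size: float) -> tuple[float, float]:
    """Principal-axis length (m) and mean width = area/length (m)."""
    pts = cells.astype(float)
    if len(pts) == 1:
        return cell_size, cell_size
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    proj = centered @ vt[0]
    length = (proj.max() - proj.min() + 1.0) * cell_size
    width = len(pts) * cell_size**2 / length
    return float(length), float(width)


def river_corridors(
    water_mask: BinaryMask,
    min_width_m: float = 30.0,
    min_length_m: float = 5000.0,
) -> BinaryMask:
    """Water components long and wide enough to act as corridors."""
    out = np.zeros(water_mask.bits.shape, dtype=bool)
    for patch in label_mask(water_mask):
        length, width = component_length_width(patch.cells, water_mask.cell_size)
        if length > min_length_m and width > min_width_m:
            out[patch.cells[:, 0], patch.cells[:, 1]] = True
    return BinaryMask(water_mask.cell_size, water_mask.origin, out)


def select_nodes(
    cores: PatchSet,
    source_core_ids: list[int],
    n: int = 7,
    corridor_mask: BinaryMask | None = None,
    max_dist_m: float | None = None,
) -> PatchSet:
    """Top-n non-source core patches by area — the "stepping stones".

    Optionally restricted to patches within ``max_dist_m`` of the selected
    corridors. A rule-based surrogate for what is, in practice, an
    expert-judgment selection.
    """
    candidates = [p for p in cores if p.id not in set(source_core_ids)]
    if corridor_mask is not None and max_dist_m is not None and corridor_mask.bits.any():
        dist = ndimage.distance_transform_edt(~corridor_mask.bits) * cores.cell_size
        candidates = [
            p for p in candidates
            if dist[p.cells[:, 0], p.cells[:, 1]].min() <= max_dist_m
        ]
    candidates.sort(key=lambda p: -p.area_hm2)
    return cores.subset([p.id for p in candidates[:n]])


@dataclass
class EcologicalSecurityPattern:
    sources: BinaryMask
    corridors: BinaryMask
    nodes: BinaryMask
    restricted: BinaryMask = field(init=False)

    def __post_init__(self) -> None:
        self.restricted = self.sources | self.corridors | self.nodes


def assemble_esp(
    source_mask: BinaryMask,
    corridor_mask: BinaryMask,
    river_mask: BinaryMask | None = None,
    node_mask: BinaryMask | None = None,
) -> EcologicalSecurityPattern:
    corr = corridor_mask if river_mask is None else corridor_mask | river_mask
    nodes = node_mask if node_mask is not None else BinaryMask.empty_like(source_mask)
    return EcologicalSecurityPattern(source_mask, corr, nodes)
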