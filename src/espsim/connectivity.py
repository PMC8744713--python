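"""Patch-graph connectivity: the probability-of-connectivity index.

PC = Σᵢ Σⱼ pᵢⱼ aᵢ aⱼ / AL², summed over all ordered patch pairs including
i = j, where pᵢⱼ is the maximum over all patch paths of the product of
direct dispersal probabilities and AL is the total habitat area (sum of
patch areas; a config switch selects the total-landscape-area convention
instead). The direct probability follows a negative-exponential kernel
p(d) = exp(−k·d) calibrated so that p(threshold) = p_thr — the standard
reading of a "distance threshold 1500 m, probability 0.5" pair; a hard
threshold mode (p = p_thr below the threshold, else 0) is also provided.

dPC_k = 100 · (PC − PC_remove,k)/PC, the percent loss of PC when patch k
is removed; AL is held fixed under removal (only paths through k are
lost), which keeps dPC within [0, 100].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path
from scipy.spatial import cKDTree

from .patches import Patch, PatchSet

#: Direct probabilities below this are pruned from the path graph.
PRUNE_P = 1e-9


def patch_distance(a: Patch, b: Patch, cell_size: float) -> float:
    """Minimum Euclidean distance (m) between boundary-cell centers; 0 if
    the patches touch (share an 8-adjacency)."""
    if a.id == b.id and a is b:
        return 0.0
    ta = cKDTree(a.boundary * cell_size)
    d, _ = ta.query(b.boundary * cell_size)
    dmin = float(d.min())
    if dmin <= cell_size * np.sqrt(2) + 1e-9:  # adjacent cells => touching
        return 0.0
    return dmin


def direct_probability(
    d: float | np.ndarray,
    threshold: float = 1500.0,
    p_thr: float = 0.5,
    mode: str = "kernel",
) -> float | np.ndarray:
    """Dispersal probability for an edge-to-edge distance ``d`` in meters."""
    if mode == "kernel":
        k = -np.log(p_thr) / threshold
        return np.exp(-k * np.asarray(d, dtype=float))
    if mode == "hard":
        return np.where(np.asarray(d, dtype=float) <= threshold, p_thr, 0.0)
    raise ValueError(f"unknown dispersal mode {mode!r}")


@dataclass
class ConnectivityGraph:
    ids: list[int]
    areas_hm2: np.ndarray
    direct_p: np.ndarray  # symmetric, unit diagonal
    AL_hm2: float
    distance_threshold: float
    p_at_threshold: float

    def __post_init__(self) -> None:
        p = self.direct_p
        if not np.allclose(p, p.T):
            raise ValueError("direct probabilities must be symmetric")
        if not np.allclose(np.diag(p), 1.0):
            raise ValueError("p_ii must equal 1")


def build_graph(
    patches: PatchSet,
    threshold: float = 1500.0,
    p_thr: float = 0.5,
    mode: str = "kernel",
    AL_hm2: float | None = None,
) -> ConnectivityGraph:
    """Pairwise direct dispersal probabilities between all patches.

    ``AL_hm2`` defaults to the sum of patch areas (the "total area of all
    patches" convention); pass the landscape area to use the reference-
    software convention instead.
    """
    n = len(patches)
    areas = np.array([p.area_hm2 for p in patches])
    dp = np.eye(n)
    plist = list(patches)
    for i in range(n):
        for j in range(i + 1, n):
            d = patch_distance(plist[i], plist[j], patches.cell_size)
            dp[i, j] = dp[j, i] = direct_probability(d, threshold, p_thr, mode)
    al = float(areas.sum()) if AL_hm2 is None else float(AL_hm2)
    return ConnectivityGraph(patches.ids(), areas, dp, al, threshold, p_thr)


def _max_product_matrix(direct_p: np.ndarray) -> np.ndarray:
    """pᵢⱼ* = max over paths of the product of step probabilities.

    Solved as all-pairs shortest paths on −ln(p) edge weights; direct
    probabilities below PRUNE_P are treated as no edge.
    """
    with np.errstate(divide="ignore"):
        w = -np.log(direct_p)
    w[direct_p < PRUNE_P] = np.inf
    np.fill_diagonal(w, 0.0)
    dist = shortest_path(w, method="D", directed=False)
    return np.exp(-dist)


def max_product_probability(graph: ConnectivityGraph, i: int, j: int) -> float:
    """Maximum path probability between patch ids ``i`` and ``j``."""
    ii, jj = graph.ids.index(i), graph.ids.index(j)
    return float(_max_product_matrix(graph.direct_p)[ii, jj])


def compute_pc(graph: ConnectivityGraph) -> float:
    pstar = _max_product_matrix(graph.direct_p)
    a = graph.areas_hm2
    return float(np.sum(pstar * np.outer(a, a)) / graph.AL_hm2**2)


def compute_dpc(graph: ConnectivityGraph, k: int) -> float:
    """Percent loss of PC when patch ``k`` (by id) is removed; AL fixed."""
    pc = compute_pc(graph)
    kk = graph.ids.index(k)
    keep = np.arange(len(graph.ids)) != kk
    sub = graph.direct_p[np.ix_(keep, keep)]
    a = graph.areas_hm2[keep]
    pc_rm = float(np.sum(_max_product_matrix(sub) * np.outer(a, a)) / graph.AL_hm2**2)
    return 100.0 * (pc - pc_rm) / pc


@dataclass
class DPCTable:
    table: pd.DataFrame  # columns: patch_id, area_hm2, dpc
    pc: float

    def dpc_of(self, pid: int) -> float:
        row = self.table.loc[self.table.patch_id == pid, "dpc"]
        return float(row.iloc[0])


def dpc_table(graph: ConnectivityGraph) -> DPCTable:
    pc = compute_pc(graph)
    rows = [
        {"patch_id": pid, "area_hm2": a, "dpc": compute_dpc(graph, pid)}
        for pid, a in zip(graph.ids, graph.areas_hm2)
    ]
    return DPCTable(pd.DataFrame(rows, columns=["patch_id", "area_hm2", "dpc"]), pc)


# ---------------------------------------------------------------------------
# Source selection


def patch_elongation(patch: Patch) -> float:
    """length² / area in cell units, length = extent along the principal axis."""
    cells = patch.cells.astype(float)
    if len(cells) == 1:
        return 1.0
    centered = cells - cells.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    proj = centered @ vt[0]
    length = proj.max() - proj.min() + 1.0
    return float(length**2 / len(cells))


def is_river(
    patch: Patch,
    elongation_threshold: float = 10.0,
    river_mask: np.ndarray | None = None,
) -> bool:
    if river_mask is not None and river_mask[patch.cells[:, 0], patch.cells[:, 1]].any():
        return True
    return patch_elongation(patch) > elongation_threshold


@dataclass
class SourceSelection:
    sources: PatchSet  # re-numbered union of selected cores and water bodies
    core_ids: list[int]  # ids in the *core* PatchSet that were selected
    water_ids: list[int]  # ids in the *water* PatchSet that were selected


def select_sources(
    cores: PatchSet,
    dpc: DPCTable,
    water_patches: PatchSet | None = None,
    dpc_min: float = 1.0,
    water_min_area_hm2: float = 100.0,
    elongation_threshold: float = 10.0,
    river_mask: np.ndarray | None = None,
) -> SourceSelection:
    """Cores with dPC above threshold plus large non-river water bodies."""
    core_ids = [
        p.id for p in cores if p.id in dpc.table.patch_id.values
        and dpc.dpc_of(p.id) > dpc_min
    ]
    water_ids: list[int] = []
    if water_patches is not None:
        for p in water_patches:
            if p.area_hm2 > water_min_area_hm2 and not is_river(
                p, elongation_threshold, river_mask
            ):
                water_ids.append(p.id)
    merged: list[Patch] = []
    nid = 0
    for p in cores:
        if p.id in core_ids:
            nid += 1
            merged.append(Patch(nid, p.area_hm2, p.cells, p.boundary))
    if water_patches is not None:
        for p in water_patches:
            if p.id in water_ids:
                nid += 1
                merged.append(Patch(nid, p.area_hm2, p.cells, p.boundary))
    if not merged:
        warnings.warn("no ecological sources selected", stacklevel=2)
    sources = PatchSet(merged, cores.cell_size, cores.origin, cores.shape)
    return SourceSelection(sources, core_ids, water_ids)
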