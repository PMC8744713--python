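import numpy as np
import networkx as nx
import pytest

from espsim import corridors
from espsim.grids import (
    ARABLE,
    CONSTRUCTION,
    WOODLAND,
    BinaryMask,
    ContinuousGrid,
    LandUseGrid,
)
from espsim.patches import label_mask

from conftest import make_continuous, make_mask


def uniform_resistance(shape, value, cell_size=30.0):
    return corridors.ResistanceSurface(
        np.full(shape, float(value)),
        np.full(shape, float(value)),
        np.full(shape, float(value)),
        (0.7, 0.3),
        cell_size,
        (0.0, 0.0),
    )


def random_resistance(rng, shape, cell_size=30.0):
    vals = rng.uniform(1, 100, shape)
    return corridors.ResistanceSurface(
        vals, vals, vals, (0.7, 0.3), cell_size, (0.0, 0.0)
    )


def networkx_cost_oracle(res, source_cells):
    """Explicit-graph shortest path (independent of the lattice solver)."""
    rows, cols = res.shape
    g = nx.Graph()
    for i in range(rows):
        for j in range(cols):
            for di, dj in ((0, 1), (1, 0), (1, 1), (1, -1)):
                ni, nj = i + di, j + dj
                if 0 <= ni < rows and 0 <= nj < cols:
                    step = np.sqrt(2) if di and dj else 1.0
                    w = 0.5 * (res.values[i, j] + res.values[ni, nj]) * step * res.cell_size
                    g.add_edge((i, j), (ni, nj), weight=w)
    dist = nx.multi_source_dijkstra_path_length(g, set(map(tuple, source_cells)))
    out = np.full(res.shape, np.inf)
    for (i, j), d in dist.items():
        out[i, j] = d
    return out


class TestResistance:
    def test_hand_arithmetic_on_score_table(self):
        lu = LandUseGrid(30.0, (0.0, 0.0), np.array([[WOODLAND, CONSTRUCTION]]))
        relief = make_continuous(np.array([[60.0, 5.0]]))
        res = corridors.build_resistance(lu, relief)
        assert res.values[0, 0] == pytest.approx(0.7 * 1 + 0.3 * 1)  # 1.0
        assert res.values[0, 1] == pytest.approx(0.7 * 100 + 0.3 * 90)  # 97.0

    def test_values_bounded(self, rng):
        lu = LandUseGrid(30.0, (0.0, 0.0), rng.integers(1, 7, (15, 15)))
        relief = make_continuous(rng.uniform(0, 80, (15, 15)))
        res = corridors.build_resistance(lu, relief)
        assert res.values.min() >= 1.0
        assert res.values.max() <= 100.0

    def test_relief_bins(self):
        lu = LandUseGrid(30.0, (0.0, 0.0), np.full((1, 6), WOODLAND))
        relief = make_continuous(np.array([[0.0, 10.0, 20.0, 30.0, 40.0, 55.0]]))
        res = corridors.build_resistance(lu, relief)
        assert list(res.relief_score[0]) == [90, 70, 50, 30, 10, 1]

    def test_frame_mismatch_rejected(self):
        lu = LandUseGrid(30.0, (0.0, 0.0), np.full((3, 3), ARABLE))
        relief = make_continuous(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            corridors.build_resistance(lu, relief)


class TestCostDistance:
    def test_sources_zero_and_one_step(self):
        res = uniform_resistance((3, 3), 4.0)
        src = np.zeros((3, 3), dtype=bool)
        src[1, 1] = True
        cd = corridors.cost_distance(res, make_mask(src))
        assert cd.values[1, 1] == 0.0
        assert cd.values[1, 2] == pytest.approx(4.0 * 30.0)
        assert cd.values[0, 0] == pytest.approx(4.0 * 30.0 * np.sqrt(2))

    def test_empty_sources_rejected(self):
        with pytest.raises(ValueError):
            corridors.cost_distance(
                uniform_resistance((3, 3), 1.0),
                make_mask(np.zeros((3, 3), dtype=bool)),
            )

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_explicit_graph_oracle(self, seed):
        rng = np.random.default_rng(seed)
        res = random_resistance(rng, (20, 20))
        src = rng.random((20, 20)) < 0.05
        src[0, 0] = True
        cd = corridors.cost_distance(res, make_mask(src))
        oracle = networkx_cost_oracle(res, np.argwhere(src))
        assert np.allclose(cd.values, oracle)

    def test_monotone_in_resistance(self):
        rng = np.random.default_rng(7)
        res = random_resistance(rng, (12, 12))
        src = np.zeros((12, 12), dtype=bool)
        src[0, 0] = True
        before = corridors.cost_distance(res, make_mask(src)).values
        res.values[6, 6] += 50.0
        after = corridors.cost_distance(res, make_mask(src)).values
        assert np.all(after >= before - 1e-9)


class TestLeastCostPath:
    def _two_patches(self, shape=(10, 18)):
        bits = np.zeros(shape, dtype=bool)
        bits[4:6, 0:2] = True
        bits[4:6, 16:18] = True
        return label_mask(make_mask(bits))

    def test_cost_symmetric_and_matches_cost_distance(self):
        rng = np.random.default_rng(3)
        res = random_resistance(rng, (10, 18))
        ps = self._two_patches()
        a, b = ps.patches
        pab = corridors.least_cost_path(res, a, b)
        pba = corridors.least_cost_path(res, b, a)
        assert pab.cost == pytest.approx(pba.cost, rel=1e-9)
        cd = corridors.cost_distance(
            res, BinaryMask(30.0, (0.0, 0.0), ps.subset([a.id]).mask().bits)
        )
        far = cd.values[b.boundary[:, 0], b.boundary[:, 1]].min()
        assert pab.cost == pytest.approx(far, rel=1e-9)

    def test_path_follows_low_resistance_channel(self):
        vals = np.full((9, 15), 100.0)
        vals[7, :] = 1.0  # cheap channel along row 7
        res = corridors.ResistanceSurface(
            vals, vals, vals, (0.7, 0.3), 30.0, (0.0, 0.0)
        )
        bits = np.zeros((9, 15), dtype=bool)
        bits[7, 0] = True
        bits[7, 14] = True
        ps = label_mask(make_mask(bits))
        path = corridors.least_cost_path(res, ps.patches[0], ps.patches[1])
        assert np.all(path.cells[:, 0] == 7)

    def test_endpoints_in_patches(self):
        rng = np.random.default_rng(9)
        res = random_resistance(rng, (10, 18))
        ps = self._two_patches()
        path = corridors.least_cost_path(res, ps.patches[0], ps.patches[1])
        cells = {tuple(c) for c in path.cells}
        assert cells & {tuple(c) for c in ps.patches[0].cells}
        assert cells & {tuple(c) for c in ps.patches[1].cells}


class TestGravity:
    def test_closed_form_unit(self):
        g = corridors.gravity_interaction(np.e, np.e, 1.0, 1.0, 5.0, 5.0)
        assert g == pytest.approx(1.0)

    def test_inverse_square_and_symmetry(self):
        a = corridors.gravity_interaction(50.0, 80.0, 2.0, 3.0, 10.0, 40.0)
        b = corridors.gravity_interaction(80.0, 50.0, 3.0, 2.0, 10.0, 40.0)
        half = corridors.gravity_interaction(50.0, 80.0, 2.0, 3.0, 5.0, 40.0)
        assert a == pytest.approx(b)
        assert half == pytest.approx(4 * a)

    def test_touching_patches_infinite(self):
        assert corridors.gravity_interaction(10.0, 10.0, 1.0, 1.0, 0.0, 5.0) == np.inf


class TestSelectCorridors:
    def _gravity_matrix(self, n_sources=4, seed=0):
        rng = np.random.default_rng(seed)
        paths = []
        for i in range(1, n_sources + 1):
            for j in range(i + 1, n_sources + 1):
                p = corridors.CorridorPath(
                    i, j, np.array([[0, 0]]), rng.uniform(10, 100), 100.0
                )
                p.gravity = rng.uniform(0.1, 10.0)
                paths.append(p)
        return corridors.GravityMatrix(paths, {}, {}, 100.0)

    def test_k_at_least_all_keeps_all(self):
        gm = self._gravity_matrix()
        assert len(corridors.select_corridors(gm, k=100)) == len(gm.paths)

    def test_spanning_connectivity_enforced(self):
        gm = self._gravity_matrix(n_sources=5, seed=3)
        kept = corridors.select_corridors(gm, k=1)
        g = nx.Graph((p.i, p.j) for p in kept)
        g.add_nodes_from(range(1, 6))
        assert nx.is_connected(g)

    def test_threshold_above_max_falls_back_to_spanning(self):
        gm = self._gravity_matrix(n_sources=4, seed=5)
        kept = corridors.select_corridors(gm, rule="threshold", g_min=1e9)
        g = nx.Graph((p.i, p.j) for p in kept)
        g.add_nodes_from(range(1, 5))
        assert nx.is_connected(g)


class TestBufferAndRivers:
    def test_zero_radius_is_path_only(self):
        p = corridors.CorridorPath(1, 2, np.array([[2, 2], [2, 3]]), 1.0, 30.0)
        like = make_continuous(np.zeros((5, 5)))
        mask = corridors.buffer_paths([p], 0.0, like)
        assert mask.popcount() == 2

    def test_buffer_matches_distance_field_oracle(self):
        p = corridors.CorridorPath(
            1, 2, np.array([[5, c] for c in range(2, 12)]), 1.0, 300.0
        )
        like = make_continuous(np.zeros((11, 14)))
        mask = corridors.buffer_paths([p], 100.0, like)
        path_bits = np.zeros((11, 14), dtype=bool)
        path_bits[5, 2:12] = True
        rr, cc = np.indices((11, 14))
        src = np.argwhere(path_bits)
        dist = np.min(
            np.hypot(rr[..., None] - src[:, 0], cc[..., None] - src[:, 1]), axis=-1
        ) * 30.0
        assert np.array_equal(mask.bits, dist <= 100.0)
        assert np.all(mask.bits[path_bits])

    def test_pond_excluded_channel_included_lake_excluded(self):
        bits = np.zeros((60, 210), dtype=bool)
        bits[0, 0] = True  # 1-cell pond
        bits[5:7, 5:205] = True  # 2 wide x 200 long channel: 6000 x 60 m
        bits[8:58, 8:58] = True  # 50x50 lake
        out = corridors.river_corridors(make_mask(bits), 30.0, 5000.0)
        assert not out.bits[0, 0]
        assert out.bits[5:7, 5:205].all()
        assert not out.bits[20:50, 20:50].any()


class TestNodesAndAssembly:
    def test_node_ranking_by_area(self):
        bits = np.zeros((40, 40), dtype=bool)
        bits[1:8, 1:9] = True  # 56 cells
        bits[12:18, 1:7] = True  # 36 cells
        bits[22:25, 1:4] = True  # 9 cells
        cores = label_mask(make_mask(bits))
        picked = corridors.select_nodes(cores, source_core_ids=[], n=2)
        areas = sorted((p.n_cells for p in picked), reverse=True)
        assert areas == [56, 36]
        assert len(corridors.select_nodes(cores, [], n=0)) == 0

    def test_sources_excluded_from_nodes(self):
        bits = np.zeros((20, 20), dtype=bool)
        bits[1:5, 1:5] = True
        bits[10:12, 10:12] = True
        cores = label_mask(make_mask(bits))
        big = max(cores, key=lambda p: p.n_cells)
        picked = corridors.select_nodes(cores, source_core_ids=[big.id], n=5)
        assert big.id not in picked.ids()

    def test_restricted_is_union_without_double_count(self):
        a = make_mask(np.eye(5, dtype=bool))
        b = make_mask(np.fliplr(np.eye(5, dtype=bool)))
        esp = corridors.assemble_esp(a, b)
        assert esp.restricted.popcount() == int((a.bits | b.bits).sum())
        assert np.all(esp.restricted.bits[a.bits])
        # idempotent under re-assembly
        esp2 = corridors.assemble_esp(esp.sources, esp.corridors, None, esp.nodes)
        assert np.array_equal(esp2.restricted.bits, esp.restricted.bits)

    def test_empty_components_empty_restriction(self):
        empty = make_mask(np.zeros((4, 4), dtype=bool))
        esp = corridors.assemble_esp(empty, empty)
        assert esp.restricted.popcount() == 0
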