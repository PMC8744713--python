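import itertools

import numpy as np
import pytest

from espsim import connectivity
from espsim.patches import Patch, PatchSet, label_mask

from conftest import make_mask


def graph_from_matrix(p, areas, AL=None):
    n = len(areas)
    return connectivity.ConnectivityGraph(
        ids=list(range(1, n + 1)),
        areas_hm2=np.asarray(areas, dtype=float),
        direct_p=np.asarray(p, dtype=float),
        AL_hm2=float(sum(areas)) if AL is None else AL,
        distance_threshold=1500.0,
        p_at_threshold=0.5,
    )


def random_symmetric_p(rng, n, zero_frac=0.2):
    p = rng.random((n, n))
    p[rng.random((n, n)) < zero_frac] = 0.0
    p = np.triu(p, 1)
    p = p + p.T
    np.fill_diagonal(p, 1.0)
    return p


def brute_force_max_product(p, i, j):
    """Exhaustive maximum over all simple paths of the product of steps."""
    n = p.shape[0]
    if i == j:
        return 1.0
    best = 0.0
    others = [k for k in range(n) if k not in (i, j)]
    for r in range(len(others) + 1):
        for mid in itertools.permutations(others, r):
            path = [i, *mid, j]
            prod = 1.0
            for a, b in zip(path, path[1:]):
                prod *= p[a, b]
            best = max(best, prod)
    return best


def brute_force_pc(p, areas, al):
    n = len(areas)
    total = 0.0
    for i in range(n):
        for j in range(n):
            total += brute_force_max_product(p, i, j) * areas[i] * areas[j]
    return total / al**2


class TestPatchDistance:
    def test_self_distance_zero(self):
        bits = np.zeros((5, 5), dtype=bool)
        bits[2, 2] = True
        ps = label_mask(make_mask(bits))
        p = ps.patches[0]
        assert connectivity.patch_distance(p, p, 30.0) == 0.0

    def test_five_columns_apart(self):
        bits = np.zeros((3, 8), dtype=bool)
        bits[1, 1] = True
        bits[1, 6] = True
        ps = label_mask(make_mask(bits))
        d = connectivity.patch_distance(ps.patches[0], ps.patches[1], 30.0)
        assert d == pytest.approx(150.0)

    def test_matches_all_boundary_pairs_scan(self, rng):
        bits = rng.random((15, 15)) < 0.15
        ps = label_mask(make_mask(bits))
        if len(ps) < 2:
            pytest.skip("need two patches")
        a, b = ps.patches[0], ps.patches[1]
        d = connectivity.patch_distance(a, b, 30.0)
        exhaustive = min(
            np.hypot(*(ca - cb)) * 30.0
            for ca in a.boundary.astype(float)
            for cb in b.boundary.astype(float)
        )
        if exhaustive <= 30.0 * np.sqrt(2) + 1e-9:
            exhaustive = 0.0
        assert d == pytest.approx(exhaustive)


class TestDirectProbability:
    def test_kernel_values(self):
        assert connectivity.direct_probability(0.0) == pytest.approx(1.0)
        assert connectivity.direct_probability(1500.0, 1500.0, 0.5) == pytest.approx(0.5)
        assert connectivity.direct_probability(3000.0, 1500.0, 0.5) == pytest.approx(0.25)

    def test_hard_threshold_mode(self):
        assert connectivity.direct_probability(1000.0, 1500.0, 0.5, mode="hard") == 0.5
        assert connectivity.direct_probability(2000.0, 1500.0, 0.5, mode="hard") == 0.0


class TestMaxProduct:
    def test_identity_pair(self):
        g = graph_from_matrix(np.eye(3), [1, 1, 1])
        assert connectivity.max_product_probability(g, 1, 1) == 1.0

    def test_stepping_stone_beats_direct(self):
        p = np.array([[1.0, 0.6, 0.01], [0.6, 1.0, 0.6], [0.01, 0.6, 1.0]])
        g = graph_from_matrix(p, [10, 10, 10])
        assert connectivity.max_product_probability(g, 1, 3) == pytest.approx(0.36)

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    def test_matches_exhaustive_enumeration(self, n):
        rng = np.random.default_rng(n)
        p = random_symmetric_p(rng, n)
        g = graph_from_matrix(p, list(rng.uniform(1, 50, n)))
        for i in range(n):
            for j in range(n):
                got = connectivity.max_product_probability(g, i + 1, j + 1)
                assert got == pytest.approx(brute_force_max_product(p, i, j))


class TestPC:
    def test_single_patch_is_one(self):
        g = graph_from_matrix([[1.0]], [42.0])
        assert connectivity.compute_pc(g) == pytest.approx(1.0)

    def test_two_unreachable_patches_closed_form(self):
        p = np.eye(2)
        g = graph_from_matrix(p, [30.0, 70.0])
        expected = (30.0**2 + 70.0**2) / 100.0**2
        assert connectivity.compute_pc(g) == pytest.approx(expected)

    def test_matches_naive_double_sum(self):
        rng = np.random.default_rng(17)
        p = random_symmetric_p(rng, 5)
        areas = list(rng.uniform(5, 100, 5))
        g = graph_from_matrix(p, areas)
        assert connectivity.compute_pc(g) == pytest.approx(
            brute_force_pc(p, areas, sum(areas))
        )

    def test_invariant_under_relabeling(self):
        rng = np.random.default_rng(23)
        p = random_symmetric_p(rng, 5)
        areas = rng.uniform(5, 100, 5)
        perm = rng.permutation(5)
        g1 = graph_from_matrix(p, list(areas))
        g2 = graph_from_matrix(p[np.ix_(perm, perm)], list(areas[perm]))
        assert connectivity.compute_pc(g1) == pytest.approx(connectivity.compute_pc(g2))

    def test_monotone_in_direct_probability(self):
        rng = np.random.default_rng(29)
        p = random_symmetric_p(rng, 5)
        areas = list(rng.uniform(5, 100, 5))
        before = connectivity.compute_pc(graph_from_matrix(p, areas))
        p2 = p.copy()
        p2[0, 1] = p2[1, 0] = min(1.0, p[0, 1] + 0.3)
        after = connectivity.compute_pc(graph_from_matrix(p2, areas))
        assert after >= before - 1e-12


class TestDPC:
    def test_sole_patch_removal_is_total_loss(self):
        g = graph_from_matrix([[1.0]], [42.0])
        assert connectivity.compute_dpc(g, 1) == pytest.approx(100.0)

    def test_isolated_tiny_patch_closed_form(self):
        p = np.eye(3)
        p[0, 1] = p[1, 0] = 0.5
        areas = [100.0, 100.0, 1.0]
        g = graph_from_matrix(p, areas)
        pc = connectivity.compute_pc(g)
        expected = 100.0 * 1.0**2 / (g.AL_hm2**2 * pc)
        assert connectivity.compute_dpc(g, 3) == pytest.approx(expected)

    def test_never_negative(self):
        rng = np.random.default_rng(31)
        for _ in range(5):
            p = random_symmetric_p(rng, 6)
            g = graph_from_matrix(p, list(rng.uniform(1, 100, 6)))
            for pid in g.ids:
                assert connectivity.compute_dpc(g, pid) >= -1e-9

    def test_symmetric_twin_patches_equal(self):
        p = np.eye(4)
        p[0, 1] = p[1, 0] = 0.4  # twins 1,2 mutually linked
        p[0, 2] = p[2, 0] = 0.7
        p[1, 2] = p[2, 1] = 0.7  # both linked equally to 3
        g = graph_from_matrix(p, [20.0, 20.0, 50.0, 5.0])
        assert connectivity.compute_dpc(g, 1) == pytest.approx(
            connectivity.compute_dpc(g, 2)
        )


class TestSelectSources:
    def _patch(self, pid, area, cells):
        cells = np.asarray(cells)
        return Patch(pid, area, cells, cells)

    def test_empty_when_nothing_qualifies(self):
        bits = np.zeros((20, 20), dtype=bool)
        bits[2, 2] = bits[10, 10] = True
        cores = label_mask(make_mask(bits))
        g = connectivity.build_graph(cores)
        dpc = connectivity.dpc_table(g)
        with pytest.warns(UserWarning, match="no ecological sources"):
            sel = connectivity.select_sources(
                cores, dpc, None, dpc_min=1e9, water_min_area_hm2=100.0
            )
        assert len(sel.sources) == 0

    def test_compact_lake_included_elongated_river_excluded(self):
        # compact lake: 34x34 cells at 30 m = 104 hm²
        lake = self._patch(
            1, 104.0, [(r, c) for r in range(34) for c in range(34)]
        )
        # river: 2 cells wide, 600 long => elongation ~ 600²/1200 = 300
        river = self._patch(
            2, 108.0, [(r, c) for r in range(2) for c in range(600)]
        )
        water = PatchSet([lake, river], 30.0, (0.0, 0.0), (700, 700))
        cores = PatchSet([], 30.0, (0.0, 0.0), (700, 700))
        dpc = connectivity.DPCTable(
            table=__import__("pandas").DataFrame(
                columns=["patch_id", "area_hm2", "dpc"]
            ),
            pc=1.0,
        )
        sel = connectivity.select_sources(cores, dpc, water)
        assert sel.water_ids == [1]
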