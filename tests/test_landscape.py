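"""Watershed tessellation, saddles, networks, profiles and block errors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gasmap as gm
from gasmap import landscape as ls
from gasmap.datatypes import ValidationError

from oracles import brute_minimax_within_union, brute_saddles, brute_tessellate


def _grid(values, spacing=1.0, cap=np.inf):
    v = np.asarray(values, float)
    return gm.ScalarGrid3D([0.0, 0.0, 0.0], [spacing] * 3, v, cap)


class TestTessellate:
    def test_single_well_is_one_basin(self):
        x, y, z = np.meshgrid(*[np.arange(7)] * 3, indexing="ij")
        v = (x - 3.0) ** 2 + (y - 3.0) ** 2 + (z - 3.0) ** 2
        tess = ls.tessellate(_grid(v), 26, cutoff=1e6)
        assert tess.n_basins == 1
        assert tess.minima_index[0] == np.ravel_multi_index((3, 3, 3), (7, 7, 7))
        assert np.all(tess.labels == 0)

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_flat_grid_tie_rule_selects_first_voxel(self, connectivity):
        tess = ls.tessellate(_grid(np.zeros((4, 4, 4))), connectivity, cutoff=1.0)
        assert tess.n_basins == 1
        assert tess.minima_index[0] == 0  # smallest linearized index wins ties
        assert np.all(tess.labels == 0)

    def test_partition_covers_non_excluded_voxels(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(6, 6, 6))
        tess = ls.tessellate(_grid(v), 26, cutoff=0.5)
        assert tess.basin_sizes().sum() == (v <= 0.5).sum()
        assert np.all((tess.labels >= 0) == (v <= 0.5))

    def test_minimum_is_lowest_in_its_basin(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=(6, 6, 6))
        tess = ls.tessellate(_grid(v), 26, cutoff=1e6)
        flat = v.ravel()
        for b in range(tess.n_basins):
            basin_vals = flat[(tess.labels.ravel() == b)]
            assert tess.minima_energy[b] == basin_vals.min()

    def test_all_excluded_flagged(self):
        with pytest.raises(ValidationError, match="excluded"):
            ls.tessellate(_grid(np.ones((3, 3, 3))), 26, cutoff=0.0)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.sampled_from([6, 18, 26]))
    def test_matches_brute_force_descent(self, seed, connectivity):
        rng = np.random.default_rng(seed)
        v = np.round(rng.normal(size=(5, 5, 5)), 2)  # rounding provokes ties
        tess = ls.tessellate(_grid(v), connectivity, cutoff=1.0)
        roots = brute_tessellate(v, connectivity, 1.0)
        expected_labels = np.full(v.size, -1)
        lut = {r: i for i, r in enumerate(sorted(set(roots[roots >= 0])))}
        for i, r in enumerate(roots):
            if r >= 0:
                expected_labels[i] = lut[r]
        assert np.array_equal(tess.labels.ravel(), expected_labels)


class TestFindSaddles:
    def test_one_dimensional_ridge(self):
        # two wells at 0 and 0.5 separated by a single 3.0 voxel
        v = np.full((5, 1, 1), 1.0)
        v[0, 0, 0], v[2, 0, 0], v[4, 0, 0] = 0.0, 3.0, 0.5
        tess = ls.tessellate(_grid(v), 6, cutoff=10.0)
        saddles = ls.find_saddles(_grid(v), tess)
        assert len(saddles) == 1
        assert saddles[0].free_energy == 3.0
        assert saddles[0].voxel == (2, 0, 0)

    def test_non_adjacent_basins_get_no_saddle(self):
        # three wells along a line; outer two share no boundary
        v = np.full((7, 1, 1), 5.0)
        v[0], v[3], v[6] = 0.0, 0.1, 0.2
        v[1], v[5] = 2.0, 2.0
        v[2], v[4] = 4.0, 4.0
        tess = ls.tessellate(_grid(v), 6, cutoff=10.0)
        saddles = ls.find_saddles(_grid(v), tess)
        pairs = {s.basin_pair for s in saddles}
        assert (0, 1) in pairs and (1, 2) in pairs and (0, 2) not in pairs

    def test_saddle_dominates_both_minima_and_paths_descend(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=(7, 7, 7))
        g = _grid(v)
        tess = ls.tessellate(g, 26, cutoff=1e6)
        for s in ls.find_saddles(g, tess):
            lo, hi = s.basin_pair
            assert s.free_energy >= tess.minima_energy[lo]
            assert s.free_energy >= tess.minima_energy[hi]
            # endpoints are the two minima
            assert s.path_indices[0] == tess.minima_index[lo]
            assert s.path_indices[-1] == tess.minima_index[hi]
            # traced descent never exceeds the saddle energy
            path_vals = v.ravel()[s.path_indices]
            assert path_vals.max() <= s.free_energy + 1e-12
            # energies decrease monotonically away from the saddle
            peak = int(np.argmax(path_vals))
            assert np.all(np.diff(path_vals[: peak + 1]) >= -1e-12) or peak == 0
            assert np.all(np.diff(path_vals[peak:]) <= 1e-12)

    @settings(max_examples=15, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.sampled_from([6, 26]))
    def test_matches_brute_force_boundary_scan(self, seed, connectivity):
        rng = np.random.default_rng(seed)
        v = np.round(rng.normal(size=(5, 5, 5)), 2)
        g = _grid(v)
        tess = ls.tessellate(g, connectivity, cutoff=2.0)
        got = {
            s.basin_pair: (s.free_energy, np.ravel_multi_index(s.voxel, v.shape))
            for s in ls.find_saddles(g, tess)
        }
        roots = brute_tessellate(v, connectivity, 2.0)
        lut = {r: i for i, r in enumerate(sorted(set(roots[roots >= 0])))}
        expected = {}
        for (ra, rb), (val, sv, _pv) in brute_saddles(v, roots, connectivity).items():
            expected[(lut[ra], lut[rb]) if lut[ra] < lut[rb] else (lut[rb], lut[ra])] = (
                val,
                sv,
            )
        assert set(got) == set(expected)
        for pair, (val, sv) in expected.items():
            assert got[pair][0] == pytest.approx(val)
            assert got[pair][1] == sv

    def test_saddle_equals_minimax_within_basin_union(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            v = rng.normal(size=(6, 6, 6))
            g = _grid(v)
            tess = ls.tessellate(g, 26, cutoff=1e6)
            roots = brute_tessellate(v, 26, 1e6)
            for s in ls.find_saddles(g, tess):
                lo, hi = s.basin_pair
                mm = brute_minimax_within_union(
                    v, roots, int(tess.minima_index[lo]), int(tess.minima_index[hi]), 26
                )
                assert s.free_energy == pytest.approx(mm)


class TestNetwork:
    def _simple(self):
        v = np.full((5, 1, 1), 1.0)
        v[0, 0, 0], v[2, 0, 0], v[4, 0, 0] = -1.0, 3.0, -0.5
        g = _grid(v)
        tess = ls.tessellate(g, 6, cutoff=10.0)
        saddles = ls.find_saddles(g, tess)
        return g, tess, saddles

    def test_saddles_above_cutoff_yield_edgeless_network(self):
        g, tess, saddles = self._simple()
        net = ls.build_network(g, tess, saddles, cutoff=2.0, cutoff_mode="saddle")
        assert net.graph.number_of_nodes() == tess.n_basins
        assert net.graph.number_of_edges() == 0

    def test_barriers_stored_both_ways(self):
        g, tess, saddles = self._simple()
        net = ls.build_network(g, tess, saddles, cutoff=10.0, cutoff_mode="saddle")
        d = net.graph.edges[0, 1]
        assert d["saddle_energy"] == 3.0
        assert d["barrier_forward"] == pytest.approx(4.0)  # 3 - (-1)
        assert d["barrier_reverse"] == pytest.approx(3.5)  # 3 - (-0.5)

    def test_lowering_cutoff_never_adds_edges(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=(6, 6, 6))
        g = _grid(v)
        tess = ls.tessellate(g, 26, cutoff=1e6)
        saddles = ls.find_saddles(g, tess)
        edges = [
            set(
                ls.build_network(g, tess, saddles, cutoff=c, cutoff_mode="saddle").graph.edges
            )
            for c in (2.0, 1.0, 0.0, -1.0)
        ]
        for bigger, smaller in zip(edges, edges[1:]):
            assert smaller <= bigger

    def test_exterior_flags_mark_face_touching_basins(self):
        v = np.full((5, 1, 1), 1.0)
        v[0, 0, 0], v[2, 0, 0], v[4, 0, 0] = -1.0, 3.0, -0.5
        g = _grid(v)
        tess = ls.tessellate(g, 6, cutoff=10.0)
        net = ls.build_network(g, tess, ls.find_saddles(g, tess), 10.0, "saddle")
        # both basins touch the x faces of this 1D grid
        assert set(net.exterior_nodes) == {0, 1}


class TestProfiles:
    def _network(self, m0, s01, m1):
        v = np.full((3, 1, 1), 0.0)
        v[0, 0, 0], v[1, 0, 0], v[2, 0, 0] = m0, s01, m1
        g = _grid(v, cap=1e9)
        tess = ls.tessellate(g, 6, cutoff=1e8)
        return ls.build_network(g, tess, ls.find_saddles(g, tess), 1e8, "saddle")

    def test_barrier_between_deep_and_shallow_minima(self):
        # published-style minima pair: crossing from a -20.47 minimum over a
        # 19.03 saddle costs 39.5; onward to the -7.12 minimum
        net = self._network(-20.47, 19.03, -7.12)
        prof = ls.extract_profile(net, [0, 1])
        assert prof.minima_energies[0] == -20.47
        assert prof.minima_energies[1] == -7.12
        assert prof.forward_barriers[0] == pytest.approx(39.5)

    def test_simple_arithmetic(self):
        net = self._network(-5.0, 10.0, 0.0)
        prof = ls.extract_profile(net, [0, 1])
        assert prof.forward_barriers[0] == pytest.approx(15.0)

    def test_reverse_route_thermodynamic_consistency(self):
        net = self._network(-5.0, 10.0, -2.0)
        fwd = ls.extract_profile(net, [0, 1])
        rev = ls.extract_profile(net, [1, 0])
        # forward - reverse barrier = free-energy difference of the minima
        dG = net.graph.nodes[1]["energy"] - net.graph.nodes[0]["energy"]
        assert fwd.forward_barriers[0] - rev.forward_barriers[0] == pytest.approx(dG)

    def test_missing_edge_rejected(self):
        net = self._network(-5.0, 10.0, 0.0)
        with pytest.raises(ValidationError, match="not connected"):
            ls.extract_profile(net, [0, 0])
        with pytest.raises(ValidationError, match="not in network"):
            ls.extract_profile(net, [0, 7])

    def test_alternating_sequence(self):
        net = self._network(-5.0, 10.0, 0.0)
        prof = ls.extract_profile(net, [0, 1])
        assert prof.alternating_sequence() == [-5.0, 10.0, 0.0]


class TestBlockErrors:
    def _map(self, values):
        return _grid(values, cap=1e9)

    def test_identical_blocks_have_zero_errors(self):
        rng = np.random.default_rng(6)
        v = rng.normal(size=(6, 6, 6))
        rep = ls.block_errors(self._map(v), self._map(v.copy()), matching_radius=1.0)
        assert np.all(rep.minima_errors == 0.0)
        assert np.all(rep.saddle_errors == 0.0)
        assert not rep.unmatched_minima and not rep.unmatched_saddles

    def test_uniform_shift_gives_half_difference(self):
        rng = np.random.default_rng(7)
        v = rng.normal(size=(6, 6, 6))
        rep = ls.block_errors(self._map(v), self._map(v + 2.0), matching_radius=1.0)
        assert np.allclose(rep.minima_errors, 1.0)
        assert np.allclose(rep.saddle_errors, 1.0)

    def test_feature_in_one_block_flagged_uncomputable(self):
        v1 = np.full((9, 1, 1), 5.0)
        v1[1, 0, 0] = -1.0
        v1[7, 0, 0] = -2.0  # second well only in block 1
        v2 = np.full((9, 1, 1), 5.0)
        v2[1, 0, 0] = -1.2
        rep = ls.block_errors(self._map(v1), self._map(v2), matching_radius=1.5)
        assert rep.minima_errors[0] == pytest.approx(0.1)
        assert np.isnan(rep.minima_errors[1])
        assert rep.unmatched_minima == [1]

    def test_grid_mismatch_rejected(self):
        a = self._map(np.zeros((3, 3, 3)))
        b = gm.ScalarGrid3D([1, 0, 0], [1, 1, 1], np.zeros((3, 3, 3)), 1e9)
        with pytest.raises(ValidationError, match="grids"):
            ls.block_errors(a, b)


class TestMinimaxHelper:
    def test_two_wells_with_known_pass(self):
        v = np.full((5, 1, 1), 1.0)
        v[0, 0, 0], v[2, 0, 0], v[4, 0, 0] = 0.0, 3.0, 0.5
        g = _grid(v)
        assert ls.minimax_energy(g, [0, 0, 0], [4, 0, 0], 6) == 3.0

    def test_detour_beats_direct_ridge(self):
        # a low side corridor should set the minimax, not the direct ridge
        v = np.full((3, 3, 1), 10.0)
        v[0, 0, 0], v[2, 0, 0] = 0.0, 0.0
        v[1, 0, 0] = 9.0  # direct ridge
        v[0, 1, 0], v[1, 1, 0], v[2, 1, 0] = 2.0, 2.0, 2.0  # corridor
        g = _grid(v)
        assert ls.minimax_energy(g, [0, 0, 0], [2, 0, 0], 6) == 2.0
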