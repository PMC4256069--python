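"""Implicit-ligand-sampling engine: pair energies, maps, reference conversion."""

import numpy as np
import pytest

import gasmap as gm
from gasmap.datatypes import KB, ValidationError
from gasmap.ils import estimate_bulk_offset

from oracles import brute_pair_energy

SETTINGS = gm.ILSSettings(n_insertions_per_voxel=64, seed=0)


def _one_atom_frame(eps=0.4, sigma=3.0, pos=(0.0, 0.0, 0.0)):
    return np.array([list(pos)]), np.array([[eps, sigma]])


class TestInsertionEnergy:
    def test_lj_minimum_with_far_second_site(self):
        # one probe site at the LJ minimum distance, the other beyond the
        # cutoff: total energy is exactly -epsilon_combined
        coords, lj = _one_atom_frame()
        settings = gm.ILSSettings(n_insertions_per_voxel=1, lj_cutoff=4.0, seed=0)
        probe = gm.default_o2_probe()
        sig_c = 0.5 * (3.0 + 3.0)
        eps_c = np.sqrt(0.4 * 0.4)
        rmin = 2 ** (1 / 6) * sig_c
        # probe centre placed so site A sits at rmin, site B points away
        center = np.array([rmin + probe.bond_length / 2, 0.0, 0.0])
        e = gm.insertion_energy(coords, lj, probe, center, [1.0, 0.0, 0.0], settings)
        assert np.isclose(e, -eps_c, atol=1e-12)

    def test_zero_crossing_at_sigma(self):
        coords, lj = _one_atom_frame()
        settings = gm.ILSSettings(n_insertions_per_voxel=1, lj_cutoff=4.0, seed=0)
        probe = gm.default_o2_probe()
        center = np.array([3.0 + probe.bond_length / 2, 0.0, 0.0])
        e = gm.insertion_energy(coords, lj, probe, center, [1.0, 0.0, 0.0], settings)
        assert np.isclose(e, 0.0, atol=1e-12)

    def test_matches_hand_enumerated_four_pairs(self):
        # diatomic probe between two matrix atoms = sum of four explicit pairs
        coords = np.array([[0.0, 0.0, 0.0], [6.0, 1.0, -0.5]])
        lj = np.array([[0.3, 2.8], [0.7, 3.2]])
        probe = gm.ProbeSpec(site_lj=[[0.45, 3.1], [0.38, 2.9]], bond_length=1.3)
        center = np.array([3.1, 0.4, 0.2])
        u = np.array([0.6, 0.64, 0.48])
        u = u / np.linalg.norm(u)
        settings = gm.ILSSettings(n_insertions_per_voxel=1, lj_cutoff=14.0, seed=0)
        got = gm.insertion_energy(coords, lj, probe, center, u, settings)
        sites = [center + 0.65 * u, center - 0.65 * u]
        expected = 0.0
        for s, (pe, psig) in zip(sites, probe.site_lj):
            for a, (me, msig) in zip(coords, lj):
                expected += brute_pair_energy(s, pe, psig, a, me, msig, 14.0)
        assert np.isclose(got, expected, rtol=1e-12)

    def test_unnormalised_orientation_rejected(self):
        coords, lj = _one_atom_frame()
        with pytest.raises(ValidationError, match="orientation"):
            gm.insertion_energy(
                coords, lj, gm.default_o2_probe(), [1, 1, 1], [1.0, 1.0, 0.0], SETTINGS
            )


class TestComputeIlsMap:
    def test_ghost_probe_gives_identically_zero_map(self, ghost_probe):
        spec = gm.make_two_cavity_box(seed=2)
        ens = gm.make_fluctuating_ensemble(spec, 3)
        grid = gm.make_grid([2, 2, 2], 2.0, (4, 4, 5))
        fe = gm.compute_ils_map(ens, ghost_probe, grid, SETTINGS)
        assert np.all(fe.grid.values == 0.0)

    def test_voxels_beyond_cutoff_are_exactly_zero(self, o2_probe):
        coords, lj = _one_atom_frame(pos=(2.0, 2.0, 2.0))
        ens = gm.ConformationEnsemble(coords[None], lj, [60, 60, 60])
        settings = gm.ILSSettings(n_insertions_per_voxel=32, lj_cutoff=5.0, seed=1)
        # voxel cube at ~50 Å: farther than cutoff + bond from the only atom
        grid = gm.make_grid([50, 50, 50], 1.0, 2)
        fe = gm.compute_ils_map(ens, o2_probe, grid, settings)
        assert np.all(fe.grid.values == 0.0)

    def test_deterministic_given_seed(self, o2_probe, two_cavity):
        _, ens, _ = two_cavity
        grid = gm.make_grid([4, 4, 4], 2.0, 3)
        a = gm.compute_ils_map(ens, o2_probe, grid, SETTINGS)
        b = gm.compute_ils_map(ens, o2_probe, grid, SETTINGS)
        assert np.array_equal(a.grid.values, b.grid.values)

    def test_frame_pooling_matches_weighted_combination(self, o2_probe):
        # pooled ensemble == Boltzmann-factor combination of the two halves
        spec = gm.ToySystemSpec(
            box_lengths=[20, 20, 20],
            mean_positions=[[10.0, 10.0, 10.0]],
            lj_epsilon=[0.4],
            lj_sigma=[0.2],
            thermal_sigma=[0.3],
            cavity_centers=np.zeros((0, 3)),
            gate_indices=[],
            seed=4,
        )
        full = gm.make_fluctuating_ensemble(spec, 5)
        part_a = gm.ConformationEnsemble(
            full.coordinates[:2], full.lj_params, full.box_lengths
        )
        part_b = gm.ConformationEnsemble(
            full.coordinates[2:], full.lj_params, full.box_lengths
        )
        grid = gm.make_grid([11, 9, 9], 1.0, 3)
        kt = SETTINGS.kt
        fe = gm.compute_ils_map(full, o2_probe, grid, SETTINGS)
        fa = gm.compute_ils_map(part_a, o2_probe, grid, SETTINGS)
        fb = gm.compute_ils_map(part_b, o2_probe, grid, SETTINGS)
        combined = -kt * np.log(
            0.4 * np.exp(-fa.grid.values / kt) + 0.6 * np.exp(-fb.grid.values / kt)
        )
        assert np.allclose(fe.grid.values, combined, atol=1e-10)

    def test_added_repulsive_atom_never_lowers_free_energy(self, o2_probe):
        # r << sigma dominance: with tiny epsilon the added atom is purely
        # repulsive at short range, so nearby voxels can only go up
        base_coords, base_lj = _one_atom_frame(pos=(10.0, 10.0, 14.0))
        ens1 = gm.ConformationEnsemble(base_coords[None], base_lj, [20, 20, 20])
        added = np.vstack([base_coords, [[10.0, 10.0, 10.0]]])
        lj2 = np.vstack([base_lj, [[1e-8, 6.0]]])
        ens2 = gm.ConformationEnsemble(added[None], lj2, [20, 20, 20])
        grid = gm.make_grid([8.5, 8.5, 8.5], 1.0, 4)
        fe1 = gm.compute_ils_map(ens1, o2_probe, grid, SETTINGS)
        fe2 = gm.compute_ils_map(ens2, o2_probe, grid, SETTINGS)
        assert np.all(fe2.grid.values >= fe1.grid.values - 1e-9)

    def test_grid_outside_box_rejected(self, o2_probe, two_cavity):
        _, ens, _ = two_cavity
        grid = gm.make_grid([-5, 0, 0], 1.0, 3)
        with pytest.raises(ValidationError, match="grid"):
            gm.compute_ils_map(ens, o2_probe, grid, SETTINGS)


class TestReferenceConversion:
    def _map(self):
        grid = gm.make_grid([0, 0, 0], 1.0, 2).with_values(
            np.arange(8, dtype=float).reshape(2, 2, 2), 100.0
        )
        return gm.FreeEnergyMap(grid=grid, reference="vacuum", settings=SETTINGS)

    def test_zero_offset_is_identity(self):
        fe = self._map()
        out = gm.convert_reference(fe, 0.0)
        assert np.array_equal(out.grid.values, fe.grid.values)
        assert out.reference == "water"

    def test_offset_arithmetic(self):
        grid = gm.make_grid([0, 0, 0], 1.0, (1, 1, 1)).with_values(
            np.array([[[3.0]]]), 100.0
        )
        fe = gm.FreeEnergyMap(grid=grid, reference="vacuum", settings=SETTINGS)
        out = gm.convert_reference(fe, -2.0)
        assert out.grid.values[0, 0, 0] == 5.0

    def test_cap_preserved(self):
        grid = gm.make_grid([0, 0, 0], 1.0, (1, 1, 2)).with_values(
            np.array([[[3.0, 100.0]]]), 100.0
        )
        fe = gm.FreeEnergyMap(grid=grid, reference="vacuum", settings=SETTINGS)
        out = gm.convert_reference(fe, 1.0)
        assert out.grid.values[0, 0, 1] == 100.0

    def test_double_conversion_rejected(self):
        out = gm.convert_reference(self._map(), 1.0)
        with pytest.raises(ValidationError, match="water"):
            gm.convert_reference(out, 1.0)


class TestBulkOffset:
    def test_empty_box_gives_zero(self, o2_probe):
        ens = gm.ConformationEnsemble(
            np.zeros((2, 0, 3)), np.zeros((0, 2)), [12, 12, 12]
        )
        offset, se = estimate_bulk_offset(ens, o2_probe, SETTINGS)
        assert offset == 0.0 and se == 0.0

    def test_ghost_probe_gives_exactly_zero(self, ghost_probe):
        spec = gm.make_two_cavity_box(seed=5)
        ens = gm.make_fluctuating_ensemble(spec, 2)
        offset, _ = estimate_bulk_offset(ens, ghost_probe, SETTINGS)
        assert offset == 0.0

    def test_dilute_fluid_matches_quadrature_within_bootstrap_error(self, o2_probe):
        from gasmap.quadrature import quadrature_ils_map

        rng = np.random.default_rng(6)
        n_atoms, box = 4, 16.0
        spec = gm.ToySystemSpec(
            box_lengths=[box] * 3,
            mean_positions=rng.uniform(3, box - 3, size=(n_atoms, 3)),
            lj_epsilon=[0.3] * n_atoms,
            lj_sigma=[3.0] * n_atoms,
            thermal_sigma=[0.35] * n_atoms,
            cavity_centers=np.zeros((0, 3)),
            gate_indices=[],
            seed=9,
        )
        ens = gm.make_fluctuating_ensemble(spec, 4)
        settings = gm.ILSSettings(n_insertions_per_voxel=800, seed=10)
        dims = np.array([8, 8, 8])
        spacing = np.array([box] * 3) / dims
        grid = gm.make_grid(spacing / 2, spacing, dims)
        offset, se = estimate_bulk_offset(ens, o2_probe, settings, grid=grid)

        kt = settings.kt
        b_frames = []
        for f in range(4):
            qmap = quadrature_ils_map(
                ens.coordinates[f], ens.lj_params, o2_probe, grid,
                n_position=8, n_polar=8, n_azimuth=8, value_cap=np.inf,
            )
            b_frames.append(np.exp(-qmap.values / kt).mean())
        expected = -kt * np.log(np.mean(b_frames))
        assert se > 0
        assert abs(offset - expected) < 2 * se

    def test_conversion_zeroes_bulk_region(self, o2_probe):
        # re-referencing by the bulk offset makes bulk voxels read ~0
        rng = np.random.default_rng(12)
        n_atoms, box = 5, 18.0
        spec = gm.ToySystemSpec(
            box_lengths=[box] * 3,
            mean_positions=rng.uniform(3, box - 3, size=(n_atoms, 3)),
            lj_epsilon=[0.3] * n_atoms,
            lj_sigma=[3.0] * n_atoms,
            thermal_sigma=[0.3] * n_atoms,
            cavity_centers=np.zeros((0, 3)),
            gate_indices=[],
            seed=13,
        )
        ens = gm.make_fluctuating_ensemble(spec, 3)
        settings = gm.ILSSettings(n_insertions_per_voxel=400, seed=14)
        dims = np.array([6, 6, 6])
        spacing = np.array([box] * 3) / dims
        grid = gm.make_grid(spacing / 2, spacing, dims)
        offset, se = estimate_bulk_offset(ens, o2_probe, settings, grid=grid)
        fe = gm.compute_ils_map(ens, o2_probe, grid, settings)
        converted = gm.convert_reference(fe, offset)
        kt = settings.kt
        bulk_mean = -kt * np.log(np.exp(-converted.grid.values / kt).mean())
        assert abs(bulk_mean) < max(3 * se, 0.05)
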