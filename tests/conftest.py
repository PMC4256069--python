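"""Shared fixtures. Expensive artifacts (maps, trajectories) are session-scoped
so the acceptance checks and unit tests reuse them."""

from __future__ import annotations

import numpy as np
import pytest

import gasmap as gm


@pytest.fixture(scope="session")
def o2_probe():
    return gm.default_o2_probe()


@pytest.fixture(scope="session")
def ghost_probe():
    """Non-interacting (zero-epsilon) probe: the ideal-gas limit."""
    return gm.ProbeSpec.homonuclear(0.0, 3.0, 1.21)


@pytest.fixture(scope="session")
def frozen_atom():
    """A single frozen point-like LJ scatterer centred in a large box.

    The narrow core (sigma 0.2 Å; combined wall with the O2-like probe at
    about 1.6 Å) keeps the repulsive wall inside the first voxel shell of a
    1 Å grid, so the free-energy surface is well resolved.
    """
    coords = np.array([[[20.0, 20.0, 20.0]]])
    lj = np.array([[0.4, 0.2]])
    ens = gm.ConformationEnsemble(coords, lj, [40.0, 40.0, 40.0])
    grid = gm.make_grid([15.0, 15.0, 15.0], 1.0, 11, value_cap=100.0)
    return ens, grid


@pytest.fixture(scope="session")
def frozen_atom_quadrature(frozen_atom, o2_probe):
    """Reference map by deterministic quadrature (independent oracle)."""
    from gasmap.quadrature import quadrature_ils_map

    ens, grid = frozen_atom
    return quadrature_ils_map(
        ens.coordinates[0], ens.lj_params, o2_probe, grid,
        n_position=12, n_polar=12, n_azimuth=12,
    )


@pytest.fixture(scope="session")
def two_cavity():
    spec = gm.make_two_cavity_box(seed=7)
    ens = gm.make_fluctuating_ensemble(spec, 1)
    grid = gm.make_grid([1.5, 1.5, 1.0], 1.0, (12, 12, 21), value_cap=100.0)
    return spec, ens, grid


@pytest.fixture(scope="session")
def two_cavity_map(two_cavity, o2_probe):
    _, ens, grid = two_cavity
    settings = gm.ILSSettings(n_insertions_per_voxel=2000, seed=11)
    return gm.compute_ils_map(ens, o2_probe, grid, settings)


@pytest.fixture(scope="session")
def two_cavity_traj(two_cavity, o2_probe):
    _, ens, _ = two_cavity
    return gm.sample_explicit_ligand(
        ens, o2_probe, 400_000, seed=13, step_translation=1.2
    )


@pytest.fixture(scope="session")
def channel_grid():
    """Grid covering the exterior mouth, both cavities and the gate."""
    return gm.make_grid([6.0, 6.0, 4.0], 1.5, (9, 9, 20), value_cap=100.0)


@pytest.fixture(scope="session")
def channel_maps(channel_grid, o2_probe):
    """ILS maps of the gated channel system at three opening fractions."""
    settings = gm.ILSSettings(n_insertions_per_voxel=192, seed=3)
    maps = {}
    for f in (0.2, 0.6, 1.0):
        spec = gm.make_channel_system(f, seed=2)
        ens = gm.make_fluctuating_ensemble(spec, 6)
        maps[f] = gm.compute_ils_map(ens, o2_probe, channel_grid, settings)
    return maps
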