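"""Synthetic ground-truth systems for validating gas-channel mapping.

Two kinds of systems are generated:

* fluctuating LJ matrices — assemblies of Lennard-Jones sites whose positions
  jitter isotropically about engineered mean positions, forming internal
  cavities connected by constrictions that open and close with the thermal
  motion of designated "gate" sites;
* explicit-ligand trajectories — Metropolis Monte Carlo walks of a rigid
  diatomic probe through such a matrix, whose stationary distribution is the
  Boltzmann density in the (frame-averaged) field.

Both give analytically tractable ground truth for free-energy maps, density
maps and pathway networks.
"""

from __future__ import annotations

import numpy as np

from .datatypes import (
    ConformationEnsemble,
    KB,
    LigandTrajectory,
    ProbeSpec,
    ToySystemSpec,
    ValidationError,
)
from .ils import combine_lj, probe_site_positions

__all__ = [
    "make_fluctuating_ensemble",
    "make_channel_system",
    "make_two_cavity_box",
    "sample_explicit_ligand",
]


def make_fluctuating_ensemble(spec: ToySystemSpec, n_frames: int) -> ConformationEnsemble:
    """Draw an ensemble of frames from a toy-system specification.

    Each site's position in each frame is its mean plus an isotropic Gaussian
    displacement with that site's ``thermal_sigma``. Bit-identical output is
    guaranteed for the same ``(spec.seed, n_frames)``.
    """
    if n_frames < 1:
        raise ValidationError("n_frames: must be >= 1")
    rng = np.random.default_rng([spec.seed, 0xF1])
    disp = rng.normal(size=(n_frames, spec.n_sites, 3)) * spec.thermal_sigma[None, :, None]
    coords = spec.mean_positions[None, :, :] + disp
    return ConformationEnsemble(coords, spec.lj_params, spec.box_lengths)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n nearly uniform unit vectors (golden-spiral construction)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def make_channel_system(open_fraction: float, seed: int = 0) -> ToySystemSpec:
    """Two spherical cavities joined by a gated constriction, with one cavity
    open to the exterior through a permanent mouth.

    Geometry (Å): a 24 × 24 × 36 box; two cavity shells of radius 5 centred on
    the z-axis at z = 13 and z = 23, built from LJ sites on Fibonacci-sphere
    points. Facing polar caps of the shells are removed to form a neck between
    the cavities, and the lower cavity's bottom cap is removed as a mouth to
    the exterior. A ring of six gate sites at the neck midplane (z = 18)
    controls the constriction: its radius grows geometrically from 0.8 Å
    (fully occluding) at ``open_fraction = 0`` to 7 Å (clear of the channel
    axis) at ``open_fraction = 1``, mimicking steric gating by side-chain
    motion. Gate-saddle free energies therefore decrease monotonically with
    ``open_fraction``.
    """
    if not 0.0 <= open_fraction <= 1.0:
        raise ValidationError("open_fraction: must lie in [0, 1]")

    box = np.array([24.0, 24.0, 36.0])
    axis_xy = np.array([12.0, 12.0])
    cav_a = np.array([12.0, 12.0, 13.0])  # lower cavity, open to the exterior
    cav_b = np.array([12.0, 12.0, 23.0])  # inner cavity
    shell_radius = 5.0
    cone_cos = np.cos(np.radians(38.0))  # polar caps removed at < 38 degrees

    pts = _fibonacci_sphere(64)
    # lower cavity: drop the cap facing the neck (+z) and the mouth cap (-z)
    keep_a = (pts[:, 2] < cone_cos) & (pts[:, 2] > -cone_cos)
    shell_a = cav_a + shell_radius * pts[keep_a]
    # inner cavity: drop only the cap facing the neck (-z)
    keep_b = pts[:, 2] > -cone_cos
    shell_b = cav_b + shell_radius * pts[keep_b]

    # gate ring: radius interpolates geometrically between closed and open
    r_closed, r_open = 0.8, 7.0
    r_gate = r_closed * (r_open / r_closed) ** open_fraction
    ang = 2.0 * np.pi * (np.arange(6) + 0.5) / 6.0
    gate = np.column_stack([
        axis_xy[0] + r_gate * np.cos(ang),
        axis_xy[1] + r_gate * np.sin(ang),
        np.full(6, 18.0),
    ])

    positions = np.vstack([shell_a, shell_b, gate])
    n_shell = len(shell_a) + len(shell_b)
    n = len(positions)
    eps = np.full(n, 0.45)
    sig = np.full(n, 3.0)
    tsig = np.full(n, 0.25)
    gate_idx = np.arange(n_shell, n)

    return ToySystemSpec(
        box_lengths=box,
        mean_positions=positions,
        lj_epsilon=eps,
        lj_sigma=sig,
        thermal_sigma=tsig,
        cavity_centers=np.vstack([cav_a, cav_b]),
        gate_indices=gate_idx,
        seed=seed,
        metadata={
            "open_fraction": float(open_fraction),
            "gate_ring_radius": float(r_gate),
            "shell_radius": shell_radius,
            "neck_midplane_z": 18.0,
            "mouth_direction": "-z",
            "description": (
                "two radius-5 cavity shells at z=13/23 joined by a gated neck; "
                "lower cavity opens to the exterior through a bottom mouth"
            ),
        },
    )


def make_two_cavity_box(
    separation: float = 8.0,
    well_epsilon: tuple[float, float] = (2.0, 0.9),
    seed: int = 0,
) -> ToySystemSpec:
    """A frozen box with two attractive pockets of different depths.

    Eight LJ sites at the corners of a small cube around each cavity centre
    create a smooth attractive pocket; the two pockets differ in well depth,
    so the cavity free-energy difference (and hence the equilibrium occupancy
    ratio) is nonzero and known from quadrature. The box is kept small and
    the wells a few kT deep so that Monte Carlo walkers revisit both pockets
    often. Thermal fluctuation is zero: the system is a single frozen frame.
    """
    box = np.array([14.0, 14.0, 14.0 + separation])
    c1 = np.array([7.0, 7.0, 7.0])
    c2 = c1 + np.array([0.0, 0.0, separation])
    corners = np.array(
        [[i, j, k] for i in (-1, 1) for j in (-1, 1) for k in (-1, 1)], float
    ) * (4.2 / np.sqrt(3.0))
    positions = np.vstack([c1 + corners, c2 + corners])
    eps = np.concatenate([np.full(8, well_epsilon[0]), np.full(8, well_epsilon[1])])
    return ToySystemSpec(
        box_lengths=box,
        mean_positions=positions,
        lj_epsilon=eps,
        lj_sigma=np.full(16, 3.0),
        thermal_sigma=np.zeros(16),
        cavity_centers=np.vstack([c1, c2]),
        gate_indices=np.array([], int),
        seed=seed,
        metadata={"separation": float(separation), "well_epsilon": list(well_epsilon)},
    )


def _probe_energy(
    coords: np.ndarray,  # (S, 3) one frame
    eps: np.ndarray,
    sig: np.ndarray,
    sites: np.ndarray,  # (2, 3)
    cutoff2: float,
) -> float:
    d = coords[None, :, :] - sites[:, None, :]
    d2 = np.einsum("psk,psk->ps", d, d)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        x3 = (sig[None, :] ** 2 / d2) ** 3
        e = 4.0 * eps[None, :] * (x3 * x3 - x3)
        e = np.where((d2 <= cutoff2) & (eps[None, :] > 0), e, 0.0)
    e = np.where((d2 == 0.0) & (eps[None, :] > 0), np.inf, e)
    return float(e.sum())


def _random_rotation_step(rng: np.random.Generator, u: np.ndarray, sigma: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.normal(0.0, sigma)
    c, s = np.cos(angle), np.sin(angle)
    nu = u * c + np.cross(axis, u) * s + axis * np.dot(axis, u) * (1.0 - c)
    return nu / np.linalg.norm(nu)


def sample_explicit_ligand(
    ensemble: ConformationEnsemble,
    probe: ProbeSpec,
    n_steps: int,
    temperature: float = 310.0,
    seed: int = 0,
    step_translation: float = 0.6,
    step_rotation: float = 0.5,
    lj_cutoff: float = 14.0,
    combining_rule: str = "lorentz_berthelot",
    acceptance_window: int = 2000,
) -> LigandTrajectory:
    """Metropolis Monte Carlo trajectory of the rigid diatomic probe.

    Each sweep draws one frame of the ensemble (by frame weight), proposes a
    joint translation + rotation of the probe and accepts it with the
    Metropolis criterion in that frame's field. For a frozen (single-frame)
    ensemble the stationary distribution is exactly the Boltzmann density
    exp(−βE(r, ω)); for fluctuating ensembles it approximates the
    frame-averaged density. Positions outside the box are rejected (hard
    walls), so recorded centres always lie inside the box.

    Raises a diagnostic error if a full ``acceptance_window`` of sweeps
    passes without a single acceptance.
    """
    if ensemble.n_frames < 1:
        raise ValidationError("ensemble: empty")
    if n_steps < 1:
        raise ValidationError("n_steps: must be >= 1")
    rng = np.random.default_rng([seed, 0xE1])
    kt = KB * float(temperature)
    cutoff2 = lj_cutoff**2
    box = ensemble.box_lengths

    eps = np.empty((2, ensemble.n_sites))
    sig = np.empty((2, ensemble.n_sites))
    for s in range(2):
        eps[s], sig[s] = combine_lj(probe.site_lj[s], ensemble.lj_params, combining_rule)

    def energy(frame_idx: int, pos: np.ndarray, u: np.ndarray) -> float:
        sites = probe_site_positions(pos, u, probe.bond_length)
        coords = ensemble.coordinates[frame_idx]
        total = 0.0
        for s in range(2):
            total += _probe_energy(coords, eps[s], sig[s], sites[s][None, :], cutoff2)
        return total

    # find a reasonable-energy starting placement
    for _attempt in range(1000):
        pos = rng.uniform(0.0, 1.0, 3) * box
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        if energy(0, pos, u) < 100.0:
            break
    else:
        raise ValidationError("could not find a finite-energy starting placement")

    weights = ensemble.frame_weights
    frame_choices = rng.choice(ensemble.n_frames, size=n_steps, p=weights)
    out = np.empty((n_steps, 1, 3))
    accepted_in_window = 0
    steps_in_window = 0
    e = energy(int(frame_choices[0]), pos, u)
    last_frame = int(frame_choices[0])
    for step in range(n_steps):
        f = int(frame_choices[step])
        if f != last_frame:  # field changes with the frame drawn for this sweep
            e = energy(f, pos, u)
            last_frame = f
        new_pos = pos + rng.normal(0.0, step_translation, 3)
        new_u = _random_rotation_step(rng, u, step_rotation)
        if np.all(new_pos >= 0.0) and np.all(new_pos <= box):
            new_e = energy(f, new_pos, new_u)
            if new_e <= e or rng.uniform() < np.exp(-(new_e - e) / kt):
                pos, u, e = new_pos, new_u, new_e
                accepted_in_window += 1
        out[step, 0] = pos
        steps_in_window += 1
        if steps_in_window == acceptance_window:
            if accepted_in_window == 0:
                raise ValidationError(
                    f"zero acceptance over {acceptance_window} sweeps: "
                    "step size or system pathological"
                )
            accepted_in_window = 0
            steps_in_window = 0
    return LigandTrajectory(out, box)
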