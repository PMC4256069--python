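"""Implicit ligand sampling: probe free-energy maps from conformational ensembles.

The potential of mean force for placing a small apolar probe at grid position r
is estimated by test-particle insertion,

    ΔG(r) = −kB·T · ln ⟨ exp(−E_int(r, ω) / kB·T) ⟩,

where the average runs over ensemble frames (weighted by their frame weights)
and, per frame, over random probe placements within the voxel cube with
uniformly random orientations ω. E_int is the Lennard-Jones interaction energy
between the rigid diatomic probe and all matrix sites within the cutoff. The
resulting map is referenced to vacuum; :func:`convert_reference` shifts it to
the bulk-water reference.
"""

from __future__ import annotations

import hashlib

import numpy as np

from .datatypes import (
    ConformationEnsemble,
    FreeEnergyMap,
    ILSSettings,
    ProbeSpec,
    ScalarGrid3D,
    ValidationError,
)

__all__ = [
    "make_grid",
    "insertion_energy",
    "compute_ils_map",
    "convert_reference",
    "estimate_bulk_offset",
]


def make_grid(origin, spacing, dims, fill: float = 0.0, value_cap: float = np.inf) -> ScalarGrid3D:
    """Build an empty grid template covering a region of interest."""
    spacing = np.broadcast_to(np.asarray(spacing, float), (3,))
    dims = tuple(int(d) for d in np.broadcast_to(np.asarray(dims), (3,)))
    return ScalarGrid3D(np.asarray(origin, float), spacing, np.full(dims, fill), value_cap)


def combine_lj(probe_site: np.ndarray, matrix_lj: np.ndarray, rule: str) -> tuple[np.ndarray, np.ndarray]:
    """Cross-interaction LJ parameters for one probe site against all matrix sites.

    Lorentz-Berthelot combines sigma arithmetically and epsilon geometrically;
    the geometric rule (GROMOS convention) uses geometric means for both.
    """
    eps_p, sig_p = probe_site
    eps = np.sqrt(eps_p * matrix_lj[:, 0])
    if rule == "lorentz_berthelot":
        sig = 0.5 * (sig_p + matrix_lj[:, 1])
    elif rule == "geometric":
        sig = np.sqrt(sig_p * matrix_lj[:, 1])
    else:
        raise ValidationError(f"combining_rule: unknown rule {rule!r}")
    return eps, sig


def probe_site_positions(centers: np.ndarray, orientations: np.ndarray, bond_length: float) -> np.ndarray:
    """Place the two probe sites at center ± (bond_length/2)·orientation.

    Returns an array of shape (..., 2, 3).
    """
    half = 0.5 * bond_length * orientations
    return np.stack([centers + half, centers - half], axis=-2)


def _pair_energies(
    site_pos: np.ndarray,  # (M, 3) probe-site positions
    frame_coords: np.ndarray,  # (F, S, 3)
    eps: np.ndarray,  # (S,)
    sig: np.ndarray,  # (S,)
    settings: ILSSettings,
    box_lengths: np.ndarray | None,
) -> np.ndarray:
    """LJ energy of each probe site against all matrix sites: shape (F, M)."""
    d = frame_coords[:, None, :, :] - site_pos[None, :, None, :]  # (F, M, S, 3)
    if settings.periodic:
        if box_lengths is None:
            raise ValidationError("periodic=True requires box lengths")
        d -= box_lengths * np.rint(d / box_lengths)
    d2 = np.einsum("fmsk,fmsk->fms", d, d)
    cut2 = settings.lj_cutoff**2
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        x3 = (sig[None, None, :] ** 2 / d2) ** 3
        e = 4.0 * eps[None, None, :] * (x3 * x3 - x3)
        e = np.where(d2 <= cut2, e, 0.0)
    # non-interacting sites contribute exactly 0 (overrides overflow artifacts);
    # exact coincidence with an interacting site is infinitely repulsive
    interacting = eps[None, None, :] > 0.0
    e = np.where(interacting, e, 0.0)
    e = np.where(interacting & (d2 == 0.0), np.inf, e)
    return e.sum(axis=2)


def insertion_energy(
    frame_coords: np.ndarray,
    matrix_lj: np.ndarray,
    probe: ProbeSpec,
    position,
    orientation,
    settings: ILSSettings,
    box_lengths=None,
) -> float:
    """Interaction energy (kJ·mol⁻¹) of the probe at one placement in one frame.

    The probe's two LJ sites sit at ``position ± (bond_length/2)·orientation``;
    each interacts with every matrix site within ``settings.lj_cutoff``
    (minimum image if periodic) through the 12-6 potential with the configured
    combining rule. Overlaps give large positive finite energies, an exact
    coincidence gives +inf.
    """
    frame_coords = np.asarray(frame_coords, float).reshape(1, -1, 3)
    matrix_lj = np.asarray(matrix_lj, float).reshape(-1, 2)
    u = np.asarray(orientation, float)
    norm = np.linalg.norm(u)
    if not np.isclose(norm, 1.0, atol=1e-6):
        raise ValidationError("orientation: must be a unit vector")
    sites = probe_site_positions(np.asarray(position, float), u / norm, probe.bond_length)
    total = 0.0
    box = None if box_lengths is None else np.asarray(box_lengths, float)
    for s in range(2):
        eps, sig = combine_lj(probe.site_lj[s], matrix_lj, settings.combining_rule)
        total += _pair_energies(sites[s][None, :], frame_coords, eps, sig, settings, box)[0, 0]
    return float(total)


def _unit_vectors_from_uniform(q2: np.ndarray) -> np.ndarray:
    """Map (n, 2) uniform variates to uniformly distributed unit vectors."""
    z = 2.0 * q2[:, 0] - 1.0
    phi = 2.0 * np.pi * q2[:, 1]
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _voxel_insertions(
    rng: np.random.Generator, center, spacing, n: int, region: str, sampling: str
):
    """Probe centers within the voxel and uniform orientations.

    All three schemes are unbiased for the voxel average; "sobol" uses a
    scrambled 5D low-discrepancy sequence over (position, cos θ, φ), which
    sharply reduces the variance of the Boltzmann average in voxels straddling
    a steric wall.
    """
    if sampling == "sobol":
        import warnings

        from scipy.stats import qmc

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # non-power-of-two n
            q = qmc.Sobol(d=5, scramble=True, rng=rng).random(n)
        pos_unit = q[:, :3]
        u = _unit_vectors_from_uniform(q[:, 3:5])
    elif sampling == "stratified":
        k = max(1, round(n ** (1.0 / 3.0)))
        cells = np.stack(
            np.meshgrid(*[np.arange(k)] * 3, indexing="ij"), axis=-1
        ).reshape(-1, 3)
        idx = rng.permutation(np.arange(n) % k**3)
        pos_unit = (cells[idx] + rng.uniform(0.0, 1.0, size=(n, 3))) / k
        u = _unit_vectors_from_uniform(rng.uniform(0.0, 1.0, size=(n, 2)))
    else:
        pos_unit = rng.uniform(0.0, 1.0, size=(n, 3))
        u = _unit_vectors_from_uniform(rng.uniform(0.0, 1.0, size=(n, 2)))

    if region == "cube":
        offsets = (pos_unit - 0.5) * spacing
    else:  # inscribed sphere of the voxel cube, sampled radially
        r_max = 0.5 * float(np.min(spacing))
        direction = _unit_vectors_from_uniform(pos_unit[:, 1:3])
        radii = r_max * pos_unit[:, 0] ** (1.0 / 3.0)
        offsets = direction * radii[:, None]
    return center + offsets, u


def _boltzmann_log_mean(energies: np.ndarray, weights: np.ndarray, kt: float) -> float:
    """log of the frame-weighted mean Boltzmann factor, shift-stabilised.

    ``energies`` has shape (F, M): per frame, per insertion. Exact (returns 0.0)
    when every energy is identically zero.
    """
    b = -energies / kt  # (F, M)
    m = b.max()
    if not np.isfinite(m):  # every placement infinitely repulsive
        return -np.inf
    per_frame = np.exp(b - m).mean(axis=1)
    if np.all(per_frame == per_frame[0]):
        mean = float(per_frame[0])  # weighted mean of a constant, exactly
    else:
        mean = float(np.dot(weights, per_frame) / weights.sum())
    if mean == 0.0:
        return -np.inf
    return float(m) + float(np.log(mean))


def _ensemble_hash(ensemble: ConformationEnsemble) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(ensemble.coordinates).tobytes())
    h.update(np.ascontiguousarray(ensemble.lj_params).tobytes())
    h.update(np.ascontiguousarray(ensemble.box_lengths).tobytes())
    return h.hexdigest()[:16]


# keep per-voxel work below ~2e7 pair terms by chunking insertions
_MAX_TERMS = 20_000_000


def compute_ils_map(
    ensemble: ConformationEnsemble,
    probe: ProbeSpec,
    grid: ScalarGrid3D,
    settings: ILSSettings,
) -> FreeEnergyMap:
    """Compute the vacuum-referenced probe free-energy map on ``grid``.

    Per voxel, ``settings.n_insertions_per_voxel`` probe placements are drawn
    from a dedicated RNG stream seeded by (settings.seed, voxel index), so the
    result is independent of evaluation order. The same placement set is
    evaluated against every frame, which makes pooling frames from two
    ensembles exactly equivalent to weight-combining their per-ensemble
    Boltzmann averages. Voxels whose average Boltzmann factor underflows (or
    whose free energy exceeds ``settings.value_cap``) are set to the cap.
    """
    if ensemble.n_frames == 0:
        raise ValidationError("ensemble: empty")
    if not settings.periodic:
        centers = grid.voxel_centers()
        half = 0.5 * grid.spacing
        if np.any(centers - half < -1e-9) or np.any(centers + half > ensemble.box_lengths + 1e-9):
            raise ValidationError("grid: extends outside the box (periodic=False)")

    kt = settings.kt
    weights = ensemble.frame_weights
    coords = ensemble.coordinates
    n_ins = settings.n_insertions_per_voxel

    eps = np.empty((2, ensemble.n_sites))
    sig = np.empty((2, ensemble.n_sites))
    for s in range(2):
        eps[s], sig[s] = combine_lj(probe.site_lj[s], ensemble.lj_params, settings.combining_rule)

    terms_per_ins = max(1, 2 * ensemble.n_frames * ensemble.n_sites)
    chunk = max(1, min(n_ins, _MAX_TERMS // terms_per_ins))

    values = np.empty(grid.dims)
    flat = values.reshape(-1)
    box = ensemble.box_lengths if settings.periodic else None
    nx, ny, nz = grid.dims
    for v in range(grid.n_voxels):
        i, j, k = v // (ny * nz), (v // nz) % ny, v % nz
        center = grid.origin + grid.spacing * np.array([i, j, k], float)
        rng = np.random.default_rng([settings.seed, v])
        pos, u = _voxel_insertions(
            rng, center, grid.spacing, n_ins, settings.insertion_region, settings.sampling
        )
        sites = probe_site_positions(pos, u, probe.bond_length)  # (n_ins, 2, 3)
        energies = np.empty((ensemble.n_frames, n_ins))
        for lo in range(0, n_ins, chunk):
            hi = min(lo + chunk, n_ins)
            e = _pair_energies(sites[lo:hi, 0], coords, eps[0], sig[0], settings, box)
            e += _pair_energies(sites[lo:hi, 1], coords, eps[1], sig[1], settings, box)
            energies[:, lo:hi] = e
        log_mean = _boltzmann_log_mean(energies, weights, kt)
        dg = settings.value_cap if log_mean == -np.inf else -kt * log_mean
        flat[v] = min(dg, settings.value_cap)

    out = ScalarGrid3D(grid.origin, grid.spacing, values, settings.value_cap)
    provenance = {
        "ensemble_hash": _ensemble_hash(ensemble),
        "n_frames": ensemble.n_frames,
        "n_insertions_per_voxel": n_ins,
        "n_capped_voxels": int(np.count_nonzero(values >= settings.value_cap)),
    }
    return FreeEnergyMap(grid=out, reference="vacuum", settings=settings, provenance=provenance)


def convert_reference(fe_map: FreeEnergyMap, dG_vac_to_wat: float) -> FreeEnergyMap:
    """Convert a vacuum-referenced map to the bulk-water reference.

    ΔG_wat→pos = ΔG_vac→pos − ΔG_vac→wat; capped voxels stay at the cap.
    """
    if fe_map.reference != "vacuum":
        raise ValidationError("convert_reference: map is already water-referenced")
    return fe_map.shifted(float(dG_vac_to_wat), "water")


def estimate_bulk_offset(
    reference_ensemble: ConformationEnsemble,
    probe: ProbeSpec,
    settings: ILSSettings,
    grid: ScalarGrid3D | None = None,
    n_bootstrap: int = 200,
) -> tuple[float, float]:
    """Excess insertion free energy of the probe in a bulk reference ensemble.

    Inserts the probe throughout a homogeneous reference box and returns
    −kB·T·ln of the ensemble/position/orientation-averaged Boltzmann factor,
    together with a bootstrap standard error over frames. The result is the
    ΔG_vac→wat-style offset used by :func:`convert_reference`.
    """
    if reference_ensemble.n_frames == 0:
        raise ValidationError("reference_ensemble: empty")
    if grid is None:
        box = reference_ensemble.box_lengths
        dims = np.array([8, 8, 8])
        spacing = box / dims
        grid = make_grid(spacing / 2.0, spacing, dims)

    kt = settings.kt
    coords = reference_ensemble.coordinates
    weights = reference_ensemble.frame_weights
    n_ins = settings.n_insertions_per_voxel
    eps = np.empty((2, reference_ensemble.n_sites))
    sig = np.empty((2, reference_ensemble.n_sites))
    for s in range(2):
        eps[s], sig[s] = combine_lj(
            probe.site_lj[s], reference_ensemble.lj_params, settings.combining_rule
        )
    box = reference_ensemble.box_lengths if settings.periodic else None

    # per-frame mean Boltzmann factor pooled over all voxels (shift-stabilised)
    nx, ny, nz = grid.dims
    shift = 0.0
    per_frame = np.zeros(reference_ensemble.n_frames)
    n_total = 0
    for v in range(grid.n_voxels):
        i, j, k = v // (ny * nz), (v // nz) % ny, v % nz
        center = grid.origin + grid.spacing * np.array([i, j, k], float)
        rng = np.random.default_rng([settings.seed, v])
        pos, u = _voxel_insertions(
            rng, center, grid.spacing, n_ins, settings.insertion_region, settings.sampling
        )
        sites = probe_site_positions(pos, u, probe.bond_length)
        e = _pair_energies(sites[:, 0], coords, eps[0], sig[0], settings, box)
        e += _pair_energies(sites[:, 1], coords, eps[1], sig[1], settings, box)
        with np.errstate(over="ignore"):
            per_frame += np.exp(-e / kt - shift).sum(axis=1)
        n_total += n_ins
    per_frame /= n_total

    if np.all(per_frame == per_frame[0]):
        mean = float(per_frame[0])
    else:
        mean = float(np.dot(weights, per_frame) / weights.sum())
    offset = np.inf if mean == 0.0 else -kt * (np.log(mean) + shift)

    rng = np.random.default_rng([settings.seed, 0xB00])
    n_frames = reference_ensemble.n_frames
    reps = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        idx = rng.integers(0, n_frames, size=n_frames)
        w = weights[idx]
        m = float(np.dot(w, per_frame[idx]) / w.sum())
        reps[b] = np.inf if m == 0.0 else -kt * (np.log(m) + shift)
    finite = reps[np.isfinite(reps)]
    se = float(np.std(finite)) if finite.size else np.inf
    return float(offset), se
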