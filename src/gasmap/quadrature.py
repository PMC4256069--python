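"""Deterministic quadrature reference for test-particle insertion free energies.

This module recomputes the per-voxel Boltzmann-averaged insertion integral by
dense deterministic quadrature — a midpoint product rule over positions within
the voxel cube and a Gauss-Legendre × midpoint product rule over orientations —
entirely independently of the stochastic engine in :mod:`gasmap.ils`. It is the
oracle the stochastic map is validated against on small frozen systems, and is
practical only for such systems (cost grows as positions × orientations ×
matrix sites per voxel).

The implementation deliberately shares no sampling or energy code with the
stochastic engine.
"""

from __future__ import annotations

import numpy as np

from .datatypes import KB, ProbeSpec, ScalarGrid3D, ValidationError

__all__ = ["quadrature_ils_map", "quadrature_region_log_partition"]


def _combined_params(probe_site, lj_params, rule):
    eps_p, sig_p = float(probe_site[0]), float(probe_site[1])
    eps_m = np.asarray(lj_params, float)[:, 0]
    sig_m = np.asarray(lj_params, float)[:, 1]
    if rule == "lorentz_berthelot":
        sig = (sig_p + sig_m) / 2.0
    elif rule == "geometric":
        sig = np.sqrt(sig_p * sig_m)
    else:
        raise ValidationError(f"unknown combining rule {rule!r}")
    return np.sqrt(eps_p * eps_m), sig


def _lj_sum(points: np.ndarray, atoms: np.ndarray, eps: np.ndarray, sig: np.ndarray, cutoff: float) -> np.ndarray:
    """Σ over atoms of 12-6 LJ at each point; plain truncation at the cutoff."""
    out = np.zeros(points.shape[0])
    for a in range(atoms.shape[0]):
        if eps[a] == 0.0:
            continue
        d2 = np.sum((points - atoms[a]) ** 2, axis=1)
        with np.errstate(divide="ignore", over="ignore"):
            sr6 = (sig[a] ** 2 / d2) ** 3
            e = 4.0 * eps[a] * (sr6 * sr6 - sr6)
        e = np.where(d2 <= cutoff**2, e, 0.0)
        e = np.where(d2 == 0.0, np.inf, e)
        out += e
    return out


def _orientation_nodes(n_polar: int, n_azimuth: int) -> tuple[np.ndarray, np.ndarray]:
    """Unit vectors and weights integrating uniformly over the sphere."""
    x, w = np.polynomial.legendre.leggauss(n_polar)  # nodes in cos(theta)
    phi = 2.0 * np.pi * (np.arange(n_azimuth) + 0.5) / n_azimuth
    cos_t = np.repeat(x, n_azimuth)
    wt = np.repeat(w / 2.0, n_azimuth) / n_azimuth  # ∫ d(cosθ)/2 · dφ/2π
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
    ph = np.tile(phi, n_polar)
    u = np.column_stack([sin_t * np.cos(ph), sin_t * np.sin(ph), cos_t])
    return u, wt


def _position_offsets(spacing: np.ndarray, n_position: int) -> np.ndarray:
    """Midpoint-rule sub-cube offsets relative to the voxel center."""
    t = (np.arange(n_position) + 0.5) / n_position - 0.5
    gx, gy, gz = np.meshgrid(t * spacing[0], t * spacing[1], t * spacing[2], indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


def quadrature_ils_map(
    frame_coords: np.ndarray,
    lj_params: np.ndarray,
    probe: ProbeSpec,
    grid: ScalarGrid3D,
    temperature: float = 310.0,
    lj_cutoff: float = 14.0,
    combining_rule: str = "lorentz_berthelot",
    n_position: int = 12,
    n_polar: int = 12,
    n_azimuth: int = 12,
    value_cap: float = 100.0,
    voxel_subset=None,
) -> ScalarGrid3D:
    """Free-energy map of a frozen frame by dense deterministic quadrature.

    Parameters mirror the physical settings of the stochastic engine; the
    position rule uses ``n_position``³ midpoints per voxel and the orientation
    rule ``n_polar × n_azimuth`` nodes. Voxels whose averaged Boltzmann factor
    underflows are set to ``value_cap``. ``voxel_subset`` (flat C-order voxel
    indices) restricts the computation to a region of interest; the other
    voxels are filled with the cap.
    """
    atoms = np.asarray(frame_coords, float).reshape(-1, 3)
    lj = np.asarray(lj_params, float).reshape(-1, 2)
    kt = KB * float(temperature)

    u, wt = _orientation_nodes(n_polar, n_azimuth)
    pos_off = _position_offsets(grid.spacing, n_position)
    n_pos = pos_off.shape[0]
    n_orn = u.shape[0]
    # relative probe-site offsets for every (position, orientation) node
    half_bond = 0.5 * probe.bond_length
    rel = (
        pos_off[:, None, None, :]
        + np.array([1.0, -1.0])[None, None, :, None] * (half_bond * u)[None, :, None, :]
    )  # (n_pos, n_orn, 2, 3)
    rel_flat = rel.reshape(-1, 3)
    weights = np.repeat(wt[None, :], n_pos, axis=0).ravel() / n_pos  # (n_pos*n_orn,)

    eps0, sig0 = _combined_params(probe.site_lj[0], lj, combining_rule)
    eps1, sig1 = _combined_params(probe.site_lj[1], lj, combining_rule)

    values = np.empty(grid.dims)
    flat = values.reshape(-1)
    centers = grid.voxel_centers()
    voxels = range(grid.n_voxels) if voxel_subset is None else voxel_subset
    if voxel_subset is not None:
        flat.fill(value_cap)
    for v in voxels:
        pts = centers[v] + rel_flat  # (n_pos*n_orn*2, 3)
        e = _lj_sum(pts[0::2], atoms, eps0, sig0, lj_cutoff)
        e = e + _lj_sum(pts[1::2], atoms, eps1, sig1, lj_cutoff)
        with np.errstate(over="ignore"):
            b = np.exp(-e / kt)
        mean = float(np.dot(weights, b))
        if mean <= 0.0:
            flat[v] = value_cap
        else:
            flat[v] = min(-kt * np.log(mean), value_cap)
    return ScalarGrid3D(grid.origin, grid.spacing, values, value_cap)


def quadrature_region_log_partition(
    frame_coords: np.ndarray,
    lj_params: np.ndarray,
    probe: ProbeSpec,
    region_grid: ScalarGrid3D,
    mask: np.ndarray,
    temperature: float = 310.0,
    lj_cutoff: float = 14.0,
    combining_rule: str = "lorentz_berthelot",
    n_position: int = 10,
    n_polar: int = 10,
    n_azimuth: int = 10,
) -> float:
    """log of the configurational partition integral over a masked region.

    Computes ln Σ_{voxels in mask} V_voxel · ⟨exp(−βE)⟩_voxel by the same
    quadrature rules as :func:`quadrature_ils_map`. The difference of two such
    values is the free-energy difference −ΔΔG/kB·T between two regions, the
    analytic ground truth for cavity-occupancy ratios.
    """
    kt = KB * float(temperature)
    mask = np.asarray(mask, bool)
    if mask.shape != region_grid.dims:
        raise ValidationError("mask: shape must match the region grid")
    subset = np.flatnonzero(mask.ravel())
    dense = quadrature_ils_map(
        frame_coords, lj_params, probe, region_grid, temperature, lj_cutoff,
        combining_rule, n_position, n_polar, n_azimuth, value_cap=np.inf,
        voxel_subset=subset,
    )
    with np.errstate(over="ignore"):
        b = np.exp(-dense.values.ravel()[subset] / kt)
    total = float(b.sum()) * dense.voxel_volume
    if total <= 0.0:
        return -np.inf
    return float(np.log(total))
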