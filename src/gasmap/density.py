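"""Ligand probability-density maps and region occupancy from trajectories.

A density map is the raw per-voxel histogram of ligand centre-of-geometry
positions normalised by frame count and voxel volume, so summing
value × voxel volume over the grid recovers the mean number of ligands inside
the grid. Iso-level reports count voxels above a density threshold and their
26-connected components — the numerical counterpart of drawing an isosurface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .datatypes import (
    LigandTrajectory,
    RegionSpec,
    ScalarGrid3D,
    SuperpositionResult,
    ValidationError,
)

__all__ = [
    "DensityMapResult",
    "IsosurfaceReport",
    "OccupancySeries",
    "compute_density_map",
    "isosurface_report",
    "region_occupancy",
]


@dataclass(frozen=True)
class DensityMapResult:
    """A density grid (Å⁻³) plus the tally of positions that fell outside it."""

    grid: ScalarGrid3D
    n_inside: int
    n_outside: int
    mean_inside: float  # mean ligand count inside the grid per frame


def compute_density_map(
    traj: LigandTrajectory,
    grid: ScalarGrid3D,
    alignment: list[SuperpositionResult] | None = None,
) -> DensityMapResult:
    """Histogram ligand positions into a normalised probability density grid.

    Each present ligand is assigned to its nearest voxel centre; voxel values
    are counts / (n_frames × voxel volume). Positions outside the grid are
    ignored for the map but tallied. An optional per-frame rigid alignment
    (e.g. from superposing the host matrix onto a reference) is applied to
    the ligand positions before binning.
    """
    if traj.n_frames == 0:
        raise ValidationError("trajectory: zero frames")
    if alignment is not None and len(alignment) != traj.n_frames:
        raise ValidationError("alignment: need one superposition per frame")

    pos = traj.positions
    if alignment is not None:
        pos = np.stack([alignment[f].apply(pos[f]) for f in range(traj.n_frames)])
    flat = pos.reshape(-1, 3)
    present = ~np.isnan(flat).any(axis=1)
    pts = flat[present]

    idx = np.rint((pts - grid.origin) / grid.spacing).astype(int)
    inside = np.all((idx >= 0) & (idx < np.array(grid.dims)), axis=1)
    ii = idx[inside]
    counts = np.zeros(grid.dims)
    np.add.at(counts, (ii[:, 0], ii[:, 1], ii[:, 2]), 1.0)
    values = counts / (traj.n_frames * grid.voxel_volume)
    return DensityMapResult(
        grid=grid.with_values(values, value_cap=np.inf),
        n_inside=int(inside.sum()),
        n_outside=int(len(pts) - inside.sum()),
        mean_inside=float(inside.sum() / traj.n_frames),
    )


@dataclass(frozen=True)
class IsosurfaceReport:
    """Voxels at or above an iso-level and their 26-connected components."""

    level: float
    n_voxels: int
    n_components: int
    mask: ScalarGrid3D  # 1.0 inside the iso-level, 0.0 outside


def isosurface_report(grid: ScalarGrid3D, level: float = 1.5e-4) -> IsosurfaceReport:
    """Count voxels ≥ ``level`` and their 26-connected components.

    The default level (1.5 × 10⁻⁴ Å⁻³) is the contour conventionally used to
    visualise high-affinity gas regions in density maps.
    """
    if not level > 0:
        raise ValidationError("level: must be > 0")
    above = grid.values >= level
    _, n_comp = ndimage.label(above, structure=np.ones((3, 3, 3), int))
    return IsosurfaceReport(
        level=float(level),
        n_voxels=int(above.sum()),
        n_components=int(n_comp),
        mask=grid.with_values(above.astype(float), value_cap=np.inf),
    )


@dataclass(frozen=True)
class OccupancySeries:
    """Per-frame ligand counts in a region and their windowed time average."""

    counts: np.ndarray  # (n_frames,) int
    mean: float
    window: tuple[int, int]


def region_occupancy(
    traj: LigandTrajectory,
    region: RegionSpec,
    window: tuple[int, int] | None = None,
) -> OccupancySeries:
    """Count ligands inside a region per frame and average over a window.

    ``window`` is a half-open frame range (start, stop); by default the whole
    trajectory is averaged.
    """
    counts = np.array(
        [int(region.contains(traj.positions[f]).sum()) for f in range(traj.n_frames)]
    )
    if window is None:
        window = (0, traj.n_frames)
    lo, hi = window
    if not (0 <= lo < hi <= traj.n_frames):
        raise ValidationError("window: must satisfy 0 <= start < stop <= n_frames")
    return OccupancySeries(counts=counts, mean=float(counts[lo:hi].mean()), window=(lo, hi))
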