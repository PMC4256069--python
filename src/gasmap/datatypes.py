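"""Core domain types shared across the package.

All coordinates are in Å, energies in kJ·mol⁻¹, temperatures in K.
Grids are axis-aligned with C-ordered (x, y, z) value arrays; voxel *centers*
define positions: ``position = origin + index * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

#: Molar gas constant in kJ·mol⁻¹·K⁻¹ (energies here are per mole).
KB = 0.008314462618


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


def _as_array(x, shape=None, name="array") -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if shape is not None and a.shape != tuple(shape):
        raise ValidationError(f"{name}: expected shape {tuple(shape)}, got {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValidationError(f"{name}: contains non-finite values")
    return a


@dataclass(frozen=True)
class ScalarGrid3D:
    """Axis-aligned 3D grid of scalar values.

    Parameters
    ----------
    origin : (3,) array
        Position of the *center* of voxel (0, 0, 0), Å.
    spacing : (3,) array
        Voxel edge lengths per axis, Å.
    values : (nx, ny, nz) array
        Per-voxel scalar (kJ·mol⁻¹ for energy maps, Å⁻³ for densities).
    value_cap : float
        Sentinel for "effectively infinite" energy; voxels at the cap are
        treated as impenetrable by downstream landscape analysis.
    """

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray
    value_cap: float = np.inf

    def __post_init__(self):
        origin = _as_array(self.origin, (3,), "origin")
        spacing = _as_array(self.spacing, (3,), "spacing")
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3 or min(values.shape) < 1:
            raise ValidationError(f"values: expected 3D array, got shape {values.shape}")
        if np.any(spacing <= 0):
            raise ValidationError("spacing: must be > 0 on every axis")
        finite = np.isfinite(values)
        if not np.all(finite | (values == self.value_cap)):
            raise ValidationError("values: must be finite or equal to value_cap")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "values", values)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_voxels(self) -> int:
        return self.values.size

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis voxel-center coordinates."""
        return tuple(
            self.origin[i] + self.spacing[i] * np.arange(self.dims[i]) for i in range(3)
        )

    def voxel_centers(self) -> np.ndarray:
        """All voxel-center positions as an (n_voxels, 3) array in C order."""
        ax, ay, az = self.axes()
        gx, gy, gz = np.meshgrid(ax, ay, az, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def position_of(self, index: Sequence[int]) -> np.ndarray:
        return self.origin + self.spacing * np.asarray(index, dtype=float)

    def index_of(self, position) -> tuple[int, int, int]:
        """Nearest voxel (center) index of a position; may lie outside the grid."""
        idx = np.rint((np.asarray(position, float) - self.origin) / self.spacing)
        return tuple(int(i) for i in idx)

    def contains_index(self, index) -> bool:
        return all(0 <= i < n for i, n in zip(index, self.dims))

    def with_values(self, values: np.ndarray, value_cap: float | None = None) -> "ScalarGrid3D":
        return ScalarGrid3D(
            self.origin, self.spacing, values,
            self.value_cap if value_cap is None else value_cap,
        )


@dataclass(frozen=True)
class ConformationEnsemble:
    """Frames of matrix-site coordinates with per-site LJ parameters.

    This is the fluctuating environment the probe is inserted into: the
    ensemble average in the ILS free-energy estimate runs over its frames.

    Attributes
    ----------
    coordinates : (n_frames, n_sites, 3) array, Å
    lj_params : (n_sites, 2) array
        Columns are (epsilon kJ·mol⁻¹, sigma Å).
    box_lengths : (3,) array, Å (orthorhombic box)
    frame_weights : (n_frames,) array
        Non-negative, normalized to sum to 1. Defaults to uniform.
    """

    coordinates: np.ndarray
    lj_params: np.ndarray
    box_lengths: np.ndarray
    frame_weights: np.ndarray | None = None

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValidationError(
                f"coordinates: expected (n_frames, n_sites, 3), got {coords.shape}"
            )
        if not np.all(np.isfinite(coords)):
            raise ValidationError("coordinates: contains non-finite values")
        lj = _as_array(self.lj_params, (coords.shape[1], 2), "lj_params")
        if np.any(lj[:, 0] < 0):
            raise ValidationError("lj_params: epsilon must be >= 0")
        if np.any(lj[:, 1] <= 0):
            raise ValidationError("lj_params: sigma must be > 0")
        box = _as_array(self.box_lengths, (3,), "box_lengths")
        if np.any(box <= 0):
            raise ValidationError("box_lengths: must be > 0")
        if self.frame_weights is None:
            w = np.full(coords.shape[0], 1.0 / coords.shape[0])
        else:
            w = _as_array(self.frame_weights, (coords.shape[0],), "frame_weights")
            if np.any(w < 0):
                raise ValidationError("frame_weights: must be >= 0")
            total = w.sum()
            if total <= 0:
                raise ValidationError("frame_weights: must sum to a positive value")
            w = w / total
        object.__setattr__(self, "coordinates", coords)
        object.__setattr__(self, "lj_params", lj)
        object.__setattr__(self, "box_lengths", box)
        object.__setattr__(self, "frame_weights", w)

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_sites(self) -> int:
        return self.coordinates.shape[1]


@dataclass(frozen=True)
class ProbeSpec:
    """Rigid diatomic apolar probe: two LJ sites a fixed bond length apart.

    Charges are fixed at zero — the probe interacts through dispersion and
    steric repulsion only, appropriate for O₂-like gas molecules.
    """

    site_lj: np.ndarray  # (2, 2): rows are sites, columns (epsilon, sigma)
    bond_length: float

    def __post_init__(self):
        lj = _as_array(self.site_lj, (2, 2), "site_lj")
        if np.any(lj[:, 0] < 0):
            raise ValidationError("site_lj: epsilon must be >= 0")
        if np.any(lj[:, 1] <= 0):
            raise ValidationError("site_lj: sigma must be > 0")
        if not self.bond_length > 0:
            raise ValidationError("bond_length: must be > 0")
        object.__setattr__(self, "site_lj", lj)

    @classmethod
    def homonuclear(cls, epsilon: float, sigma: float, bond_length: float) -> "ProbeSpec":
        return cls(site_lj=[[epsilon, sigma], [epsilon, sigma]], bond_length=bond_length)


#: Default O₂-like probe: homonuclear diatomic with typical united-site LJ
#: parameters (ε ≈ 0.4 kJ·mol⁻¹, σ ≈ 3.0 Å) and the O–O bond length.
def default_o2_probe() -> ProbeSpec:
    return ProbeSpec.homonuclear(epsilon=0.40, sigma=3.00, bond_length=1.21)


@dataclass(frozen=True)
class ILSSettings:
    """Sampling controls for the implicit-ligand-sampling engine."""

    n_insertions_per_voxel: int = 400
    insertion_region: Literal["cube", "inscribed_sphere"] = "cube"
    lj_cutoff: float = 14.0
    temperature: float = 310.0
    periodic: bool = False
    seed: int = 0
    value_cap: float = 100.0
    combining_rule: Literal["lorentz_berthelot", "geometric"] = "lorentz_berthelot"
    #: Placement scheme for the per-voxel insertions. "sobol" (default) draws
    #: scrambled low-discrepancy points over (position, orientation) — unbiased
    #: and markedly lower-variance near steric walls; "stratified" jitters a
    #: position sub-grid; "uniform" is plain independent sampling.
    sampling: Literal["sobol", "stratified", "uniform"] = "sobol"

    def __post_init__(self):
        if self.n_insertions_per_voxel < 1:
            raise ValidationError("n_insertions_per_voxel: must be >= 1")
        if not self.lj_cutoff > 0:
            raise ValidationError("lj_cutoff: must be > 0")
        if not self.temperature > 0:
            raise ValidationError("temperature: must be > 0")
        if self.insertion_region not in ("cube", "inscribed_sphere"):
            raise ValidationError(f"insertion_region: unknown mode {self.insertion_region!r}")
        if self.combining_rule not in ("lorentz_berthelot", "geometric"):
            raise ValidationError(f"combining_rule: unknown rule {self.combining_rule!r}")
        if self.sampling not in ("sobol", "stratified", "uniform"):
            raise ValidationError(f"sampling: unknown scheme {self.sampling!r}")

    @property
    def kt(self) -> float:
        return KB * self.temperature


@dataclass(frozen=True)
class FreeEnergyMap:
    """A probe free-energy grid with its provenance.

    ``reference`` states the zero of energy: "vacuum" (free energy of moving
    the probe from vacuum to each voxel) or "water" (from bulk water).
    """

    grid: ScalarGrid3D
    reference: Literal["vacuum", "water"]
    settings: ILSSettings
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.reference not in ("vacuum", "water"):
            raise ValidationError(f"reference: must be 'vacuum' or 'water', got {self.reference!r}")

    def shifted(self, offset: float, reference: str) -> "FreeEnergyMap":
        """Subtract ``offset`` from all non-capped voxels and relabel the reference."""
        v = self.grid.values
        capped = v >= self.grid.value_cap
        new = np.where(capped, self.grid.value_cap, v - offset)
        prov = dict(self.provenance)
        prov["reference_offset"] = float(offset)
        return FreeEnergyMap(
            grid=self.grid.with_values(new), reference=reference,
            settings=self.settings, provenance=prov,
        )


@dataclass(frozen=True)
class SuperpositionResult:
    """Rigid-body least-squares fit of one frame onto a reference."""

    rotation: np.ndarray  # (3, 3), proper orthonormal
    translation: np.ndarray  # (3,)
    rmsd: float

    def __post_init__(self):
        rot = _as_array(self.rotation, (3, 3), "rotation")
        if not np.isclose(np.linalg.det(rot), 1.0, atol=1e-6):
            raise ValidationError("rotation: must be proper (det = +1)")
        trans = _as_array(self.translation, (3,), "translation")
        if self.rmsd < 0:
            raise ValidationError("rmsd: must be >= 0")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", trans)

    def apply(self, positions: np.ndarray) -> np.ndarray:
        return positions @ self.rotation.T + self.translation


@dataclass(frozen=True)
class ToySystemSpec:
    """A fluctuating LJ matrix with engineered cavities and gated constrictions.

    Each matrix site fluctuates isotropically about its mean position with a
    Gaussian displacement of standard deviation ``thermal_sigma`` — the
    minimal model of thermal side-chain motion opening and closing a channel.
    """

    box_lengths: np.ndarray
    mean_positions: np.ndarray  # (n_sites, 3)
    lj_epsilon: np.ndarray  # (n_sites,)
    lj_sigma: np.ndarray  # (n_sites,)
    thermal_sigma: np.ndarray  # (n_sites,)
    cavity_centers: np.ndarray  # (n_cavities, 3)
    gate_indices: np.ndarray  # indices into sites flagged as constriction gates
    temperature: float = 310.0
    seed: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        box = _as_array(self.box_lengths, (3,), "box_lengths")
        if np.any(box <= 0):
            raise ValidationError("box_lengths: must be > 0")
        pos = np.asarray(self.mean_positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValidationError(f"mean_positions: expected (n_sites, 3), got {pos.shape}")
        if not np.all(np.isfinite(pos)):
            raise ValidationError("mean_positions: contains non-finite values")
        if np.any(pos < 0) or np.any(pos > box):
            raise ValidationError("mean_positions: all mean positions must lie inside the box")
        n = pos.shape[0]
        eps = _as_array(self.lj_epsilon, (n,), "lj_epsilon")
        sig = _as_array(self.lj_sigma, (n,), "lj_sigma")
        tsig = _as_array(self.thermal_sigma, (n,), "thermal_sigma")
        if np.any(eps < 0):
            raise ValidationError("lj_epsilon: must be >= 0")
        if np.any(sig <= 0):
            raise ValidationError("lj_sigma: must be > 0")
        if np.any(tsig < 0):
            raise ValidationError("thermal_sigma: must be >= 0")
        cav = np.asarray(self.cavity_centers, dtype=float).reshape(-1, 3)
        gates = np.asarray(self.gate_indices, dtype=int).ravel()
        if gates.size and (gates.min() < 0 or gates.max() >= n):
            raise ValidationError("gate_indices: out of range")
        if not self.temperature > 0:
            raise ValidationError("temperature: must be > 0")
        object.__setattr__(self, "box_lengths", box)
        object.__setattr__(self, "mean_positions", pos)
        object.__setattr__(self, "lj_epsilon", eps)
        object.__setattr__(self, "lj_sigma", sig)
        object.__setattr__(self, "thermal_sigma", tsig)
        object.__setattr__(self, "cavity_centers", cav)
        object.__setattr__(self, "gate_indices", gates)

    @property
    def n_sites(self) -> int:
        return self.mean_positions.shape[0]

    @property
    def lj_params(self) -> np.ndarray:
        return np.column_stack([self.lj_epsilon, self.lj_sigma])


@dataclass(frozen=True)
class LigandTrajectory:
    """Per-frame ligand center-of-geometry positions.

    ``positions`` has shape (n_frames, n_ligands, 3); a ligand absent from a
    frame is marked with NaN in all three components.
    """

    positions: np.ndarray
    box_lengths: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 3 or pos.shape[2] != 3:
            raise ValidationError(f"positions: expected (n_frames, n_ligands, 3), got {pos.shape}")
        absent = np.isnan(pos)
        if np.any(absent.any(axis=2) != absent.all(axis=2)):
            raise ValidationError("positions: absence must be marked with NaN in all 3 components")
        if np.any(np.isinf(pos)):
            raise ValidationError("positions: contains infinite values")
        box = _as_array(self.box_lengths, (3,), "box_lengths")
        if np.any(box <= 0):
            raise ValidationError("box_lengths: must be > 0")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "box_lengths", box)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_ligands(self) -> int:
        return self.positions.shape[1]


@dataclass(frozen=True)
class RegionSpec:
    """Geometric region for occupancy counting.

    kinds
    -----
    slab : params = {"axis": 0|1|2, "lo": float, "hi": float}
    sphere : params = {"center": (3,), "radius": float}
    grid_mask : params = {"grid": ScalarGrid3D with boolean-like values}
    """

    kind: Literal["slab", "sphere", "grid_mask"]
    params: dict

    def __post_init__(self):
        if self.kind == "slab":
            axis = self.params.get("axis")
            lo, hi = self.params.get("lo"), self.params.get("hi")
            if axis not in (0, 1, 2):
                raise ValidationError("slab: axis must be 0, 1 or 2")
            if lo is None or hi is None or not lo < hi:
                raise ValidationError("slab: bounds must satisfy lo < hi")
        elif self.kind == "sphere":
            center = np.asarray(self.params.get("center"), dtype=float)
            if center.shape != (3,) or not np.all(np.isfinite(center)):
                raise ValidationError("sphere: center must be a finite 3-vector")
            if not self.params.get("radius", 0) > 0:
                raise ValidationError("sphere: radius must be > 0")
        elif self.kind == "grid_mask":
            if not isinstance(self.params.get("grid"), ScalarGrid3D):
                raise ValidationError("grid_mask: params['grid'] must be a ScalarGrid3D")
        else:
            raise ValidationError(f"unknown region kind {self.kind!r}")

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership for an (n, 3) array of positions (NaN rows → False)."""
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        valid = ~np.isnan(pts).any(axis=1)
        out = np.zeros(len(pts), dtype=bool)
        if self.kind == "slab":
            ax, lo, hi = self.params["axis"], self.params["lo"], self.params["hi"]
            out[valid] = (pts[valid, ax] >= lo) & (pts[valid, ax] < hi)
        elif self.kind == "sphere":
            c = np.asarray(self.params["center"], float)
            r = self.params["radius"]
            out[valid] = np.sum((pts[valid] - c) ** 2, axis=1) <= r * r
        else:
            grid: ScalarGrid3D = self.params["grid"]
            idx = np.rint((pts[valid] - grid.origin) / grid.spacing).astype(int)
            inside = np.all((idx >= 0) & (idx < np.array(grid.dims)), axis=1)
            sub = np.zeros(inside.shape, dtype=bool)
            ii = idx[inside]
            sub[inside] = grid.values[ii[:, 0], ii[:, 1], ii[:, 2]] > 0
            out[valid] = sub
        return out


__all__ = [
    "KB",
    "ValidationError",
    "ScalarGrid3D",
    "ConformationEnsemble",
    "ProbeSpec",
    "default_o2_probe",
    "ILSSettings",
    "FreeEnergyMap",
    "SuperpositionResult",
    "ToySystemSpec",
    "LigandTrajectory",
    "RegionSpec",
    "replace",
]
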