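"""Reading, writing and superposing conformational ensembles and grids.

Ensembles travel as multi-model PDB or XYZ frame stacks (read and written
through MDAnalysis) with a plain-text Lennard-Jones sidecar table
(``site_id  epsilon  sigma`` columns; the orthorhombic box appears as a
``# box`` comment). Volumetric grids are stored as OpenDX files via
gridData, with the value cap recorded in a header comment so energy maps
round-trip losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .datatypes import (
    ConformationEnsemble,
    ScalarGrid3D,
    SuperpositionResult,
    ValidationError,
)

__all__ = [
    "superpose_frames",
    "read_ensemble",
    "write_ensemble",
    "read_lj_table",
    "write_lj_table",
    "read_grid",
    "write_grid",
    "write_superposition_report",
]


def superpose_frames(
    ensemble: ConformationEnsemble,
    reference: np.ndarray,
    fit_subset: np.ndarray,
) -> tuple[ConformationEnsemble, list[SuperpositionResult]]:
    """Rigidly fit every frame onto a reference using a subset of sites.

    The rotation/translation minimising the RMSD of the ``fit_subset`` sites
    onto the reference (Kabsch least squares) is found per frame and applied
    to *all* sites of that frame — the standard protocol of fitting a
    trajectory on backbone atoms before grid analysis.

    ``reference`` may hold positions for all sites (indexed by the subset) or
    for the subset only.
    """
    from scipy.spatial.transform import Rotation

    subset = np.asarray(fit_subset, int).ravel()
    if subset.size < 3:
        raise ValidationError("fit_subset: need at least 3 sites")
    ref = np.asarray(reference, float)
    if ref.shape == (ensemble.n_sites, 3):
        ref_sub = ref[subset]
    elif ref.shape == (subset.size, 3):
        ref_sub = ref
    else:
        raise ValidationError(
            "reference: must provide positions for all sites or for the fit subset"
        )
    ref_centroid = ref_sub.mean(axis=0)
    ref_c = ref_sub - ref_centroid
    svals = np.linalg.svd(ref_c, compute_uv=False)
    if svals[1] < 1e-8 * max(1.0, svals[0]):
        raise ValidationError("fit_subset: reference subset sites are collinear")

    new_coords = np.empty_like(ensemble.coordinates)
    results = []
    for f in range(ensemble.n_frames):
        mov = ensemble.coordinates[f][subset]
        mov_centroid = mov.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref_c, mov - mov_centroid)
        rmat = rot.as_matrix()
        translation = ref_centroid - rmat @ mov_centroid
        new_coords[f] = ensemble.coordinates[f] @ rmat.T + translation
        resid = new_coords[f][subset] - ref_sub
        results.append(
            SuperpositionResult(
                rotation=rmat,
                translation=translation,
                rmsd=float(np.sqrt((resid**2).sum() / subset.size)),
            )
        )
    fitted = ConformationEnsemble(
        new_coords, ensemble.lj_params, ensemble.box_lengths, ensemble.frame_weights
    )
    return fitted, results


# ---------------------------------------------------------------------------
# LJ sidecar table


def write_lj_table(lj_params: np.ndarray, path, box_lengths=None) -> None:
    """Plain-text sidecar: ``site_id epsilon sigma`` rows, box in a comment."""
    lj = np.asarray(lj_params, float).reshape(-1, 2)
    lines = ["# gasmap LJ site parameters: site_id epsilon(kJ/mol) sigma(A)"]
    if box_lengths is not None:
        b = np.asarray(box_lengths, float)
        lines.append(f"# box {b[0]:.6f} {b[1]:.6f} {b[2]:.6f}")
    for i, (e, s) in enumerate(lj):
        lines.append(f"{i} {e:.8g} {s:.8g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_lj_table(path) -> tuple[np.ndarray, np.ndarray | None]:
    """Read the LJ sidecar; returns (params, box or None)."""
    box = None
    rows = []
    for ln, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split()
            if parts[:1] == ["box"] and len(parts) == 4:
                box = np.array([float(x) for x in parts[1:]])
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValidationError(f"{path}: line {ln}: expected 'site_id epsilon sigma'")
        rows.append((int(parts[0]), float(parts[1]), float(parts[2])))
    if not rows:
        raise ValidationError(f"{path}: no LJ parameter rows found")
    rows.sort()
    ids = [r[0] for r in rows]
    if ids != list(range(len(rows))):
        raise ValidationError(f"{path}: site ids must be 0..n-1 without gaps")
    return np.array([[e, s] for _, e, s in rows]), box


# ---------------------------------------------------------------------------
# Ensembles


def _mda_universe(ensemble: ConformationEnsemble):
    import MDAnalysis as mda

    u = mda.Universe.empty(
        n_atoms=ensemble.n_sites, n_residues=1, atom_resindex=np.zeros(ensemble.n_sites, int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", [f"S{i}" for i in range(ensemble.n_sites)])
    u.add_TopologyAttr("resnames", ["SYS"])
    u.add_TopologyAttr("resids", [1])
    dims = np.array([*ensemble.box_lengths, 90.0, 90.0, 90.0], dtype=np.float32)
    u.load_new(
        ensemble.coordinates.astype(np.float32),
        format="memory",
        dimensions=np.tile(dims, (ensemble.n_frames, 1)),
    )
    return u


def write_ensemble(ensemble: ConformationEnsemble, path, lj_path=None) -> None:
    """Write an ensemble as a multi-frame coordinate file (PDB or XYZ by
    extension), optionally with its LJ sidecar."""
    import MDAnalysis as mda

    path = Path(path)
    u = _mda_universe(ensemble)
    with mda.Writer(str(path), n_atoms=ensemble.n_sites, multiframe=True) as w:
        for _ in u.trajectory:
            w.write(u.atoms)
    if lj_path is not None:
        write_lj_table(ensemble.lj_params, lj_path, ensemble.box_lengths)


def read_ensemble(paths, lj_table) -> ConformationEnsemble:
    """Assemble a ConformationEnsemble from coordinate file(s) and a sidecar.

    ``paths`` is one path or a list; frames are concatenated in order. Every
    frame must contain the same number of sites, matching the sidecar; the
    box is taken from the coordinate file when present, else from the
    sidecar's ``# box`` comment.
    """
    import MDAnalysis as mda

    if isinstance(paths, (str, Path)):
        paths = [paths]
    lj, box_sidecar = read_lj_table(lj_table)

    frames = []
    box = None
    n_sites = None
    for pi, p in enumerate(paths):
        try:
            u = mda.Universe(str(p))
        except Exception as exc:  # noqa: BLE001 - re-raise with file context
            raise ValidationError(f"{p}: could not parse coordinate file: {exc}") from exc
        if n_sites is None:
            n_sites = len(u.atoms)
        elif len(u.atoms) != n_sites:
            raise ValidationError(
                f"{p} (file {pi}, frame {len(frames)}): has {len(u.atoms)} sites, "
                f"expected {n_sites}"
            )
        for ts in u.trajectory:
            frames.append(ts.positions.astype(float).copy())
            if box is None and ts.dimensions is not None and ts.dimensions[:3].all():
                box = ts.dimensions[:3].astype(float)
    if n_sites != lj.shape[0]:
        raise ValidationError(
            f"LJ sidecar has {lj.shape[0]} sites but coordinates have {n_sites}"
        )
    if box is None:
        box = box_sidecar
    if box is None:
        raise ValidationError("no box information in coordinate files or LJ sidecar")
    return ConformationEnsemble(np.stack(frames), lj, box)


# ---------------------------------------------------------------------------
# Grids (OpenDX)


def write_grid(grid: ScalarGrid3D, path) -> None:
    """Write a grid as OpenDX; the value cap is recorded in a header comment."""
    from gridData import Grid

    g = Grid(grid.values, origin=np.asarray(grid.origin), delta=np.asarray(grid.spacing))
    g.export(str(path), file_format="dx")
    text = Path(path).read_text()
    Path(path).write_text(f"# gasmap value_cap={grid.value_cap!r}\n" + text)


def read_grid(path) -> ScalarGrid3D:
    """Read an OpenDX grid written by :func:`write_grid` (or any DX file)."""
    from gridData import Grid

    cap = np.inf
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "value_cap=" in line:
                cap = float(line.split("value_cap=")[1].strip().strip("'\""))
    g = Grid(str(path))
    return ScalarGrid3D(
        origin=np.asarray(g.origin, float),
        spacing=np.asarray(
            g.delta if np.ndim(g.delta) == 1 else np.diag(g.delta), float
        ),
        values=np.asarray(g.grid, float),
        value_cap=cap,
    )


def write_superposition_report(results: list[SuperpositionResult], path) -> None:
    """Per-frame superposition results as JSON."""
    payload = [
        {
            "frame": i,
            "rotation": r.rotation.tolist(),
            "translation": r.translation.tolist(),
            "rmsd": r.rmsd,
        }
        for i, r in enumerate(results)
    ]
    Path(path).write_text(json.dumps(payload, indent=1))
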