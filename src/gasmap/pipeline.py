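"""End-to-end pipeline: synthesize → ILS map → density map → landscape → report.

A single TOML (or dict) configuration drives all stages; every random choice
derives from one seed, so a rerun with the same configuration reproduces
bit-identical artifacts, which the written manifest records with SHA-256
checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from . import density as density_mod
from . import ensemble_io, ils, landscape, synthetic
from .datatypes import ILSSettings, ValidationError, default_o2_probe

logger = logging.getLogger("gasmap.pipeline")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

_DEFAULTS: dict = {
    "run": {"outdir": "gasmap_out", "seed": 0, "stages": ["synth", "ils", "density", "landscape"]},
    "synth": {"open_fraction": 1.0, "n_frames": 6},
    "probe": {"epsilon": 0.40, "sigma": 3.00, "bond_length": 1.21},
    "input": {},  # optional: {"ensemble": path, "lj_table": path} replaces synth
    "ils": {
        "insertions": 128,
        "spacing": 1.5,
        "temperature": 310.0,
        "lj_cutoff": 14.0,
        "value_cap": 100.0,
        "reference_offset": 0.0,
    },
    "density": {"n_steps": 20000, "iso_level": 1.5e-4},
    "landscape": {"cutoff": 20.0, "connectivity": 26, "cutoff_mode": "voxel"},
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``_DEFAULTS`` for the schema)."""

    sections: dict = field(default_factory=dict)

    def __post_init__(self):
        merged = {}
        for name, defaults in _DEFAULTS.items():
            merged[name] = {**defaults, **self.sections.get(name, {})}
        unknown = set(self.sections) - set(_DEFAULTS)
        if unknown:
            raise ValidationError(f"config: unknown sections {sorted(unknown)}")
        self.sections = merged
        inp = merged["input"]
        if inp:
            for key in ("ensemble", "lj_table"):
                if key not in inp:
                    raise ValidationError(f"config [input]: missing {key!r}")
                if not Path(inp[key]).exists():
                    raise ValidationError(f"config [input]: {key} file not found: {inp[key]}")
        for stage in merged["run"]["stages"]:
            if stage not in ("synth", "ils", "density", "landscape"):
                raise ValidationError(f"config: unknown stage {stage!r}")

    def __getitem__(self, name: str) -> dict:
        return self.sections[name]


def load_config(path) -> PipelineConfig:
    with open(path, "rb") as fh:
        return PipelineConfig(tomllib.load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _auto_grid(box: np.ndarray, spacing: float, cap: float):
    dims = np.maximum(2, np.floor(box / spacing).astype(int))
    origin = (box - spacing * (dims - 1)) / 2.0
    return ils.make_grid(origin, spacing, dims, value_cap=cap)


def run_pipeline(config: PipelineConfig | dict, outdir=None) -> dict:
    """Execute the configured stages and write artifacts plus a manifest.

    Returns the manifest dictionary. A stage failure aborts the run with the
    failing stage named; artifacts written up to that point stay on disk next
    to a ``FAILED.<stage>`` marker file.
    """
    if isinstance(config, dict):
        config = PipelineConfig(config)
    run_cfg = config["run"]
    out = Path(outdir if outdir is not None else run_cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(run_cfg["seed"])
    stages = list(run_cfg["stages"])

    probe_cfg = config["probe"]
    probe = default_o2_probe()
    if probe_cfg:
        from .datatypes import ProbeSpec

        probe = ProbeSpec.homonuclear(
            probe_cfg["epsilon"], probe_cfg["sigma"], probe_cfg["bond_length"]
        )

    manifest: dict = {
        "config": config.sections,
        "stages_run": [],
        "artifacts": {},
        "stats": {},
    }
    artifacts = manifest["artifacts"]

    def register(name: str, path: Path):
        artifacts[name] = {"path": str(path), "sha256": _sha256(path)}

    ensemble = None
    fe_map = None
    current = None
    try:
        if config["input"]:
            ensemble = ensemble_io.read_ensemble(
                config["input"]["ensemble"], config["input"]["lj_table"]
            )

        if "synth" in stages and ensemble is None:
            current = "synth"
            t0 = time.perf_counter()
            spec = synthetic.make_channel_system(config["synth"]["open_fraction"], seed=seed)
            ensemble = synthetic.make_fluctuating_ensemble(spec, config["synth"]["n_frames"])
            ens_path = out / "ensemble.xyz"
            lj_path = out / "lj_table.txt"
            ensemble_io.write_ensemble(ensemble, ens_path, lj_path)
            register("ensemble", ens_path)
            register("lj_table", lj_path)
            manifest["stats"]["synth"] = {
                "n_sites": ensemble.n_sites,
                "n_frames": ensemble.n_frames,
                "gate_ring_radius": spec.metadata["gate_ring_radius"],
                "seconds": round(time.perf_counter() - t0, 3),
            }
            manifest["stages_run"].append("synth")
            logger.info("synth: %d sites x %d frames", ensemble.n_sites, ensemble.n_frames)

        if "ils" in stages:
            current = "ils"
            if ensemble is None:
                raise ValidationError("ils stage needs an ensemble (run synth or set [input])")
            t0 = time.perf_counter()
            icfg = config["ils"]
            settings = ILSSettings(
                n_insertions_per_voxel=int(icfg["insertions"]),
                lj_cutoff=icfg["lj_cutoff"],
                temperature=icfg["temperature"],
                seed=seed,
                value_cap=icfg["value_cap"],
            )
            grid = _auto_grid(ensemble.box_lengths, icfg["spacing"], icfg["value_cap"])
            fe_map = ils.compute_ils_map(ensemble, probe, grid, settings)
            if icfg["reference_offset"] != 0.0:
                fe_map = ils.convert_reference(fe_map, icfg["reference_offset"])
            map_path = out / "map.dx"
            ensemble_io.write_grid(fe_map.grid, map_path)
            register("free_energy_map", map_path)
            manifest["stats"]["ils"] = {
                "n_voxels": fe_map.grid.n_voxels,
                "n_capped_voxels": fe_map.provenance["n_capped_voxels"],
                "seconds": round(time.perf_counter() - t0, 3),
            }
            manifest["stages_run"].append("ils")
            logger.info(
                "ils: %d voxels, %d capped",
                fe_map.grid.n_voxels,
                fe_map.provenance["n_capped_voxels"],
            )

        if "density" in stages:
            current = "density"
            if ensemble is None:
                raise ValidationError("density stage needs an ensemble")
            t0 = time.perf_counter()
            dcfg = config["density"]
            traj = synthetic.sample_explicit_ligand(
                ensemble, probe, int(dcfg["n_steps"]),
                temperature=config["ils"]["temperature"], seed=seed,
            )
            grid = _auto_grid(ensemble.box_lengths, config["ils"]["spacing"], np.inf)
            dens = density_mod.compute_density_map(traj, grid)
            dens_path = out / "density.dx"
            ensemble_io.write_grid(dens.grid, dens_path)
            register("density_map", dens_path)
            iso = density_mod.isosurface_report(dens.grid, dcfg["iso_level"])
            manifest["stats"]["density"] = {
                "mean_inside": dens.mean_inside,
                "iso_voxels": iso.n_voxels,
                "iso_components": iso.n_components,
                "seconds": round(time.perf_counter() - t0, 3),
            }
            manifest["stages_run"].append("density")
            logger.info("density: %d iso voxels in %d components", iso.n_voxels, iso.n_components)

        if "landscape" in stages:
            current = "landscape"
            if fe_map is None:
                raise ValidationError("landscape stage needs the ils stage (or a map input)")
            t0 = time.perf_counter()
            lcfg = config["landscape"]
            tess = landscape.tessellate(
                fe_map.grid, int(lcfg["connectivity"]), float(lcfg["cutoff"])
            )
            saddles = landscape.find_saddles(fe_map.grid, tess)
            net = landscape.build_network(
                fe_map.grid, tess, saddles, float(lcfg["cutoff"]), lcfg["cutoff_mode"]
            )
            net_path = out / "network.json"
            _write_network_json(net, net_path)
            register("network", net_path)
            profile_stats = _demo_profile(net, out, register)
            manifest["stats"]["landscape"] = {
                "n_minima": tess.n_basins,
                "n_saddles": len(saddles),
                "n_exterior": len(net.exterior_nodes),
                **profile_stats,
                "seconds": round(time.perf_counter() - t0, 3),
            }
            manifest["stages_run"].append("landscape")
            logger.info("landscape: %d minima, %d saddles", tess.n_basins, len(saddles))

    except Exception as exc:
        marker = out / f"FAILED.{current}"
        marker.write_text(f"stage {current!r} failed: {exc}\n")
        raise ValidationError(f"pipeline stage {current!r} failed: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
    return manifest


def _write_network_json(net: landscape.PathwayNetwork, path: Path) -> None:
    g = net.graph
    payload = {
        "cutoff": net.cutoff,
        "cutoff_mode": net.cutoff_mode,
        "nodes": [
            {
                "id": int(u),
                "position": [round(float(x), 6) for x in d["position"]],
                "energy": round(float(d["energy"]), 6),
                "exterior": bool(d["exterior"]),
            }
            for u, d in sorted(g.nodes(data=True))
        ],
        "edges": [
            {
                "basins": [int(u), int(v)],
                "saddle_energy": round(float(d["saddle_energy"]), 6),
                "saddle_voxel": list(d["saddle_voxel"]),
                "barrier_forward": round(float(d["barrier_forward"]), 6),
                "barrier_reverse": round(float(d["barrier_reverse"]), 6),
                "path": [[round(float(x), 6) for x in p] for p in d["path"]],
            }
            for u, v, d in sorted(g.edges(data=True))
        ],
    }
    path.write_text(json.dumps(payload, indent=1))


def _demo_profile(net: landscape.PathwayNetwork, out: Path, register) -> dict:
    """Profile along the route from an exterior minimum to the deepest minimum."""
    g = net.graph
    if g.number_of_nodes() == 0:
        return {"profile": "no minima"}
    deepest = min(g.nodes, key=lambda u: g.nodes[u]["energy"])
    ext = [u for u in net.exterior_nodes if u != deepest]
    if not ext:
        return {"profile": "no exterior minimum distinct from the deepest"}
    start = min(ext, key=lambda u: g.nodes[u]["energy"])
    try:
        route = nx.shortest_path(g, start, deepest)
    except nx.NetworkXNoPath:
        return {"profile": "exterior and deepest minima not connected below cutoff"}
    if len(route) < 2:
        return {"profile": "trivial route"}
    prof = landscape.extract_profile(net, route)
    lines = ["step,node,minimum_energy,saddle_energy,forward_barrier"]
    for i, u in enumerate(route):
        s = "" if i >= len(prof.saddle_energies) else f"{prof.saddle_energies[i]:.6f}"
        b = "" if i >= len(prof.forward_barriers) else f"{prof.forward_barriers[i]:.6f}"
        lines.append(f"{i},{u},{prof.minima_energies[i]:.6f},{s},{b}")
    prof_path = out / "profile.csv"
    prof_path.write_text("\n".join(lines) + "\n")
    register("profile", prof_path)
    return {
        "profile_route": [int(u) for u in route],
        "profile_max_barrier": float(prof.forward_barriers.max()),
    }
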