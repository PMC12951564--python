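"""Configuration-driven orchestration of the analysis stages.

A run config (YAML) either points at input files (topology PDB, charge
table, trajectory) or at a builder spec that generates a synthetic system;
it then lists the stages to run and any parameter overrides.  Each stage
writes tidy TSV under ``<out>/<stage>/``; a JSON manifest records the
package version, parameters, seed and input hashes so a run can be
reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model import Topology, Trajectory
from . import builder, clustering, conformation, electrostatics, hydration, io

logger = logging.getLogger("glycotraj")

KNOWN_STAGES = ("rmsd", "rmsf", "rg", "ree", "torsions", "pucker", "fes",
                "rdf", "hbonds", "dipoles", "efield", "cluster")

DEFAULTS = {
    "d_cut": 3.5,
    "angle_cut_deg": 150.0,
    "first_shell_cutoff": 3.5,
    "cavity_radius": 4.0,
    "fes_bins": 72,
    "temperature_K": 298.0,
    "rdf_r_max": 10.0,
    "rdf_bin_width": 0.05,
    "k_range": [2, 10],
    "n_blocks": 2,
    "points_per_block": 12,
    "include_solvent": False,
}


@dataclass
class RunConfig:
    stages: list[str]
    output_dir: Path
    seed: int = 0
    topology: Path | None = None
    charges: Path | None = None
    trajectory: Path | None = None
    builder_spec: dict | None = None
    chain: str = "A"
    params: dict = field(default_factory=lambda: dict(DEFAULTS))


def validate_config(path: str | Path) -> RunConfig:
    """Load, validate and normalize a YAML run config; raise with the
    offending key path on any violation."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    errors: list[str] = []
    stages = raw.get("stages", list(KNOWN_STAGES))
    for s in stages:
        if s not in KNOWN_STAGES:
            errors.append(f"stages: unknown stage {s!r} (known: {', '.join(KNOWN_STAGES)})")
    params = dict(DEFAULTS)
    for key, val in (raw.get("params") or {}).items():
        if key not in DEFAULTS:
            errors.append(f"params.{key}: unknown parameter")
            continue
        params[key] = val
    for key in ("d_cut", "first_shell_cutoff", "cavity_radius", "rdf_r_max", "rdf_bin_width"):
        if not isinstance(params[key], (int, float)) or params[key] <= 0:
            errors.append(f"params.{key}: must be a positive number")
    if params["fes_bins"] < 2:
        errors.append("params.fes_bins: must be >= 2")
    builder_spec = raw.get("builder")
    topology = raw.get("topology")
    trajectory = raw.get("trajectory")
    if builder_spec is None and trajectory is None:
        errors.append("trajectory: missing, and no builder spec given")
    for key in ("topology", "charges", "trajectory"):
        if raw.get(key) is not None and not Path(raw[key]).exists():
            errors.append(f"{key}: file {raw[key]!r} does not exist")
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    return RunConfig(
        stages=stages,
        output_dir=Path(raw.get("output_dir", "out")),
        seed=int(raw.get("seed", 0)),
        topology=Path(topology) if topology else None,
        charges=Path(raw["charges"]) if raw.get("charges") else None,
        trajectory=Path(trajectory) if trajectory else None,
        builder_spec=builder_spec,
        chain=raw.get("chain", "A"),
        params=params,
    )


def _build_from_spec(spec: dict, seed: int) -> Trajectory:
    chain_spec = builder.ChainSpec(
        n_residues=int(spec.get("n_residues", 12)),
        linkage=spec.get("linkage", "alpha-1-4"),
        phi_deg=spec.get("phi_deg", 103.0),
        psi_deg=spec.get("psi_deg", 115.0),
    )
    n_frames = int(spec.get("n_frames", 100))
    noise = float(spec.get("noise_sigma_A", 0.1))
    n_waters = int(spec.get("n_waters", 0))
    top, frame = builder.build_chain(chain_spec, seed=seed)
    if n_waters:
        top, frame = builder.place_waters(
            (top, frame), n_waters, mode=spec.get("water_mode", "shell"),
            water_model=spec.get("water_model", "3-site"), seed=seed,
        )
    rng = np.random.default_rng(seed)
    frames = [
        frame.__class__(frame.coordinates + rng.normal(scale=noise, size=frame.coordinates.shape),
                        frame.box)
        for _ in range(n_frames)
    ]
    if spec.get("box_edge"):
        edge = float(spec["box_edge"])
        for f in frames:
            f.box = np.array([edge, edge, edge])
    return Trajectory(topology=top, frames=frames)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute every requested stage; independent stages keep running after a
    failure, and the manifest records what succeeded."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    t0 = time.time()

    inputs = {}
    if config.builder_spec is not None:
        traj = _build_from_spec(config.builder_spec, config.seed)
    else:
        top, _ = io.read_structure(config.topology, config.charges)
        traj = io.read_trajectory(config.trajectory, top)
        for key in ("topology", "charges", "trajectory"):
            p = getattr(config, key)
            if p is not None:
                inputs[key] = {"path": str(p), "sha256": _sha256(p)}
    top = traj.topology
    chain = config.chain
    params = config.params
    heavy = top.select(heavy=True, chain_id=chain)

    status: dict[str, str] = {}
    aligned_cache: Trajectory | None = None

    def aligned() -> Trajectory:
        nonlocal aligned_cache
        if aligned_cache is None:
            aligned_cache, _ = electrostatics.align_axis(traj, chain)
        return aligned_cache

    for stage in config.stages:
        stage_dir = out / stage
        stage_dir.mkdir(exist_ok=True)
        try:
            if stage == "rmsd":
                vals = conformation.rmsd_series(traj, selection=heavy)
                pd.DataFrame({"frame": np.arange(len(vals)), "rmsd_A": vals}).to_csv(
                    stage_dir / "rmsd.tsv", sep="\t", index=False)
            elif stage == "rmsf":
                res, vals = conformation.rmsf_per_residue(traj, chain)
                pd.DataFrame({"residue": res + 1, "rmsf_A": vals}).to_csv(
                    stage_dir / "rmsf.tsv", sep="\t", index=False)
            elif stage == "rg":
                vals = [conformation.radius_of_gyration(f, top, heavy) for f in traj.frames]
                pd.DataFrame({"frame": np.arange(len(vals)), "rg_A": vals}).to_csv(
                    stage_dir / "rg.tsv", sep="\t", index=False)
            elif stage == "ree":
                vals = [conformation.end_to_end(f, top, chain) for f in traj.frames]
                pd.DataFrame({"frame": np.arange(len(vals)), "ree_A": vals}).to_csv(
                    stage_dir / "ree.tsv", sep="\t", index=False)
            elif stage == "torsions":
                rows = []
                for k, per_frame in enumerate(conformation.glycosidic_torsions(traj, chain)):
                    for t in per_frame:
                        rows.append({"frame": k, "linkage": t.linkage_index + 1,
                                     "phi_deg": t.phi_deg, "psi_deg": t.psi_deg})
                pd.DataFrame(rows).to_csv(stage_dir / "torsions.tsv", sep="\t", index=False)
            elif stage == "pucker":
                rows = []
                for k, per_frame in enumerate(conformation.ring_pucker_series(traj, chain)):
                    for r, p in enumerate(per_frame):
                        rows.append({"frame": k, "residue": r + 1, "Q_A": p.Q,
                                     "theta_deg": p.theta_deg, "phi_deg": p.phi_deg})
                pd.DataFrame(rows).to_csv(stage_dir / "pucker.tsv", sep="\t", index=False)
            elif stage == "fes":
                tors = conformation.glycosidic_torsions(traj, chain)
                phi = np.array([t.phi_deg for fr in tors for t in fr])
                psi = np.array([t.psi_deg for fr in tors for t in fr])
                grid = conformation.fes_2d(phi, psi, bins=params["fes_bins"],
                                           temperature_K=params["temperature_K"])
                rows = []
                for i in range(grid.counts.shape[0]):
                    for j in range(grid.counts.shape[1]):
                        if not grid.mask[i, j]:
                            rows.append({
                                "phi_center": 0.5 * (grid.phi_edges[i] + grid.phi_edges[i + 1]),
                                "psi_center": 0.5 * (grid.psi_edges[j] + grid.psi_edges[j + 1]),
                                "free_energy_kcal_mol": grid.free_energy[i, j],
                            })
                pd.DataFrame(rows).to_csv(stage_dir / "fes.tsv", sep="\t", index=False)
            elif stage == "rdf":
                for label, res in hydration.rdf_per_oxygen_type(
                        traj, chain, params["rdf_r_max"], params["rdf_bin_width"]).items():
                    pd.DataFrame({"r_A": res.bin_centers, "g_r": res.g_of_r}).to_csv(
                        stage_dir / f"rdf_{label}.tsv", sep="\t", index=False)
            elif stage == "hbonds":
                recs = hydration.detect_hbonds(traj, params["d_cut"], params["angle_cut_deg"])
                pd.DataFrame([vars(r) for r in recs]).to_csv(
                    stage_dir / "hbonds.tsv", sep="\t", index=False)
                hydration.hbond_counts_by_oxygen(recs, top, traj.n_frames).to_csv(
                    stage_dir / "hbond_summary.tsv", sep="\t", index=False)
            elif stage == "dipoles":
                recs = electrostatics.ring_dipoles(aligned(), chain)
                pd.DataFrame([
                    {"group": r.group_label, "frame": r.frame, "mu_x_D": r.mu_vec[0],
                     "mu_y_D": r.mu_vec[1], "mu_z_D": r.mu_vec[2], "mu_D": r.mu_mag}
                    for r in recs
                ]).to_csv(stage_dir / "dipoles_rings.tsv", sep="\t", index=False)
            elif stage == "efield":
                prof = electrostatics.field_profile(
                    aligned(), chain, include_solvent=params["include_solvent"],
                    n_blocks=params["n_blocks"], points_per_block=params["points_per_block"])
                pd.DataFrame({
                    "point_index": prof.point_index,
                    "axis_position_A": prof.mean_axis_position,
                    "mean_MV_cm": prof.mean_E_mag,
                    "ci95_MV_cm": prof.ci95,
                }).to_csv(stage_dir / "field_profile.tsv", sep="\t", index=False)
            elif stage == "cluster":
                feats = clustering.feature_matrix(traj, heavy)
                lo, hi = params["k_range"]
                result = clustering.select_k(feats, range(int(lo), int(hi) + 1))
                pd.DataFrame({"frame": np.arange(len(result.labels)),
                              "cluster": result.labels}).to_csv(
                    stage_dir / "labels.tsv", sep="\t", index=False)
                pd.DataFrame({"k": list(result.db_by_k), "db": list(result.db_by_k.values())}
                             ).to_csv(stage_dir / "db_curve.tsv", sep="\t", index=False)
                pd.DataFrame({"cluster": np.arange(result.k),
                              "population": result.populations,
                              "representative_frame": result.representative_frames}
                             ).to_csv(stage_dir / "cluster_summary.tsv", sep="\t", index=False)
                for c, fidx in enumerate(result.representative_frames):
                    io.write_pdb(top, traj.frames[int(fidx)], stage_dir / f"rep_cluster{c}.pdb")
            status[stage] = "ok"
            logger.info("stage %s: ok", stage)
        except Exception as exc:  # stage isolation: later stages still run
            status[stage] = f"failed: {exc}"
            logger.error("stage %s failed: %s", stage, exc)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "chain": chain,
        "stages": status,
        "params": {k: (list(v) if isinstance(v, (list, tuple)) else v)
                   for k, v in params.items()},
        "inputs": inputs,
        "builder": config.builder_spec,
        "elapsed_s": round(time.time() - t0, 2),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    if any(v != "ok" for v in status.values()):
        raise RuntimeError(
            "one or more stages failed: "
            + ", ".join(f"{k} ({v})" for k, v in status.items() if v != "ok")
        )
    return out
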