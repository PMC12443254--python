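"""Stage orchestration: extract -> prep -> pca -> density -> classify -> report.

A run config names the input ensembles (file-backed trajectories or named
synthetic presets), the prep policy (per-simulation discard, subsample
count, default 3,000 frames per system), the density pair, and the state
taxonomy.  Every run writes feature CSVs, a PCA model JSON with score
CSVs, density grids with HDR masks, state occupancy tables and a manifest
recording the seed and per-stage row counts, so a run is reproducible
bit-for-bit from config + inputs + seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .config import load_dof_catalogue, write_features
from .density import boltzmann_invert, density_2d, density_mode, hdr_region
from .descriptors import FeatureMatrix, extract_features
from .pca import fit_pooled_pca, project
from .prep import DiscardPolicy, discard_initial, subsample_even
from .states import (ActivationAxis, RotamerTaxonomy, StateRecord,
                     activation_coordinate, classify_f6x44, classify_toggle,
                     detect_hbond, summarize_states)
from .structures import load_bw_map, read_structure, read_trajectory

__all__ = ["SimulationEntry", "RunConfig", "validate_config", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class SimulationEntry:
    id: str
    preset: str | None = None            # synthetic ensemble
    n_frames: int = 1000
    topology: str | None = None          # or file-backed trajectory
    trajectory: str | None = None
    frame_spacing_ns: float = 1.0
    discard_ns: float = 0.0


@dataclasses.dataclass(frozen=True)
class RunConfig:
    simulations: tuple[SimulationEntry, ...]
    seed: int = 0
    subsample_n: int = 3000
    density_pair: tuple[str, str] = ("tm26", "tm37")
    hdr_mass: float = 0.5
    bw_map_path: str | None = None
    dof_catalogue_path: str | None = None
    axis_inactive: tuple[float, float] = (14.0, 19.0)
    axis_active: tuple[float, float] = (21.0, 14.0)


def validate_config(source: str | Path | Mapping[str, Any]) -> RunConfig:
    """Parse and cross-validate a run config; all violations are reported
    together, each with its config path."""
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text())
    else:
        raw = dict(source)
    problems: list[str] = []
    sims = []
    seen: set[str] = set()
    for i, s in enumerate(raw.get("simulations", [])):
        sid = str(s.get("id", ""))
        where = f"simulations[{i}]"
        if not sid:
            problems.append(f"{where}: missing id")
        elif sid in seen:
            problems.append(f"{where}: duplicate simulation id {sid!r}")
        seen.add(sid)
        preset_name = s.get("preset")
        if preset_name is not None and preset_name not in synthetic.PRESET_NAMES:
            problems.append(f"{where}: unknown preset {preset_name!r}")
        if preset_name is None:
            for key in ("topology", "trajectory"):
                p = s.get(key)
                if not p:
                    problems.append(f"{where}: needs {key} (or a preset)")
                elif not Path(p).exists():
                    problems.append(f"{where}.{key}: no such file {p}")
        sims.append(SimulationEntry(
            id=sid, preset=preset_name, n_frames=int(s.get("n_frames", 1000)),
            topology=s.get("topology"), trajectory=s.get("trajectory"),
            frame_spacing_ns=float(s.get("frame_spacing_ns", 1.0)),
            discard_ns=float(s.get("discard_ns", 0.0)),
        ))
    if not sims:
        problems.append("simulations: at least one entry required")
    for key in ("bw_map", "dof_catalogue"):
        p = raw.get(key)
        if p and not Path(p).exists():
            problems.append(f"{key}: no such file {p}")
    # cross-check: every BW code in the DOF catalogue must resolve in the map
    if raw.get("dof_catalogue") and Path(str(raw["dof_catalogue"])).exists():
        try:
            dofs = load_dof_catalogue(raw["dof_catalogue"])
            bw = (load_bw_map(raw["bw_map"]) if raw.get("bw_map")
                  and Path(str(raw["bw_map"])).exists()
                  else synthetic.toy_bw_map())
            for d in dofs:
                for sel in d.selectors:
                    if sel.bw is not None and sel.bw not in bw:
                        problems.append(
                            f"dof_catalogue.{d.name}: BW code {sel.bw!r} "
                            "missing from BW map")
        except (KeyError, ValueError) as exc:
            problems.append(f"dof_catalogue: {exc}")
    if problems:
        raise ValueError("invalid run config:\n  " + "\n  ".join(problems))
    pair = raw.get("density_pair", ["tm26", "tm37"])
    return RunConfig(
        simulations=tuple(sims),
        seed=int(raw.get("seed", 0)),
        subsample_n=int(raw.get("subsample_n", 3000)),
        density_pair=(str(pair[0]), str(pair[1])),
        hdr_mass=float(raw.get("hdr_mass", 0.5)),
        bw_map_path=raw.get("bw_map"),
        dof_catalogue_path=raw.get("dof_catalogue"),
        axis_inactive=tuple(raw.get("axis_inactive", (14.0, 19.0))),
        axis_active=tuple(raw.get("axis_active", (21.0, 14.0))),
    )


def _extract_one(entry: SimulationEntry, config: RunConfig,
                 seed: int) -> FeatureMatrix:
    if entry.preset is not None:
        spec = synthetic.preset(entry.preset, n_frames=entry.n_frames,
                                seed=seed)
        fm, labels = synthetic.sample_features(spec)
        fm.provenance["simulation_id"] = entry.id
        return fm
    bw = (load_bw_map(config.bw_map_path) if config.bw_map_path
          else synthetic.toy_bw_map())
    dofs = (load_dof_catalogue(config.dof_catalogue_path)
            if config.dof_catalogue_path else synthetic.toy_dof_catalogue())
    topo = read_structure(entry.topology)
    traj = read_trajectory(entry.trajectory, topo,
                           frame_spacing_ns=entry.frame_spacing_ns)
    return extract_features(traj, dofs, bw_map=bw, simulation_id=entry.id)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict[str, Any]:
    """Run all stages and write the artifact bundle; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"seed": config.seed, "stages": {},
                                "warnings": []}
    prepped: dict[str, FeatureMatrix] = {}
    counts: dict[str, dict[str, int]] = {}

    for i, entry in enumerate(config.simulations):
        # per-simulation child seed keeps ensembles independent yet reproducible
        fm = _extract_one(entry, config, seed=config.seed + 1000 * i)
        raw_rows = len(fm.values)
        write_features(fm, out / f"features_{entry.id}")
        policy = DiscardPolicy(mode="explicit-ns",
                               explicit_ns=entry.discard_ns)
        fm = discard_initial(fm, policy)
        fm = subsample_even(fm, config.subsample_n)
        if len(fm.values) < config.subsample_n:
            manifest["warnings"].append(
                f"{entry.id}: only {len(fm.values)} frames after discard")
        prepped[entry.id] = fm
        counts[entry.id] = {
            "raw": raw_rows,
            "post_discard": int(fm.provenance.get("n_after_discard", raw_rows)),
            "post_subsample": len(fm.values),
        }
    manifest["stages"]["prep"] = counts

    model = fit_pooled_pca(prepped, tolerate_constant=True)
    model.to_json(out / "pca_model.json")
    all_scores = []
    for sid, fm in prepped.items():
        scores = project(model, fm, n_pcs=min(4, len(model.dof_names)))
        scores.insert(0, "simulation_id", sid)
        all_scores.append(scores)
    pd.concat(all_scores).to_csv(out / "pca_scores.csv")
    manifest["stages"]["pca"] = {
        "eigenvalues_top4": model.eigenvalues[:4].tolist(),
        "evr_top4": model.explained_variance_ratio[:4].tolist(),
        "n_rows": model.n_rows,
    }

    dx, dy = config.density_pair
    pooled = pd.concat([fm.values for fm in prepped.values()])
    dmap = density_2d(pooled[dx].to_numpy(), pooled[dy].to_numpy(),
                      bin_widths=(0.2, 0.2))
    dmap = boltzmann_invert(dmap)
    region = hdr_region(dmap, config.hdr_mass)
    mode = density_mode(dmap)
    np.savetxt(out / "density_grid.csv", dmap.prob, delimiter=",")
    np.savetxt(out / "hdr_mask.csv", region.mask.astype(int), delimiter=",",
               fmt="%d")
    (out / "density_meta.json").write_text(json.dumps({
        "pair": [dx, dy], "bin_widths": [0.2, 0.2],
        "axis_x": dmap.axes[0].tolist(), "axis_y": dmap.axes[1].tolist(),
        "temperature_K": dmap.temperature_K,
        "hdr_mass_captured": region.captured_mass,
        "mode": list(mode),
    }, indent=1))
    manifest["stages"]["density"] = {"mode": list(mode),
                                     "hdr_mass": region.captured_mass}

    taxonomy = RotamerTaxonomy()
    axis = ActivationAxis(config.axis_inactive, config.axis_active)
    records = []
    for sid, fm in prepped.items():
        v = fm.values
        coord, act_label = activation_coordinate(
            v[dx].to_numpy(), v[dy].to_numpy(), axis)
        table = pd.DataFrame({
            "toggle": classify_toggle(v["chi1_w6x48"].to_numpy(),
                                      v["chi2_w6x48"].to_numpy(), taxonomy),
            "f6x44": classify_f6x44(v["chi1_f6x44"].to_numpy(), taxonomy),
            "hbond": detect_hbond(v["dist_wn"].to_numpy()),
            "activation": coord,
            "activation_label": act_label,
        }, index=v.index)
        records.append(StateRecord(simulation_id=sid, table=table))
        table.to_csv(out / f"states_{sid}.csv")
    occupancy = summarize_states(records)
    occupancy.to_csv(out / "state_occupancy.csv")
    manifest["stages"]["classify"] = {
        "simulations": list(prepped), "labels": "toggle/f6x44/hbond/activation"}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return manifest
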