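"""Ground-truth synthetic ensembles for the descriptor pipeline.

Two levels of synthesis:

* **feature level** -- :func:`sample_features` draws frames from named
  Gaussian basins (wrapped Gaussians for angles), optionally switching
  between basins with a per-step Markov chain, as a statistical stand-in
  for real receptor trajectories;
* **structure level** -- :func:`build_structure` realizes one feature
  vector as a toy atomistic model in which every degree of freedom is
  carried by a minimal dedicated atom group, so descriptors are
  independently settable and extraction round-trips exactly.  These are
  deliberately *not* physical receptors: they decouple descriptor testing
  from protein modeling.

Preset basins encode the conformational states discussed for the 5-HT2A
receptor: the beta-arrestin-ideal basin at TM3-7 ~ 15 A / TM2-6 ~ 18 A,
the G-protein-ideal basin at TM2-6 ~ 21 A, and the toggle-switch chi2
basins at ~50 deg (on) and ~120 deg (off).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .descriptors import DOFDefinition, FeatureMatrix
from .structures import (AtomSelector, BWMap, StructureModel,
                         TrajectoryHandle, write_multimodel_pdb,
                         write_structure)

__all__ = ["BasinSpec", "SwitchingSpec", "EnsembleSpec", "sample_features",
           "build_structure", "write_fixture", "preset", "PRESET_NAMES",
           "toy_dof_catalogue", "toy_bw_map", "BASE_DOFS", "LIGAND_DOFS",
           "CONSTRUCTIBLE_RANGES"]

BASE_DOFS = (
    "tm26", "tm37",
    "chi1_w6x48", "chi2_w6x48", "chi1_f6x44", "chi2_f6x44",
    "dist_wn", "dist_tyrtyr", "tm5_bulge",
    "ionic_lock", "hydrophobic_lock",
    "z_distance", "z_angle",
)
LIGAND_DOFS = ("lig_5x46", "lig_5x44", "lig_3x32", "lig_3x36", "lig_6x55")

ANGLE_DOFS = frozenset({"chi1_w6x48", "chi2_w6x48", "chi1_f6x44",
                        "chi2_f6x44", "z_angle"})
PERIODIC_DOFS = frozenset({"chi1_w6x48", "chi2_w6x48", "chi1_f6x44",
                           "chi2_f6x44"})

DEFAULT_SD_DISTANCE = 0.8    # A
DEFAULT_SD_ANGLE = 10.0      # deg

# Feature ranges the toy builder can realize exactly (used by round-trip
# property tests to draw random constructible vectors).
CONSTRUCTIBLE_RANGES: dict[str, tuple[float, float]] = {
    "tm26": (5.0, 40.0), "tm37": (5.0, 40.0),
    "chi1_w6x48": (-179.0, 180.0), "chi2_w6x48": (-179.0, 180.0),
    "chi1_f6x44": (-179.0, 180.0), "chi2_f6x44": (-179.0, 180.0),
    "dist_wn": (0.05, 20.0), "dist_tyrtyr": (0.05, 40.0),
    "tm5_bulge": (0.05, 40.0), "ionic_lock": (0.05, 40.0),
    "hydrophobic_lock": (0.05, 40.0),
    "z_distance": (-30.0, 30.0), "z_angle": (-89.0, 89.0),
    "lig_5x46": (0.05, 20.0), "lig_5x44": (0.05, 20.0),
    "lig_3x32": (0.05, 20.0), "lig_3x36": (0.05, 20.0),
    "lig_6x55": (0.05, 20.0),
}


def toy_bw_map() -> BWMap:
    """BW map of the toy fixture receptor.

    Literature-anchored positions keep their real 5-HT2A residue numbers;
    positions whose numbers are not anchored (6x30, 3x50, 3x46, 6x37, 5x44,
    3x36, 6x55) carry synthetic fixture numbering.
    """
    return BWMap(entries={
        "6x48": 336, "6x44": 332, "6x41": 329, "5x58": 254, "5x46": 242,
        "5x50": 246, "7x53": 380, "7x49": 376, "7x41": 369, "3x32": 155,
        "3x40": 163,
        # synthetic fixture numbers:
        "6x30": 320, "3x50": 173, "3x46": 169, "6x37": 325,
        "5x44": 238, "3x36": 159, "6x55": 343,
    }, receptor="toy-5HT2A-fixture")


def toy_dof_catalogue(include_ligand: bool = False) -> list[DOFDefinition]:
    """DOF catalogue matching the toy fixture geometry."""
    R = "R"
    ca = ("CA",)
    defs = [
        DOFDefinition("tm26", "centroid-distance", (
            AtomSelector(resid_range=(90, 91), atom_names=ca, segid=R),
            AtomSelector(resid_range=(330, 331), atom_names=ca, segid=R))),
        DOFDefinition("tm37", "centroid-distance", (
            AtomSelector(resid_range=(160, 161), atom_names=ca, segid=R),
            AtomSelector(resid_range=(385, 386), atom_names=ca, segid=R))),
        DOFDefinition("chi1_w6x48", "dihedral-chi1",
                      (AtomSelector(bw="6x48", segid=R),), unit="deg"),
        DOFDefinition("chi2_w6x48", "dihedral-chi2",
                      (AtomSelector(bw="6x48", segid=R),), unit="deg"),
        DOFDefinition("chi1_f6x44", "dihedral-chi1",
                      (AtomSelector(bw="6x44", segid=R),), unit="deg"),
        DOFDefinition("chi2_f6x44", "dihedral-chi2",
                      (AtomSelector(bw="6x44", segid=R),), unit="deg"),
        DOFDefinition("dist_wn", "atom-distance", (
            AtomSelector(bw="6x48", atom_names=("NE1",), segid=R),
            AtomSelector(bw="7x49", atom_names=("OD1",), segid=R))),
        DOFDefinition("dist_tyrtyr", "atom-distance", (
            AtomSelector(bw="5x58", atom_names=("OH",), segid=R),
            AtomSelector(bw="7x53", atom_names=("OH",), segid=R))),
        DOFDefinition("tm5_bulge", "centroid-distance", (
            AtomSelector(bw="5x46", group="heavy", segid=R),
            AtomSelector(bw="7x41", group="heavy", segid=R))),
        DOFDefinition("ionic_lock", "centroid-distance", (
            AtomSelector(bw="6x30", group="sidechain-heavy", segid=R),
            AtomSelector(bw="3x50", group="sidechain-heavy", segid=R))),
        DOFDefinition("hydrophobic_lock", "centroid-distance", (
            AtomSelector(bw="3x46", group="sidechain-heavy", segid=R),
            AtomSelector(bw="6x37", group="sidechain-heavy", segid=R))),
        DOFDefinition("z_distance", "z-distance", (
            AtomSelector(resid_range=(90, 386), atom_names=ca, segid=R),
            AtomSelector(resid_range=(238, 244), atom_names=ca, segid="G"),
            AtomSelector(resid_range=(232, 238), atom_names=ca, segid="G"))),
        DOFDefinition("z_angle", "z-angle", (
            AtomSelector(resid_range=(90, 386), atom_names=ca, segid=R),
            AtomSelector(resid_range=(238, 244), atom_names=ca, segid="G"),
            AtomSelector(resid_range=(232, 238), atom_names=ca, segid="G")),
            unit="deg"),
    ]
    if include_ligand:
        lig = AtomSelector(resname="LIG", group="polar-heavy",
                           exclude_caps=False)
        for name, bw in zip(LIGAND_DOFS, ("5x46", "5x44", "3x32", "3x36",
                                          "6x55")):
            defs.append(DOFDefinition(name, "min-polar-distance",
                                      (lig, AtomSelector(bw=bw, group="polar-heavy", segid=R))))
    return defs


# ---------------------------------------------------------------------------
# specs

@dataclasses.dataclass(frozen=True)
class BasinSpec:
    """One Gaussian basin: per-DOF mean/SD, optional cross-DOF correlation."""

    name: str
    means: Mapping[str, float]
    sds: Mapping[str, float]
    correlation: np.ndarray | None = None   # over the order of `means`

    def __post_init__(self) -> None:
        for d, s in self.sds.items():
            if s < 0:
                raise ValueError(f"basin {self.name!r}: negative SD for {d}")
        for d, m in self.means.items():
            if d in PERIODIC_DOFS and not (-180.0 < m <= 180.0):
                raise ValueError(f"basin {self.name!r}: angular mean for {d} "
                                 "outside (-180, 180]")
        if self.correlation is not None:
            c = np.asarray(self.correlation, dtype=float)
            if not np.allclose(c, c.T):
                raise ValueError("correlation matrix not symmetric")
            if np.linalg.eigvalsh(c).min() < -1e-10:
                raise ValueError("correlation matrix not positive semidefinite")


@dataclasses.dataclass(frozen=True)
class SwitchingSpec:
    """Markov switching between basins (per-frame transition matrix)."""

    basin_names: tuple[str, ...]
    transition: np.ndarray
    initial: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.transition, dtype=float)
        k = len(self.basin_names)
        if t.shape != (k, k):
            raise ValueError("transition matrix shape mismatch")
        if not np.allclose(t.sum(axis=1), 1.0):
            raise ValueError("transition matrix rows must sum to 1")

    def stationary(self) -> np.ndarray:
        """Stationary distribution (left eigenvector of the unit eigenvalue)."""
        t = np.asarray(self.transition, dtype=float)
        vals, vecs = np.linalg.eig(t.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()


@dataclasses.dataclass(frozen=True)
class EnsembleSpec:
    """Everything needed to generate one synthetic ensemble."""

    basins: tuple[BasinSpec, ...]
    n_frames: int = 1000
    frame_spacing_ns: float = 1.0
    seed: int = 0
    switching: SwitchingSpec | None = None
    preset_name: str = ""
    # linear drift added deterministically: (dof, onset_frame, rate/frame)
    drift: tuple[str, int, float] | None = None

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not self.basins:
            raise ValueError("at least one basin required")


def _wrap(a: np.ndarray) -> np.ndarray:
    w = -((-a + 180.0) % 360.0 - 180.0)
    w[w == -180.0] = 180.0
    return w


def sample_features(spec: EnsembleSpec, n: int | None = None,
                    seed: int | None = None
                    ) -> tuple[FeatureMatrix, np.ndarray]:
    """Draw a labelled feature ensemble.

    Basin assignment follows the Markov chain (or stays in the single
    basin); values are Gaussian around the basin mean, wrapped into
    (-180, 180] for periodic DOFs.  Fully deterministic given the seed.
    Returns (FeatureMatrix, per-frame basin labels).
    """
    n = n or spec.n_frames
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    dofs = list(spec.basins[0].means.keys())
    for b in spec.basins:
        if list(b.means.keys()) != dofs:
            raise ValueError("all basins must define the same DOFs in order")

    if spec.switching is None:
        states = np.zeros(n, dtype=int)
    else:
        t = np.asarray(spec.switching.transition, dtype=float)
        cum = np.cumsum(t, axis=1)
        states = np.empty(n, dtype=int)
        states[0] = spec.switching.initial
        u = rng.random(n)
        for i in range(1, n):
            states[i] = int(np.searchsorted(cum[states[i - 1]], u[i]))

    p = len(dofs)
    values = np.empty((n, p))
    for k, basin in enumerate(spec.basins):
        rows = np.flatnonzero(states == k)
        if rows.size == 0:
            continue
        mean = np.array([basin.means[d] for d in dofs])
        sd = np.array([basin.sds.get(d, 0.0) for d in dofs])
        if basin.correlation is not None:
            cov = np.outer(sd, sd) * np.asarray(basin.correlation, dtype=float)
            draws = rng.multivariate_normal(mean, cov, size=rows.size,
                                            method="svd")
        else:
            draws = mean + sd * rng.standard_normal((rows.size, p))
        values[rows] = draws
    for j, d in enumerate(dofs):
        if d in PERIODIC_DOFS:
            values[:, j] = _wrap(values[:, j])
    if spec.drift is not None:
        dof, onset, rate = spec.drift
        j = dofs.index(dof)
        ramp = np.clip(np.arange(n) - onset, 0, None) * rate
        values[:, j] += ramp

    times = np.arange(n) * spec.frame_spacing_ns
    df = pd.DataFrame(values, columns=dofs,
                      index=pd.Index(times, name="time_ns"))
    fm = FeatureMatrix(
        values=df,
        units={d: ("deg" if d in ANGLE_DOFS else "A") for d in dofs},
        periodic={d: d in PERIODIC_DOFS for d in dofs},
        provenance={"generator": "synthetic", "seed": int(seed),
                    "preset": spec.preset_name, "n_frames": int(n),
                    "frame_spacing_ns": float(spec.frame_spacing_ns)},
    )
    labels = np.array([spec.basins[s].name for s in states], dtype=object)
    return fm, labels


# ---------------------------------------------------------------------------
# toy structure builder

def _nerf(a, b, c, r, theta_deg, phi_deg):
    """Place atom D from A,B,C with bond length r (C-D), angle theta
    (B-C-D) and torsion phi (A-B-C-D)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = np.radians(theta_deg)
    phi = np.radians(phi_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-r * np.cos(theta),
                        r * np.sin(theta) * np.cos(phi),
                        r * np.sin(theta) * np.sin(phi)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


class _Builder:
    def __init__(self):
        self.names, self.elements, self.resids = [], [], []
        self.resnames, self.segids, self.xyz = [], [], []

    def add(self, name, element, resid, resname, segid, pos):
        self.names.append(name)
        self.elements.append(element)
        self.resids.append(resid)
        self.resnames.append(resname)
        self.segids.append(segid)
        self.xyz.append(np.asarray(pos, dtype=float))

    def model(self, title="synthetic toy receptor") -> StructureModel:
        return StructureModel(
            names=np.array(self.names, dtype=object),
            elements=np.array(self.elements, dtype=object),
            resids=np.array(self.resids, dtype=int),
            resnames=np.array(self.resnames, dtype=object),
            segids=np.array(self.segids, dtype=object),
            coords=np.stack(self.xyz), title=title,
        )


def _sidechain(b: _Builder, resid: int, resname: str, base,
               chi1: float, chi2: float, with_ne1: bool):
    base = np.asarray(base, dtype=float)
    n = base
    ca = base + np.array([1.458, 0.0, 0.0])
    ang = np.radians(69.0)   # gives an N-CA-CB angle of 111 deg
    cb = ca + 1.53 * np.array([np.cos(ang), np.sin(ang), 0.0])
    cg = _nerf(n, ca, cb, 1.52, 113.9, chi1)
    cd1 = _nerf(ca, cb, cg, 1.43, 126.9, chi2)
    b.add("N", "N", resid, resname, "R", n)
    b.add("CA", "C", resid, resname, "R", ca)
    b.add("CB", "C", resid, resname, "R", cb)
    b.add("CG", "C", resid, resname, "R", cg)
    b.add("CD1", "C", resid, resname, "R", cd1)
    if with_ne1:
        ne1 = _nerf(cb, cg, cd1, 1.37, 110.0, 180.0)
        b.add("NE1", "N", resid, resname, "R", ne1)
        return ne1
    return cd1


def _pair_group(b: _Builder, resids, resname, name, element, centroid, axis):
    """Two identically named atoms symmetric about the requested centroid."""
    centroid = np.asarray(centroid, dtype=float)
    off = np.asarray(axis, dtype=float)
    b.add(name, element, resids[0], resname, "R", centroid - off)
    b.add(name, element, resids[1], resname, "R", centroid + off)


def build_structure(features: Mapping[str, float]) -> StructureModel:
    """Realize one feature vector as a toy structure.

    Requires every DOF in ``BASE_DOFS``; ligand DOFs are optional and add a
    LIG heteromolecule with one polar atom per requested distance.  Values
    outside :data:`CONSTRUCTIBLE_RANGES` raise.
    """
    missing = [d for d in BASE_DOFS if d not in features]
    if missing:
        raise ValueError(f"feature vector lacks DOFs: {missing}")
    for d, v in features.items():
        if d in PERIODIC_DOFS:
            continue   # torsions are constructible anywhere on the circle
        lo, hi = CONSTRUCTIBLE_RANGES[d]
        if not lo <= v <= hi:
            raise ValueError(
                f"{d} = {v} outside constructible range [{lo}, {hi}]")
    f = {k: float(v) for k, v in features.items()}
    b = _Builder()

    # TM helix-end centroid groups (two CA atoms each, centroid exact)
    ey = np.array([0.0, 1.0, 0.0])
    _pair_group(b, (90, 91), "ALA", "CA", "C", (0.0, 0.0, 0.0), ey)
    _pair_group(b, (330, 331), "ALA", "CA", "C", (f["tm26"], 0.0, 0.0), ey)
    _pair_group(b, (160, 161), "ALA", "CA", "C", (0.0, 30.0, 0.0), ey)
    _pair_group(b, (385, 386), "ALA", "CA", "C", (f["tm37"], 30.0, 0.0), ey)

    # torsion-driven side chains
    ne1 = _sidechain(b, 336, "TRP", (100.0, 0.0, 0.0),
                     f["chi1_w6x48"], f["chi2_w6x48"], with_ne1=True)
    _sidechain(b, 332, "PHE", (150.0, 0.0, 0.0),
               f["chi1_f6x44"], f["chi2_f6x44"], with_ne1=False)

    # marker atoms at exact pair distances
    b.add("OD1", "O", 376, "ASN", "R", ne1 + np.array([0, 0, f["dist_wn"]]))
    b.add("OH", "O", 254, "TYR", "R", (200.0, 0.0, 0.0))
    b.add("OH", "O", 380, "TYR", "R", (200.0 + f["dist_tyrtyr"], 0.0, 0.0))
    b.add("OG", "O", 242, "SER", "R", (250.0, 0.0, 0.0))
    b.add("CA", "C", 369, "GLY", "R", (250.0 + f["tm5_bulge"], 0.0, 0.0))
    b.add("OE1", "O", 320, "GLU", "R", (300.0, 0.0, 0.0))
    b.add("NH1", "N", 173, "ARG", "R", (300.0 + f["ionic_lock"], 0.0, 0.0))
    b.add("CD1", "C", 169, "ILE", "R", (350.0, 0.0, 0.0))
    b.add("CD2", "C", 325, "LEU", "R", (350.0 + f["hydrophobic_lock"], 0.0, 0.0))

    # ligand-residue polar markers, 60 A apart so minima never cross over
    lig_anchor = {"lig_5x46": np.array([250.0, 0.0, 0.0])}
    marker_specs = [("lig_5x44", "OG", "O", 238, "SER", (400.0, 0.0, 0.0)),
                    ("lig_3x32", "OD1", "O", 155, "ASP", (460.0, 0.0, 0.0)),
                    ("lig_3x36", "OG", "O", 159, "SER", (520.0, 0.0, 0.0)),
                    ("lig_6x55", "OD1", "O", 343, "ASN", (580.0, 0.0, 0.0))]
    lig_requested = [d for d in LIGAND_DOFS if d in f]
    for name, atom, el, resid, resname, pos in marker_specs:
        if name in lig_requested:
            b.add(atom, el, resid, resname, "R", pos)
            lig_anchor[name] = np.asarray(pos)
    for i, name in enumerate(lig_requested):
        b.add(f"O{i + 1}", "O", 900, "LIG", "L",
              lig_anchor[name] + np.array([0.0, f[name], 0.0]))

    # receptor TM-bundle CA centroid, computed exactly as the z selector does
    ca_mask = [(nm == "CA" and sg == "R" and 90 <= rid <= 386)
               for nm, sg, rid in zip(b.names, b.segids, b.resids)]
    c_rec = np.mean([p for p, m in zip(b.xyz, ca_mask) if m], axis=0)

    # G-protein construct: interface helix (238-244) and tail (232-238)
    c1 = np.array([c_rec[0] + 20.0, c_rec[1], c_rec[2] - f["z_distance"]])
    L = 10.0
    th = np.radians(f["z_angle"])
    c2 = c1 + L * np.array([np.cos(th), 0.0, np.sin(th)])
    p238 = 0.5 * (c1 + c2) + np.array([0.0, 1.0, 0.0])
    b.add("CA", "C", 238, "ALA", "G", p238)
    offs = [np.array([0.0, s * d, 0.0]) for d in (1.0, 2.0, 3.0)
            for s in (1.0, -1.0)]
    c_iface_rest = (7.0 * c1 - p238) / 6.0
    for resid, off in zip(range(239, 245), offs):
        b.add("CA", "C", resid, "ALA", "G", c_iface_rest + off)
    c_tail_rest = (7.0 * c2 - p238) / 6.0
    for resid, off in zip(range(232, 238), offs):
        b.add("CA", "C", resid, "ALA", "G", c_tail_rest + off)

    return b.model()


def build_trajectory(fm: FeatureMatrix) -> TrajectoryHandle:
    """Realize every row of a feature matrix as one frame of a toy trajectory."""
    frames = []
    topo = None
    for _, row in fm.values.iterrows():
        m = build_structure(row.to_dict())
        if topo is None:
            topo = m
        frames.append(m.coords)
    spacing = fm.provenance.get("frame_spacing_ns")
    if not spacing:
        t = fm.times_ns
        spacing = float(t[1] - t[0]) if len(t) > 1 and t[1] > t[0] else 1.0
    return TrajectoryHandle(topo, np.stack(frames), frame_spacing_ns=spacing)


def write_fixture(spec: EnsembleSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write a full fixture: topology PDB, multi-model PDB trajectory,
    ground-truth CSV (labels + feature values) and a manifest JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fm, labels = sample_features(spec)
    traj = build_trajectory(fm)
    paths = {
        "topology": out / "topology.pdb",
        "trajectory": out / "trajectory.pdb",
        "ground_truth": out / "ground_truth.csv",
        "manifest": out / "manifest.json",
    }
    write_structure(traj.topology, paths["topology"])
    write_multimodel_pdb(traj, paths["trajectory"])
    gt = fm.values.copy()
    gt.insert(0, "basin", labels)
    gt.to_csv(paths["ground_truth"], float_format="%.6f")
    manifest = {
        "seed": spec.seed,
        "preset": spec.preset_name,
        "n_frames": spec.n_frames,
        "n_atoms": traj.topology.n_atoms,
        "frame_spacing_ns": spec.frame_spacing_ns,
        "basins": [{"name": b.name, "means": dict(b.means),
                    "sds": dict(b.sds)} for b in spec.basins],
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=1))
    return paths


# ---------------------------------------------------------------------------
# presets

def _basin(name: str, **overrides) -> BasinSpec:
    inactive = {
        "tm26": 14.0, "tm37": 19.0,
        "chi1_w6x48": -60.0, "chi2_w6x48": 120.0,
        "chi1_f6x44": -60.0, "chi2_f6x44": 90.0,
        "dist_wn": 6.0, "dist_tyrtyr": 13.0, "tm5_bulge": 10.0,
        "ionic_lock": 3.5, "hydrophobic_lock": 4.5,
        "z_distance": 10.0, "z_angle": 20.0,
    }
    means = dict(inactive)
    means.update(overrides)
    sds = {d: (DEFAULT_SD_ANGLE if d in ANGLE_DOFS else DEFAULT_SD_DISTANCE)
           for d in means}
    return BasinSpec(name=name, means=means, sds=sds)


_ACTIVE_OVERRIDES = dict(
    tm26=21.0, tm37=14.0, chi2_w6x48=50.0, chi2_f6x44=90.0,
    chi1_f6x44=175.0, dist_wn=3.0, dist_tyrtyr=7.0, tm5_bulge=8.0,
    ionic_lock=9.0, hydrophobic_lock=8.0,
)

PRESET_NAMES = ("inactive_apo", "active_g_protein", "beta_arrestin_ideal",
                "g_protein_ideal", "toggle_two_state", "alternative_rotamer",
                "drifting_construct")


def preset(name: str, n_frames: int = 1000, seed: int = 0) -> EnsembleSpec:
    """Named ensemble specs with documented basin means.

    ``beta_arrestin_ideal`` places the basin at TM3-7 = 15 A / TM2-6 = 18 A
    and ``g_protein_ideal`` at TM2-6 = 21 A; ``toggle_two_state`` switches
    the toggle chi2 between the 50 deg (on) and 120 deg (off) basins with a
    symmetric 0.01/step Markov chain.
    """
    if name == "inactive_apo":
        basins = (_basin("inactive"),)
        switching = None
    elif name == "active_g_protein":
        basins = (_basin("active", **_ACTIVE_OVERRIDES),)
        switching = None
    elif name == "beta_arrestin_ideal":
        basins = (_basin("beta_arrestin",
                         **{**_ACTIVE_OVERRIDES, "tm26": 18.0, "tm37": 15.0}),)
        switching = None
    elif name == "g_protein_ideal":
        basins = (_basin("g_protein",
                         **{**_ACTIVE_OVERRIDES, "tm26": 21.0, "tm37": 14.0,
                            "tm5_bulge": 7.5}),)
        switching = None
    elif name == "toggle_two_state":
        on = _basin("toggle_on", **{**_ACTIVE_OVERRIDES, "chi2_w6x48": 50.0})
        off = _basin("toggle_off", **{**_ACTIVE_OVERRIDES, "chi2_w6x48": 120.0})
        basins = (on, off)
        switching = SwitchingSpec(("toggle_on", "toggle_off"),
                                  np.array([[0.99, 0.01], [0.01, 0.99]]))
    elif name == "alternative_rotamer":
        basins = (_basin("alternative",
                         **{**_ACTIVE_OVERRIDES, "chi1_w6x48": 45.0,
                            "chi2_w6x48": 100.0}),)
        switching = None
    elif name == "drifting_construct":
        basins = (_basin("drifting", **_ACTIVE_OVERRIDES),)
        return EnsembleSpec(basins=basins, n_frames=n_frames, seed=seed,
                            preset_name=name,
                            drift=("z_distance", n_frames // 4, -0.05))
    else:
        raise ValueError(f"unknown preset {name!r}; one of {PRESET_NAMES}")
    return EnsembleSpec(basins=basins, n_frames=n_frames, seed=seed,
                        switching=switching, preset_name=name)
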