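"""Structure and trajectory I/O plus Ballesteros-Weinstein address resolution.

The in-memory unit is :class:`StructureModel`, a flat table of atoms with
coordinates in Angstrom.  Structures are read with :mod:`gemmi` (PDB and
mmCIF); trajectories are either multi-model PDB files (read with gemmi, so
text fixtures round-trip exactly) or DCD/XTC files read through MDAnalysis.

Residues are addressed either by raw residue number or by their
Ballesteros-Weinstein (BW) code ("6x48" is the toggle-switch tryptophan on
helix 6), translated through a :class:`BWMap` supplied as configuration.
"""

from __future__ import annotations

import dataclasses
import io
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "StructureModel",
    "TrajectoryHandle",
    "BWMap",
    "AtomSelector",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_multimodel_pdb",
    "resolve_selector",
    "load_bw_map",
]

# Elements considered polar for minimum-polar-distance descriptors.
POLAR_ELEMENTS = frozenset({"N", "O", "S"})

_AA_SET = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "HSD",
    "HSE", "HSP", "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR",
    "TRP", "TYR", "VAL",
}
# Terminal capping groups (acetyl / methylamide) are parsed like any other
# residue but excluded from helix-range selections by default.
CAP_RESNAMES = frozenset({"ACE", "NME", "CT3", "ACP"})

_BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT", "H", "HA", "HN"})


@dataclasses.dataclass
class StructureModel:
    """A single frame of coordinates with per-atom metadata.

    All arrays share one length; coordinates are Angstrom.
    """

    names: np.ndarray       # atom names, dtype object/str
    elements: np.ndarray    # element symbols, upper case
    resids: np.ndarray      # integer residue numbers
    resnames: np.ndarray
    segids: np.ndarray      # chain / segment identifiers
    coords: np.ndarray      # (n, 3) float64
    title: str = ""
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.names)
        for arr in (self.elements, self.resids, self.resnames, self.segids):
            if len(arr) != n:
                raise ValueError("atom metadata arrays have unequal lengths")
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords shape {self.coords.shape} != ({n}, 3)")
        if n == 0:
            raise ValueError("empty structure")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def with_coords(self, coords: np.ndarray, frame_index: int = 0) -> "StructureModel":
        """Same topology, new coordinates (used by trajectory iteration)."""
        return dataclasses.replace(self, coords=np.asarray(coords, dtype=float),
                                   frame_index=frame_index)

    def subset(self, idx: np.ndarray) -> "StructureModel":
        idx = np.asarray(idx)
        return StructureModel(
            names=self.names[idx], elements=self.elements[idx],
            resids=self.resids[idx], resnames=self.resnames[idx],
            segids=self.segids[idx], coords=self.coords[idx],
            title=self.title, frame_index=self.frame_index,
        )


class TrajectoryHandle:
    """Sequence of frames sharing one topology.

    ``frame_spacing_ns`` is user-supplied metadata (time between stored
    frames); frame times are ``index * frame_spacing_ns``.
    """

    def __init__(self, topology: StructureModel,
                 frames: Sequence[np.ndarray] | np.ndarray,
                 frame_spacing_ns: float = 1.0):
        if frame_spacing_ns <= 0:
            raise ValueError("frame spacing must be positive (ns)")
        frames = np.asarray(frames, dtype=float)
        if frames.ndim != 3 or frames.shape[1:] != (topology.n_atoms, 3):
            raise ValueError(
                f"frames shape {frames.shape} incompatible with topology of "
                f"{topology.n_atoms} atoms")
        self.topology = topology
        self._frames = frames
        self.frame_spacing_ns = float(frame_spacing_ns)

    @property
    def n_frames(self) -> int:
        return len(self._frames)

    @property
    def times_ns(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_spacing_ns

    def frame(self, i: int) -> StructureModel:
        return self.topology.with_coords(self._frames[i], frame_index=i)

    def __len__(self) -> int:
        return self.n_frames

    def __iter__(self):
        for i in range(self.n_frames):
            yield self.frame(i)


@dataclasses.dataclass(frozen=True)
class BWMap:
    """Ballesteros-Weinstein code -> residue number for one receptor."""

    entries: Mapping[str, int]
    receptor: str = ""

    def __post_init__(self) -> None:
        vals = list(self.entries.values())
        if len(set(vals)) != len(vals):
            raise ValueError("BW map is not injective on residue numbers")

    def resid(self, code: str) -> int:
        try:
            return int(self.entries[code])
        except KeyError:
            raise KeyError(
                f"BW code {code!r} not present in map for "
                f"{self.receptor or 'receptor'}; add it to the BW map config"
            ) from None

    def __contains__(self, code: str) -> bool:
        return code in self.entries


# Default 5-HT2A map: only residue numbers actually anchored in the
# literature narrative are shipped; positions such as 6x30 or 3x50 must be
# supplied by the user's own map.
DEFAULT_5HT2A_BW = BWMap(
    entries={
        "6x48": 336, "6x44": 332, "6x41": 329,
        "5x58": 254, "5x46": 242, "5x50": 246,
        "7x53": 380, "7x49": 376, "7x41": 369,
        "3x32": 155, "3x40": 163,
    },
    receptor="5-HT2A",
)


@dataclasses.dataclass(frozen=True)
class AtomSelector:
    """Declarative atom selection.

    Exactly one of ``bw`` or ``resid_range`` scopes the residues (or neither,
    selecting all residues); ``atom_names`` and/or ``group`` filter atoms.
    Named groups: ``calpha``, ``heavy``, ``sidechain-heavy``, ``polar-heavy``,
    ``all``.
    """

    bw: str | None = None
    resid_range: tuple[int, int] | None = None
    atom_names: tuple[str, ...] | None = None
    group: str | None = None
    segid: str | None = None
    resname: str | None = None
    exclude_caps: bool = True

    _GROUPS = ("calpha", "heavy", "sidechain-heavy", "polar-heavy", "all")

    def __post_init__(self) -> None:
        if self.bw is not None and self.resid_range is not None:
            raise ValueError("selector may not combine a BW code with a residue range")
        if self.group is not None and self.group not in self._GROUPS:
            raise ValueError(f"unknown group {self.group!r}; one of {self._GROUPS}")


def resolve_selector(model: StructureModel, selector: AtomSelector,
                     bw_map: BWMap | None = None) -> np.ndarray:
    """Resolve a selector to an ordered array of atom indices.

    Deterministic and order-stable: indices are returned in model order.
    Raises ``KeyError`` for an unmapped BW code and ``ValueError`` when the
    selection is empty.
    """
    mask = np.ones(model.n_atoms, dtype=bool)
    if selector.bw is not None:
        if bw_map is None:
            raise ValueError("selector uses a BW code but no BW map was given")
        mask &= model.resids == bw_map.resid(selector.bw)
    elif selector.resid_range is not None:
        lo, hi = selector.resid_range
        mask &= (model.resids >= lo) & (model.resids <= hi)
    if selector.segid is not None:
        mask &= model.segids == selector.segid
    if selector.resname is not None:
        mask &= model.resnames == selector.resname
    if selector.exclude_caps:
        mask &= ~np.isin(model.resnames, list(CAP_RESNAMES))
    if selector.atom_names is not None:
        mask &= np.isin(model.names, list(selector.atom_names))
    if selector.group is not None and selector.group != "all":
        heavy = model.elements != "H"
        if selector.group == "calpha":
            mask &= model.names == "CA"
        elif selector.group == "heavy":
            mask &= heavy
        elif selector.group == "sidechain-heavy":
            mask &= heavy & ~np.isin(model.names, list(_BACKBONE_NAMES))
        elif selector.group == "polar-heavy":
            mask &= np.isin(model.elements, list(POLAR_ELEMENTS))
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError(f"selector {selector} matched no atoms")
    return idx


# ---------------------------------------------------------------------------
# gemmi-backed readers/writers

def _element_of(atom, resname: str) -> str:
    el = atom.element.name.upper() if atom.element else ""
    if not el or el == "X":
        # fall back to the leading alphabetic character of the atom name
        for ch in atom.name:
            if ch.isalpha():
                el = ch.upper()
                break
    return el


def _model_from_gemmi(gmodel, title: str, frame_index: int) -> StructureModel:
    names, elements, resids, resnames, segids, xyz = [], [], [], [], [], []
    for chain in gmodel:
        for res in chain:
            for atom in res:
                names.append(atom.name)
                elements.append(_element_of(atom, res.name))
                resids.append(res.seqid.num)
                resnames.append(res.name)
                segids.append(chain.name)
                xyz.append((atom.pos.x, atom.pos.y, atom.pos.z))
    if not names:
        raise ValueError("empty structure: no ATOM/HETATM records parsed")
    return StructureModel(
        names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        resids=np.array(resids, dtype=int),
        resnames=np.array(resnames, dtype=object),
        segids=np.array(segids, dtype=object),
        coords=np.array(xyz, dtype=float),
        title=title, frame_index=frame_index,
    )


def _read_gemmi(path: str | Path, fmt: str | None):
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path))
        else:
            raise ValueError(f"unsupported structure format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"failed to parse {path}: {exc}") from exc
    return st


def read_structure(path: str | Path, fmt: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel` (first model)."""
    st = _read_gemmi(path, fmt)
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    return _model_from_gemmi(st[0], title=st.name, frame_index=0)


def read_trajectory(path: str | Path, topology: StructureModel | str | Path,
                    fmt: str | None = None,
                    frame_spacing_ns: float = 1.0) -> TrajectoryHandle:
    """Read a trajectory: multi-model PDB, or DCD/XTC via MDAnalysis.

    ``topology`` may be a :class:`StructureModel` or a path to a PDB file.
    Every frame must carry the same atom count as the topology.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower().lstrip(".")
        fmt = {"pdb": "pdb", "dcd": "dcd", "xtc": "xtc"}.get(suffix)
        if fmt is None:
            raise ValueError(f"cannot infer trajectory format from {path.name!r}")
    if not isinstance(topology, StructureModel):
        topology = read_structure(topology)

    if fmt == "pdb":
        st = _read_gemmi(path, "pdb")
        frames = []
        for i, gmodel in enumerate(st):
            m = _model_from_gemmi(gmodel, title=st.name, frame_index=i)
            if m.n_atoms != topology.n_atoms:
                raise ValueError(
                    f"{path}: model {i + 1} has {m.n_atoms} atoms, "
                    f"topology has {topology.n_atoms}")
            frames.append(m.coords)
        if not frames:
            raise ValueError(f"{path}: no MODEL blocks found")
        return TrajectoryHandle(topology, np.stack(frames), frame_spacing_ns)

    if fmt in {"dcd", "xtc"}:
        import warnings

        import MDAnalysis as mda

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # MDAnalysis needs a topology file; write the StructureModel out.
            import tempfile

            with tempfile.NamedTemporaryFile("w", suffix=".pdb", delete=False) as fh:
                fh.write(_to_pdb_text(topology))
                tmp = fh.name
            u = mda.Universe(tmp, str(path))
            if u.atoms.n_atoms != topology.n_atoms:
                raise ValueError(
                    f"{path}: trajectory has {u.atoms.n_atoms} atoms, "
                    f"topology has {topology.n_atoms}")
            frames = []
            try:
                for ts in u.trajectory:
                    frames.append(ts.positions.astype(float).copy())
            except (EOFError, OSError) as exc:
                raise ValueError(
                    f"{path}: truncated trajectory after frame {len(frames)}"
                ) from exc
        return TrajectoryHandle(topology, np.stack(frames), frame_spacing_ns)

    raise ValueError(f"unsupported trajectory format {fmt!r}")


def _to_pdb_text(model: StructureModel, model_number: int | None = None) -> str:
    buf = io.StringIO()
    if model_number is not None:
        buf.write(f"MODEL     {model_number:4d}\n")
    serial = 0
    for i in range(model.n_atoms):
        serial += 1
        name = str(model.names[i])
        pretty = name if len(name) >= 4 else f" {name:<3s}"
        record = "ATOM" if str(model.resnames[i]) in _AA_SET else "HETATM"
        x, y, z = model.coords[i]
        el = str(model.elements[i])
        buf.write(
            f"{record:<6s}{serial % 100000:5d} {pretty:<4s} "
            f"{str(model.resnames[i]):<3s} {str(model.segids[i])[:1]:1s}"
            f"{int(model.resids[i]):4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{el:>2s}\n"
        )
    if model_number is not None:
        buf.write("ENDMDL\n")
    return buf.getvalue()


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a single-frame PDB file (fixed-width ATOM records)."""
    Path(path).write_text(_to_pdb_text(model) + "END\n")


def write_multimodel_pdb(trajectory: TrajectoryHandle, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (the text trajectory dialect)."""
    parts = []
    for i in range(trajectory.n_frames):
        parts.append(_to_pdb_text(trajectory.frame(i), model_number=i + 1))
    Path(path).write_text("".join(parts) + "END\n")


def load_bw_map(path: str | Path) -> BWMap:
    """Load a BW map from a YAML file with keys ``receptor`` and ``entries``."""
    data = yaml.safe_load(Path(path).read_text())
    return BWMap(entries={str(k): int(v) for k, v in data["entries"].items()},
                 receptor=str(data.get("receptor", "")))
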