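"""YAML configuration loaders: DOF catalogues, restraint sets, run configs.

A DOF catalogue file is a list of entries::

    - name: tm26
      kind: centroid-distance
      unit: A
      selectors:
        - {resid_range: [90, 91], atom_names: [CA], segid: R}
        - {resid_range: [330, 331], atom_names: [CA], segid: R}

Restraint entries carry ``lo``/``hi`` (A), ``k`` and explicit ``k_units``
(the half-harmonic convention E = 0.5 k x^2 is fixed, so the units of k
must be declared rather than assumed).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import yaml

from .descriptors import DOFDefinition, FeatureMatrix
from .restraints import FlatBottomRestraint
from .structures import AtomSelector

__all__ = ["selector_from_dict", "load_dof_catalogue", "load_restraints",
           "write_features", "read_features"]


def selector_from_dict(d: Mapping[str, Any]) -> AtomSelector:
    rng = d.get("resid_range")
    names = d.get("atom_names")
    return AtomSelector(
        bw=d.get("bw"),
        resid_range=tuple(rng) if rng else None,
        atom_names=tuple(names) if names else None,
        group=d.get("group"),
        segid=d.get("segid"),
        resname=d.get("resname"),
        exclude_caps=bool(d.get("exclude_caps", True)),
    )


def load_dof_catalogue(path: str | Path) -> list[DOFDefinition]:
    entries = yaml.safe_load(Path(path).read_text())
    if not isinstance(entries, list):
        raise ValueError(f"{path}: DOF catalogue must be a YAML list")
    out = []
    for e in entries:
        out.append(DOFDefinition(
            name=e["name"], kind=e["kind"],
            selectors=tuple(selector_from_dict(s) for s in e["selectors"]),
            unit=e.get("unit", "A"), reference=e.get("reference"),
        ))
    return out


def load_restraints(path: str | Path) -> list[FlatBottomRestraint]:
    entries = yaml.safe_load(Path(path).read_text())
    out = []
    for e in entries:
        if "k_units" not in e:
            raise ValueError(
                f"restraint {e.get('name')!r}: k_units must be declared "
                "(e.g. kcal/mol/A^2)")
        out.append(FlatBottomRestraint(
            name=e["name"],
            selector_a=selector_from_dict(e["selectors"][0]),
            selector_b=selector_from_dict(e["selectors"][1]),
            lo=float(e["lo"]), hi=float(e["hi"]), k=float(e["k"]),
        ))
    return out


def write_features(fm: FeatureMatrix, base: str | Path) -> tuple[Path, Path]:
    """Write a feature matrix as <base>.csv plus a <base>.json sidecar with
    units, periodicity and provenance."""
    base = Path(base)
    csv_path = base.with_suffix(".csv")
    json_path = base.with_suffix(".json")
    fm.values.to_csv(csv_path, float_format="%.8f")
    json_path.write_text(json.dumps({
        "units": fm.units, "periodic": fm.periodic,
        "provenance": fm.provenance,
    }, indent=1))
    return csv_path, json_path


def read_features(base: str | Path) -> FeatureMatrix:
    import pandas as pd

    base = Path(base)
    df = pd.read_csv(base.with_suffix(".csv"), index_col=0)
    meta = json.loads(base.with_suffix(".json").read_text())
    return FeatureMatrix(values=df, units=meta["units"],
                         periodic=meta["periodic"],
                         provenance=meta.get("provenance", {}))
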