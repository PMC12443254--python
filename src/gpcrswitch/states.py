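"""Discrete conformational-state labels from descriptor values.

Covers the toggle-switch tryptophan rotamer (on / off / alternative), the
PIF phenylalanine chi1 branch (gauche / anti), the heavy-atom hydrogen-bond
criterion, and a scalar coordinate along the (TM2-6, TM3-7) activation
axis drawn between the inactive and active anchor conformations.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = ["RotamerTaxonomy", "ActivationAxis", "StateRecord",
           "circular_distance", "classify_toggle", "classify_f6x44",
           "detect_hbond", "activation_coordinate", "summarize_states"]

TOGGLE_LABELS = ("on", "off", "alternative")
F6X44_LABELS = ("gauche", "anti")
ACTIVATION_LABELS = ("inactive", "partially-active", "active")


def circular_distance(a, b):
    """Shortest angular separation in degrees, in [0, 180]."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    out = np.where(d > 180.0, 360.0 - d, d)
    return float(out) if out.ndim == 0 else out


@dataclasses.dataclass(frozen=True)
class RotamerTaxonomy:
    """Rotamer basin centers and the alternative-state chi1 window.

    The toggle tryptophan is 'on' near chi2 = 50 deg and 'off' near
    chi2 = 120 deg; the alternative rotamer is defined by chi1 in
    [30, 60] deg and takes precedence over the chi2 split.
    """

    toggle_on_chi2: float = 50.0
    toggle_off_chi2: float = 120.0
    alternative_chi1: tuple[float, float] = (30.0, 60.0)
    f6x44_anti_center: float = 180.0
    f6x44_anti_halfwidth: float = 60.0


@dataclasses.dataclass(frozen=True)
class ActivationAxis:
    """Axis between inactive and active anchors in (TM2-6, TM3-7) space (A).

    The scalar coordinate is the signed projection onto the unit axis,
    zero at the inactive anchor.  Labels split the anchor-to-anchor length
    into thirds by default.
    """

    inactive_anchor: tuple[float, float]
    active_anchor: tuple[float, float]
    thresholds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if np.allclose(self.inactive_anchor, self.active_anchor):
            raise ValueError("degenerate activation axis: identical anchors")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.subtract(self.active_anchor,
                                                self.inactive_anchor)))

    @property
    def unit(self) -> np.ndarray:
        v = np.subtract(self.active_anchor, self.inactive_anchor, dtype=float)
        return v / np.linalg.norm(v)

    def label_thresholds(self) -> tuple[float, float]:
        if self.thresholds is not None:
            return self.thresholds
        L = self.length
        return (L / 3.0, 2.0 * L / 3.0)


@dataclasses.dataclass
class StateRecord:
    """Per-frame state labels for one simulation."""

    simulation_id: str
    table: pd.DataFrame    # columns: toggle, f6x44, hbond, bulge, activation, activation_label


def classify_toggle(chi1, chi2, taxonomy: RotamerTaxonomy = RotamerTaxonomy()):
    """Toggle-switch rotamer label(s); 'alternative' wins on chi1.

    Accepts scalars or arrays; angles are taken modulo 360 so adding a full
    turn never changes the label.
    """
    scalar = np.asarray(chi1).ndim == 0
    chi1 = np.atleast_1d(np.asarray(chi1, dtype=float))
    chi2 = np.atleast_1d(np.asarray(chi2, dtype=float))
    lo, hi = taxonomy.alternative_chi1
    c1 = -((-chi1 + 180.0) % 360.0 - 180.0)    # wrap to (-180, 180]
    c1[c1 == -180.0] = 180.0
    alt = (c1 >= lo) & (c1 <= hi)
    d_on = circular_distance(chi2, taxonomy.toggle_on_chi2)
    d_off = circular_distance(chi2, taxonomy.toggle_off_chi2)
    labels = np.where(alt, "alternative", np.where(d_on <= d_off, "on", "off"))
    return str(labels[0]) if scalar else labels


def classify_f6x44(chi1, taxonomy: RotamerTaxonomy = RotamerTaxonomy()):
    """PIF phenylalanine chi1 branch: anti within 60 deg of 180, else gauche.

    The boundary itself (circular distance exactly 60 deg) counts as anti.
    """
    scalar = np.asarray(chi1).ndim == 0
    d = np.atleast_1d(circular_distance(chi1, taxonomy.f6x44_anti_center))
    labels = np.where(d <= taxonomy.f6x44_anti_halfwidth, "anti", "gauche")
    return str(labels[0]) if scalar else labels


def detect_hbond(distance, cutoff: float = 3.5):
    """Heavy-atom donor-acceptor criterion: bonded iff distance <= cutoff (A).

    No angular term: trajectories may lack consistent hydrogens, and the
    distance distribution is the reported observable.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    d = np.asarray(distance, dtype=float)
    out = d <= cutoff
    return bool(out) if out.ndim == 0 else out


def activation_coordinate(tm26, tm37, axis: ActivationAxis):
    """Scalar position along the activation axis and its label(s).

    Returns ``(coordinate, label)``; the coordinate is in Angstrom, zero at
    the inactive anchor and ``axis.length`` at the active anchor.
    """
    pts = np.stack([np.atleast_1d(np.asarray(tm26, dtype=float)),
                    np.atleast_1d(np.asarray(tm37, dtype=float))], axis=-1)
    s = (pts - np.asarray(axis.inactive_anchor)) @ axis.unit
    t1, t2 = axis.label_thresholds()
    labels = np.where(s < t1, "inactive",
                      np.where(s < t2, "partially-active", "active"))
    if np.isscalar(tm26) or np.asarray(tm26).ndim == 0:
        return float(s[0]), str(labels[0])
    return s, labels


def summarize_states(records: Iterable[StateRecord]) -> pd.DataFrame:
    """Per-simulation occupancy fractions for each label vocabulary.

    Every label of each closed vocabulary appears as a column, so absent
    states show up as exact zeros; fractions sum to 1 per taxonomy.
    """
    records = list(records)
    if not records:
        raise ValueError("no state records")
    rows = []
    for rec in records:
        n = len(rec.table)
        row: dict[str, float | str] = {"simulation_id": rec.simulation_id}
        for lab in TOGGLE_LABELS:
            row[f"toggle_{lab}"] = float((rec.table["toggle"] == lab).sum() / n)
        if "f6x44" in rec.table:
            for lab in F6X44_LABELS:
                row[f"f6x44_{lab}"] = float((rec.table["f6x44"] == lab).sum() / n)
        if "hbond" in rec.table:
            row["hbond_fraction"] = float(rec.table["hbond"].mean())
        if "activation_label" in rec.table:
            for lab in ACTIVATION_LABELS:
                row[f"activation_{lab}"] = float(
                    (rec.table["activation_label"] == lab).sum() / n)
        rows.append(row)
    return pd.DataFrame(rows).set_index("simulation_id")
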