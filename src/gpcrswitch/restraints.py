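"""Flat-bottom harmonic restraints on collective variables (CVs) and
coupling monitoring of the intracellular G-protein construct.

The potential is zero inside the flat range [lo, hi] and half-harmonic
outside: E = 0.5 * k * (d - bound)^2, in kcal/mol for k in kcal/mol/A^2.
The half factor is a declared convention (MD engines differ); config must
state the force-constant units explicitly.  This module only evaluates and
monitors restraints; it never applies forces inside an engine.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .descriptors import AtomSelector, z_distance_angle
from .structures import BWMap, TrajectoryHandle, resolve_selector

__all__ = ["FlatBottomRestraint", "restraint_energy", "restraint_force",
           "CouplingReport", "monitor_coupling"]


@dataclasses.dataclass(frozen=True)
class FlatBottomRestraint:
    """One restrained atom-pair distance CV."""

    name: str
    selector_a: AtomSelector
    selector_b: AtomSelector
    lo: float
    hi: float
    k: float                      # kcal/mol/A^2

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError(f"restraint {self.name!r}: lo > hi")
        if self.k < 0:
            raise ValueError(f"restraint {self.name!r}: negative force constant")


def restraint_energy(cv_value, restraint: FlatBottomRestraint):
    """Flat-bottom energy in kcal/mol; vectorized over cv_value."""
    d = np.asarray(cv_value, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite CV value")
    over = np.clip(d - restraint.hi, 0.0, None)
    under = np.clip(restraint.lo - d, 0.0, None)
    e = 0.5 * restraint.k * (over ** 2 + under ** 2)
    return float(e) if e.ndim == 0 else e


def restraint_force(cv_value, restraint: FlatBottomRestraint):
    """-dE/dd on the CV: zero inside, signed toward the flat region outside."""
    d = np.asarray(cv_value, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite CV value")
    over = np.clip(d - restraint.hi, 0.0, None)
    under = np.clip(restraint.lo - d, 0.0, None)
    f = -restraint.k * over + restraint.k * under
    return float(f) if f.ndim == 0 else f


@dataclasses.dataclass
class CouplingReport:
    table: pd.DataFrame            # per-frame CVs, energies, z_dist, z_angle
    max_violation_kcal: float
    coupled: bool
    drift_onset_frame: int | None  # first frame the moving average drifted


def monitor_coupling(trajectory: TrajectoryHandle,
                     restraints: Sequence[FlatBottomRestraint],
                     receptor_sel: AtomSelector,
                     iface_sel: AtomSelector,
                     tail_sel: AtomSelector,
                     bw_map: BWMap | None = None,
                     drift_threshold_A: float = 2.0,
                     window: int = 20) -> CouplingReport:
    """Per-frame CV values, restraint energies and Z-distance/Z-angle.

    The construct is flagged as decoupled when the moving average of the
    Z-distance departs from its initial value by more than
    ``drift_threshold_A``; the first offending frame is reported.
    """
    n = trajectory.n_frames
    cols: dict[str, np.ndarray] = {}
    for r in restraints:
        cols[f"cv_{r.name}"] = np.empty(n)
        cols[f"energy_{r.name}"] = np.empty(n)
    zd = np.empty(n)
    za = np.empty(n)
    for i in range(n):
        frame = trajectory.frame(i)
        for r in restraints:
            a = resolve_selector(frame, r.selector_a, bw_map)
            b = resolve_selector(frame, r.selector_b, bw_map)
            d = float(np.linalg.norm(frame.coords[a].mean(axis=0)
                                     - frame.coords[b].mean(axis=0)))
            cols[f"cv_{r.name}"][i] = d
            cols[f"energy_{r.name}"][i] = restraint_energy(d, r)
        zd[i], za[i] = z_distance_angle(frame, receptor_sel, iface_sel,
                                        tail_sel, bw_map)
    cols["z_distance"] = zd
    cols["z_angle"] = za
    table = pd.DataFrame(cols, index=pd.Index(trajectory.times_ns,
                                              name="time_ns"))
    energies = [cols[f"energy_{r.name}"] for r in restraints]
    max_violation = float(np.max(energies)) if energies else 0.0

    w = min(window, n)
    ma = pd.Series(zd).rolling(w, min_periods=1).mean().to_numpy()
    drift = np.abs(ma - ma[0]) > drift_threshold_A
    onset = int(np.argmax(drift)) if drift.any() else None
    coupled = onset is None
    return CouplingReport(table=table, max_violation_kcal=max_violation,
                          coupled=coupled, drift_onset_frame=onset)
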