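"""Equilibration discard and even subsampling ahead of pooled analysis.

The pipeline order is fixed: discard the unequilibrated head of each
trajectory first, then evenly subsample what remains (default 3,000 frames
per system) before pooling for PCA or density estimation.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .descriptors import (AtomSelector, FeatureMatrix, ReferenceState,
                          rmsd_to_reference)
from .structures import BWMap, TrajectoryHandle

__all__ = ["DiscardPolicy", "rmsd_timeseries", "discard_initial",
           "subsample_even", "detect_plateau"]

log = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class DiscardPolicy:
    """Either an explicit per-simulation cut (ns) or an automatic plateau rule.

    The automatic rule slides a linear fit over the receptor-Calpha RMSD
    series and declares equilibration at the first window whose fitted
    slope magnitude drops below ``slope_tol`` (A/ns).
    """

    mode: str = "explicit-ns"            # or "auto-plateau"
    explicit_ns: float = 0.0
    window_frames: int = 100
    slope_tol: float = 0.001

    def __post_init__(self) -> None:
        if self.mode not in ("explicit-ns", "auto-plateau"):
            raise ValueError(f"unknown discard mode {self.mode!r}")
        if self.explicit_ns < 0:
            raise ValueError("explicit discard must be >= 0 ns")
        if self.window_frames < 2:
            raise ValueError("plateau window must span at least 2 frames")


def rmsd_timeseries(trajectory: TrajectoryHandle, reference: ReferenceState,
                    fit_selector: AtomSelector, calc_selector: AtomSelector,
                    bw_map: BWMap | None = None) -> pd.Series:
    """Per-frame RMSD to a reference, indexed by frame time in ns."""
    vals = [rmsd_to_reference(trajectory.frame(i), reference.model,
                              fit_selector, calc_selector, bw_map)
            for i in range(trajectory.n_frames)]
    return pd.Series(vals, index=pd.Index(trajectory.times_ns, name="time_ns"),
                     name="rmsd_A")


def detect_plateau(series: pd.Series, window_frames: int = 100,
                   slope_tol: float = 0.001) -> float:
    """First time (ns) at which the windowed RMSD slope flattens.

    Returns the start time of the first window whose least-squares slope
    satisfies |slope| < slope_tol (A/ns); falls back to 0 if the very first
    window already qualifies, or to the last window start if none does.
    """
    t = series.index.to_numpy(dtype=float)
    y = series.to_numpy(dtype=float)
    n = len(y)
    if n < window_frames:
        return 0.0
    for start in range(0, n - window_frames + 1):
        tw = t[start:start + window_frames]
        yw = y[start:start + window_frames]
        slope = np.polyfit(tw, yw, 1)[0]
        if abs(slope) < slope_tol:
            return float(tw[0])
    return float(t[n - window_frames])


def discard_initial(features: FeatureMatrix, policy: DiscardPolicy,
                    rmsd_series: pd.Series | None = None) -> FeatureMatrix:
    """Drop rows with time < cutoff; provenance records the cutoff used."""
    if policy.mode == "explicit-ns":
        cutoff = policy.explicit_ns
    else:
        if rmsd_series is None:
            raise ValueError("auto-plateau policy requires an RMSD series")
        cutoff = detect_plateau(rmsd_series, policy.window_frames,
                                policy.slope_tol)
    t = features.times_ns
    keep = t >= cutoff
    if not keep.any():
        raise ValueError(
            f"discard cutoff {cutoff} ns removes every frame "
            f"(trajectory ends at {t[-1]} ns)")
    out = FeatureMatrix(features.values.loc[keep], dict(features.units),
                        dict(features.periodic), dict(features.provenance))
    out.provenance["discard_ns"] = float(cutoff)
    out.provenance["n_after_discard"] = int(keep.sum())
    return out


def subsample_even(features: FeatureMatrix, n: int = 3000) -> FeatureMatrix:
    """Evenly sample ``min(n, rows)`` rows, first and last frame included.

    Indices are floor-rounded points on a linear ramp from the first to the
    last row, which makes them strictly increasing whenever rows > n, so no
    frame is ever duplicated and row order is preserved.
    """
    if n < 1:
        raise ValueError("subsample size must be >= 1")
    rows = len(features.values)
    if rows <= n:
        if rows < n:
            log.warning("subsample_even: only %d rows available, requested %d",
                        rows, n)
        idx = np.arange(rows)
    elif n == 1:
        idx = np.array([0])
    else:
        idx = np.floor(np.linspace(0, rows - 1, n)).astype(int)
    out = FeatureMatrix(features.values.iloc[idx], dict(features.units),
                        dict(features.periodic), dict(features.provenance))
    out.provenance["n_after_subsample"] = int(len(idx))
    return out
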