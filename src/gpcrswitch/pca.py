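"""Pooled correlation-matrix PCA over descriptor time series.

Descriptors mix Angstrom and degree units, so every column is z-scored
(population convention) before the eigendecomposition; for standardized
input the eigenvalue sum equals the number of DOFs, which is how explained
variance ratios relate to raw eigenvalues.

Angular columns are re-centered before standardization: the branch cut of
each periodic column is moved to the least-populated angle (the antimode)
so that a basin straddling +-180 deg is not split into two artificial
clusters.  The recentered values may therefore leave (-180, 180]; they stay
on one continuous branch, which is what a linear method needs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .descriptors import FeatureMatrix

__all__ = ["PCAModel", "ProjectionSet", "recenter_circular", "standardize",
           "fit_pca", "fit_pooled_pca", "project", "loadings_report",
           "second_pca"]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class PCAModel:
    dof_names: list[str]
    mean: np.ndarray            # per-DOF mean of the (recentered) pooled data
    scale: np.ndarray           # per-DOF population SD
    loadings: np.ndarray        # (n_dofs, n_pcs), columns orthonormal
    eigenvalues: np.ndarray     # non-increasing, >= 0
    explained_variance_ratio: np.ndarray
    n_rows: int
    branch_centers: dict[str, float] = dataclasses.field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "dof_names": self.dof_names,
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "n_rows": self.n_rows,
            "branch_centers": self.branch_centers,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PCAModel":
        d = json.loads(Path(path).read_text())
        return cls(d["dof_names"], np.array(d["mean"]), np.array(d["scale"]),
                   np.array(d["loadings"]), np.array(d["eigenvalues"]),
                   np.array(d["explained_variance_ratio"]), d["n_rows"],
                   d.get("branch_centers", {}))


@dataclasses.dataclass
class ProjectionSet:
    scores: dict[str, pd.DataFrame]          # simulation id -> frames x PCs
    reference_scores: pd.DataFrame | None = None


def recenter_circular(values: np.ndarray, bin_width: float = 1.0) -> tuple[np.ndarray, float]:
    """Shift the branch cut of an angular column to its antimode.

    The circle is binned at ``bin_width`` degrees; the emptiest bin center c
    becomes the cut and every value is mapped into (c, c + 360].  Returns
    the shifted values and c.
    """
    v = np.asarray(values, dtype=float)
    edges = np.arange(-180.0, 180.0 + bin_width, bin_width)
    counts, _ = np.histogram(np.where(v > 180.0, v - 360.0, v), bins=edges)
    # smooth circularly (~15 deg window) so sparse bins inside a basin are
    # not mistaken for the antimode
    half = max(1, int(round(7.5 / bin_width)))
    kernel = np.ones(2 * half + 1)
    smooth = np.convolve(np.tile(counts, 3), kernel, mode="same")
    smooth = smooth[len(counts):2 * len(counts)]
    lows = np.flatnonzero(smooth == smooth.min())
    # tie-break: emptiest bin farthest (circularly) from the mode bin
    imode = int(np.argmax(smooth))
    nbins = len(counts)
    circ = np.minimum(np.abs(lows - imode), nbins - np.abs(lows - imode))
    cut = float(edges[int(lows[np.argmax(circ)])])
    shifted = ((v - cut) % 360.0) + cut
    return shifted, cut


def standardize(pooled: pd.DataFrame, tolerate_constant: bool = False):
    """Z-score each column with the population SD (ddof=0).

    Returns ``(standardized DataFrame, means, scales)``.  A constant column
    is an error unless ``tolerate_constant``, in which case it becomes
    zeros (scale recorded as 1) with a warning.
    """
    if len(pooled) < 2:
        raise ValueError("need at least 2 rows to standardize")
    x = pooled.to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in pooled features")
    mean = x.mean(axis=0)
    scale = x.std(axis=0, ddof=0)
    const = scale == 0.0
    if const.any():
        names = [c for c, f in zip(pooled.columns, const) if f]
        if not tolerate_constant:
            raise ValueError(f"constant DOF column(s): {names}")
        log.warning("constant DOF column(s) standardized to zeros: %s", names)
        scale = np.where(const, 1.0, scale)
    z = (x - mean) / scale
    return pd.DataFrame(z, index=pooled.index, columns=pooled.columns), mean, scale


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    # orient each loading vector so its largest-|weight| element is positive
    out = vecs.copy()
    for j in range(out.shape[1]):
        k = int(np.argmax(np.abs(out[:, j])))
        if out[k, j] < 0:
            out[:, j] = -out[:, j]
    return out


def fit_pca(standardized: pd.DataFrame) -> PCAModel:
    """Eigendecomposition of the (population) covariance of standardized data.

    Deterministic: eigenvalues sorted non-increasing, each loading vector
    oriented so its largest-magnitude weight is positive.
    """
    z = standardized.to_numpy(dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite values")
    n, p = z.shape
    cov = z.T @ z / n
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = _fix_signs(evecs[:, order])
    total = evals.sum()
    evr = evals / total if total > 0 else np.zeros_like(evals)
    return PCAModel(
        dof_names=list(standardized.columns),
        mean=np.zeros(p), scale=np.ones(p),
        loadings=evecs, eigenvalues=evals,
        explained_variance_ratio=evr, n_rows=n,
    )


def fit_pooled_pca(matrices: Mapping[str, FeatureMatrix],
                   tolerate_constant: bool = False) -> PCAModel:
    """Concatenate per-simulation feature matrices (equal per-frame weight),
    recenter angular columns, standardize, and fit.

    The returned model carries the pooled means/scales and per-column branch
    centers so that later data (trajectories or experimental reference
    structures) is projected into exactly the same space.
    """
    if not matrices:
        raise ValueError("no feature matrices supplied")
    first = next(iter(matrices.values()))
    cols = first.dof_names
    for sim, fm in matrices.items():
        if fm.dof_names != cols:
            raise ValueError(f"simulation {sim!r} has mismatching DOF columns")
    pooled = pd.concat([fm.values for fm in matrices.values()],
                       ignore_index=True)
    centers: dict[str, float] = {}
    for col in cols:
        if first.periodic.get(col, False):
            shifted, cut = recenter_circular(pooled[col].to_numpy())
            pooled[col] = shifted
            centers[col] = cut
    z, mean, scale = standardize(pooled, tolerate_constant)
    model = fit_pca(z)
    model.mean = mean
    model.scale = scale
    model.branch_centers = centers
    return model


def _apply_branch(model: PCAModel, df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col, cut in model.branch_centers.items():
        v = df[col].to_numpy(dtype=float)
        df[col] = ((v - cut) % 360.0) + cut
    return df


def project(model: PCAModel, features: FeatureMatrix | pd.DataFrame,
            n_pcs: int | None = None) -> pd.DataFrame:
    """Scores of rows in the model's PC space (pooled means/scales applied)."""
    df = features.values if isinstance(features, FeatureMatrix) else features
    missing = [c for c in model.dof_names if c not in df.columns]
    extra = [c for c in df.columns if c not in model.dof_names]
    if missing or extra:
        raise ValueError(f"column mismatch: missing {missing}, extra {extra}")
    df = _apply_branch(model, df[model.dof_names])
    z = (df.to_numpy(dtype=float) - model.mean) / model.scale
    k = n_pcs or model.loadings.shape[1]
    scores = z @ model.loadings[:, :k]
    return pd.DataFrame(scores, index=df.index,
                        columns=[f"PC{i + 1}" for i in range(k)])


def loadings_report(model: PCAModel, pc_index: int) -> list[tuple[str, float]]:
    """(DOF, signed weight) pairs for one PC, sorted by |weight| descending."""
    if not 0 <= pc_index < model.loadings.shape[1]:
        raise IndexError(f"PC index {pc_index} out of range")
    w = model.loadings[:, pc_index]
    order = np.argsort(-np.abs(w))
    return [(model.dof_names[i], float(w[i])) for i in order]


def second_pca(matrices: Mapping[str, FeatureMatrix],
               ligand_dofs: Sequence[str],
               apo_ids: Sequence[str] = (),
               tolerate_constant: bool = False) -> PCAModel:
    """Ligand-aware PCA: apo simulations excluded, ligand-distance columns
    required in every retained matrix."""
    present_apo = [sim for sim in matrices if sim in set(apo_ids)]
    if present_apo:
        raise ValueError(f"apo simulations present in second PCA input: {present_apo}")
    for sim, fm in matrices.items():
        missing = [c for c in ligand_dofs if c not in fm.dof_names]
        if missing:
            raise ValueError(f"simulation {sim!r} lacks ligand DOFs {missing}")
    return fit_pooled_pca(matrices, tolerate_constant)
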