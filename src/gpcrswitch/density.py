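"""Population densities over descriptors and their Boltzmann inversion.

Densities are Gaussian kernel estimates evaluated on fixed grids (0.2 A
bins for distances, 1 deg for angles, matching the analysis the maps feed).
The Boltzmann transform F = -kB*T*ln(p/pmax) expresses populations in
kcal/mol; these are population-derived maps of the sampled ensemble, not
converged free-energy surfaces, and the API names them accordingly.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

__all__ = ["DensityMap", "HDRegion", "density_1d", "density_2d",
           "boltzmann_invert", "hdr_region", "density_mode",
           "KB_KCAL_PER_MOL_K", "DEFAULT_TEMPERATURE_K"]

KB_KCAL_PER_MOL_K = 0.0019872041       # Boltzmann constant, kcal/mol/K
DEFAULT_TEMPERATURE_K = 303.15         # production-ensemble temperature


@dataclasses.dataclass
class DensityMap:
    """Gridded probability density (1D or 2D).

    ``prob`` holds the density per cell such that sum(prob) * cell_area = 1.
    ``free_energy`` (kcal/mol, min 0 at the mode) is attached by
    :func:`boltzmann_invert`; unsampled cells are +inf.
    """

    axes: tuple[np.ndarray, ...]       # bin centers per dimension
    bin_widths: tuple[float, ...]
    prob: np.ndarray
    periodic: tuple[bool, ...]
    temperature_K: float = DEFAULT_TEMPERATURE_K
    free_energy: np.ndarray | None = None

    @property
    def dimension(self) -> int:
        return len(self.axes)

    @property
    def cell_area(self) -> float:
        return float(np.prod(self.bin_widths))

    def normalization(self) -> float:
        return float(self.prob.sum() * self.cell_area)


@dataclasses.dataclass
class HDRegion:
    """Highest-density region: the smallest cell set capturing target mass."""

    mask: np.ndarray
    captured_mass: float
    contour_level: float
    target_mass: float


def _grid(values: np.ndarray, bin_width: float, periodic: bool,
          pad_sd: float = 3.0) -> np.ndarray:
    if periodic:
        # full circle, centers at ...,-179.5+w,... chosen so edges align at 180
        n = int(round(360.0 / bin_width))
        edges = np.linspace(-180.0, 180.0, n + 1)
        return 0.5 * (edges[:-1] + edges[1:])
    pad = pad_sd * values.std() + bin_width
    lo = np.floor((values.min() - pad) / bin_width) * bin_width
    hi = np.ceil((values.max() + pad) / bin_width) * bin_width
    centers = np.arange(lo + bin_width / 2, hi, bin_width)
    return centers


def _circular_sd(v_deg: np.ndarray) -> float:
    """Circular standard deviation in degrees (resultant-length estimator)."""
    r = np.abs(np.mean(np.exp(1j * np.radians(v_deg))))
    r = min(max(r, 1e-12), 1.0 - 1e-15)
    return float(np.degrees(np.sqrt(-2.0 * np.log(r))))


DEFAULT_BW_SCALE = 2.0


def _bandwidth(v: np.ndarray, periodic: bool, ndim: int,
               scale: float = DEFAULT_BW_SCALE) -> float:
    """Per-axis bandwidth: Scott's rule times an oversmoothing factor.

    The default doubles Scott's rule: with unimodal Gaussian basins the
    wider kernel leaves the mode location unbiased while markedly reducing
    its sampling scatter, which is what the landscape maps are read for.
    Circular SD is used on angular axes.
    """
    sd = _circular_sd(v) if periodic else float(np.std(v))
    n = v.size
    return max(sd, 1e-9) * scale * n ** (-1.0 / (ndim + 4))


def _kde_grid(columns, centers, bandwidths, periodic) -> np.ndarray:
    """Product-Gaussian KDE evaluated on a rectangular grid.

    Periodic axes wrap the kernel over +-360 deg.  A separable product
    kernel keeps per-axis bandwidths independent, which scipy's single
    shared covariance factor cannot express for mixed linear/angular axes.
    """
    n = columns[0].size
    # per-axis kernel matrix K_d: (n_centers_d, n)
    kmats = []
    for v, c, h, per in zip(columns, centers, bandwidths, periodic):
        diff = c[:, None] - v[None, :]
        if per:
            diff = (diff + 180.0) % 360.0 - 180.0
        k = np.exp(-0.5 * (diff / h) ** 2) / (h * np.sqrt(2.0 * np.pi))
        if per:
            # wrapped-kernel correction for mass beyond one turn
            for shift in (-360.0, 360.0):
                k += np.exp(-0.5 * ((diff + shift) / h) ** 2) / (
                    h * np.sqrt(2.0 * np.pi))
        kmats.append(k)
    if len(kmats) == 1:
        return kmats[0].sum(axis=1) / n
    # 2D: p(i,j) = sum_s Kx[i,s] Ky[j,s] / n
    return kmats[0] @ kmats[1].T / n


def density_1d(values, bin_width: float, periodic: bool = False,
               temperature_K: float = DEFAULT_TEMPERATURE_K,
               bw_scale: float = DEFAULT_BW_SCALE) -> DensityMap:
    """Gaussian-KDE density on a regular grid.

    Angular data is wrapped into (-180, 180] and the sample is replicated at
    +-360 deg before estimation, so a basin straddling the branch cut
    appears once instead of as two edge artifacts.  The gridded density is
    renormalized to unit mass on its own support.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("need at least 2 values for a density estimate")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite values")
    if periodic:
        v = -((-v + 180.0) % 360.0 - 180.0)
        v[v == -180.0] = 180.0
    centers = _grid(v, bin_width, periodic)
    h = _bandwidth(v, periodic, ndim=1, scale=bw_scale)
    p = _kde_grid([v], [centers], [h], [periodic])
    p = np.clip(p, 0.0, None)
    p /= p.sum() * bin_width
    return DensityMap(axes=(centers,), bin_widths=(bin_width,), prob=p,
                      periodic=(periodic,), temperature_K=temperature_K)


def density_2d(x, y, bin_widths: tuple[float, float],
               periodic: tuple[bool, bool] = (False, False),
               temperature_K: float = DEFAULT_TEMPERATURE_K,
               bw_scale: float = DEFAULT_BW_SCALE) -> DensityMap:
    """2D Gaussian-KDE density on a rectangular grid (x is axis 0)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ValueError("need at least 2 points")
    cx = _grid(x, bin_widths[0], periodic[0])
    cy = _grid(y, bin_widths[1], periodic[1])
    hx = _bandwidth(x, periodic[0], ndim=2, scale=bw_scale)
    hy = _bandwidth(y, periodic[1], ndim=2, scale=bw_scale)
    p = _kde_grid([x, y], [cx, cy], [hx, hy], list(periodic))
    p = np.clip(p, 0.0, None)
    p /= p.sum() * bin_widths[0] * bin_widths[1]
    return DensityMap(axes=(cx, cy), bin_widths=tuple(bin_widths), prob=p,
                      periodic=tuple(periodic), temperature_K=temperature_K)


def boltzmann_invert(density: DensityMap,
                     temperature_K: float | None = None) -> DensityMap:
    """Attach F = -kB*T*ln(p/pmax) in kcal/mol; unsampled cells become +inf."""
    T = temperature_K if temperature_K is not None else density.temperature_K
    if T <= 0:
        raise ValueError("temperature must be positive")
    p = density.prob
    pmax = p.max()
    if pmax <= 0:
        raise ValueError("all-zero density cannot be Boltzmann inverted")
    with np.errstate(divide="ignore"):
        f = -KB_KCAL_PER_MOL_K * T * np.log(p / pmax)
    return dataclasses.replace(density, free_energy=f, temperature_K=T)


def hdr_region(density: DensityMap, target_mass: float = 0.5) -> HDRegion:
    """Smallest cell set whose probability mass reaches ``target_mass``.

    Cells are taken in descending probability; equal-probability ties are
    broken by row-major grid order, so the mask is deterministic.
    """
    if not 0.0 < target_mass < 1.0:
        raise ValueError("target mass must be in (0, 1)")
    flat = density.prob.ravel()
    order = np.argsort(-flat, kind="stable")
    mass = np.cumsum(flat[order]) * density.cell_area
    k = int(np.searchsorted(mass, target_mass) + 1)
    k = min(k, flat.size)
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[:k]] = True
    return HDRegion(mask=mask.reshape(density.prob.shape),
                    captured_mass=float(mass[k - 1]),
                    contour_level=float(flat[order[k - 1]]),
                    target_mass=target_mass)


def density_mode(density: DensityMap) -> tuple[float, ...]:
    """Grid coordinates of the maximum-probability cell center.

    Ties go to the lowest row-major index with a warning.
    """
    flat = density.prob.ravel()
    imax = int(np.argmax(flat))
    if np.count_nonzero(flat == flat[imax]) > 1:
        warnings.warn("density mode is tied; returning lowest row-major cell",
                      stacklevel=2)
    idx = np.unravel_index(imax, density.prob.shape)
    return tuple(float(density.axes[d][idx[d]]) for d in range(density.dimension))
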