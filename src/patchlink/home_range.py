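"""Kernel utilization distributions and volume-contour home ranges.

The utilization distribution (UD) is the equal-weight mixture of isotropic
bivariate normal kernels centred on the fixes, with per-axis sd equal to the
smoothing bandwidth ``h`` (default 200 m, fixed rather than cross-validated).
It is evaluated on a regular grid (default 25 m resolution, fine relative to
h) padded at least 4 h beyond the fix bounding box, which bounds truncated
probability mass below 1e-3. The p-volume contour (default 0.95) is the
smallest set of highest-density cells enclosing a fraction p of the mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import FixSet

__all__ = ["UtilizationDistribution", "HomeRange", "TooFewFixesError", "estimate_ud", "volume_contour"]


class TooFewFixesError(ValueError):
    """Too few fixes to represent a home range."""


@dataclass
class UtilizationDistribution:
    """Kernel density over a grid; units of density are m^-2."""

    density: np.ndarray  # row 0 = southernmost row
    cell_size_m: float
    origin_xy: tuple[float, float]
    h_m: float
    n_fixes: int
    fix_xy: np.ndarray

    def mass(self) -> float:
        """Total probability mass captured by the grid (~1)."""
        return float(self.density.sum() * self.cell_size_m**2)

    def pdf(self, x, y) -> np.ndarray:
        """Exact (non-gridded) mixture density at arbitrary points."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        dx = x[..., None] - self.fix_xy[:, 0]
        dy = y[..., None] - self.fix_xy[:, 1]
        k = np.exp(-(dx**2 + dy**2) / (2 * self.h_m**2))
        return k.sum(axis=-1) / (2 * np.pi * self.h_m**2 * self.n_fixes)

    def mode_xy(self) -> tuple[float, float]:
        i, j = np.unravel_index(int(np.argmax(self.density)), self.density.shape)
        return (
            self.origin_xy[0] + (j + 0.5) * self.cell_size_m,
            self.origin_xy[1] + (i + 0.5) * self.cell_size_m,
        )


@dataclass
class HomeRange:
    """Boolean grid mask of the isopleth-level volume contour."""

    mask: np.ndarray
    isopleth_level: float
    cell_size_m: float
    origin_xy: tuple[float, float]

    @property
    def area_ha(self) -> float:
        return float(self.mask.sum()) * self.cell_size_m**2 / 1e4

    def contains(self, x, y) -> np.ndarray:
        """Whether points fall in a masked cell (False outside the grid)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        j = np.floor((x - self.origin_xy[0]) / self.cell_size_m).astype(int)
        i = np.floor((y - self.origin_xy[1]) / self.cell_size_m).astype(int)
        ok = (i >= 0) & (i < self.mask.shape[0]) & (j >= 0) & (j < self.mask.shape[1])
        out = np.zeros(np.shape(x), dtype=bool)
        out[ok] = self.mask[i[ok], j[ok]]
        return out


def estimate_ud(
    fixes: FixSet | np.ndarray,
    h_m: float = 200.0,
    grid_resolution_m: float = 25.0,
    pad_factor: float = 4.0,
    min_fixes: int = 5,
) -> UtilizationDistribution:
    """Estimate the kernel UD of one individual's fixes.

    ``fixes`` may be a single-individual :class:`FixSet` or an (n, 2) array of
    reported coordinates. Fewer than ``min_fixes`` fixes raise
    :class:`TooFewFixesError`, mirroring the exclusion of under-sampled birds.
    """
    if isinstance(fixes, FixSet):
        if len(fixes.individuals) > 1:
            raise ValueError("estimate_ud expects fixes of a single individual")
        xy = fixes.xy
    else:
        xy = np.asarray(fixes, dtype=float).reshape(-1, 2)
    if len(xy) < min_fixes:
        raise TooFewFixesError(
            f"{len(xy)} fixes are insufficient to represent a home range (need >= {min_fixes})"
        )
    if not np.all(np.isfinite(xy)):
        raise ValueError("fix coordinates must be finite")
    if h_m <= 0 or grid_resolution_m <= 0:
        raise ValueError("h_m and grid_resolution_m must be > 0")

    pad = pad_factor * h_m
    res = grid_resolution_m
    x0 = np.floor((xy[:, 0].min() - pad) / res) * res
    y0 = np.floor((xy[:, 1].min() - pad) / res) * res
    n_cols = int(np.ceil((xy[:, 0].max() + pad - x0) / res))
    n_rows = int(np.ceil((xy[:, 1].max() + pad - y0) / res))
    xc = x0 + (np.arange(n_cols) + 0.5) * res
    yc = y0 + (np.arange(n_rows) + 0.5) * res

    density = np.zeros((n_rows, n_cols))
    inv2h2 = 1.0 / (2.0 * h_m**2)
    for fx, fy in xy:  # separable kernel: rank-1 update per fix
        gx = np.exp(-((xc - fx) ** 2) * inv2h2)
        gy = np.exp(-((yc - fy) ** 2) * inv2h2)
        density += np.outer(gy, gx)
    density /= 2.0 * np.pi * h_m**2 * len(xy)
    return UtilizationDistribution(
        density=density,
        cell_size_m=res,
        origin_xy=(float(x0), float(y0)),
        h_m=h_m,
        n_fixes=len(xy),
        fix_xy=xy.copy(),
    )


def volume_contour(ud: UtilizationDistribution, isopleth_level: float = 0.95) -> HomeRange:
    """Smallest highest-density cell set enclosing ``isopleth_level`` of the mass.

    The threshold is the largest density t such that cells with density >= t
    enclose at least the requested fraction of the UD's (gridded) mass;
    removing the least-dense included cell would drop below it.
    """
    if not 0.0 < isopleth_level < 1.0:
        raise ValueError("isopleth_level must lie in (0, 1)")
    flat = ud.density.ravel()
    order = np.argsort(flat)[::-1]
    cell_area = ud.cell_size_m**2
    cmass = np.cumsum(flat[order]) * cell_area
    total = cmass[-1]
    k = int(np.searchsorted(cmass, isopleth_level * total))
    threshold = flat[order[min(k, len(order) - 1)]]
    mask = ud.density >= threshold
    return HomeRange(
        mask=mask,
        isopleth_level=isopleth_level,
        cell_size_m=ud.cell_size_m,
        origin_xy=ud.origin_xy,
    )
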