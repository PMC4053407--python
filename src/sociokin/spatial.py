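"""Fixed-kernel utilization distributions and volume-of-intersection
home-range overlap.

The utilization distribution (UD) of an individual is estimated with a
fixed bivariate-normal kernel (sd = bandwidth on both axes, default
250 m) evaluated on a shared square lattice (default 200 x 200 cells)
covering the pooled bounding box of all individuals' fixes expanded by
three bandwidths; sharing the lattice makes pairwise overlap well
defined.  The overlap of two UDs is the volume of intersection

    VI = sum_cells min(UD_a, UD_b)

which ranges from 0 (disjoint ranges) to 1 (identical UDs) and weighs
intensity of use, not just shared area.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .config import PipelineConfig
from .matrices import DyadicMatrix

MIN_FIXES = 5


@dataclass
class UDGrid:
    x_centers: np.ndarray
    y_centers: np.ndarray
    density: np.ndarray  # (ny, nx) probability mass per cell, sums to 1

    @property
    def origin(self) -> tuple[float, float]:
        return float(self.x_centers[0]), float(self.y_centers[0])

    @property
    def cell_size(self) -> tuple[float, float]:
        dx = float(self.x_centers[1] - self.x_centers[0]) if len(self.x_centers) > 1 else 0.0
        dy = float(self.y_centers[1] - self.y_centers[0]) if len(self.y_centers) > 1 else 0.0
        return dx, dy

    def same_geometry(self, other: "UDGrid") -> bool:
        return (
            self.density.shape == other.density.shape
            and np.allclose(self.x_centers, other.x_centers)
            and np.allclose(self.y_centers, other.y_centers)
        )


def pooled_extent(points: np.ndarray, bandwidth: float) -> tuple[float, float, float, float]:
    """Bounding box of ``points`` expanded by three bandwidths."""
    pts = np.asarray(points, dtype=float)
    pad = 3.0 * bandwidth
    return (
        float(pts[:, 0].min() - pad),
        float(pts[:, 0].max() + pad),
        float(pts[:, 1].min() - pad),
        float(pts[:, 1].max() + pad),
    )


class KernelUD(BaseEstimator):
    """Fixed bivariate-normal kernel UD estimator (sklearn style).

    Parameters
    ----------
    bandwidth : float
        Kernel standard deviation in metres on both axes.
    grid_cells : int
        Number of lattice cells per axis.
    extent : tuple (xmin, xmax, ymin, ymax) or None
        Evaluation extent.  Pass the pooled extent of all individuals when
        UDs will be compared; None uses the fitted points' own bounding
        box expanded by three bandwidths.

    Attributes
    ----------
    grid_ : UDGrid
        Normalised per-cell probability mass.
    """

    def __init__(self, bandwidth: float = 250.0, grid_cells: int = 200,
                 extent: tuple | None = None):
        self.bandwidth = bandwidth
        self.grid_cells = grid_cells
        self.extent = extent

    def fit(self, X, y=None):
        pts = np.asarray(X, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("X must be an (n, 2) array of metric coordinates")
        if len(pts) < MIN_FIXES:
            raise ValueError(
                f"kernel UD requires at least {MIN_FIXES} fixes, got {len(pts)}"
            )
        if self.bandwidth <= 0 or self.grid_cells < 2:
            raise ValueError("bandwidth must be positive and grid_cells >= 2")
        xmin, xmax, ymin, ymax = (
            self.extent if self.extent is not None
            else pooled_extent(pts, self.bandwidth)
        )
        nx = ny = int(self.grid_cells)
        xc = xmin + (np.arange(nx) + 0.5) * (xmax - xmin) / nx
        yc = ymin + (np.arange(ny) + 0.5) * (ymax - ymin) / ny
        h2 = 2.0 * self.bandwidth ** 2
        # separable Gaussian: density = Gy @ Gx with G*(cell, fix)
        gx = np.exp(-((xc[:, None] - pts[None, :, 0]) ** 2) / h2)
        gy = np.exp(-((yc[:, None] - pts[None, :, 1]) ** 2) / h2)
        dens = gy @ gx.T  # (ny, nx)
        total = dens.sum()
        if total <= 0:
            raise ValueError("all kernel mass fell outside the extent")
        self.grid_ = UDGrid(x_centers=xc, y_centers=yc, density=dens / total)
        self.n_fixes_ = len(pts)
        return self


def kernel_ud(points, bandwidth: float = 250.0, grid_cells: int = 200,
              extent: tuple | None = None) -> UDGrid:
    """Functional wrapper around :class:`KernelUD`."""
    return KernelUD(bandwidth=bandwidth, grid_cells=grid_cells,
                    extent=extent).fit(points).grid_


def vi_overlap(a: UDGrid, b: UDGrid) -> float:
    """Volume of intersection of two UDs on the same lattice."""
    if not a.same_geometry(b):
        raise ValueError("UD grids have different geometry; no resampling is done")
    return float(np.minimum(a.density, b.density).sum())


def overlap_matrix(fixes, config: PipelineConfig | None = None,
                   min_fixes: int = MIN_FIXES) -> DyadicMatrix:
    """Pairwise VI overlap of all individuals' kernel UDs.

    Individuals with fewer than ``min_fixes`` fixes are excluded with a
    warning.  All UDs share the pooled extent of the retained fixes.
    """
    config = config or PipelineConfig()
    counts = fixes.groupby("individual_id").size()
    keep = sorted(str(i) for i in counts.index[counts >= min_fixes])
    dropped = sorted(str(i) for i in counts.index[counts < min_fixes])
    if dropped:
        warnings.warn(
            f"excluding individuals with <{min_fixes} fixes from overlap: {dropped}",
            stacklevel=2,
        )
    if len(keep) < 2:
        raise ValueError("need at least two individuals with enough fixes")
    sub = fixes[fixes["individual_id"].astype(str).isin(keep)]
    pts_all = sub[["x", "y"]].to_numpy(float)
    extent = pooled_extent(pts_all, config.kernel_bandwidth_m)
    uds = {}
    for ind in keep:
        pts = sub.loc[sub["individual_id"].astype(str) == ind, ["x", "y"]].to_numpy(float)
        uds[ind] = kernel_ud(pts, bandwidth=config.kernel_bandwidth_m,
                             grid_cells=config.kernel_grid_cells, extent=extent)
    n = len(keep)
    vi = np.full((n, n), np.nan)
    for i, j in itertools.combinations(range(n), 2):
        vi[i, j] = vi[j, i] = vi_overlap(uds[keep[i]], uds[keep[j]])
    return DyadicMatrix(keep, vi, kind="overlap")
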