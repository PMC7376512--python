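"""Low-resolution density heatmaps over a slide.

A heatmap is a coarse accumulator grid covering the invasive tumor
regions.  For a *count* heatmap, each bin holds the number of input
cells whose centroid lies within the drawing radius of the bin center
(equivalently, each cell adds 1 to every bin whose center falls inside
its disc).  A *ratio* heatmap divides a positive-cell count heatmap by a
total-cell count heatmap on the same grid, and carries an eligibility
mask requiring a minimum total cell count per bin, which suppresses
spurious high-ratio hot spots at the sparse tissue periphery.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Heatmap:
    """Accumulator grid with geometry metadata.

    ``values`` has shape (ny, nx); bin (i, j) covers the half-open square
    [x0 + j*b, x0 + (j+1)*b) x [y0 + i*b, y0 + (i+1)*b) with center at
    (x0 + (j+0.5)*b, y0 + (i+0.5)*b).  ``mask`` marks bins eligible as
    hot-spot seeds.
    """

    values: np.ndarray
    origin: tuple[float, float]
    bin_size: float
    basis: str  # "count_positive" | "count_total" | "ratio"
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask must share a shape")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be > 0")
        if self.basis == "ratio":
            v = self.values
            if v.size and (np.nanmin(v) < -1e-12 or np.nanmax(v) > 1 + 1e-12):
                raise ValueError("ratio values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def bin_centers(self) -> np.ndarray:
        """All bin centers as an (ny*nx, 2) array in row-major order."""
        ny, nx = self.values.shape
        xs = self.origin[0] + (np.arange(nx) + 0.5) * self.bin_size
        ys = self.origin[1] + (np.arange(ny) + 0.5) * self.bin_size
        gx, gy = np.meshgrid(xs, ys)
        return np.column_stack([gx.ravel(), gy.ravel()])

    def bin_indices(self, x, y) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map points to (row, col) bin indices; third array flags in-grid points."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ix = np.floor((x - self.origin[0]) / self.bin_size).astype(int)
        iy = np.floor((y - self.origin[1]) / self.bin_size).astype(int)
        ny, nx = self.values.shape
        ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        return iy, ix, ok

    def with_mask(self, mask: np.ndarray) -> "Heatmap":
        return replace(self, mask=mask)


def _as_xy(cells) -> np.ndarray:
    if isinstance(cells, pd.DataFrame):
        return cells[["x_um", "y_um"]].to_numpy(dtype=float)
    xy = np.asarray(cells, dtype=float)
    if xy.size == 0:
        return xy.reshape(0, 2)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("cells must be a DataFrame or an (n, 2) array")
    return xy


def grid_geometry(bounds, bin_size: float) -> tuple[tuple[float, float], int, int]:
    """Origin and grid shape covering ``bounds`` = (x0, y0, x1, y1)."""
    x0, y0, x1, y1 = map(float, bounds)
    if x1 <= x0 or y1 <= y0:
        raise ValueError("bounds must have positive extent")
    nx = int(np.ceil((x1 - x0) / bin_size))
    ny = int(np.ceil((y1 - y0) / bin_size))
    return (x0, y0), ny, nx


def _rasterize_discs(xy: np.ndarray, radius: float, origin, ny: int, nx: int,
                     bin_size: float) -> np.ndarray:
    """Exact disc accumulation: each cell adds 1 to every bin whose
    center lies within ``radius`` (closed) of the cell.

    Per grid row the member bins form a contiguous run, so each
    (cell, row) pair contributes one +1/-1 pair to a difference array
    that is cumulatively summed along x — O(cells * rows_per_disc).
    """
    x0, y0 = origin
    b = bin_size
    rb = radius / b
    # fractional (row, col) position of each cell on the bin-center grid
    fy = (xy[:, 1] - y0) / b - 0.5
    fx = (xy[:, 0] - x0) / b - 0.5
    diff = np.zeros((ny, nx + 1), dtype=np.int64)
    i_lo = np.ceil(fy - rb).astype(int)
    n_rows = int(np.floor(2 * rb)) + 1
    for t in range(n_rows + 1):
        i = i_lo + t
        dy = (i - fy) * b
        inside = (np.abs(dy) <= radius) & (i >= 0) & (i < ny)
        if not inside.any():
            continue
        halfw = np.sqrt(np.maximum(radius**2 - dy[inside]**2, 0.0)) / b
        fxi = fx[inside]
        j0 = np.ceil(fxi - halfw).astype(int)
        j1 = np.floor(fxi + halfw).astype(int)
        ok = (j0 <= j1) & (j1 >= 0) & (j0 <= nx - 1)
        if not ok.any():
            continue
        rows = i[inside][ok]
        j0 = np.clip(j0[ok], 0, nx - 1)
        j1 = np.clip(j1[ok], 0, nx - 1)
        np.add.at(diff, (rows, j0), 1)
        np.add.at(diff, (rows, j1 + 1), -1)
    return np.cumsum(diff, axis=1)[:, :nx].astype(float)


def build_count_heatmap(cells, radius_um: float, bin_size: float, bounds,
                        basis: str = "count_positive") -> Heatmap:
    """Count, for every bin center, the cells within the drawing radius.

    Disc membership is exact (Euclidean distance from bin center to
    nucleus centroid, closed boundary); an empty cell list yields an
    all-zero heatmap.
    """
    if radius_um <= 0 or bin_size <= 0:
        raise ValueError("radius and bin_size must be > 0")
    origin, ny, nx = grid_geometry(bounds, bin_size)
    xy = _as_xy(cells)
    if len(xy) == 0:
        values = np.zeros((ny, nx), dtype=float)
    else:
        values = _rasterize_discs(xy, radius_um, origin, ny, nx, bin_size)
    return Heatmap(values, origin, bin_size, basis, np.ones((ny, nx), dtype=bool))


def build_ratio_heatmap(pos_heatmap: Heatmap, total_heatmap: Heatmap,
                        min_cells: int) -> Heatmap:
    """Positive-over-total ratio heatmap with a minimum-cell eligibility mask.

    Bins whose total accumulated cell count falls below ``min_cells`` are
    masked ineligible regardless of their ratio, and bins with zero total
    get ratio 0.
    """
    if (pos_heatmap.shape != total_heatmap.shape
            or pos_heatmap.origin != total_heatmap.origin
            or pos_heatmap.bin_size != total_heatmap.bin_size):
        raise ValueError("positive and total heatmaps must share geometry")
    tot = total_heatmap.values
    pos = pos_heatmap.values
    ratio = np.divide(pos, tot, out=np.zeros_like(pos, dtype=float), where=tot > 0)
    mask = tot >= min_cells
    return Heatmap(ratio, pos_heatmap.origin, pos_heatmap.bin_size, "ratio", mask)
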