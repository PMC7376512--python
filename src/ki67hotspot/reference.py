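"""Slow reference implementations for validation.

These recompute the hot-spot operations by exhaustive enumeration —
full distance matrices for heatmap accumulation, argmax over every bin
center for circle placement, a linear descending threshold sweep for
contour extraction — and exist to cross-check the optimised
implementations on small inputs.  They deliberately share no code with
:mod:`ki67hotspot.heatmap` / :mod:`ki67hotspot.detect` beyond the data
types.
"""

from __future__ import annotations

from collections import deque

import numpy as np
import pandas as pd
from scipy import ndimage


def brute_force_count_grid(xy: np.ndarray, radius: float, bin_size: float,
                           bounds) -> np.ndarray:
    """Per-bin disc counts via the full bin-center x cell distance matrix."""
    x0, y0, x1, y1 = bounds
    nx = int(np.ceil((x1 - x0) / bin_size))
    ny = int(np.ceil((y1 - y0) / bin_size))
    out = np.zeros((ny, nx))
    if len(xy) == 0:
        return out
    for i in range(ny):
        cy = y0 + (i + 0.5) * bin_size
        for j in range(nx):
            cx = x0 + (j + 0.5) * bin_size
            d2 = (xy[:, 0] - cx) ** 2 + (xy[:, 1] - cy) ** 2
            out[i, j] = np.count_nonzero(d2 <= radius**2)
    return out


def flood_fill(grid: np.ndarray, seed: tuple[int, int]) -> np.ndarray:
    """8-connected component of True cells containing ``seed`` (pure BFS)."""
    ny, nx = grid.shape
    out = np.zeros_like(grid, dtype=bool)
    if not grid[seed]:
        return out
    q = deque([seed])
    out[seed] = True
    while q:
        i, j = q.popleft()
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                ii, jj = i + di, j + dj
                if 0 <= ii < ny and 0 <= jj < nx and grid[ii, jj] \
                        and not out[ii, jj]:
                    out[ii, jj] = True
                    q.append((ii, jj))
    return out


def _seed_bin(values: np.ndarray, mask: np.ndarray):
    if not mask.any():
        return None
    best = None
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            if mask[i, j] and (best is None or values[i, j] > values[best]):
                best = (i, j)
    return best


def exhaustive_circle(values: np.ndarray, mask: np.ndarray, origin,
                      bin_size: float, radius: float,
                      cells: pd.DataFrame):
    """Circle placement by explicit scan over all eligible bin centers.

    Returns (center, n_cells, n_positive) or None when no bin is
    eligible.  Ties resolve to the smallest (row, col) in row-major
    order, matching the documented rule.
    """
    seed = _seed_bin(values, mask)
    if seed is None:
        return None
    i, j = seed
    cx = origin[0] + (j + 0.5) * bin_size
    cy = origin[1] + (i + 0.5) * bin_size
    d2 = (cells["x_um"].to_numpy() - cx) ** 2 + (cells["y_um"].to_numpy() - cy) ** 2
    inside = d2 <= radius**2
    n = int(inside.sum())
    npos = int((inside & (cells["ki67_status"].to_numpy() == "positive")).sum())
    return (cx, cy), n, npos


def sweep_contour(values: np.ndarray, mask: np.ndarray, origin,
                  bin_size: float, cells: pd.DataFrame, min_cells: int):
    """Contour extraction by a full linear sweep over descending levels.

    Walks every distinct heatmap level from the seed value downward and
    returns the component at the first (highest) level holding at least
    ``min_cells`` cells, or None.  Component extraction per level uses
    8-connected labelling; returns (component bool grid, n, n_positive).
    """
    seed = _seed_bin(values, mask)
    if seed is None:
        return None
    ix = np.floor((cells["x_um"].to_numpy() - origin[0]) / bin_size).astype(int)
    iy = np.floor((cells["y_um"].to_numpy() - origin[1]) / bin_size).astype(int)
    ny, nx = values.shape
    ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
    pos = (cells["ki67_status"].to_numpy() == "positive")[ok]
    iy, ix = iy[ok], ix[ok]
    levels = np.unique(values)[::-1]
    levels = levels[levels <= values[seed]]
    for level in levels:
        labels, _ = ndimage.label(values >= level, structure=np.ones((3, 3)))
        comp = labels == labels[seed]
        inside = comp[iy, ix]
        n = int(inside.sum())
        if n >= min_cells:
            return comp, n, int((inside & pos).sum())
    return None


def point_in_polygon(poly: np.ndarray, x: float, y: float) -> bool:
    """Even-odd ray casting with on-edge points counted inside."""
    n = len(poly)
    inside = False
    for k in range(n):
        x1, y1 = poly[k]
        x2, y2 = poly[(k + 1) % n]
        # on-segment check (closed boundary)
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        if abs(cross) < 1e-9 and min(x1, x2) - 1e-9 <= x <= max(x1, x2) + 1e-9 \
                and min(y1, y2) - 1e-9 <= y <= max(y1, y2) + 1e-9:
            return True
        if (y1 > y) != (y2 > y):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xint:
                inside = not inside
    return inside
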