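"""Rasterization of localization tables and binary-map morphology.

Localization maps are rendered on a 10-nm grid by default. Binning is
half-open — a point exactly on a pixel boundary lands in the higher-index
pixel — and row index follows y, column index follows x.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .io_tables import LocalizationTable, Rect

__all__ = [
    "PixelMap",
    "disc_structuring_element",
    "render_histogram",
    "render_ash",
    "binarize",
    "density_filter",
    "dilate_binary",
]


@dataclass
class PixelMap:
    """A raster (counts or {0,1}) rendered from localizations.

    ``grid[i, j]`` covers x in [origin_x + j·p, origin_x + (j+1)·p) and
    y in [origin_y + i·p, origin_y + (i+1)·p).
    """

    grid: np.ndarray
    pixel_size: float
    roi: Rect
    origin: tuple[float, float] = None  # defaults to roi lower-left

    def __post_init__(self) -> None:
        if self.origin is None:
            self.origin = (self.roi.x0, self.roi.y0)
        self.grid = np.asarray(self.grid)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def is_binary(self) -> bool:
        return bool(np.isin(self.grid, (0, 1)).all())

    def pixel_indices(self, x, y, clip: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """Row/column indices of points (half-open binning)."""
        rows = np.floor((np.asarray(y, dtype=float) - self.origin[1]) / self.pixel_size).astype(int)
        cols = np.floor((np.asarray(x, dtype=float) - self.origin[0]) / self.pixel_size).astype(int)
        if clip:
            rows = np.clip(rows, 0, self.grid.shape[0] - 1)
            cols = np.clip(cols, 0, self.grid.shape[1] - 1)
        return rows, cols

    def contains_points(self, xy) -> np.ndarray:
        """True where a point falls in a nonzero pixel (outside grid → False)."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        rows, cols = self.pixel_indices(xy[:, 0], xy[:, 1])
        ok = (rows >= 0) & (rows < self.grid.shape[0]) & (cols >= 0) & (cols < self.grid.shape[1])
        out = np.zeros(len(xy), dtype=bool)
        out[ok] = self.grid[rows[ok], cols[ok]] > 0
        return out

    def copy_with(self, grid: np.ndarray) -> "PixelMap":
        return PixelMap(grid=grid, pixel_size=self.pixel_size, roi=self.roi, origin=self.origin)


def _grid_shape(roi: Rect, pixel_size: float) -> tuple[int, int]:
    ny = int(np.ceil(roi.height / pixel_size - 1e-9))
    nx = int(np.ceil(roi.width / pixel_size - 1e-9))
    return max(ny, 1), max(nx, 1)


def disc_structuring_element(radius_pixels: int) -> np.ndarray:
    """Euclidean disc on the lattice: offsets with dx² + dy² ≤ r²."""
    r = int(radius_pixels)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (xx**2 + yy**2) <= r**2


def render_histogram(table: LocalizationTable, pixel_size: float = 10.0) -> PixelMap:
    """Plain 2D histogram of localizations (ASH with shifts = 1)."""
    return render_ash(table, pixel_size=pixel_size, shifts=1)


def render_ash(table: LocalizationTable, pixel_size: float = 10.0, shifts: int = 2) -> PixelMap:
    """Averaged-shifted-histogram rendering.

    The raster is the average of ``shifts²`` 2D histograms whose bin origins
    are offset on a sub-pixel lattice of spacing ``pixel_size/shifts``.
    Shifted bins are clipped at the ROI boundary (no wraparound), so the
    total mass always equals the number of localizations.
    """
    if shifts < 1:
        raise ValueError("shifts must be ≥ 1")
    ny, nx = _grid_shape(table.roi, pixel_size)
    grid = np.zeros((ny, nx), dtype=float)
    if len(table) == 0:
        warnings.warn("rendering an empty localization table → all-zero map")
        return PixelMap(grid, pixel_size, table.roi)
    x = table.data["x"].to_numpy() - table.roi.x0
    y = table.data["y"].to_numpy() - table.roi.y0
    m = int(shifts)
    for i in range(m):
        for j in range(m):
            cols = np.floor(x / pixel_size + i / m).astype(int)
            rows = np.floor(y / pixel_size + j / m).astype(int)
            np.clip(cols, 0, nx - 1, out=cols)
            np.clip(rows, 0, ny - 1, out=rows)
            np.add.at(grid, (rows, cols), 1.0)
    grid /= m * m
    return PixelMap(grid, pixel_size, table.roi)


def binarize(pixel_map: PixelMap, threshold: float = 0.0) -> PixelMap:
    """Binary map: pixel = 1 iff count > threshold."""
    return pixel_map.copy_with((pixel_map.grid > threshold).astype(np.uint8))


def density_filter(
    table: LocalizationTable,
    radius: float = 100.0,
    min_neighbors: int = 5,
) -> LocalizationTable:
    """Keep localizations with ≥ ``min_neighbors`` others within ``radius`` nm.

    Neighbor counting is a single pass on the unfiltered table (the filter is
    not iterated) and distances are inclusive of the radius.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if len(table) == 0:
        return table
    xy = table.xy
    tree = cKDTree(xy)
    counts = np.zeros(len(xy), dtype=int)
    pairs = tree.query_pairs(r=radius, output_type="ndarray")
    if len(pairs):
        np.add.at(counts, pairs[:, 0], 1)
        np.add.at(counts, pairs[:, 1], 1)
    return table.subset(counts >= min_neighbors)


def dilate_binary(pixel_map: PixelMap, radius_pixels: int) -> PixelMap:
    """Morphological dilation with a Euclidean disc structuring element."""
    if radius_pixels < 0:
        raise ValueError("radius_pixels must be ≥ 0")
    if radius_pixels == 0:
        return pixel_map.copy_with((pixel_map.grid > 0).astype(np.uint8))
    selem = disc_structuring_element(radius_pixels)
    out = ndimage.binary_dilation(pixel_map.grid > 0, structure=selem)
    return pixel_map.copy_with(out.astype(np.uint8))
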