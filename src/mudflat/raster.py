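"""A minimal metric raster: a 2-D array with a cell size and lower-left origin.

Rows index northing (row 0 is the southernmost row), columns index easting.
Cells are half-open squares ``[x, x + cell) x [y, y + cell)``: a point lying
exactly on a cell edge belongs to the cell at its lower-left. All modules that
exchange masks, basin maps or interpolated surfaces use this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SpatialError


@dataclass
class Raster:
    data: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D (rows=northing, cols=easting)")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(x0, y0, x1, y1) — outer bounds of the covered area."""
        ny, nx = self.data.shape
        x0, y0 = self.origin
        return x0, y0, x0 + nx * self.cell_size, y0 + ny * self.cell_size

    def contains(self, x: float, y: float) -> bool:
        x0, y0, x1, y1 = self.extent
        return (x0 <= x < x1) and (y0 <= y < y1)

    def cell_index(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/column of the cell owning (x, y); vectorized; half-open cells."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x0, y0, x1, y1 = self.extent
        if np.any(x < x0) or np.any(x >= x1) or np.any(y < y0) or np.any(y >= y1):
            raise SpatialError("point outside raster extent")
        col = np.floor((x - x0) / self.cell_size).astype(int)
        row = np.floor((y - y0) / self.cell_size).astype(int)
        return row, col

    def value_at(self, x, y):
        row, col = self.cell_index(x, y)
        return self.data[row, col]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid arrays (X, Y) of cell-center coordinates, shape == data."""
        ny, nx = self.data.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(nx) + 0.5) * self.cell_size
        ys = y0 + (np.arange(ny) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def copy_with(self, data: np.ndarray) -> "Raster":
        return Raster(data, self.cell_size, self.origin)


def full_mask(width_m: float, height_m: float, cell_size: float) -> Raster:
    """Convenience: an all-true boolean raster covering a rectangle at (0, 0)."""
    nx = int(round(width_m / cell_size))
    ny = int(round(height_m / cell_size))
    return Raster(np.ones((ny, nx), dtype=bool), cell_size)
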