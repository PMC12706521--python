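"""Regular planar grids for gridded community assembly.

Coordinates are planar and in kilometres (equal-area convention): the grid
origin is the lower-left corner, cell ids are dense row-major indices with
row 0 at the bottom, and each cell covers the half-open rectangle
``[left, right) x [bottom, top)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError


@dataclass(frozen=True)
class GridSpec:
    """A regular grid of square cells on a planar (km) coordinate system.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions; both must be positive.
    cell_size
        Side length of each square cell, in km.
    x0, y0
        Coordinates of the lower-left corner of the grid, in km.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    x0: float = 0.0
    y0: float = 0.0

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise InvalidParameterError("grid must have at least one row and column")
        if not self.cell_size > 0:
            raise InvalidParameterError("cell size must be positive")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_id(self, row: int, col: int) -> int:
        """Row-major cell id; row 0 is the bottom row."""
        return row * self.n_cols + col

    def rowcol(self, cell_id: np.ndarray | int):
        return np.divmod(np.asarray(cell_id), self.n_cols)

    def cell_centers(self) -> np.ndarray:
        """(n_cells, 2) array of cell-center (x, y) coordinates in km."""
        rows, cols = self.rowcol(np.arange(self.n_cells))
        x = self.x0 + (cols + 0.5) * self.cell_size
        y = self.y0 + (rows + 0.5) * self.cell_size
        return np.column_stack([x, y])

    def cell_bounds(self, cell_id: int) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of one cell."""
        row, col = self.rowcol(cell_id)
        xmin = self.x0 + col * self.cell_size
        ymin = self.y0 + row * self.cell_size
        return (xmin, ymin, xmin + self.cell_size, ymin + self.cell_size)

    def locate(self, x: np.ndarray, y: np.ndarray):
        """Bin point coordinates into cells with half-open intervals.

        Returns ``(cell_ids, inside)`` where ``cell_ids`` holds -1 for
        points outside the grid and ``inside`` is the boolean mask of
        in-grid points.  A point on the left/bottom edge of a cell belongs
        to that cell; points on the grid's outer right/top edge fall out.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.cell_size).astype(int)
        row = np.floor((y - self.y0) / self.cell_size).astype(int)
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        ids = np.where(inside, row * self.n_cols + col, -1)
        return ids, inside
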