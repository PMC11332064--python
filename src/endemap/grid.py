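"""Regular lon/lat analysis grid.

Cells are squares of ``cell_size`` degrees, indexed row-major with cell id
``row * n_cols + col``.  Row 0 is the southernmost row and column 0 the
westernmost column, so cell 0 sits at the grid origin (its lower-left
corner is ``(origin_lon, origin_lat)``).  Cell extents are half-open
intervals ``[lo, hi)``: a point lying exactly on a shared edge belongs to
the cell with the larger index coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Grid"]


@dataclass(frozen=True)
class Grid:
    origin_lon: float
    origin_lat: float
    cell_size: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_to_rowcol(self, cell_id: int) -> tuple[int, int]:
        if not 0 <= cell_id < self.n_cells:
            raise IndexError(f"cell id {cell_id} outside grid")
        return divmod(cell_id, self.n_cols)

    def rowcol_to_cell(self, row: int, col: int) -> int:
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"(row={row}, col={col}) outside grid")
        return row * self.n_cols + col

    def cell_bounds(self, cell_id: int) -> tuple[float, float, float, float]:
        """(min_lon, min_lat, max_lon, max_lat) of a cell."""
        row, col = self.cell_to_rowcol(cell_id)
        lon0 = self.origin_lon + col * self.cell_size
        lat0 = self.origin_lat + row * self.cell_size
        return lon0, lat0, lon0 + self.cell_size, lat0 + self.cell_size

    def cell_center(self, cell_id: int) -> tuple[float, float]:
        lon0, lat0, lon1, lat1 = self.cell_bounds(cell_id)
        return (lon0 + lon1) / 2.0, (lat0 + lat1) / 2.0

    def cell_centers(self) -> np.ndarray:
        """(n_cells, 2) array of (lon, lat) centers, cell-id order."""
        rows, cols = np.divmod(np.arange(self.n_cells), self.n_cols)
        lon = self.origin_lon + (cols + 0.5) * self.cell_size
        lat = self.origin_lat + (rows + 0.5) * self.cell_size
        return np.column_stack([lon, lat])

    def point_to_cell(self, lon: float, lat: float) -> int | None:
        """Cell containing a point, or None if outside the grid extent."""
        col = int(np.floor((lon - self.origin_lon) / self.cell_size))
        row = int(np.floor((lat - self.origin_lat) / self.cell_size))
        if 0 <= row < self.n_rows and 0 <= col < self.n_cols:
            return row * self.n_cols + col
        return None

    def neighbors(self, cell_id: int) -> list[int]:
        """Rook (4-)adjacent cell ids."""
        row, col = self.cell_to_rowcol(cell_id)
        out = []
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            r, c = row + dr, col + dc
            if 0 <= r < self.n_rows and 0 <= c < self.n_cols:
                out.append(r * self.n_cols + c)
        return out

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return (
            self.origin_lon,
            self.origin_lat,
            self.origin_lon + self.n_cols * self.cell_size,
            self.origin_lat + self.n_rows * self.cell_size,
        )
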