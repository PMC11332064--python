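"""Cells x species presence/absence matrix, the central container.

Row sums are per-cell species richness (SR); column sums are species range
sizes in cells.  All diversity metrics, the null model and the prioritizer
consume this object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import Grid

__all__ = ["PresenceMatrix"]


@dataclass
class PresenceMatrix:
    grid: Grid
    species: list[str]
    values: np.ndarray = field(repr=False)  # (n_cells, n_species) uint8

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (self.grid.n_cells, len(self.species)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{self.grid.n_cells} cells x {len(self.species)} species"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("presence matrix entries must be 0/1")
        self.values = self.values.astype(np.uint8)
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species ids")

    @property
    def n_cells(self) -> int:
        return self.grid.n_cells

    @property
    def n_species(self) -> int:
        return len(self.species)

    def richness(self) -> np.ndarray:
        """Per-cell species richness (row sums)."""
        return self.values.sum(axis=1).astype(np.int64)

    def range_sizes(self) -> np.ndarray:
        """Per-species range size in cells (column sums)."""
        return self.values.sum(axis=0).astype(np.int64)

    def species_cells(self, species: str) -> np.ndarray:
        """Sorted cell ids occupied by one species."""
        j = self.species.index(species)
        return np.flatnonzero(self.values[:, j])

    def drop_empty_species(self) -> "PresenceMatrix":
        keep = self.values.sum(axis=0) > 0
        return PresenceMatrix(
            self.grid,
            [s for s, k in zip(self.species, keep) if k],
            self.values[:, keep],
        )

    @classmethod
    def from_cell_sets(
        cls, grid: Grid, ranges: dict[str, "np.ndarray | list[int] | set[int]"]
    ) -> "PresenceMatrix":
        """Build from a mapping species -> iterable of occupied cell ids."""
        species = list(ranges)
        values = np.zeros((grid.n_cells, len(species)), dtype=np.uint8)
        for j, sp in enumerate(species):
            cells = np.asarray(sorted(ranges[sp]), dtype=int)
            if cells.size and (cells.min() < 0 or cells.max() >= grid.n_cells):
                raise ValueError(f"range of {sp} falls outside the grid")
            values[cells, j] = 1
        return cls(grid, species, values)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.species)
        df.insert(0, "cell_id", np.arange(self.n_cells))
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, grid: Grid) -> "PresenceMatrix":
        df = pd.read_csv(path)
        if "cell_id" in df.columns:
            df = df.sort_values("cell_id").drop(columns="cell_id")
        return cls(grid, list(df.columns), df.to_numpy())
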