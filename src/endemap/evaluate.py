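"""Solution evaluation: overlaps, center coverage, protected-area gaps.

Compares prioritization solutions with each other, with the map of
centers of endemism, and with an existing protected-area (PA) network; a
cell counts as protected when at least a threshold fraction (default
25%) of its area is covered by PA polygons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .grid import Grid
from .presence import PresenceMatrix
from .prioritize import PriorityRanking, top_fraction

__all__ = [
    "ProtectedMask",
    "protected_mask",
    "coverage_from_polygons",
    "solution_overlap",
    "center_coverage",
    "protection_classes",
    "species_protection",
    "PROTECTION_CLASSES",
]

PROTECTION_CLASSES = (
    "PA_not_selected",
    "selected_PA_17_30",
    "selected_PA_top17",
    "selected_unPA_17_30",
    "selected_unPA_top17",
    "neither",
)


@dataclass
class ProtectedMask:
    """Per-cell protected flag plus the coverage layer it came from."""

    flags: np.ndarray  # (n_cells,) bool
    coverage: np.ndarray | None = field(default=None, repr=False)
    threshold: float = 0.25

    @property
    def cells(self) -> np.ndarray:
        return np.flatnonzero(self.flags)


def protected_mask(coverage: np.ndarray, threshold: float = 0.25) -> ProtectedMask:
    """Flag cells with PA coverage >= threshold (boundary counts)."""
    coverage = np.asarray(coverage, dtype=float)
    if ((coverage < 0) | (coverage > 1)).any():
        raise ValueError("coverage fractions must lie in [0, 1]")
    return ProtectedMask(coverage >= threshold, coverage, threshold)


def coverage_from_polygons(polygons, grid: Grid) -> np.ndarray:
    """Per-cell fraction of area intersected by PA polygons."""
    geom = shapely.union_all(list(polygons))
    cov = np.zeros(grid.n_cells)
    cell_area = grid.cell_size ** 2
    for cid in range(grid.n_cells):
        box = shapely.box(*grid.cell_bounds(cid))
        cov[cid] = box.intersection(geom).area / cell_area
    return np.clip(cov, 0.0, 1.0)


def solution_overlap(set_a, set_b, n_cells: int | None = None) -> tuple[int, float]:
    """Shared cell count and percent of the first set that is shared."""
    a = set(np.asarray(list(set_a), dtype=int).tolist())
    b = set(np.asarray(list(set_b), dtype=int).tolist())
    if n_cells is not None:
        for s in (a, b):
            bad = [c for c in s if not 0 <= c < n_cells]
            if bad:
                raise ValueError(f"cell ids outside grid: {bad[:5]}")
    shared = len(a & b)
    pct = 100.0 * shared / len(a) if a else 0.0
    return shared, pct


def center_coverage(
    ranking: PriorityRanking,
    classes: np.ndarray,
    fractions,
    class_names=("neo", "paleo", "mixed", "super"),
) -> pd.DataFrame:
    """Proportion of each center class inside the top-f cells, per fraction.

    Classes with no cells get NaN (flagged absent).  Non-decreasing in f
    for every class, since top fractions are nested.
    """
    classes = np.asarray(classes, dtype=object)
    if classes.size != ranking.n_cells:
        raise ValueError("classification and ranking cover different grids")
    rows = []
    for f in fractions:
        top = set(top_fraction(ranking, f).tolist())
        for cls in class_names:
            cls_cells = np.flatnonzero(classes == cls)
            if cls_cells.size == 0:
                prop = np.nan
            else:
                prop = sum(c in top for c in cls_cells) / cls_cells.size
            rows.append({"fraction": f, "class": cls,
                         "n_cells": cls_cells.size, "proportion_covered": prop})
    return pd.DataFrame(rows)


def protection_classes(
    ranking: PriorityRanking,
    mask: ProtectedMask,
    lower: float = 0.17,
    upper: float = 0.30,
) -> np.ndarray:
    """Five-way protection/selection class per cell (plus 'neither').

    Cross of selection status {top 17%, 17-30%, not selected} with the
    protected flag; unselected and unprotected cells fall in 'neither'.
    """
    if mask.flags.size != ranking.n_cells:
        raise ValueError("mask and ranking cover different grids")
    top_lo = np.zeros(ranking.n_cells, dtype=bool)
    top_lo[top_fraction(ranking, lower)] = True
    top_hi = np.zeros(ranking.n_cells, dtype=bool)
    top_hi[top_fraction(ranking, upper)] = True
    mid = top_hi & ~top_lo
    out = np.full(ranking.n_cells, "neither", dtype=object)
    prot = mask.flags
    out[prot & ~top_hi] = "PA_not_selected"
    out[prot & mid] = "selected_PA_17_30"
    out[prot & top_lo] = "selected_PA_top17"
    out[~prot & mid] = "selected_unPA_17_30"
    out[~prot & top_lo] = "selected_unPA_top17"
    return out


def species_protection(presence: PresenceMatrix, cellset) -> pd.DataFrame:
    """Percent of each species' range inside a cell set, plus a summary.

    Returns a tidy per-species table with a ``.attrs`` summary holding the
    mean percent and the counts of species with strictly less than 50%
    and strictly less than 10% of their range covered.
    """
    sel = np.zeros(presence.n_cells, dtype=bool)
    cells = np.asarray(list(cellset), dtype=int)
    if cells.size:
        sel[cells] = True
    ranges = presence.range_sizes()
    if (ranges == 0).any():
        raise ValueError("presence matrix has empty species columns")
    covered = (presence.values.astype(bool) & sel[:, None]).sum(axis=0)
    pct = 100.0 * covered / ranges
    df = pd.DataFrame(
        {"species": presence.species, "range_cells": ranges,
         "protected_cells": covered, "percent_protected": pct}
    )
    df.attrs["mean_percent"] = float(pct.mean())
    df.attrs["n_below_50"] = int((pct < 50.0).sum())
    df.attrs["n_below_10"] = int((pct < 10.0).sum())
    return df
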