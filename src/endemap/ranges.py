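"""Species ranges from point records: clusters, MCPs, buffers, filters.

The range of a species is estimated as the minimum convex polygon (MCP)
of its occurrence records, buffered outward by one grid-cell width, then
rasterized to the analysis grid and filtered by elevation and land-use
suitability.  Species with spatially disjunct record groups are first
split into single-linkage clusters (default cutoff 50 km) and one MCP is
built per cluster; species flagged as continuously distributed keep a
single MCP.  Two-record clusters (and degenerate collinear point sets)
get the randomized-disc treatment: 100 random points are drawn inside a
one-cell-width disc around each record and the hull of those points is
used, so that positional uncertainty at the grid scale is reflected in
the polygon.

Distances are computed on an equirectangular local projection (km); at
the few-km scales involved the error against geodesics is negligible and
all geometry stays planar.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from shapely.geometry import MultiPoint, Point

from .grid import Grid
from .presence import PresenceMatrix

__all__ = [
    "CoarseRange",
    "cluster_records",
    "build_mcp",
    "buffer_range",
    "rasterize_range",
    "apply_filters",
    "build_coarse_range",
    "ranges_to_presence",
]

KM_PER_DEG = 111.195  # mean meridian degree


def _project_km(lons, lats, ref_lat: float) -> np.ndarray:
    """Equirectangular local projection to km."""
    x = np.asarray(lons) * KM_PER_DEG * np.cos(np.radians(ref_lat))
    y = np.asarray(lats) * KM_PER_DEG
    return np.column_stack([x, y])


@dataclass
class CoarseRange:
    """A species' buffered MCPs plus the cells of its raw records."""

    species: str
    polygons: list = field(default_factory=list)  # shapely polygons
    record_cells: set[int] = field(default_factory=set)

    @property
    def geometry(self):
        return shapely.union_all(self.polygons) if self.polygons else None


def cluster_records(points: np.ndarray, linkage_cutoff_km: float = 50.0) -> np.ndarray:
    """Single-linkage spatial clusters of (lon, lat) records.

    Returns 0-based cluster labels; any two points in different clusters
    are more than the cutoff apart (single-linkage guarantee).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 0:
        raise ValueError("need at least one record")
    if points.shape[0] == 1:
        return np.zeros(1, dtype=int)
    xy = _project_km(points[:, 0], points[:, 1], ref_lat=points[:, 1].mean())
    z = linkage(pdist(xy), method="single")
    labels = fcluster(z, t=linkage_cutoff_km, criterion="distance")
    return labels - 1


def _is_degenerate(points: np.ndarray) -> bool:
    """Fewer than 3 points, or all collinear (zero-area hull)."""
    if points.shape[0] < 3:
        return True
    hull = MultiPoint([tuple(p) for p in points]).convex_hull
    return hull.geom_type != "Polygon" or hull.area == 0.0


def build_mcp(points: np.ndarray, grid: Grid, seed: int = 0,
              n_random: int = 100):
    """Minimum convex polygon of a record set.

    For three or more non-collinear points this is their convex hull.
    For two points (or any collinear set) the hull is degenerate, so
    ``n_random`` points are drawn uniformly inside a disc of one cell
    width around each record and the hull of the draws is returned.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] < 2:
        raise ValueError("build_mcp needs at least 2 points")
    if not _is_degenerate(points):
        return MultiPoint([tuple(p) for p in points]).convex_hull
    rng = np.random.default_rng(seed)
    draws = []
    radius = grid.cell_size
    for p in points:
        # uniform in a disc: sqrt-radius trick
        r = radius * np.sqrt(rng.random(n_random))
        theta = 2 * np.pi * rng.random(n_random)
        draws.append(np.column_stack([p[0] + r * np.cos(theta),
                                      p[1] + r * np.sin(theta)]))
    cloud = np.vstack(draws)
    return MultiPoint([tuple(p) for p in cloud]).convex_hull


def buffer_range(geom, width: float):
    """Euclidean outward buffer (width in degrees, one cell size)."""
    if isinstance(geom, (tuple, list)) and len(geom) == 2:
        geom = Point(*geom)
    return geom.buffer(width, quad_segs=16)


def rasterize_range(coarse: CoarseRange, grid: Grid,
                    mode: str = "center") -> set[int]:
    """Cells of a coarse range: center-in-polygon plus all record cells.

    ``mode="intersects"`` includes any cell whose box intersects a
    polygon instead of the center rule.
    """
    geom = coarse.geometry
    cells: set[int] = set(coarse.record_cells)
    if geom is not None and not geom.is_empty:
        if mode == "center":
            centers = grid.cell_centers()
            inside = shapely.contains_xy(geom, centers[:, 0], centers[:, 1])
            cells.update(np.flatnonzero(inside).tolist())
        elif mode == "intersects":
            for cid in range(grid.n_cells):
                if shapely.box(*grid.cell_bounds(cid)).intersects(geom):
                    cells.add(cid)
        else:
            raise ValueError("mode must be 'center' or 'intersects'")
    if not cells:
        raise ValueError(
            f"range of {coarse.species} covers no cell and has no records "
            "on the grid"
        )
    return cells


def apply_filters(
    cells: set[int],
    record_cells: set[int],
    record_elevations=None,
    elevation: np.ndarray | None = None,
    exclusion_mask: np.ndarray | None = None,
) -> set[int]:
    """Suitability filters: elevation envelope and exclusion mask.

    Removes cells whose elevation lies outside the [min, max] of the
    species' record elevations, and cells flagged in the exclusion mask
    (croplands/urban).  Cells holding a record are never removed.
    """
    out = set(cells)
    if elevation is not None and record_elevations is not None:
        record_elevations = np.asarray(list(record_elevations), dtype=float)
        if record_elevations.size:
            lo, hi = record_elevations.min(), record_elevations.max()
            elevation = np.asarray(elevation, dtype=float)
            out = {c for c in out if lo <= elevation[c] <= hi}
    if exclusion_mask is not None:
        excl = np.asarray(exclusion_mask).astype(bool)
        out = {c for c in out if not excl[c]}
    return out | set(record_cells)


def build_coarse_range(
    points: np.ndarray,
    grid: Grid,
    species: str = "",
    continuous: bool = False,
    linkage_cutoff_km: float = 50.0,
    seed: int = 0,
) -> CoarseRange:
    """Coarse range of one species: per-cluster MCPs plus one-cell buffers.

    Single-record species (and single-point clusters) are represented by
    the buffered point alone.  Continuously distributed species skip
    clustering and get one MCP over all records.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 0:
        raise ValueError("need at least one record")
    record_cells = {
        cid for cid in (grid.point_to_cell(lon, lat) for lon, lat in points)
        if cid is not None
    }
    if continuous and points.shape[0] >= 3:
        groups = [points]
    else:
        labels = cluster_records(points, linkage_cutoff_km)
        groups = [points[labels == k] for k in np.unique(labels)]
    polygons = []
    width = grid.cell_size
    for gi, grp in enumerate(groups):
        if grp.shape[0] == 1:
            polygons.append(buffer_range(Point(*grp[0]), width))
        else:
            mcp = build_mcp(grp, grid, seed=seed + gi)
            polygons.append(buffer_range(mcp, width))
    return CoarseRange(species, polygons, record_cells)


def ranges_to_presence(
    occurrences: pd.DataFrame,
    grid: Grid,
    continuous_flags: dict[str, bool] | None = None,
    elevation: np.ndarray | None = None,
    exclusion_mask: np.ndarray | None = None,
    linkage_cutoff_km: float = 50.0,
    seed: int = 0,
) -> tuple[PresenceMatrix, dict[str, CoarseRange]]:
    """Full range pipeline: occurrence table -> presence matrix.

    ``occurrences`` needs columns species/longitude/latitude and may carry
    an elevation column (used for the per-species elevation envelope;
    otherwise record elevations are read off the elevation raster).
    Species whose filtered range is empty cannot occur (record cells are
    always kept), so every column of the result is non-empty.
    """
    required = {"species", "longitude", "latitude"}
    if not required.issubset(occurrences.columns):
        raise ValueError(f"occurrence table needs columns {sorted(required)}")
    continuous_flags = continuous_flags or {}
    cell_ranges: dict[str, set[int]] = {}
    coarse: dict[str, CoarseRange] = {}
    for i, (sp, sub) in enumerate(occurrences.groupby("species", sort=True)):
        pts = sub[["longitude", "latitude"]].to_numpy(dtype=float)
        cr = build_coarse_range(
            pts, grid, species=str(sp),
            continuous=bool(continuous_flags.get(sp, False)),
            linkage_cutoff_km=linkage_cutoff_km, seed=seed + 1000 * i,
        )
        cells = rasterize_range(cr, grid)
        if "elevation" in sub.columns:
            rec_elev = sub["elevation"].to_numpy(dtype=float)
        elif elevation is not None:
            rec_elev = [elevation[c] for c in sorted(cr.record_cells)]
        else:
            rec_elev = None
        cells = apply_filters(cells, cr.record_cells, rec_elev,
                              elevation, exclusion_mask)
        cell_ranges[str(sp)] = cells
        coarse[str(sp)] = cr
    matrix = PresenceMatrix.from_cell_sets(grid, cell_ranges)
    return matrix.drop_empty_species(), coarse
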