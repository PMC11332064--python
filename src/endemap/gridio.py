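"""File I/O glue: ESRI ASCII grids, Newick trees, GeoJSON polygons.

ESRI ASCII rasters store the top (northern) row first; internally per-cell
vectors are in cell-id order (row 0 = south), so rows are flipped on the
way in and out.
"""

from __future__ import annotations

import json

import dendropy
import numpy as np
import shapely
import shapely.geometry

from .grid import Grid

__all__ = [
    "write_ascii_grid",
    "read_ascii_grid",
    "read_newick",
    "write_newick",
    "write_polygons_geojson",
    "read_polygons_geojson",
]

NODATA = -9999


def write_ascii_grid(path, values: np.ndarray, grid: Grid, fmt: str = "%.6g") -> None:
    """Write per-cell values (cell-id order or (n_rows, n_cols)) as ESRI ASCII."""
    arr = np.asarray(values, dtype=float).reshape(grid.n_rows, grid.n_cols)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.origin_lon!r}\n")
        fh.write(f"yllcorner {grid.origin_lat!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {NODATA}\n")
        for row in arr[::-1]:  # north first
            fh.write(" ".join(fmt % v for v in row) + "\n")


def read_ascii_grid(path) -> tuple[np.ndarray, Grid]:
    """Read an ESRI ASCII raster -> (per-cell values in cell-id order, Grid)."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                       "nodata_value", "xllcenter", "yllcenter"}:
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    cell = header["cellsize"]
    x0 = header.get("xllcorner", header.get("xllcenter", 0) - cell / 2)
    y0 = header.get("yllcorner", header.get("yllcenter", 0) - cell / 2)
    arr = np.asarray(rows, dtype=float)
    if arr.shape != (n_rows, n_cols):
        raise ValueError(f"raster body {arr.shape} does not match header")
    nodata = header.get("nodata_value")
    if nodata is not None:
        arr[arr == nodata] = np.nan
    grid = Grid(x0, y0, cell, n_rows, n_cols)
    return arr[::-1].reshape(-1), grid


def read_newick(source: str, from_path: bool = True) -> dendropy.Tree:
    """Parse a rooted Newick tree, preserving underscores in tip labels."""
    kwargs = dict(schema="newick", preserve_underscores=True)
    if from_path:
        return dendropy.Tree.get(path=source, **kwargs)
    return dendropy.Tree.get(data=source, **kwargs)


def write_newick(tree: dendropy.Tree, path=None) -> str:
    s = tree.as_string(schema="newick", unquoted_underscores=True,
                       suppress_rooting=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s


def write_polygons_geojson(path, polygons: dict) -> None:
    """Write {species: shapely geometry} as a GeoJSON FeatureCollection."""
    features = [
        {
            "type": "Feature",
            "properties": {"species": sp},
            "geometry": shapely.geometry.mapping(geom),
        }
        for sp, geom in polygons.items()
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_polygons_geojson(path) -> dict:
    with open(path) as fh:
        fc = json.load(fh)
    out = {}
    for feat in fc["features"]:
        sp = feat["properties"].get("species", str(len(out)))
        out[sp] = shapely.geometry.shape(feat["geometry"])
    return out
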