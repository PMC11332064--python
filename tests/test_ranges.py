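"""Range estimation: clustering, MCPs, buffering, rasterization, filters."""

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from endemap import Grid
from endemap.ranges import (
    KM_PER_DEG,
    CoarseRange,
    apply_filters,
    buffer_range,
    build_coarse_range,
    build_mcp,
    cluster_records,
    ranges_to_presence,
    rasterize_range,
)


def km_to_deg(km: float) -> float:
    return km / KM_PER_DEG


class TestClusterRecords:
    def test_single_point_single_cluster(self):
        assert cluster_records(np.array([[10.0, 0.0]])).tolist() == [0]

    def test_close_points_merge(self):
        pts = np.array([[0.0, 0.0], [km_to_deg(1.0), 0.0]])
        labels = cluster_records(pts, linkage_cutoff_km=50)
        assert len(set(labels)) == 1

    def test_single_linkage_resolution(self):
        # pairwise distances ~{10, 10, 200} km: the two near points merge
        pts = np.array([
            [0.0, 0.0],
            [0.0, km_to_deg(10.0)],
            [0.0, km_to_deg(200.0)],
        ])
        labels = cluster_records(pts, linkage_cutoff_km=50)
        assert labels[0] == labels[1] != labels[2]

    def test_intercluster_distance_exceeds_cutoff(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.uniform(0, 3, 40), rng.uniform(0, 3, 40)])
        labels = cluster_records(pts, linkage_cutoff_km=30)
        proj = pts * KM_PER_DEG  # near the equator, ref_lat ~ 1.5 deg
        for a in range(40):
            for b in range(a):
                if labels[a] != labels[b]:
                    d = np.hypot(*(proj[a] - proj[b]))
                    assert d > 29.0  # cutoff minus projection slack


class TestBuildMcp:
    grid = Grid(0, 0, km_to_deg(4.6), 10, 10)

    def test_hull_identity_on_square(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        hull = build_mcp(square, self.grid, seed=0)
        assert hull.equals(Polygon([(0, 0), (1, 0), (1, 1), (0, 1)]))

    def test_interior_point_ignored(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0.5, 0.5]], float)
        hull = build_mcp(pts, self.grid, seed=0)
        assert hull.equals(Polygon([(0, 0), (1, 0), (1, 1), (0, 1)]))

    def test_two_point_randomized_stadium(self):
        d = km_to_deg(10.0)
        r = self.grid.cell_size  # one-cell-width disc radius
        hull = build_mcp(np.array([[0.0, 0.0], [d, 0.0]]), self.grid,
                         seed=1, n_random=2000)
        stadium = np.pi * r**2 + 2 * r * d
        assert hull.area == pytest.approx(stadium, rel=0.05)
        assert hull.contains(Point(0, 0)) and hull.contains(Point(d, 0))

    def test_collinear_points_use_randomized_rule(self):
        pts = np.array([[0, 0], [0.1, 0], [0.2, 0]], dtype=float)
        hull = build_mcp(pts, self.grid, seed=2)
        assert hull.geom_type == "Polygon" and hull.area > 0

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            build_mcp(np.array([[0.0, 0.0]]), self.grid, seed=0)


class TestBufferRange:
    def test_point_buffer_is_disc(self):
        r = 0.3
        disc = buffer_range(Point(0, 0), r)
        assert disc.area == pytest.approx(np.pi * r**2, rel=0.01)

    def test_square_buffer_closed_form(self):
        s, r = 1.0, 0.2
        sq = Polygon([(0, 0), (s, 0), (s, s), (0, s)])
        buf = buffer_range(sq, r)
        assert buf.area == pytest.approx(s**2 + 4 * s * r + np.pi * r**2,
                                         rel=0.01)

    def test_nested_buffers_contain_single_wide_buffer(self):
        # containment up to the chord error of the polygonal arcs
        sq = Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])
        nested = buffer_range(buffer_range(sq, 0.2), 0.2)
        single = buffer_range(sq, 0.4)
        sagitta = 0.4 * (1 - np.cos(np.pi / 32))
        assert nested.buffer(2 * sagitta).contains(single)


class TestRasterizeRange:
    grid = Grid(0, 0, 1.0, 5, 5)

    def test_whole_grid_polygon(self):
        poly = Polygon([(-1, -1), (6, -1), (6, 6), (-1, 6)])
        cells = rasterize_range(CoarseRange("x", [poly]), self.grid)
        assert cells == set(range(25))

    def test_record_cell_guarantee_for_tiny_polygon(self):
        tiny = Point(2.1, 2.1).buffer(0.05)  # misses every cell center
        cr = CoarseRange("x", [tiny], record_cells={self.grid.point_to_cell(2.1, 2.1)})
        assert rasterize_range(cr, self.grid) == {12}

    def test_rectangle_spanning_columns(self):
        # columns 1-3 exactly: centers at x in {1.5, 2.5, 3.5} inside
        rect = Polygon([(1, 0), (4, 0), (4, 5), (1, 5)])
        cells = rasterize_range(CoarseRange("x", [rect]), self.grid)
        assert len(cells) == 15
        assert all(1 <= c % 5 <= 3 for c in cells)

    def test_empty_range_is_an_error(self):
        tiny = Point(2.1, 2.1).buffer(0.05)
        with pytest.raises(ValueError):
            rasterize_range(CoarseRange("x", [tiny]), self.grid)

    def test_monotone_in_polygon_size(self):
        small = Point(2.5, 2.5).buffer(1.0)
        large = Point(2.5, 2.5).buffer(2.0)
        c_small = rasterize_range(CoarseRange("x", [small]), self.grid)
        c_large = rasterize_range(CoarseRange("x", [large]), self.grid)
        assert c_small <= c_large


class TestApplyFilters:
    def test_noop_without_layers(self):
        cells = {1, 2, 3}
        assert apply_filters(cells, set()) == cells

    def test_record_cells_survive_exclusion(self):
        mask = np.zeros(10, dtype=bool)
        mask[[2, 3]] = True
        out = apply_filters({1, 2, 3}, record_cells={2}, exclusion_mask=mask)
        assert out == {1, 2}  # 3 excluded, 2 kept by its record

    def test_elevation_envelope(self):
        elev = np.array([100.0, 200.0, 900.0])
        out = apply_filters({0, 1, 2}, record_cells=set(),
                            record_elevations=[150.0, 250.0], elevation=elev)
        assert out == {1}  # 100 below and 900 above the record envelope

    def test_contraction_except_records(self):
        elev = np.array([0.0, 500.0, 1000.0, 1500.0])
        cells = {0, 1, 2}
        out = apply_filters(cells, record_cells={3},
                            record_elevations=[400.0, 600.0], elevation=elev)
        assert out <= cells | {3}
        assert 3 in out


def test_ranges_to_presence_end_to_end():
    grid = Grid(0, 0, 1.0, 6, 6)
    import pandas as pd
    records = pd.DataFrame(
        {
            "species": ["a"] * 4 + ["b"] * 2 + ["c"],
            "longitude": [1.2, 3.4, 1.4, 3.1, 0.5, 0.8, 5.5],
            "latitude": [1.3, 3.2, 3.3, 1.2, 0.5, 0.7, 5.5],
        }
    )
    matrix, coarse = ranges_to_presence(records, grid, seed=0)
    assert set(matrix.species) == {"a", "b", "c"}
    assert (matrix.range_sizes() >= 1).all()
    # every record cell is present for its species
    for sp in matrix.species:
        cells = set(matrix.species_cells(sp).tolist())
        assert coarse[sp].record_cells <= cells
    # species a's quad spans the grid interior
    assert len(matrix.species_cells("a")) > len(matrix.species_cells("c"))
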