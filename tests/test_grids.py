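"""Grid/point data model, text formats, and presence rasterization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from shapely.geometry import box

from ottersdm import (
    DegenerateInputError,
    FormatError,
    PointSet,
    RasterGrid,
    SurveyDomain,
    rasterize_presences,
    read_points,
    read_polygons,
    read_raster,
    write_points,
    write_polygons,
    write_raster,
)
from ottersdm.grids import CovariateStack, read_stack, write_stack


# ---------------------------------------------------------------------------
# point CSV I/O

class TestPointIO:
    def test_reads_rows_and_attributes(self, tmp_path):
        p = tmp_path / "pts.csv"
        p.write_text("x,y,boulder\n0,0,10\n131,0,20\n262,131,30\n")
        pts = read_points(p)
        assert len(pts) == 3
        assert list(pts.attributes.columns) == ["boulder"]
        assert pts.attributes["boulder"].tolist() == [10, 20, 30]

    def test_header_only_file_gives_empty_set(self, tmp_path):
        p = tmp_path / "pts.csv"
        p.write_text("x,y\n")
        assert len(read_points(p)) == 0

    def test_missing_coordinate_columns(self, tmp_path):
        p = tmp_path / "pts.csv"
        p.write_text("lon,lat\n1,2\n")
        with pytest.raises(FormatError, match="coordinate"):
            read_points(p)

    def test_non_numeric_cell_names_row(self, tmp_path):
        p = tmp_path / "pts.csv"
        p.write_text("x,y,v\n1,2,3\n4,5,oops\n")
        with pytest.raises(FormatError, match="row 1"):
            read_points(p)

    def test_write_read_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        pts = PointSet(x=rng.uniform(0, 1000, 17), y=rng.uniform(0, 1000, 17),
                       attributes=pd.DataFrame({"boulder": rng.uniform(0, 100, 17),
                                                "mud": rng.uniform(0, 100, 17)}))
        path = tmp_path / "rt.csv"
        write_points(pts, path)
        back = read_points(path)
        np.testing.assert_allclose(back.x, pts.x, rtol=1e-12)
        np.testing.assert_allclose(back.y, pts.y, rtol=1e-12)
        pd.testing.assert_frame_equal(back.attributes, pts.attributes)


# ---------------------------------------------------------------------------
# raster I/O

class TestRasterIO:
    def test_round_trip_values_and_mask(self, tmp_path):
        grid = RasterGrid(values=np.array([[1.5, 2.25], [3.0, 4.125]]),
                          cell_size=131.0, origin_x=10.0, origin_y=-20.0)
        path = tmp_path / "g.asc"
        write_raster(grid, path)
        back = read_raster(path)
        np.testing.assert_array_equal(back.values, grid.values)
        assert not back.nodata_mask.any()
        assert back.cell_size == 131.0  # survives the round trip exactly
        assert back.origin_x == 10.0 and back.origin_y == -20.0

    def test_nodata_cells_masked(self, tmp_path):
        mask = np.array([[True, False], [False, True]])
        grid = RasterGrid(values=np.where(mask, 0.0, 7.0), cell_size=1.0,
                          nodata_mask=mask)
        path = tmp_path / "g.asc"
        write_raster(grid, path)
        back = read_raster(path)
        np.testing.assert_array_equal(back.nodata_mask, mask)
        np.testing.assert_array_equal(back.values[~mask], grid.values[~mask])

    def test_all_nodata_grid(self, tmp_path):
        mask = np.ones((2, 2), bool)
        grid = RasterGrid(values=np.zeros((2, 2)), cell_size=1.0, nodata_mask=mask)
        path = tmp_path / "g.asc"
        write_raster(grid, path)
        assert read_raster(path).nodata_mask.all()

    @given(origin=st.floats(min_value=-1e5, max_value=1e5, allow_nan=False),
           cell=st.floats(min_value=0.1, max_value=1e4, allow_nan=False))
    def test_round_trip_origin_cellsize_property(self, tmp_path_factory, origin, cell):
        grid = RasterGrid(values=np.arange(6.0).reshape(2, 3), cell_size=cell,
                          origin_x=origin, origin_y=-origin)
        path = tmp_path_factory.mktemp("rt") / "g.asc"
        write_raster(grid, path)
        back = read_raster(path)
        assert back.cell_size == cell
        assert back.origin_x == origin
        np.testing.assert_array_equal(back.values, grid.values)

    def test_stack_round_trip(self, tmp_path, small_stack):
        write_stack(small_stack, tmp_path / "stack")
        back = read_stack(tmp_path / "stack")
        assert back.names == small_stack.names
        assert back.kinds == small_stack.kinds
        for name in back.names:
            np.testing.assert_array_equal(back.layers[name].values,
                                          small_stack.layers[name].values)


# ---------------------------------------------------------------------------
# cell convention

class TestCellConvention:
    def test_row0_is_south(self):
        grid = RasterGrid(values=np.zeros((3, 3)), cell_size=10.0)
        r, c = grid.cell_of(5.0, 5.0)
        assert (r, c) == (0, 0)
        r, c = grid.cell_of(5.0, 25.0)
        assert (r, c) == (2, 0)

    def test_shared_edge_belongs_to_one_cell(self):
        # half-open intervals: a point on the boundary x = 10 is in column 1
        grid = RasterGrid(values=np.zeros((2, 2)), cell_size=10.0)
        r, c = grid.cell_of(10.0, 10.0)
        assert (r, c) == (1, 1)
        r, c = grid.cell_of(0.0, 0.0)
        assert (r, c) == (0, 0)

    def test_off_grid_is_flagged(self):
        grid = RasterGrid(values=np.zeros((2, 2)), cell_size=10.0)
        r, _ = grid.cell_of(20.0, 5.0)  # east edge is exclusive
        assert r == -1

    @given(st.floats(min_value=0, max_value=39.999), st.floats(min_value=0, max_value=39.999))
    def test_every_interior_point_in_exactly_one_cell(self, x, y):
        grid = RasterGrid(values=np.zeros((4, 4)), cell_size=10.0)
        r, c = grid.cell_of(x, y)
        assert 0 <= r < 4 and 0 <= c < 4
        # the half-open square really contains the point
        assert grid.origin_x + c * 10 <= x < grid.origin_x + (c + 1) * 10
        assert grid.origin_y + r * 10 <= y < grid.origin_y + (r + 1) * 10


# ---------------------------------------------------------------------------
# presence rasterization

class TestRasterizePresences:
    def grid(self):
        mask = np.zeros((20, 25), bool)
        mask[0, 0] = True
        return RasterGrid(values=np.zeros((20, 25)), cell_size=10.0,
                          nodata_mask=mask)

    def test_same_cell_points_collapse(self):
        grid = self.grid()
        pts = PointSet(x=np.array([11.0, 12, 13, 14, 15]),
                       y=np.array([11.0, 12, 13, 14, 15]), role="presence")
        out = rasterize_presences(pts, grid)
        assert len(out) == 1
        assert (out.rows[0], out.cols[0]) == (1, 1)

    def test_391_distinct_cells_survive(self):
        # enough raw points to occupy 391 distinct cells plus duplicates
        grid = self.grid()
        rr, cc = np.nonzero(~grid.nodata_mask)
        take = np.random.default_rng(3).choice(rr.size, 391, replace=False)
        x, y = grid.cell_center(rr[take], cc[take])
        x = np.concatenate([x, x[:50] + 1.0])  # 50 duplicate-cell points
        y = np.concatenate([y, y[:50] + 1.0])
        out = rasterize_presences(PointSet(x=x, y=y, role="presence"), grid)
        assert len(out) == 391

    def test_nodata_and_offgrid_points_dropped(self):
        grid = self.grid()
        pts = PointSet(x=np.array([5.0, -50.0, 15.0]),
                       y=np.array([5.0, 5.0, 15.0]), role="presence")
        out = rasterize_presences(pts, grid)  # (0,0) is nodata; -50 off grid
        assert len(out) == 1

    def test_zero_survivors_is_degenerate(self):
        grid = self.grid()
        pts = PointSet(x=np.array([5.0]), y=np.array([5.0]), role="presence")
        with pytest.raises(DegenerateInputError):
            rasterize_presences(pts, grid)

    def test_idempotent_on_own_cell_centers(self):
        grid = self.grid()
        rng = np.random.default_rng(8)
        pts = PointSet(x=rng.uniform(0, 250, 300), y=rng.uniform(0, 200, 300),
                       role="presence")
        once = rasterize_presences(pts, grid)
        again = rasterize_presences(once.as_points(), grid)
        np.testing.assert_array_equal(np.sort(once.rows * 25 + once.cols),
                                      np.sort(again.rows * 25 + again.cols))
        assert len(once) == len(again)

    def test_first_record_in_input_order_kept(self):
        grid = self.grid()
        pts = PointSet(x=np.array([11.0, 31.0, 12.0]),
                       y=np.array([11.0, 11.0, 12.0]), role="presence")
        out = rasterize_presences(pts, grid)
        assert len(out) == 2


# ---------------------------------------------------------------------------
# survey domain polygons

class TestSurveyDomain:
    def test_wkt_round_trip(self, tmp_path):
        dom = SurveyDomain(polygons=[box(0, 0, 20, 100), box(40, 0, 60, 100)])
        path = tmp_path / "dom.wkt"
        write_polygons(dom, path)
        back = read_polygons(path)
        assert len(back.polygons) == 2
        assert back.polygons[0].equals(dom.polygons[0])

    def test_cell_mask_uses_centers(self):
        grid = RasterGrid(values=np.zeros((4, 4)), cell_size=10.0)
        dom = SurveyDomain(polygons=[box(0, 0, 10, 40)])  # first column only
        mask = dom.cell_mask(grid)
        np.testing.assert_array_equal(mask[:, 0], np.ones(4, bool))
        assert not mask[:, 1:].any()

    def test_invalid_wkt_rejected(self, tmp_path):
        path = tmp_path / "bad.wkt"
        path.write_text("POLYGON NOT WKT\n")
        with pytest.raises(FormatError):
            read_polygons(path)


class TestStackInvariants:
    def test_percent_cover_range_enforced(self):
        g = RasterGrid(values=np.array([[150.0]]), cell_size=1.0)
        with pytest.raises(Exception, match="percent_cover"):
            CovariateStack(layers={"boulder": g}, kinds={"boulder": "percent_cover"})

    def test_depth_must_be_negative(self):
        g = RasterGrid(values=np.array([[5.0]]), cell_size=1.0)
        with pytest.raises(Exception, match="depth"):
            CovariateStack(layers={"bathymetry": g}, kinds={"bathymetry": "depth"})

    def test_misaligned_layers_rejected(self):
        a = RasterGrid(values=np.zeros((2, 2)), cell_size=1.0)
        b = RasterGrid(values=np.zeros((3, 2)) - 5.0, cell_size=1.0)
        with pytest.raises(Exception, match="align"):
            CovariateStack(layers={"sand": a, "bathymetry": b},
                           kinds={"sand": "percent_cover", "bathymetry": "depth"})
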