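"""Planar raster grids, point sets, survey domains, and their text formats.

Coordinates are planar meters on an abstract plane; there is no datum or
projection handling.  The grid convention, fixed once for the whole package:

* row 0 is the southernmost row, column 0 the westernmost column;
* cell (r, c) covers the half-open square
  ``[origin_x + c*s, origin_x + (c+1)*s) x [origin_y + r*s, origin_y + (r+1)*s)``
  with ``s = cell_size``, so a point on a shared edge belongs to exactly one
  cell;
* ``origin_x, origin_y`` is the lower-left corner of the grid.

Rasters are stored as ESRI ASCII grids (plain text; note the format writes
rows north to south, so row order is flipped on the way in and out).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
import shapely.wkt
from shapely.geometry import Polygon

from .errors import AlignmentError, ArgumentError, DegenerateInputError, FormatError

log = logging.getLogger(__name__)

#: attribute kinds and the value ranges they promise
KIND_PERCENT = "percent_cover"
KIND_DEPTH = "depth"
KIND_RATIO = "ratio"
VALID_KINDS = (KIND_PERCENT, KIND_DEPTH, KIND_RATIO)


@dataclass
class RasterGrid:
    """A rectangular grid of real values with a nodata mask."""

    values: np.ndarray
    cell_size: float
    origin_x: float = 0.0
    origin_y: float = 0.0
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ArgumentError("values must be a non-empty 2-D array")
        if not self.cell_size > 0:
            raise ArgumentError(f"cell_size must be > 0, got {self.cell_size}")
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.values)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.values.shape:
                raise AlignmentError("nodata_mask shape differs from values shape")
        if not np.all(np.isfinite(self.values[~self.nodata_mask])):
            raise ArgumentError("values must be finite wherever nodata_mask is False")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self, values: np.ndarray | None = None,
             nodata_mask: np.ndarray | None = None) -> "RasterGrid":
        """A grid sharing this grid's frame, optionally with new values/mask."""
        return RasterGrid(
            values=self.values.copy() if values is None else np.asarray(values, float),
            cell_size=self.cell_size,
            origin_x=self.origin_x,
            origin_y=self.origin_y,
            nodata_mask=(self.nodata_mask.copy() if nodata_mask is None
                         else np.asarray(nodata_mask, bool)),
        )

    def same_frame(self, other: "RasterGrid") -> bool:
        return (self.shape == other.shape
                and math.isclose(self.cell_size, other.cell_size, rel_tol=1e-12)
                and math.isclose(self.origin_x, other.origin_x, rel_tol=1e-9, abs_tol=1e-6)
                and math.isclose(self.origin_y, other.origin_y, rel_tol=1e-9, abs_tol=1e-6))

    # -- coordinate <-> cell ------------------------------------------------
    def cell_of(self, x, y):
        """Row/col of the half-open cell containing (x, y); -1 if off-grid."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        c = np.floor((x - self.origin_x) / self.cell_size).astype(int)
        r = np.floor((y - self.origin_y) / self.cell_size).astype(int)
        off = (r < 0) | (r >= self.n_rows) | (c < 0) | (c >= self.n_cols)
        r = np.where(off, -1, r)
        c = np.where(off, -1, c)
        return r, c

    def cell_center(self, r, c):
        r = np.asarray(r)
        c = np.asarray(c)
        x = self.origin_x + (c + 0.5) * self.cell_size
        y = self.origin_y + (r + 0.5) * self.cell_size
        return x, y

    def cell_centers(self):
        """(x, y) arrays of every cell center, shape (n_rows, n_cols)."""
        rr, cc = np.meshgrid(np.arange(self.n_rows), np.arange(self.n_cols),
                             indexing="ij")
        return self.cell_center(rr, cc)


@dataclass
class CovariateStack:
    """Named, frame-aligned covariate layers forming the modeling landscape.

    ``kinds`` maps each layer name to one of 'percent_cover', 'depth' or
    'ratio', which carries the admissible value range ([0, 100], < 0, >= 1).
    The shared nodata mask is the union of the layers' masks.
    """

    layers: dict[str, RasterGrid]
    kinds: dict[str, str]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ArgumentError("stack needs at least one layer")
        names = list(self.layers)
        ref = self.layers[names[0]]
        for name in names:
            g = self.layers[name]
            if not g.same_frame(ref):
                raise AlignmentError(f"layer {name!r} is not aligned with {names[0]!r}")
            kind = self.kinds.get(name)
            if kind not in VALID_KINDS:
                raise ArgumentError(f"layer {name!r} has unknown kind {kind!r}")
            valid = g.values[~g.nodata_mask]
            if kind == KIND_PERCENT and valid.size and (valid.min() < 0 or valid.max() > 100):
                raise ArgumentError(f"percent_cover layer {name!r} outside [0, 100]")
            if kind == KIND_DEPTH and valid.size and valid.max() >= 0:
                raise ArgumentError(f"depth layer {name!r} must be < 0 where valid")
            if kind == KIND_RATIO and valid.size and valid.min() < 1:
                raise ArgumentError(f"ratio layer {name!r} must be >= 1 where valid")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def grid(self) -> RasterGrid:
        return self.layers[self.names[0]]

    @property
    def nodata_mask(self) -> np.ndarray:
        mask = np.zeros(self.grid.shape, dtype=bool)
        for g in self.layers.values():
            mask |= g.nodata_mask
        return mask

    def values_at_cells(self, rows, cols, names: Sequence[str] | None = None) -> np.ndarray:
        """Matrix (n_cells, n_covariates) of layer values at cell indices."""
        names = list(names) if names is not None else self.names
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        out = np.empty((rows.size, len(names)))
        for j, name in enumerate(names):
            out[:, j] = self.layers[name].values[rows, cols]
        return out

    def frame(self, rows, cols, names: Sequence[str] | None = None) -> pd.DataFrame:
        return pd.DataFrame(self.values_at_cells(rows, cols, names),
                            columns=names if names is not None else self.names)


@dataclass
class PointSet:
    """Point records (x, y, optional attributes) with a role tag."""

    x: np.ndarray
    y: np.ndarray
    attributes: pd.DataFrame | None = None
    role: str = "habitat_sample"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ArgumentError("x and y must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ArgumentError("coordinates must be finite")
        if self.attributes is not None and len(self.attributes) != len(self.x):
            raise ArgumentError("attribute table length differs from coordinates")

    def __len__(self) -> int:
        return self.x.size

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"x": self.x, "y": self.y})
        if self.attributes is not None:
            for col in self.attributes.columns:
                df[col] = np.asarray(self.attributes[col])
        return df


@dataclass
class CellSet:
    """Distinct grid cells (row/col indices) tied to a reference grid frame."""

    rows: np.ndarray
    cols: np.ndarray
    grid: RasterGrid
    role: str = "presence"

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=int)
        self.cols = np.asarray(self.cols, dtype=int)
        if self.rows.shape != self.cols.shape or self.rows.ndim != 1:
            raise ArgumentError("rows and cols must be 1-D arrays of equal length")

    def __len__(self) -> int:
        return self.rows.size

    def centers(self):
        return self.grid.cell_center(self.rows, self.cols)

    def as_points(self) -> PointSet:
        x, y = self.centers()
        return PointSet(x=x, y=y, role=self.role)


#: role aliases used throughout the pipeline
PresenceSet = CellSet
BackgroundSet = CellSet


@dataclass
class SurveyDomain:
    """Strip-transect polygons and their cell mask on a grid."""

    polygons: list[Polygon]

    def __post_init__(self) -> None:
        if not self.polygons:
            raise ArgumentError("survey domain needs at least one polygon")
        for p in self.polygons:
            if not p.is_valid:
                raise ArgumentError("survey polygons must be simple (non-self-intersecting)")

    def cell_mask(self, grid: RasterGrid) -> np.ndarray:
        """Boolean mask of cells whose centers fall inside any polygon."""
        xs, ys = grid.cell_centers()
        union = shapely.union_all(self.polygons)
        inside = shapely.contains_xy(union, xs.ravel(), ys.ravel())
        return inside.reshape(grid.shape)

    def cells(self, grid: RasterGrid, valid_mask: np.ndarray | None = None):
        """(rows, cols) of domain cells, optionally intersected with validity."""
        mask = self.cell_mask(grid)
        if valid_mask is not None:
            mask &= valid_mask
        rows, cols = np.nonzero(mask)
        return rows, cols


# ---------------------------------------------------------------------------
# point CSV I/O

def read_points(path: str | Path, role: str = "habitat_sample") -> PointSet:
    """Read a point CSV with header columns x,y[,attr1,...]."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise FormatError(f"{path}: cannot parse CSV: {exc}") from exc
    cols = {c.lower(): c for c in df.columns}
    if "x" not in cols or "y" not in cols:
        raise FormatError(f"{path}: missing coordinate columns 'x' and 'y'")
    attr_cols = [c for c in df.columns if c not in (cols["x"], cols["y"])]
    for col in [cols["x"], cols["y"]] + attr_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise FormatError(f"{path}: non-numeric value in column {col!r} at row {row}")
        df[col] = coerced
    attributes = df[attr_cols].reset_index(drop=True) if attr_cols else None
    return PointSet(x=df[cols["x"]].to_numpy(float),
                    y=df[cols["y"]].to_numpy(float),
                    attributes=attributes, role=role)


def write_points(points: PointSet, path: str | Path) -> None:
    points.to_frame().to_csv(Path(path), index=False)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O

def write_raster(grid: RasterGrid, path: str | Path, nodata_value: float = -9999.0) -> None:
    """Write an ESRI ASCII grid (rows stored north to south)."""
    path = Path(path)
    vals = np.where(grid.nodata_mask, nodata_value, grid.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {float(grid.origin_x)!r}\n")
        fh.write(f"yllcorner {float(grid.origin_y)!r}\n")
        fh.write(f"cellsize {float(grid.cell_size)!r}\n")
        fh.write(f"nodata_value {float(nodata_value)!r}\n")
        for row in vals[::-1]:  # ASCII grid is top-down; row 0 is south here
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")


def read_raster(path: str | Path) -> RasterGrid:
    """Read an ESRI ASCII grid written by :func:`write_raster` (or ArcGIS)."""
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if len(parts) == 2 and key in ("ncols", "nrows", "xllcorner", "yllcorner",
                                           "cellsize", "nodata_value"):
                header[key] = float(parts[1])
            else:
                rows.append(np.array(parts, dtype=float))
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise FormatError(f"{path}: missing header field {req!r}")
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if len(rows) != n_rows or any(r.size != n_cols for r in rows):
        raise FormatError(f"{path}: data block does not match declared shape")
    values = np.vstack(rows)[::-1]  # back to row 0 = south
    nodata = header.get("nodata_value", -9999.0)
    mask = values == nodata
    values = np.where(mask, np.nan, values)
    return RasterGrid(values=values, cell_size=header["cellsize"],
                      origin_x=header.get("xllcorner", 0.0),
                      origin_y=header.get("yllcorner", 0.0),
                      nodata_mask=mask)


def write_stack(stack: CovariateStack, directory: str | Path) -> None:
    """Write each layer as ``<name>.asc`` plus a ``kinds.csv`` manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, grid in stack.layers.items():
        write_raster(grid, directory / f"{name}.asc")
    pd.DataFrame({"name": stack.names,
                  "kind": [stack.kinds[n] for n in stack.names]}
                 ).to_csv(directory / "kinds.csv", index=False)


def read_stack(directory: str | Path) -> CovariateStack:
    directory = Path(directory)
    manifest = directory / "kinds.csv"
    if not manifest.exists():
        raise FormatError(f"{directory}: missing kinds.csv manifest")
    kinds_df = pd.read_csv(manifest)
    layers = {}
    kinds = {}
    for _, row in kinds_df.iterrows():
        name = str(row["name"])
        layers[name] = read_raster(directory / f"{name}.asc")
        kinds[name] = str(row["kind"])
    return CovariateStack(layers=layers, kinds=kinds)


# ---------------------------------------------------------------------------
# WKT polygon I/O

def read_polygons(path: str | Path) -> SurveyDomain:
    """Read a survey domain as WKT text, one polygon per line."""
    polygons = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            try:
                geom = shapely.wkt.loads(line)
            except Exception as exc:
                raise FormatError(f"{path}: line {i}: invalid WKT: {exc}") from exc
            if geom.geom_type == "Polygon":
                polygons.append(geom)
            elif geom.geom_type == "MultiPolygon":
                polygons.extend(geom.geoms)
            else:
                raise FormatError(f"{path}: line {i}: expected POLYGON, got {geom.geom_type}")
    return SurveyDomain(polygons=polygons)


def write_polygons(domain: SurveyDomain, path: str | Path) -> None:
    with open(path, "w") as fh:
        for poly in domain.polygons:
            fh.write(poly.wkt + "\n")


# ---------------------------------------------------------------------------
# presence rasterization

def rasterize_presences(points: PointSet, grid: RasterGrid) -> PresenceSet:
    """Collapse raw occurrence points to at most one presence per grid cell.

    Points off the grid or on nodata cells are dropped (count logged).
    Among points sharing a cell, the first in input order is kept.
    """
    r, c = grid.cell_of(points.x, points.y)
    on_grid = r >= 0
    n_off = int((~on_grid).sum())
    r, c = r[on_grid], c[on_grid]
    valid = ~grid.nodata_mask[r, c]
    n_nodata = int((~valid).sum())
    r, c = r[valid], c[valid]
    if n_off or n_nodata:
        log.info("rasterize_presences: dropped %d off-grid and %d nodata-cell points",
                 n_off, n_nodata)
    if r.size == 0:
        raise DegenerateInputError("no presence points fall on valid grid cells")
    flat = r * grid.n_cols + c
    _, first = np.unique(flat, return_index=True)
    first.sort()  # keep first-in-input-order representative per cell
    n_dup = r.size - first.size
    if n_dup:
        log.info("rasterize_presences: collapsed %d duplicate same-cell points", n_dup)
    return PresenceSet(rows=r[first], cols=c[first], grid=grid, role="presence")
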