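"""Equal-area gridding of species ranges and per-cell map layers.

Ranges (WGS84 polygons or lon/lat rectangles) are projected onto a
cylindrical equal-area projection with standard parallel 30 deg
("Behrmann") and gridded at a cell size equivalent to 0.25 deg of
equatorial arc (~27.8 km). A species occupies a cell iff the cell's
center lies inside one of its range shapes. Layers (species richness,
mean per-species metrics) are computed per occupied cell; empty cells
are missing, not zero, so layer correlations run over the occupied
domain only.

Grid convention: row-major indexing from the south-west corner, row 0
southernmost; half-open cells [min, max).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from shapely import contains_xy
from shapely.geometry import box, shape

__all__ = [
    "EARTH_RADIUS",
    "STANDARD_PARALLEL",
    "GridSpec",
    "OccurrenceGrid",
    "CellLayer",
    "behrmann_forward",
    "behrmann_inverse",
    "cell_size_from_degrees",
    "make_grid",
    "rasterize_ranges",
    "richness_layer",
    "mean_metric_layer",
    "layer_correlation",
    "read_ranges_csv",
    "write_ranges_csv",
    "read_ranges_geojson",
    "write_ascii_grid",
    "write_layer_csv",
]

EARTH_RADIUS = 6_371_007.181  # authalic radius, m
STANDARD_PARALLEL = 30.0  # degrees
_COS_SP = math.cos(math.radians(STANDARD_PARALLEL))


def behrmann_forward(lon, lat):
    """WGS84 lon/lat (deg) -> equal-area cylindrical x/y (m)."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    x = EARTH_RADIUS * np.radians(lon) * _COS_SP
    y = EARTH_RADIUS * np.sin(np.radians(lat)) / _COS_SP
    return x, y


def behrmann_inverse(x, y):
    """Equal-area cylindrical x/y (m) -> lon/lat (deg)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lon = np.degrees(x / (EARTH_RADIUS * _COS_SP))
    lat = np.degrees(np.arcsin(np.clip(y * _COS_SP / EARTH_RADIUS, -1.0, 1.0)))
    return lon, lat


def cell_size_from_degrees(degrees: float = 0.25) -> float:
    """Projected cell edge equivalent to ``degrees`` of equatorial arc."""
    return EARTH_RADIUS * math.radians(degrees)


@dataclass(frozen=True)
class GridSpec:
    """An equal-area grid: origin at the extent's lower-left (projected
    m), square cells, row 0 southernmost."""

    x0: float
    y0: float
    cell_size: float
    n_rows: int
    n_cols: int

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_center(self, row, col):
        """Projected coordinates of cell centers."""
        row = np.asarray(row)
        col = np.asarray(col)
        return (
            self.x0 + (col + 0.5) * self.cell_size,
            self.y0 + (row + 0.5) * self.cell_size,
        )

    def centers_lonlat(self):
        """(lon, lat) arrays of all cell centers, shape (n_rows, n_cols)."""
        rows, cols = np.meshgrid(
            np.arange(self.n_rows), np.arange(self.n_cols), indexing="ij"
        )
        x, y = self.cell_center(rows, cols)
        return behrmann_inverse(x, y)


def make_grid(extent: tuple[float, float, float, float],
              cell_size_deg: float = 0.25) -> GridSpec:
    """Build a grid covering a geographic extent.

    ``extent`` is (min_lon, min_lat, max_lon, max_lat) in degrees. Cell
    counts are the ceiling of the projected extent over the cell size,
    so the grid may overhang to the north-east.
    """
    min_lon, min_lat, max_lon, max_lat = extent
    if not (min_lon < max_lon and min_lat < max_lat):
        raise ValueError(f"empty or inverted extent {extent}")
    if cell_size_deg <= 0:
        raise ValueError(f"cell_size must be > 0, got {cell_size_deg}")
    cell = cell_size_from_degrees(cell_size_deg)
    x0, y0 = behrmann_forward(min_lon, min_lat)
    x1, y1 = behrmann_forward(max_lon, max_lat)
    n_cols = max(1, math.ceil((float(x1) - float(x0)) / cell - 1e-9))
    n_rows = max(1, math.ceil((float(y1) - float(y0)) / cell - 1e-9))
    return GridSpec(float(x0), float(y0), cell, n_rows, n_cols)


@dataclass
class OccurrenceGrid:
    grid: GridSpec
    cells: dict[tuple[int, int], set[str]] = field(default_factory=dict)

    def add(self, row: int, col: int, species: str) -> None:
        if not (0 <= row < self.grid.n_rows and 0 <= col < self.grid.n_cols):
            raise IndexError(f"cell ({row}, {col}) outside grid {self.grid.shape}")
        self.cells.setdefault((row, col), set()).add(species)

    @property
    def species(self) -> set[str]:
        out: set[str] = set()
        for s in self.cells.values():
            out |= s
        return out

    def cells_of(self, species: str) -> set[tuple[int, int]]:
        return {rc for rc, s in self.cells.items() if species in s}


@dataclass
class CellLayer:
    grid: GridSpec
    values: dict[tuple[int, int], float] = field(default_factory=dict)

    def to_array(self, nodata: float = np.nan) -> np.ndarray:
        arr = np.full(self.grid.shape, nodata, dtype=float)
        for (r, c), v in self.values.items():
            arr[r, c] = v
        return arr


# ---------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------


def _rect_cells(rect: tuple[float, float, float, float], grid: GridSpec):
    """Cells whose centers fall inside a lon/lat rectangle — computed
    arithmetically (the projection is separable in lon and lat)."""
    min_lon, min_lat, max_lon, max_lat = rect
    x_min, y_min = behrmann_forward(min_lon, min_lat)
    x_max, y_max = behrmann_forward(max_lon, max_lat)
    cell = grid.cell_size
    # center of col j is at x0 + (j + 0.5) cell; need x_min < center < x_max
    c_lo = math.ceil((float(x_min) - grid.x0) / cell - 0.5)
    c_hi = math.floor((float(x_max) - grid.x0) / cell - 0.5 - 1e-12)
    r_lo = math.ceil((float(y_min) - grid.y0) / cell - 0.5)
    r_hi = math.floor((float(y_max) - grid.y0) / cell - 0.5 - 1e-12)
    c_lo, c_hi = max(c_lo, 0), min(c_hi, grid.n_cols - 1)
    r_lo, r_hi = max(r_lo, 0), min(r_hi, grid.n_rows - 1)
    for r in range(r_lo, r_hi + 1):
        for c in range(c_lo, c_hi + 1):
            yield (r, c)


def rasterize_ranges(ranges: dict, grid: GridSpec) -> OccurrenceGrid:
    """Rasterize species ranges by cell-center containment.

    ``ranges`` maps species -> list of shapes, each either a lon/lat
    rectangle tuple ``(min_lon, min_lat, max_lon, max_lat)`` or a
    shapely geometry / GeoJSON-like mapping in WGS84. A species with an
    empty shape list occupies no cells.
    """
    occ = OccurrenceGrid(grid)
    lon_ctr = lat_ctr = None  # computed lazily, only for polygon input
    for species, shapes in ranges.items():
        for geom in shapes:
            if isinstance(geom, tuple) and len(geom) == 4:
                if not (geom[0] <= geom[2] and geom[1] <= geom[3]):
                    raise ValueError(
                        f"invalid rectangle for {species!r}: {geom}"
                    )
                for rc in _rect_cells(geom, grid):
                    occ.cells.setdefault(rc, set()).add(species)
                continue
            if isinstance(geom, dict):
                geom = shape(geom)
            if geom.is_empty:
                continue
            if not geom.is_valid:
                raise ValueError(f"invalid geometry for species {species!r}")
            if lon_ctr is None:
                lon_ctr, lat_ctr = grid.centers_lonlat()
            inside = contains_xy(geom, lon_ctr.ravel(), lat_ctr.ravel())
            for flat in np.nonzero(inside)[0]:
                rc = (int(flat // grid.n_cols), int(flat % grid.n_cols))
                occ.cells.setdefault(rc, set()).add(species)
    return occ


# ---------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------


def richness_layer(occ: OccurrenceGrid) -> CellLayer:
    """Species count per occupied cell; unoccupied cells are missing."""
    return CellLayer(
        occ.grid, {rc: float(len(s)) for rc, s in occ.cells.items()}
    )


def mean_metric_layer(occ: OccurrenceGrid, per_species: dict[str, float]) -> CellLayer:
    """Arithmetic mean of a per-species value over each cell's set."""
    missing = occ.species - set(per_species)
    if missing:
        raise KeyError(f"no metric value for species: {sorted(missing)}")
    return CellLayer(
        occ.grid,
        {
            rc: float(np.mean([per_species[sp] for sp in s]))
            for rc, s in occ.cells.items()
        },
    )


def layer_correlation(
    a: CellLayer,
    b: CellLayer,
    min_richness: int = 1,
    richness: CellLayer | None = None,
) -> tuple[float, float, int]:
    """Pearson correlation between two layers over their shared cells.

    Cells must be non-missing in both layers; when ``richness`` is
    supplied, cells below ``min_richness`` are excluded. Returns
    ``(r, p, n_cells)`` with p from the t transform at n - 2 df.
    """
    if a.grid != b.grid:
        raise ValueError("layers use different grids")
    keys = set(a.values) & set(b.values)
    if richness is not None and min_richness > 1:
        keys &= {rc for rc, v in richness.values.items() if v >= min_richness}
    keys = sorted(keys)
    if len(keys) < 3:
        raise ValueError(f"only {len(keys)} shared cells; need >= 3")
    va = np.array([a.values[k] for k in keys])
    vb = np.array([b.values[k] for k in keys])
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("zero variance in a layer over the shared cells")
    r, p = stats.pearsonr(va, vb)
    return float(r), float(p), len(keys)


# ---------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------


def read_ranges_csv(path) -> dict[str, list[tuple[float, float, float, float]]]:
    """Read ``species,min_lon,min_lat,max_lon,max_lat`` rectangles.

    Rectangles crossing the antimeridian (min_lon > max_lon) are split
    into two. Coordinates must lie in [-180, 180] x [-90, 90].
    """
    import pandas as pd

    df = pd.read_csv(path)
    needed = {"species", "min_lon", "min_lat", "max_lon", "max_lat"}
    if not needed <= set(df.columns):
        raise ValueError(f"ranges CSV needs columns {sorted(needed)}")
    out: dict[str, list[tuple[float, float, float, float]]] = {}
    for rec in df.itertuples(index=False):
        lo_lon, lo_lat = float(rec.min_lon), float(rec.min_lat)
        hi_lon, hi_lat = float(rec.max_lon), float(rec.max_lat)
        if not (-90 <= lo_lat <= hi_lat <= 90):
            raise ValueError(f"latitude out of range for {rec.species!r}")
        if not (-180 <= lo_lon <= 180 and -180 <= hi_lon <= 180):
            raise ValueError(f"longitude out of range for {rec.species!r}")
        rects = out.setdefault(str(rec.species), [])
        if lo_lon > hi_lon:  # antimeridian crossing: split
            rects.append((lo_lon, lo_lat, 180.0, hi_lat))
            rects.append((-180.0, lo_lat, hi_lon, hi_lat))
        else:
            rects.append((lo_lon, lo_lat, hi_lon, hi_lat))
    return out


def write_ranges_csv(ranges: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("species,min_lon,min_lat,max_lon,max_lat\n")
        for sp in sorted(ranges):
            for rect in ranges[sp]:
                if not (isinstance(rect, tuple) and len(rect) == 4):
                    rect = tuple(box(*rect.bounds).bounds)
                fh.write(sp + "," + ",".join(f"{v:.6f}" for v in rect) + "\n")


def read_ranges_geojson(path) -> dict[str, list]:
    """Read a GeoJSON FeatureCollection; species taken from the
    ``species`` property of each feature."""
    import json

    with open(path) as fh:
        gj = json.load(fh)
    out: dict[str, list] = {}
    for feat in gj.get("features", []):
        sp = feat.get("properties", {}).get("species")
        if sp is None:
            raise ValueError("GeoJSON feature lacks a 'species' property")
        out.setdefault(str(sp), []).append(shape(feat["geometry"]))
    return out


def write_ascii_grid(layer: CellLayer, path, nodata: float = -9999.0) -> None:
    """ESRI ASCII grid; rows are written north-to-south per the format."""
    g = layer.grid
    arr = layer.to_array()
    with open(path, "w") as fh:
        fh.write(f"ncols {g.n_cols}\n")
        fh.write(f"nrows {g.n_rows}\n")
        fh.write(f"xllcorner {g.x0:.6f}\n")
        fh.write(f"yllcorner {g.y0:.6f}\n")
        fh.write(f"cellsize {g.cell_size:.6f}\n")
        fh.write(f"NODATA_value {nodata:g}\n")
        for r in range(g.n_rows - 1, -1, -1):
            row = [
                f"{nodata:g}" if np.isnan(v) else f"{v:.10g}" for v in arr[r]
            ]
            fh.write(" ".join(row) + "\n")


def write_layer_csv(layer: CellLayer, path) -> None:
    with open(path, "w") as fh:
        fh.write("row,col,value\n")
        for (r, c) in sorted(layer.values):
            fh.write(f"{r},{c},{layer.values[(r, c)]:.10g}\n")
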