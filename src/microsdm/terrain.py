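"""Terrain analysis: scattered points → DEM → slope/aspect/TPI → landform classes.

The workflow mirrors a standard microtopographic survey analysis: scattered
GPS elevation points are gridded through a Delaunay triangulation (TIN) into
a fine DEM (default 0.1 m cells), slope and aspect come from Horn's 3×3
finite-difference stencil, and the topographic position index (TPI) over a
circular neighbourhood drives a six-class slope-position map:

====  ============  =========================================
code  class         criterion (TPI in neighbourhood-SD units)
====  ============  =========================================
1     valley        TPI ≤ −0.3
2     lower slope   −0.3 < TPI ≤ −0.05
3     flat slope    −0.05 < TPI ≤ 0.15 and slope ≤ 7°
4     middle slope  −0.05 < TPI ≤ 0.15 and slope > 7°
5     upper slope   0.15 < TPI ≤ 0.4
6     ridge         TPI > 0.4
====  ============  =========================================

The criteria partition the (TPI, slope) plane: every finite pair receives
exactly one code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.interpolate import LinearNDInterpolator
from scipy.ndimage import correlate
from scipy.spatial import QhullError

from .errors import (
    AlignmentError,
    GridSizeError,
    ParameterError,
    TriangulationError,
)
from .raster import RasterGrid

__all__ = [
    "ElevationPointSet",
    "CLASS_CODES",
    "CLASS_NAMES",
    "ASPECT_FLAT",
    "grid_dem",
    "compute_slope",
    "compute_aspect",
    "reclassify_aspect",
    "compute_tpi",
    "classify_microtopography",
    "rasterize_polygons",
    "patches_from_mask",
    "overlay_class_areas",
]

#: Landform class codes and display names (valley → ridge).
CLASS_CODES = {
    "valley": 1,
    "lower slope": 2,
    "flat slope": 3,
    "middle slope": 4,
    "upper slope": 5,
    "ridge": 6,
}
CLASS_NAMES = {v: k for k, v in CLASS_CODES.items()}

#: Sentinel aspect value for cells with zero gradient (no downslope direction).
ASPECT_FLAT = -1.0


@dataclass
class ElevationPointSet:
    """Scattered elevation survey points (x, y, z in metres)."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (self.x.shape == self.y.shape == self.z.shape and self.x.ndim == 1):
            raise ValueError("x, y, z must be equal-length 1-D arrays")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()
                and np.isfinite(self.z).all()):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return self.x.size

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.x, "y": self.y, "z": self.z})

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ElevationPointSet":
        return cls(df["x"].to_numpy(), df["y"].to_numpy(), df["z"].to_numpy())


def grid_dem(points: ElevationPointSet, cell_size: float = 0.1) -> RasterGrid:
    """Grid scattered points into a DEM by TIN (Delaunay) linear interpolation.

    Cell centres outside the convex hull of the points are nodata. Linear
    barycentric interpolation reproduces any plane exactly, so a survey of a
    planar surface grids back to that plane.
    """
    if len(points) < 3:
        raise TriangulationError("need at least 3 points to triangulate")
    if cell_size <= 0:
        raise ParameterError("cell_size must be positive")
    xmin, xmax = points.x.min(), points.x.max()
    ymin, ymax = points.y.min(), points.y.max()
    n_cols = max(int(np.ceil((xmax - xmin) / cell_size)), 1)
    n_rows = max(int(np.ceil((ymax - ymin) / cell_size)), 1)
    grid = RasterGrid(xmin, ymax, cell_size, np.full((n_rows, n_cols), np.nan))
    try:
        interp = LinearNDInterpolator(
            np.column_stack([points.x, points.y]), points.z
        )
    except QhullError as exc:
        raise TriangulationError(f"triangulation failed (collinear input?): {exc}")
    X, Y = grid.center_mesh()
    grid.values[:] = interp(X, Y)
    return grid


def _horn_gradients(dem: RasterGrid) -> tuple[np.ndarray, np.ndarray]:
    """Horn 3×3 gradients (dz/dx eastward, dz/dy northward) at interior cells.

    Cells on the border or adjacent to nodata get NaN gradients.
    """
    if dem.n_rows < 3 or dem.n_cols < 3:
        raise GridSizeError("DEM must be at least 3×3 for slope/aspect")
    z = dem.values
    # NaN in any neighbour propagates automatically through the sums.
    n, s = z[:-2, 1:-1], z[2:, 1:-1]
    w, e = z[1:-1, :-2], z[1:-1, 2:]
    nw, ne = z[:-2, :-2], z[:-2, 2:]
    sw, se = z[2:, :-2], z[2:, 2:]
    eight = 8.0 * dem.cell_size
    dzdx = ((ne + 2 * e + se) - (nw + 2 * w + sw)) / eight
    dzdy = ((nw + 2 * n + ne) - (sw + 2 * s + se)) / eight
    gx = np.full(dem.shape, np.nan)
    gy = np.full(dem.shape, np.nan)
    gx[1:-1, 1:-1] = dzdx
    gy[1:-1, 1:-1] = dzdy
    # focal cell itself must be valid
    gx[~dem.mask] = np.nan
    gy[~dem.mask] = np.nan
    return gx, gy


def compute_slope(dem: RasterGrid) -> RasterGrid:
    """Slope in degrees from Horn's method; border/nodata-adjacent cells nodata."""
    gx, gy = _horn_gradients(dem)
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    return dem.like(slope)


def compute_aspect(dem: RasterGrid) -> RasterGrid:
    """Aspect in degrees clockwise from north (downslope direction).

    Zero-gradient cells carry the sentinel :data:`ASPECT_FLAT` (−1).
    """
    gx, gy = _horn_gradients(dem)
    with np.errstate(invalid="ignore"):
        aspect = np.degrees(np.arctan2(-gx, -gy)) % 360.0
    flat = (gx == 0) & (gy == 0)
    aspect[flat] = ASPECT_FLAT
    return dem.like(aspect)


def reclassify_aspect(aspect: RasterGrid) -> RasterGrid:
    """Reclassify aspect into 4 insolation codes.

    1 = shady (0–45°, 315–360°), 2 = half-shady (225–315°),
    3 = half-sunny (45–135°), 4 = sunny (135–225°). A boundary angle belongs
    to the higher-numbered band (135° → 4). Flat cells → code 1 (no direct
    insolation advantage).
    """
    a = aspect.values
    valid = aspect.mask
    if np.any(valid & (a != ASPECT_FLAT) & ((a < 0) | (a > 360))):
        raise ParameterError("aspect values must lie in [0, 360] or be flat-flagged")
    codes = np.full(aspect.shape, np.nan)
    flat = valid & (a == ASPECT_FLAT)
    ang = np.where(valid & ~flat, a, np.nan)
    # shared boundaries join the higher-numbered band: 45→3, 135→4, 225→4, 315→2
    codes[((ang >= 0) & (ang < 45)) | (ang > 315)] = 1.0   # shady
    codes[(ang > 225) & (ang <= 315)] = 2.0                # half-shady
    codes[(ang >= 45) & (ang < 135)] = 3.0                 # half-sunny
    codes[(ang >= 135) & (ang <= 225)] = 4.0               # sunny
    codes[ang == 360] = 1.0
    codes[flat] = 1.0
    return aspect.like(codes)


def _disc_kernel(radius: float, cell_size: float) -> np.ndarray:
    """Boolean kernel of cells whose centres lie within ``radius`` of the focal
    centre, focal cell excluded."""
    r_cells = int(np.floor(radius / cell_size))
    offs = np.arange(-r_cells, r_cells + 1)
    dy, dx = np.meshgrid(offs, offs, indexing="ij")
    dist2 = (dx * cell_size) ** 2 + (dy * cell_size) ** 2
    kernel = dist2 <= radius**2
    kernel[r_cells, r_cells] = False
    return kernel


def compute_tpi(
    dem: RasterGrid,
    radius: float = 1.0,
    standardize: str = "neighborhood",
    include_focal: bool = False,
    min_neighbors: int = 3,
) -> RasterGrid:
    """Standardised topographic position index over a circular neighbourhood.

    Raw TPI is the focal elevation minus the mean elevation of the valid
    cells whose centres lie within ``radius`` (focal cell excluded by
    default). Standardisation divides by the SD of those neighbourhood
    elevations (``standardize="neighborhood"``) or by the global DEM SD
    (``standardize="global"``). Neighbourhoods with SD = 0 yield a
    standardised TPI of 0; cells with fewer than ``min_neighbors`` valid
    neighbours are nodata.
    """
    if radius < 2 * dem.cell_size:
        raise ParameterError(
            f"TPI radius {radius} must be at least twice the cell size "
            f"({dem.cell_size})"
        )
    if standardize not in ("neighborhood", "global"):
        raise ParameterError("standardize must be 'neighborhood' or 'global'")
    kernel = _disc_kernel(radius, dem.cell_size).astype(float)
    if include_focal:
        kernel[kernel.shape[0] // 2, kernel.shape[1] // 2] = 1.0
    valid = dem.mask.astype(float)
    z = np.where(dem.mask, dem.values, 0.0)
    count = correlate(valid, kernel, mode="constant", cval=0.0)
    zsum = correlate(z, kernel, mode="constant", cval=0.0)
    zsumsq = correlate(z * z, kernel, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = zsum / count
        var = np.maximum(zsumsq / count - mean**2, 0.0)
        sd = np.sqrt(var)
        raw = dem.values - mean
        if standardize == "global":
            g_sd = float(np.nanstd(dem.values))
            std = raw / g_sd if g_sd > 0 else np.zeros_like(raw)
        else:
            std = np.where(sd > 0, raw / sd, 0.0)
    # round counts defensively against float accumulation
    count = np.round(count).astype(int)
    bad = (~dem.mask) | (count < min_neighbors)
    std = np.where(bad, np.nan, std)
    return dem.like(std)


def classify_microtopography(
    tpi_std: RasterGrid,
    slope: RasterGrid,
    tpi_cuts: tuple[float, float, float, float] = (-0.3, -0.05, 0.15, 0.4),
    slope_cut: float = 7.0,
) -> RasterGrid:
    """Six-class slope-position map from standardised TPI and slope (degrees).

    ``tpi_cuts`` are the (valley, lower, middle/flat-vs-upper, ridge)
    thresholds; all upper bounds are inclusive ("≤"). See the module
    docstring for the class table.
    """
    tpi_std.require_alignment(slope, "TPI/slope")
    t1, t2, t3, t4 = tpi_cuts
    if not (t1 < t2 < t3 < t4):
        raise ParameterError("TPI cuts must be strictly increasing")
    t = tpi_std.values
    s = slope.values
    codes = np.full(tpi_std.shape, np.nan)
    both = tpi_std.mask & slope.mask
    codes[both & (t <= t1)] = 1.0
    codes[both & (t > t1) & (t <= t2)] = 2.0
    mid = both & (t > t2) & (t <= t3)
    codes[mid & (s <= slope_cut)] = 3.0
    codes[mid & (s > slope_cut)] = 4.0
    codes[both & (t > t3) & (t <= t4)] = 5.0
    codes[both & (t > t4)] = 6.0
    return tpi_std.like(codes)


def rasterize_polygons(polys, template: RasterGrid) -> RasterGrid:
    """Binary presence grid: 1 where a cell centre lies inside any polygon.

    ``polys`` is a sequence of shapely polygons (or a single geometry). An
    empty sequence yields an all-zero grid. Nodata follows the template.
    """
    out = np.zeros(template.shape, dtype=float)
    geoms = list(polys) if not isinstance(polys, shapely.Geometry) else [polys]
    if geoms:
        union = shapely.union_all(geoms)
        X, Y = template.center_mesh()
        inside = shapely.contains_xy(union, X.ravel(), Y.ravel())
        out = inside.reshape(template.shape).astype(float)
    out[~template.mask] = np.nan
    return template.like(out)


def patches_from_mask(binary: RasterGrid) -> list:
    """Vectorise a binary raster into patch polygons (unions of cell squares).

    Inverse of :func:`rasterize_polygons` under the centre-point rule:
    rasterising the returned polygons on the same grid reproduces the mask.
    """
    rows, cols = np.nonzero(binary.mask & (binary.values == 1))
    if rows.size == 0:
        return []
    cs = binary.cell_size
    x0 = binary.x_origin + cols * cs
    y1 = binary.y_origin - rows * cs
    boxes = shapely.box(x0, y1 - cs, x0 + cs, y1)
    # corner-touching cells make the raw union invalid; the structure-based
    # repair preserves area (the default linework repair drops corner cells)
    union = shapely.make_valid(
        shapely.coverage_union_all(boxes), method="structure"
    )
    out: list = []

    def _collect(g):
        if g.geom_type == "Polygon":
            if g.area > 0:
                out.append(g)
        elif g.geom_type in ("MultiPolygon", "GeometryCollection"):
            for part in g.geoms:
                _collect(part)

    _collect(union)
    return out


def overlay_class_areas(
    classes: RasterGrid, mask: RasterGrid | None = None
) -> pd.DataFrame:
    """Area (m²) and percentage of each landform class, optionally within a mask.

    Percentages are of the total masked valid area and sum to 100; with an
    empty mask areas are 0 and percentages NaN.
    """
    if mask is not None:
        classes.require_alignment(mask, "class/mask")
        sel = classes.mask & mask.mask & (mask.values == 1)
    else:
        sel = classes.mask
    rows = []
    total_cells = int(sel.sum())
    for name, code in CLASS_CODES.items():
        n = int((sel & (classes.values == code)).sum())
        area = n * classes.cell_area
        pct = 100.0 * n / total_cells if total_cells > 0 else np.nan
        rows.append({"class_code": code, "class_name": name,
                     "area_m2": area, "percentage": pct})
    return pd.DataFrame(rows)
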