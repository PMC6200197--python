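import numpy as np
import pytest
import shapely
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Polygon, box

from microsdm.errors import (
    AlignmentError,
    ParameterError,
    TriangulationError,
)
from microsdm.raster import RasterGrid
from microsdm.terrain import (
    ASPECT_FLAT,
    CLASS_CODES,
    ElevationPointSet,
    classify_microtopography,
    compute_aspect,
    compute_slope,
    compute_tpi,
    grid_dem,
    overlay_class_areas,
    patches_from_mask,
    rasterize_polygons,
    reclassify_aspect,
)

# ---------------------------------------------------------------- grid_dem


def test_grid_dem_reproduces_plane():
    rng = np.random.default_rng(1)
    x = rng.uniform(0, 5, 300)
    y = rng.uniform(0, 5, 300)
    pts = ElevationPointSet(x, y, 2 * x + 3 * y + 1)
    dem = grid_dem(pts, 0.1)
    X, Y = dem.center_mesh()
    expected = 2 * X + 3 * Y + 1
    assert np.nanmax(np.abs(dem.values - expected)) < 1e-10


def test_grid_dem_three_points_unique_plane():
    pts = ElevationPointSet([0.0, 4.0, 0.0], [0.0, 0.0, 4.0], [1.0, 9.0, 13.0])
    # plane through the three points: z = 1 + 2x + 3y
    dem = grid_dem(pts, 0.5)
    X, Y = dem.center_mesh()
    inside = dem.mask
    assert inside.sum() > 0
    np.testing.assert_allclose(
        dem.values[inside], (1 + 2 * X + 3 * Y)[inside], atol=1e-12
    )


def test_grid_dem_collinear_raises():
    pts = ElevationPointSet([0.0, 1.0, 2.0], [0.0, 1.0, 2.0], [0.0, 1.0, 2.0])
    with pytest.raises(TriangulationError):
        grid_dem(pts, 0.1)


def _barycentric_oracle(px, py, tri_pts, tri_z):
    """Brute-force barycentric interpolation over one containing triangle."""
    from itertools import combinations

    for (i, j, k) in combinations(range(len(tri_pts)), 3):
        (x1, y1), (x2, y2), (x3, y3) = tri_pts[i], tri_pts[j], tri_pts[k]
        det = (y2 - y3) * (x1 - x3) + (x3 - x2) * (y1 - y3)
        if abs(det) < 1e-12:
            continue
        l1 = ((y2 - y3) * (px - x3) + (x3 - x2) * (py - y3)) / det
        l2 = ((y3 - y1) * (px - x3) + (x1 - x3) * (py - y3)) / det
        l3 = 1 - l1 - l2
        if min(l1, l2, l3) >= -1e-12:
            return l1 * tri_z[i] + l2 * tri_z[j] + l3 * tri_z[k]
    return np.nan


def test_grid_dem_matches_barycentric_oracle():
    """On the Delaunay triangles themselves, linear gridding equals direct
    barycentric evaluation."""
    from scipy.spatial import Delaunay

    rng = np.random.default_rng(3)
    x = rng.uniform(0, 3, 15)
    y = rng.uniform(0, 3, 15)
    z = rng.normal(0, 1, 15)
    dem = grid_dem(ElevationPointSet(x, y, z), 0.25)
    tri = Delaunay(np.column_stack([x, y]))
    X, Y = dem.center_mesh()
    probes = [(r, c) for r in range(0, dem.n_rows, 3)
              for c in range(0, dem.n_cols, 3)]
    checked = 0
    for r, c in probes:
        if not dem.mask[r, c] or checked >= 20:
            continue
        s = tri.find_simplex(np.array([[X[r, c], Y[r, c]]]))[0]
        if s < 0:
            continue
        verts = tri.simplices[s]
        oracle = _barycentric_oracle(
            X[r, c], Y[r, c],
            [(x[v], y[v]) for v in verts], [z[v] for v in verts],
        )
        assert dem.values[r, c] == pytest.approx(oracle, abs=1e-10)
        checked += 1
    assert checked >= 10


# ------------------------------------------------------------ slope/aspect


def _plane_grid(a, b, shape=(8, 8), cs=0.1):
    g = RasterGrid(0, shape[0] * cs, cs, np.zeros(shape))
    X, Y = g.center_mesh()
    return g.like(a * X + b * Y)


def test_slope_flat_and_unit_plane():
    flat = RasterGrid(0, 1, 0.1, np.zeros((8, 8)))
    s = compute_slope(flat)
    assert np.nanmax(np.abs(s.values)) == 0.0
    ramp = _plane_grid(1.0, 0.0)
    s = compute_slope(ramp)
    inner = s.values[1:-1, 1:-1]
    np.testing.assert_allclose(inner, 45.0, atol=1e-9)
    assert np.isnan(s.values[0]).all()  # border nodata


def _horn_oracle(z, r, c, cs):
    a, b_, c_ = z[r - 1, c - 1], z[r - 1, c], z[r - 1, c + 1]
    d, f = z[r, c - 1], z[r, c + 1]
    g, h, i = z[r + 1, c - 1], z[r + 1, c], z[r + 1, c + 1]
    dzdx = ((c_ + 2 * f + i) - (a + 2 * d + g)) / (8 * cs)
    dzdy = ((a + 2 * b_ + c_) - (g + 2 * h + i)) / (8 * cs)
    return np.degrees(np.arctan(np.hypot(dzdx, dzdy)))


def test_slope_matches_horn_oracle(random_grid):
    s = compute_slope(random_grid)
    rng = np.random.default_rng(0)
    for _ in range(10):
        r = rng.integers(1, random_grid.n_rows - 1)
        c = rng.integers(1, random_grid.n_cols - 1)
        assert s.values[r, c] == pytest.approx(
            _horn_oracle(random_grid.values, r, c, 0.1), abs=1e-10
        )


@pytest.mark.parametrize(
    "a,b,expected",
    [
        (0.0, 1.0, 180.0),   # rises north → descends due south
        (1.0, 0.0, 270.0),   # rises east → descends due west
        (-1.0, 0.0, 90.0),   # descends due east
    ],
)
def test_aspect_cardinal_planes(a, b, expected):
    asp = compute_aspect(_plane_grid(a, b))
    inner = asp.values[1:-1, 1:-1]
    np.testing.assert_allclose(inner, expected, atol=1e-9)


def test_aspect_flat_flagged():
    flat = RasterGrid(0, 1, 0.1, np.full((6, 6), 3.7))
    asp = compute_aspect(flat)
    inner = asp.values[1:-1, 1:-1]
    assert (inner == ASPECT_FLAT).all()


@pytest.mark.parametrize(
    "angle,code",
    [
        (180.0, 4), (10.0, 1), (90.0, 3), (350.0, 1),
        (45.0, 3), (135.0, 4), (225.0, 4), (315.0, 2), (260.0, 2),
        (0.0, 1), (360.0, 1), (ASPECT_FLAT, 1),
    ],
)
def test_reclassify_aspect_bands(angle, code):
    g = RasterGrid(0, 1, 0.1, np.full((2, 2), angle))
    out = reclassify_aspect(g)
    assert (out.values == code).all()


def test_reclassify_aspect_out_of_range():
    g = RasterGrid(0, 1, 0.1, np.full((2, 2), 400.0))
    with pytest.raises(ParameterError):
        reclassify_aspect(g)


# ---------------------------------------------------------------------- TPI


def test_tpi_constant_dem_zero(gully_dem):
    flat = RasterGrid(0, 3, 0.1, np.full((30, 30), 5.0))
    tpi = compute_tpi(flat, 1.0)
    assert np.nanmax(np.abs(tpi.values)) == 0.0


def test_tpi_linear_ramp_zero_interior():
    ramp = _plane_grid(1.0, 0.5, shape=(40, 40), cs=0.1)
    tpi = compute_tpi(ramp, 0.5)
    # symmetric neighbourhood mean equals the centre on a linear ramp
    r = 6  # cells within full-disc reach of the border
    inner = tpi.values[r:-r, r:-r]
    np.testing.assert_allclose(inner, 0.0, atol=1e-9)


def test_tpi_radius_too_small():
    g = RasterGrid(0, 1, 0.1, np.zeros((10, 10)))
    with pytest.raises(ParameterError):
        compute_tpi(g, 0.15)


def _tpi_oracle(dem, radius, r, c):
    """Literal per-cell disc loop (focal excluded, neighbourhood SD)."""
    zs = []
    for i in range(dem.n_rows):
        for j in range(dem.n_cols):
            if (i, j) == (r, c) or np.isnan(dem.values[i, j]):
                continue
            d2 = ((i - r) * dem.cell_size) ** 2 + ((j - c) * dem.cell_size) ** 2
            if d2 <= radius**2:
                zs.append(dem.values[i, j])
    if len(zs) < 3:
        return np.nan
    zs = np.array(zs)
    raw = dem.values[r, c] - zs.mean()
    sd = zs.std()
    return raw / sd if sd > 0 else 0.0


def test_tpi_matches_bruteforce_disc(random_grid):
    tpi = compute_tpi(random_grid, 0.45)
    rng = np.random.default_rng(5)
    for _ in range(10):
        r = int(rng.integers(0, random_grid.n_rows))
        c = int(rng.integers(0, random_grid.n_cols))
        oracle = _tpi_oracle(random_grid, 0.45, r, c)
        assert tpi.values[r, c] == pytest.approx(oracle, abs=1e-9)


def test_tpi_nodata_neighbourhoods():
    vals = np.full((10, 10), np.nan)
    vals[4, 4] = 1.0
    vals[4, 5] = 2.0
    g = RasterGrid(0, 1, 0.1, vals)
    tpi = compute_tpi(g, 0.3)
    assert np.isnan(tpi.values).all()  # fewer than 3 valid neighbours anywhere


# ------------------------------------------------------------ classification


@pytest.mark.parametrize(
    "tpi,slope,expected",
    [
        (0.5, 5.0, "ridge"),
        (0.0, 10.0, "middle slope"),
        (0.0, 3.0, "flat slope"),
        (-0.5, 20.0, "valley"),
        (-0.3, 1.0, "valley"),        # inclusive upper bound
        (-0.05, 9.0, "lower slope"),
        (0.15, 8.0, "middle slope"),
        (0.4, 0.0, "upper slope"),
        (7.0, 7.0, "ridge"),
    ],
)
def test_classification_criteria(tpi, slope, expected):
    t = RasterGrid(0, 1, 0.1, np.full((2, 2), tpi))
    s = RasterGrid(0, 1, 0.1, np.full((2, 2), slope))
    out = classify_microtopography(t, s)
    assert (out.values == CLASS_CODES[expected]).all()


@given(
    tpi=st.floats(-3, 3, allow_nan=False),
    slope=st.floats(0, 90, allow_nan=False),
)
@settings(max_examples=300, deadline=None, derandomize=True)
def test_classification_total_and_exclusive(tpi, slope):
    """Every finite (TPI, slope) pair receives exactly one class code."""
    t = RasterGrid(0, 1, 0.1, np.array([[tpi]]))
    s = RasterGrid(0, 1, 0.1, np.array([[slope]]))
    out = classify_microtopography(t, s)
    assert out.values[0, 0] in set(CLASS_CODES.values())


def test_classification_threshold_straddle_grid():
    cuts = [-0.3, -0.05, 0.15, 0.4]
    eps = 1e-9
    tpis = sorted({c + d for c in cuts for d in (-eps, 0.0, eps)} | {-2.0, 0.0, 2.0})
    slopes = [7.0 - eps, 7.0, 7.0 + eps, 0.0, 45.0]
    t = RasterGrid(0, 1, 0.1, np.array([[v for v in tpis] for _ in slopes]))
    s = RasterGrid(0, 1, 0.1, np.array([[sv] * len(tpis) for sv in slopes]))
    out = classify_microtopography(t, s)
    assert not np.isnan(out.values).any()
    assert set(np.unique(out.values)) <= set(float(c) for c in CLASS_CODES.values())


def test_classification_alignment_error():
    t = RasterGrid(0, 1, 0.1, np.zeros((3, 3)))
    s = RasterGrid(0, 2, 0.1, np.zeros((3, 3)))
    with pytest.raises(AlignmentError):
        classify_microtopography(t, s)


# ------------------------------------------------------------- rasterization


def test_rasterize_aligned_square():
    template = RasterGrid(0, 3, 0.1, np.zeros((30, 30)))
    square = box(1.0, 1.0, 2.0, 2.0)  # 1 m² aligned to cell boundaries
    out = rasterize_polygons([square], template)
    assert int(out.values.sum()) == 100


def test_rasterize_outside_and_empty():
    template = RasterGrid(0, 1, 0.1, np.zeros((10, 10)))
    far = box(100, 100, 101, 101)
    assert rasterize_polygons([far], template).values.sum() == 0
    assert rasterize_polygons([], template).values.sum() == 0


def _ray_cast(poly_coords, px, py):
    """Crossing-number point-in-polygon oracle."""
    inside = False
    n = len(poly_coords)
    for i in range(n):
        x1, y1 = poly_coords[i]
        x2, y2 = poly_coords[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < xint:
                inside = not inside
    return inside


def test_rasterize_matches_raycast_oracle():
    rng = np.random.default_rng(9)
    coords = [(0.3, 0.2), (2.7, 0.5), (2.2, 2.6), (1.1, 1.4), (0.2, 2.2)]
    poly = Polygon(coords)
    template = RasterGrid(0, 3, 0.1, np.zeros((30, 30)))
    out = rasterize_polygons([poly], template)
    X, Y = template.center_mesh()
    for _ in range(20):
        r = int(rng.integers(0, 30))
        c = int(rng.integers(0, 30))
        assert bool(out.values[r, c]) == _ray_cast(coords, X[r, c], Y[r, c])


def test_patches_roundtrip_random_mask():
    rng = np.random.default_rng(4)
    vals = (rng.random((25, 25)) < 0.4).astype(float)
    g = RasterGrid(0, 2.5, 0.1, vals)
    polys = patches_from_mask(g)
    back = rasterize_polygons(polys, g)
    np.testing.assert_array_equal(back.values, vals)


# ------------------------------------------------------------ area accounting


def test_overlay_counts_and_percentages():
    codes = np.full((10, 10), 4.0)
    codes[:5, :] = 1.0  # 50 valley cells
    classes = RasterGrid(0, 1, 0.1, codes)
    mask = RasterGrid(0, 1, 0.1, np.ones((10, 10)))
    table = overlay_class_areas(classes, mask)
    valley = table[table.class_name == "valley"].iloc[0]
    assert valley.area_m2 == pytest.approx(0.5)
    assert valley.percentage == pytest.approx(50.0)
    assert table.percentage.sum() == pytest.approx(100.0, abs=1e-9)


def test_overlay_single_class_and_empty_mask():
    classes = RasterGrid(0, 1, 0.1, np.full((5, 5), 6.0))
    table = overlay_class_areas(classes)
    ridge = table[table.class_name == "ridge"].iloc[0]
    assert ridge.percentage == pytest.approx(100.0)
    empty = RasterGrid(0, 1, 0.1, np.zeros((5, 5)))
    t2 = overlay_class_areas(classes, empty)
    assert (t2.area_m2 == 0).all()
    assert t2.percentage.isna().all()


def test_overlay_area_conservation(gully_dem, gully_tpi, gully_slope):
    classes = classify_microtopography(gully_tpi, gully_slope)
    table = overlay_class_areas(classes)
    assert table.area_m2.sum() == pytest.approx(classes.n_valid * 0.01)
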