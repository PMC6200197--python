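import numpy as np
import pandas as pd
import pytest

from microsdm.errors import DesignError, InvalidSpecError, PlacementError
from microsdm.sdm import PresenceAbsenceGLM, build_training
from microsdm.synthetic import (
    DEFAULT_FACTOR_FIELDS,
    ResponseSpec,
    TerrainSpec,
    generate_factor_fields,
    generate_presence,
    generate_sampling_design,
    generate_terrain,
    generate_trenches,
    sample_stack,
    trench_count_for_area,
)
from microsdm.terrain import (
    CLASS_CODES,
    classify_microtopography,
    compute_slope,
    compute_tpi,
    grid_dem,
)

# ------------------------------------------------------------------ terrain


def test_terrain_deterministic_under_seed():
    spec = TerrainSpec(extent_x=5, extent_y=5, n_points=200, seed=3)
    a = generate_terrain(spec)
    b = generate_terrain(spec)
    np.testing.assert_array_equal(a.x, b.x)
    np.testing.assert_array_equal(a.z, b.z)


def test_terrain_respects_min_spacing():
    spec = TerrainSpec(extent_x=5, extent_y=5, n_points=150, min_spacing=0.2,
                       seed=1)
    pts = generate_terrain(spec)
    from scipy.spatial.distance import pdist

    assert pdist(np.column_stack([pts.x, pts.y])).min() >= 0.2


@pytest.mark.parametrize(
    "kwargs",
    [dict(extent_x=-1.0), dict(n_points=5), dict(n_gullies=0),
     dict(noise_sd=-0.1)],
)
def test_terrain_invalid_specs(kwargs):
    with pytest.raises(InvalidSpecError):
        generate_terrain(TerrainSpec(**kwargs))


def test_noiseless_single_gully_band_structure():
    """One cosine period: a central valley band flanked by ridge bands."""
    spec = TerrainSpec(extent_x=8, extent_y=8, n_gullies=1, ridge_amplitude=1.0,
                       base_slope=0.05, noise_sd=0.0, n_points=900, seed=2,
                       taper=False)
    dem = grid_dem(generate_terrain(spec), 0.1)
    tpi = compute_tpi(dem, 1.0)
    micro = classify_microtopography(tpi, compute_slope(dem))
    X, Y = micro.center_mesh()
    # judge band structure away from the 1 m border, where neighbourhood
    # truncation distorts TPI on a trended surface
    inner = (Y > 1) & (Y < 7)
    valley = (micro.values == CLASS_CODES["valley"]) & inner
    ridge = (micro.values == CLASS_CODES["ridge"]) & inner
    assert valley.sum() > 0 and ridge.sum() > 0
    # cos(2πx/L): minimum at x = L/2 (valley), maxima at the edges (ridges)
    assert np.all(np.abs(X[valley] - 4.0) < 2.0)
    assert np.all(np.abs(X[ridge] - 4.0) > 2.0)


def test_flat_spec_classifies_everything_flat_slope():
    spec = TerrainSpec(extent_x=5, extent_y=5, ridge_amplitude=0.0,
                       base_slope=0.0, noise_sd=0.0, n_points=400, seed=4)
    dem = grid_dem(generate_terrain(spec), 0.1)
    tpi = compute_tpi(dem, 1.0)
    micro = classify_microtopography(tpi, compute_slope(dem))
    vals = micro.values[micro.mask]
    assert set(np.unique(vals)) == {float(CLASS_CODES["flat slope"])}


# ------------------------------------------------------------- factor fields


@pytest.fixture(scope="module")
def small_terrain():
    spec = TerrainSpec(extent_x=6, extent_y=6, n_gullies=1, ridge_amplitude=0.8,
                       base_slope=0.1, noise_sd=0.0, n_points=600, seed=11)
    dem = grid_dem(generate_terrain(spec), 0.1)
    tpi = compute_tpi(dem, 1.0)
    return dem, tpi


def test_noiseless_factor_is_exact_affine_in_tpi(small_terrain):
    dem, tpi = small_terrain
    stack = generate_factor_fields(
        dem, tpi, directions={"f": +1}, noise_sd_per_factor={"f": 0.0},
        means={"f": 2.0}, amplitudes={"f": 1.5}, seed=0,
    )
    ok = stack.valid_mask()
    zt = (tpi.values - tpi.values[tpi.mask].mean()) / tpi.values[tpi.mask].std()
    resid = stack["f"].values[ok] - (2.0 + 1.5 * zt[ok])
    assert np.max(np.abs(resid)) == 0.0


def test_noiseless_factor_monotone_in_tpi(small_terrain):
    dem, tpi = small_terrain
    stack = generate_factor_fields(
        dem, tpi, directions={"up": +1, "down": -1},
        noise_sd_per_factor={"up": 0.0, "down": 0.0}, seed=0,
    )
    ok = stack.valid_mask()
    order = np.argsort(tpi.values[ok])
    assert (np.diff(stack["up"].values[ok][order]) >= 0).all()
    assert (np.diff(stack["down"].values[ok][order]) <= 0).all()


def test_moisture_higher_in_valley_than_ridge(small_terrain):
    """Spring soil moisture declines valley → ridge (direction −1)."""
    dem, tpi = small_terrain
    stack = generate_factor_fields(dem, tpi, seed=1)
    slope = compute_slope(dem)
    micro = classify_microtopography(tpi, slope)
    um = stack["UM_avg_spring"].values
    valley = micro.values == CLASS_CODES["valley"]
    ridge = micro.values == CLASS_CODES["ridge"]
    assert np.nanmean(um[valley]) > np.nanmean(um[ridge])


def test_default_fields_cover_26_factors(small_terrain):
    dem, tpi = small_terrain
    stack = generate_factor_fields(dem, tpi, seed=0)
    assert len(stack) == 26
    assert len(DEFAULT_FACTOR_FIELDS) == 26


def test_invalid_direction_rejected(small_terrain):
    dem, tpi = small_terrain
    with pytest.raises(InvalidSpecError):
        generate_factor_fields(dem, tpi, directions={"f": 0})


def test_label_independent_factors_give_chance_auc():
    """Noise-only factors (labels independent of them) fit to AUC ≈ 0.5."""
    spec = TerrainSpec(extent_x=10, extent_y=10, n_points=1000, seed=13,
                       noise_sd=0.0)
    dem = grid_dem(generate_terrain(spec), 0.1)
    tpi = compute_tpi(dem, 1.0)
    stack = generate_factor_fields(
        dem, tpi, directions={"n1": +1, "n2": -1},
        amplitudes={"n1": 0.0, "n2": 0.0},
        noise_sd_per_factor={"n1": 1.0, "n2": 1.0},
        noise_correlation_m=0.0, seed=5,
    )
    presence = generate_presence(stack, ResponseSpec({"n1": 0.0}, 0.0, seed=6))
    n_cells = int(stack.valid_mask().sum())
    assert n_cells >= 5000
    res = PresenceAbsenceGLM(build_training(presence, stack)).fit()
    assert res.training_auc == pytest.approx(0.5, abs=0.05)


# ----------------------------------------------------------------- presence


def test_presence_saturated_intercept(small_terrain):
    dem, tpi = small_terrain
    stack = generate_factor_fields(dem, tpi, seed=0)
    pres = generate_presence(stack, ResponseSpec({"pH": 0.0}, intercept=10.0,
                                                 seed=0))
    vals = pres.values[pres.mask]
    assert (vals == 1).all()


def test_presence_prevalence_half_at_zero_intercept():
    spec = TerrainSpec(extent_x=12, extent_y=12, n_points=2000, seed=7,
                       noise_sd=0.0)
    dem = grid_dem(generate_terrain(spec), 0.1)
    tpi = compute_tpi(dem, 1.0)
    stack = generate_factor_fields(dem, tpi, directions={"f": +1}, seed=1)
    pres = generate_presence(stack, ResponseSpec({"f": 0.0}, 0.0, seed=2))
    vals = pres.values[pres.mask]
    assert vals.size >= 10_000
    assert vals.mean() == pytest.approx(0.5, abs=0.02)


def test_presence_concentrates_in_valleys(small_terrain):
    dem, tpi = small_terrain
    stack = generate_factor_fields(dem, tpi, seed=3)
    # strong positive response to a factor that is high in valleys (dir −1)
    pres = generate_presence(stack, ResponseSpec({"UM_avg_spring": 3.0},
                                                 0.0, seed=4))
    micro = classify_microtopography(tpi, compute_slope(dem))
    valley = micro.values == CLASS_CODES["valley"]
    ridge = micro.values == CLASS_CODES["ridge"]
    assert np.nanmean(pres.values[valley]) > np.nanmean(pres.values[ridge])


def test_presence_unknown_factor_rejected(small_terrain):
    dem, tpi = small_terrain
    stack = generate_factor_fields(dem, tpi, seed=0)
    with pytest.raises(InvalidSpecError):
        generate_presence(stack, ResponseSpec({"nope": 1.0}))


def test_presence_deterministic_under_seed(small_terrain):
    dem, tpi = small_terrain
    stack = generate_factor_fields(dem, tpi, seed=0)
    resp = ResponseSpec({"pH": 1.0}, -0.5, seed=9)
    a = generate_presence(stack, resp)
    b = generate_presence(stack, resp)
    np.testing.assert_array_equal(a.values, b.values)


# ------------------------------------------------------------ sampling design


@pytest.fixture(scope="module")
def microtopo_map(small_terrain):
    dem, tpi = small_terrain
    return classify_microtopography(tpi, compute_slope(dem))


def test_design_default_yields_54_points(microtopo_map):
    design = generate_sampling_design(microtopo_map, seed=0)
    assert len(design) == 54
    counts = design.groupby(["gully_type", "microtopo"]).size()
    assert (counts == 9).all()


def test_design_small_arithmetic(microtopo_map):
    design = generate_sampling_design(microtopo_map, n_per_class=1, seed=0)
    assert len(design) == 6  # 1 × 3 classes × 2 gully types


def test_design_insufficient_class_named():
    from microsdm.raster import RasterGrid

    flat = RasterGrid(0, 2, 0.1, np.full((20, 20), CLASS_CODES["flat slope"]))
    with pytest.raises(DesignError, match="valley"):
        generate_sampling_design(flat, seed=0)


def test_sample_stack_reads_cell_values(small_terrain, microtopo_map):
    dem, tpi = small_terrain
    stack = generate_factor_fields(dem, tpi, seed=0)
    design = generate_sampling_design(microtopo_map, n_per_class=2, seed=1)
    samples = sample_stack(stack, design)
    for _, row in samples.iterrows():
        assert row["pH"] == stack["pH"].values[int(row["row"]), int(row["col"])]


# ---------------------------------------------------------------- trenches


def test_single_trench_area(small_terrain):
    dem, _ = small_terrain
    trenches = generate_trenches(dem, 1, seed=0)
    assert len(trenches) == 1
    assert trenches[0].area == pytest.approx(2.0)  # 4.0 m × 0.5 m


def test_no_trenches_empty_list(small_terrain):
    dem, _ = small_terrain
    assert generate_trenches(dem, 0, seed=0) == []


def test_trenches_disjoint_and_inside(small_terrain):
    dem, _ = small_terrain
    trenches = generate_trenches(dem, 5, seed=1)
    assert len(trenches) == 5
    for i in range(5):
        for j in range(i + 1, 5):
            assert not trenches[i].intersects(trenches[j])
        x0, y0, x1, y1 = trenches[i].bounds
        assert x0 >= 0 and y0 >= 0 and x1 <= 6 and y1 <= 6


def test_trench_density_scaling():
    assert trench_count_for_area(600.0) == 36     # 600 per hectare
    assert trench_count_for_area(10_000.0) == 600
    assert trench_count_for_area(100.0) == 6


def test_trench_placement_error_when_too_big(small_terrain):
    dem, _ = small_terrain
    with pytest.raises(PlacementError):
        generate_trenches(dem, 1, length_m=50.0, seed=0)


def test_trenches_deterministic(small_terrain):
    dem, _ = small_terrain
    a = generate_trenches(dem, 3, seed=5)
    b = generate_trenches(dem, 3, seed=5)
    assert all(p.equals(q) for p, q in zip(a, b))
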