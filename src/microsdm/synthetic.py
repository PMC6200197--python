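"""Synthetic study-system generator.

Emulates every input of the analysis so the full pipeline is testable
end-to-end without field data:

* **Terrain** — a planar hillslope crossed by sinusoidal ridge/valley
  gullies, surveyed by quasi-uniform scattered points with survey noise.
  This is the simplest surface producing all six landform classes.
* **Factor fields** — each soil/microclimate factor is an affine function
  of standardised TPI (sign chosen per its observed valley→ridge gradient)
  plus Gaussian noise; defaults encode realistic means, amplitudes, and
  gradient directions for 8 soil and 18 microclimate factors (underground
  temperature UT in °C and moisture UM in % by season).
* **Presence** — Bernoulli draws from a known logistic response on
  z-scored factors, giving ground truth for parameter-recovery tests.
* **Sampling design** — stratified points (default 9 per landform class ×
  3 classes × 2 gully types = 54), mirroring a paired gully survey.
* **Trenches** — non-overlapping contour-aligned level-trench rectangles
  (default 4.0 m × 0.5 m, density 600 per hectare).

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.affinity import rotate
from shapely.geometry import Polygon, box

from .errors import DesignError, InvalidSpecError, PlacementError
from .raster import RasterGrid
from .sdm import FactorStack
from .terrain import CLASS_CODES, ElevationPointSet

__all__ = [
    "TerrainSpec",
    "ResponseSpec",
    "DEFAULT_FACTOR_FIELDS",
    "generate_terrain",
    "generate_factor_fields",
    "generate_presence",
    "generate_sampling_design",
    "generate_trenches",
    "trench_count_for_area",
    "sample_stack",
]


@dataclass
class TerrainSpec:
    """Gullied-hillslope terrain specification.

    The surface is ``z = base_slope·y + ridge_amplitude·e(y)·cos(2π·
    n_gullies·x / extent_x) + N(0, noise_sd)`` sampled at ``n_points``
    scattered points, so ridges run down-slope at the extent edges and
    between gullies. With ``taper=True`` (default) the envelope
    ``e(y) = y / extent_y`` deepens the gullies downslope, the way erosion
    incises a hillslope: the crest zone stays planar, which is what puts
    flat-slope and middle-slope cells on the map alongside the
    valley/slope/ridge positions.
    """

    extent_x: float = 24.0
    extent_y: float = 24.0
    n_gullies: int = 3
    ridge_amplitude: float = 1.2
    base_slope: float = 0.12
    noise_sd: float = 0.02
    n_points: int = 3358
    min_spacing: float = 0.05
    taper: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.extent_x <= 0 or self.extent_y <= 0:
            raise InvalidSpecError("extents must be positive")
        if self.n_points < 10:
            raise InvalidSpecError("need at least 10 survey points")
        if self.n_gullies < 1:
            raise InvalidSpecError("need at least one gully")
        if self.noise_sd < 0 or self.min_spacing < 0:
            raise InvalidSpecError("noise_sd and min_spacing must be non-negative")


@dataclass
class ResponseSpec:
    """Ground-truth logistic response for presence generation.

    ``true_coefficients`` are on the z-scored factor scale; the intercept
    is in logit units.
    """

    true_coefficients: dict[str, float]
    intercept: float = 0.0
    seed: int = 0


#: Factor-field defaults: name → (mean, amplitude, direction, noise_sd).
#: Directions encode the valley→ridge gradients of a degraded gullied
#: hillslope: soils ridge-ward (warmer, drier in the growing season,
#: poorer, slightly less acid), valleys milder and more fertile.
DEFAULT_FACTOR_FIELDS: dict[str, tuple[float, float, int, float]] = {
    # 18 microclimate factors: {max,min,avg} UT/UM × season
    "UT_max_spring": (29.5, 2.5, +1, 1.25),
    "UT_min_spring": (16.1, 0.25, -1, 0.12),
    "UT_avg_spring": (21.2, 0.8, +1, 0.4),
    "UT_max_summer_autumn": (37.2, 3.0, +1, 1.5),
    "UT_min_summer_autumn": (23.2, 0.15, -1, 0.3),
    "UT_avg_summer_autumn": (27.9, 0.95, +1, 0.45),
    "UT_max_winter": (25.4, 2.2, +1, 1.1),
    "UT_min_winter": (8.5, 0.1, +1, 0.6),
    "UT_avg_winter": (13.9, 0.4, +1, 0.2),
    "UM_max_spring": (25.8, 4.3, -1, 3.0),
    "UM_min_spring": (10.6, 2.3, -1, 1.5),
    "UM_avg_spring": (13.3, 2.4, -1, 1.2),
    "UM_max_summer_autumn": (21.9, 2.0, -1, 2.0),
    "UM_min_summer_autumn": (12.4, 3.7, -1, 1.9),
    "UM_avg_summer_autumn": (15.5, 3.4, -1, 1.7),
    "UM_max_winter": (10.9, 2.3, +1, 2.0),
    "UM_min_winter": (8.2, 2.1, +1, 1.8),
    "UM_avg_winter": (9.4, 2.1, +1, 1.8),
    # 8 soil factors
    "organic_matter": (5.5, 3.6, -1, 1.8),
    "N_total": (0.40, 0.18, -1, 0.09),
    "N_avail": (39.8, 15.6, -1, 7.8),
    "P_total": (0.11, 0.02, +1, 0.03),
    "P_avail": (0.065, 0.025, -1, 0.02),
    "K_total": (2.07, 0.085, +1, 0.3),
    "K_avail": (11.7, 6.4, -1, 3.2),
    "pH": (4.51, 0.10, +1, 0.05),
}

SOIL_FACTORS = ["organic_matter", "N_total", "N_avail", "P_total",
                "P_avail", "K_total", "K_avail", "pH"]
MICROCLIMATE_FACTORS = [n for n in DEFAULT_FACTOR_FIELDS if n not in SOIL_FACTORS]


def generate_terrain(spec: TerrainSpec) -> ElevationPointSet:
    """Scatter survey points over a sinusoidally gullied hillslope.

    Points are uniform with a minimum-spacing rejection rule so the
    Delaunay gridding downstream is well-conditioned. Deterministic per
    (spec, seed).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    xs, ys = [], []
    cell = max(spec.min_spacing, 1e-9)
    occupied: dict[tuple[int, int], list[tuple[float, float]]] = {}
    attempts, max_attempts = 0, 200 * spec.n_points
    sp2 = spec.min_spacing**2
    while len(xs) < spec.n_points and attempts < max_attempts:
        attempts += 1
        px = rng.uniform(0.0, spec.extent_x)
        py = rng.uniform(0.0, spec.extent_y)
        ci, cj = int(px / cell), int(py / cell)
        ok = True
        if spec.min_spacing > 0:
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    for qx, qy in occupied.get((ci + di, cj + dj), ()):
                        if (px - qx) ** 2 + (py - qy) ** 2 < sp2:
                            ok = False
                            break
        if not ok:
            continue
        occupied.setdefault((ci, cj), []).append((px, py))
        xs.append(px)
        ys.append(py)
    if len(xs) < spec.n_points:
        raise InvalidSpecError(
            f"could not place {spec.n_points} points with spacing "
            f"{spec.min_spacing} in the extent"
        )
    x = np.array(xs)
    y = np.array(ys)
    envelope = y / spec.extent_y if spec.taper else 1.0
    z = (
        spec.base_slope * y
        + spec.ridge_amplitude * envelope
        * np.cos(2 * np.pi * spec.n_gullies * x / spec.extent_x)
        + rng.normal(0.0, spec.noise_sd, size=x.size)
    )
    return ElevationPointSet(x, y, z)


def _standardized(grid: RasterGrid) -> np.ndarray:
    v = grid.values
    m = grid.mask
    mu = float(v[m].mean())
    sd = float(v[m].std())
    return (v - mu) / sd if sd > 0 else np.zeros_like(v)


def _correlated_noise(shape, sd: float, corr_cells: float, rng) -> np.ndarray:
    """Spatially correlated Gaussian field (smoothed white noise, unit
    variance rescaled to ``sd``)."""
    from scipy.ndimage import gaussian_filter

    white = rng.normal(0.0, 1.0, size=shape)
    if corr_cells <= 0:
        return sd * white
    smooth = gaussian_filter(white, corr_cells, mode="nearest")
    s = smooth.std()
    return sd * smooth / s if s > 0 else np.zeros(shape)


def generate_factor_fields(
    dem: RasterGrid,
    tpi: RasterGrid,
    directions: dict[str, int] | None = None,
    noise_sd_per_factor: dict[str, float] | None = None,
    seed: int = 0,
    means: dict[str, float] | None = None,
    amplitudes: dict[str, float] | None = None,
    noise_correlation_m: float = 4.0,
) -> FactorStack:
    """Factor layers as affine functions of standardised TPI plus noise.

    With ``directions=None`` the 26 defaults of
    :data:`DEFAULT_FACTOR_FIELDS` are generated. The Gaussian noise field
    of each factor is spatially correlated (``noise_correlation_m``,
    default 4 m, comparable to the spacing of a 54-point design over this
    extent) — soil and microclimate variability is structured in space,
    which is what makes point-sample interpolation meaningful.
    Noiseless layers have Spearman correlation with TPI exactly equal to
    their direction.
    """
    dem.require_alignment(tpi, "DEM/TPI")
    if directions is None:
        directions = {n: d for n, (_, _, d, _) in DEFAULT_FACTOR_FIELDS.items()}
    defaults = DEFAULT_FACTOR_FIELDS
    means = means or {}
    amplitudes = amplitudes or {}
    noise_sd_per_factor = noise_sd_per_factor or {}
    rng = np.random.default_rng(seed)
    corr_cells = noise_correlation_m / dem.cell_size
    zt = _standardized(tpi)
    layers = {}
    for name, direction in directions.items():
        if direction not in (-1, 1):
            raise InvalidSpecError(f"direction for '{name}' must be ±1")
        mean, amp, _, noise = defaults.get(name, (0.0, 1.0, direction, 0.0))
        mean = means.get(name, mean)
        amp = amplitudes.get(name, amp)
        noise = noise_sd_per_factor.get(name, noise)
        vals = mean + direction * amp * zt
        if noise > 0:
            vals = vals + _correlated_noise(vals.shape, noise, corr_cells, rng)
        vals = np.where(tpi.mask & dem.mask, vals, np.nan)
        layers[name] = tpi.like(vals)
    return FactorStack(layers)


def generate_presence(factors: FactorStack, resp: ResponseSpec) -> RasterGrid:
    """Bernoulli presence raster from a known logistic response.

    The linear predictor applies ``resp.true_coefficients`` to z-scored
    factor layers (scored over the jointly valid cells), so coefficient
    magnitudes are comparable across factors and to the fitted model's
    standardised coefficients.
    """
    unknown = [n for n in resp.true_coefficients if n not in factors]
    if unknown:
        raise InvalidSpecError(f"response names unknown factors: {unknown}")
    template = factors.template
    ok = factors.valid_mask()
    eta = np.full(template.shape, float(resp.intercept))
    for name, coef in resp.true_coefficients.items():
        g = factors[name]
        v = g.values
        mu = float(v[ok].mean())
        sd = float(v[ok].std())
        z = (v - mu) / sd if sd > 0 else np.zeros_like(v)
        eta = eta + coef * z
    with np.errstate(over="ignore"):
        p = 1.0 / (1.0 + np.exp(-eta))
    rng = np.random.default_rng(resp.seed)
    draw = (rng.random(template.shape) < p).astype(float)
    draw[~ok] = np.nan
    return template.like(draw)


_CLASS_GROUPS = {
    "valley": {CLASS_CODES["valley"]},
    "slope": {CLASS_CODES["lower slope"], CLASS_CODES["flat slope"],
              CLASS_CODES["middle slope"], CLASS_CODES["upper slope"]},
    "ridge": {CLASS_CODES["ridge"]},
}


def generate_sampling_design(
    microtopo: RasterGrid,
    n_per_class: int = 9,
    classes: tuple[str, ...] = ("valley", "slope", "ridge"),
    gully_types: tuple[str, ...] = ("with", "without"),
    seed: int = 0,
) -> pd.DataFrame:
    """Stratified sampling-point skeleton: ``n_per_class`` cells per landform
    class per gully type (default 9 × 3 × 2 = 54 points).

    Gully types split the extent into west ("with") and east ("without")
    halves, emulating paired gullies with and without the species.
    """
    rng = np.random.default_rng(seed)
    X, Y = microtopo.center_mesh()
    mid = microtopo.x_origin + microtopo.n_cols * microtopo.cell_size / 2.0
    halves = {"with": X < mid, "without": X >= mid} if len(gully_types) == 2 else {
        g: np.ones(microtopo.shape, dtype=bool) for g in gully_types
    }
    rows = []
    for gtype in gully_types:
        for cls in classes:
            if cls not in _CLASS_GROUPS:
                raise DesignError(f"unknown landform class '{cls}'")
            codes = _CLASS_GROUPS[cls]
            sel = microtopo.mask & halves[gtype] & np.isin(microtopo.values, list(codes))
            idx = np.flatnonzero(sel.ravel())
            if idx.size < n_per_class:
                raise DesignError(
                    f"class '{cls}' ({gtype}) has only {idx.size} cells; "
                    f"{n_per_class} required"
                )
            pick = rng.choice(idx, size=n_per_class, replace=False)
            r, c = np.unravel_index(pick, microtopo.shape)
            for ri, ci in zip(r, c):
                rows.append({
                    "x": X[ri, ci], "y": Y[ri, ci],
                    "row": int(ri), "col": int(ci),
                    "gully_type": gtype, "microtopo": cls,
                })
    return pd.DataFrame(rows)


def trench_count_for_area(area_m2: float, density_per_ha: float = 600.0) -> int:
    """Number of trenches for an extent at the stated planting density."""
    return int(round(density_per_ha * area_m2 / 10_000.0))


def generate_trenches(
    dem: RasterGrid,
    n: int,
    length_m: float = 4.0,
    width_m: float = 0.5,
    seed: int = 0,
    max_retries_per_trench: int = 500,
) -> list[Polygon]:
    """Place ``n`` non-overlapping level-trench rectangles along contours.

    Each rectangle (default 4.0 m × 0.5 m) is centred on a random valid
    cell and rotated so its long axis is perpendicular to the local
    elevation gradient (i.e. follows the contour). Placement retries are
    bounded; failure raises :class:`PlacementError`.
    """
    if n == 0:
        return []
    x0, y1 = dem.x_origin, dem.y_origin
    x1 = x0 + dem.n_cols * dem.cell_size
    y0 = y1 - dem.n_rows * dem.cell_size
    if length_m > (x1 - x0) or length_m > (y1 - y0):
        raise PlacementError("trench footprint does not fit the extent")
    rng = np.random.default_rng(seed)
    # coarse gradient field for contour orientation
    gy, gx = np.gradient(np.where(dem.mask, dem.values, np.nan), dem.cell_size)
    gy = -gy  # row axis points south
    placed: list[Polygon] = []
    tree_geoms = []
    half = length_m / 2.0
    margin = width_m / 2.0  # rotated-bounds check rejects long-axis overhang
    for _ in range(n):
        for attempt in range(max_retries_per_trench):
            cx = rng.uniform(x0 + margin, x1 - margin)
            cy = rng.uniform(y0 + margin, y1 - margin)
            r, c = dem.cell_of(cx, cy)
            if not (0 <= r < dem.n_rows and 0 <= c < dem.n_cols and dem.mask[r, c]):
                continue
            gxx, gyy = gx[r, c], gy[r, c]
            if np.isnan(gxx) or np.isnan(gyy):
                continue
            # contour direction = gradient rotated 90°
            angle = np.degrees(np.arctan2(gxx, -gyy)) if (gxx or gyy) else 0.0
            rect = box(cx - half, cy - width_m / 2.0, cx + half, cy + width_m / 2.0)
            rect = rotate(rect, angle, origin=(cx, cy))
            bx0, by0, bx1, by1 = rect.bounds
            if bx0 < x0 or by0 < y0 or bx1 > x1 or by1 > y1:
                continue
            if tree_geoms and shapely.intersects(
                shapely.union_all(tree_geoms), rect
            ):
                continue
            placed.append(rect)
            tree_geoms.append(rect)
            break
        else:
            raise PlacementError(
                f"could not place trench {len(placed) + 1}/{n} after "
                f"{max_retries_per_trench} retries"
            )
    return placed


def sample_stack(stack: FactorStack, design: pd.DataFrame) -> pd.DataFrame:
    """Read factor values at the design points' cells → factor-sample table.

    Returns the design columns plus one column per factor in the stack.
    """
    out = design.copy()
    template = stack.template
    rows = design["row"].to_numpy(dtype=int)
    cols = design["col"].to_numpy(dtype=int)
    for name in stack.names:
        out[name] = stack[name].values[rows, cols]
    return out
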