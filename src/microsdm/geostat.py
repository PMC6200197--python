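"""Ordinary kriging of point-sampled environmental factors.

The interpolation chain is the classical geostatistical one: an empirical
semivariogram from all point pairs, a weighted-least-squares fit of a
bounded variogram model (spherical by default), and ordinary kriging —
the best linear unbiased predictor whose weights solve

    | Γ  1 | | w |   | γ₀ |
    | 1ᵀ 0 | | μ | = | 1  |

with Γᵢⱼ = γ(‖xᵢ−xⱼ‖), γ₀ the point-to-target semivariances, and the
Lagrange multiplier μ enforcing Σwᵢ = 1 (unbiasedness). The kriging
variance at a target is wᵀγ₀ + μ. With a zero nugget the predictor is an
exact interpolator at the sample points.

Interpolation quality is summarised the way geostatistical packages report
leave-one-out cross-validation: the mean prediction error (MPE, factor
units, ideally ≈ 0) and the root-mean-square standardised prediction error
(RMSSE, dimensionless, ideally ≈ 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist

from .errors import KrigingError, ParameterError, VariogramFitError
from .raster import RasterGrid

__all__ = [
    "VariogramModel",
    "CrossValidationReport",
    "empirical_semivariogram",
    "fit_variogram",
    "krige",
    "krige_points",
    "krige_factor",
    "cross_validate",
]

logger = logging.getLogger(__name__)

_FAMILIES = ("spherical", "exponential", "gaussian")

#: Diagonal ridge applied to the kriging matrix when it is numerically
#: singular (clustered or near-duplicate samples).
KRIGING_RIDGE = 1e-10


@dataclass
class VariogramModel:
    """Bounded isotropic variogram: γ(h) = nugget + psill·g(h/range).

    ``range`` is the practical range for the exponential and gaussian
    families (γ reaches ~95% of the sill there).
    """

    family: str
    nugget: float
    psill: float
    range_: float
    degenerate: bool = False

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ParameterError(f"unknown variogram family {self.family!r}")
        if self.nugget < 0 or self.psill < 0 or self.range_ <= 0:
            raise ParameterError("variogram requires nugget, psill ≥ 0 and range > 0")

    @property
    def sill(self) -> float:
        return self.nugget + self.psill

    def __call__(self, h) -> np.ndarray:
        """Semivariance at lag distance(s) h; γ(0) = 0 by convention."""
        h = np.asarray(h, dtype=float)
        r = self.range_
        if self.family == "spherical":
            hr = np.clip(h / r, 0.0, 1.0)
            g = 1.5 * hr - 0.5 * hr**3
        elif self.family == "exponential":
            g = 1.0 - np.exp(-3.0 * h / r)
        else:  # gaussian
            g = 1.0 - np.exp(-3.0 * (h / r) ** 2)
        out = self.nugget + self.psill * g
        return np.where(h == 0, 0.0, out)


@dataclass
class CrossValidationReport:
    """Leave-one-out kriging validation summary."""

    factor: str
    mean_prediction_error: float
    rms_standardized_error: float
    residuals: pd.DataFrame  # columns: observed, predicted, variance, std_resid
    n_excluded: int = 0


def _pair_distances(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    pts = np.column_stack([x, y])
    return cdist(pts, pts)


def empirical_semivariogram(
    x: np.ndarray,
    y: np.ndarray,
    values: np.ndarray,
    n_lags: int = 12,
    max_lag: float | None = None,
) -> pd.DataFrame:
    """Binned empirical semivariogram γ̂(h) = mean of ½(zᵢ−zⱼ)² per lag bin.

    ``max_lag`` defaults to half the maximum pairwise distance. Bins with no
    pairs are omitted. Returns columns (lag, semivariance, n_pairs).
    """
    x, y, values = (np.asarray(a, dtype=float) for a in (x, y, values))
    if x.size < 2:
        raise ParameterError("semivariogram needs at least 2 points")
    d = _pair_distances(x, y)
    iu = np.triu_indices(x.size, k=1)
    dist = d[iu]
    if max_lag is None:
        max_lag = dist.max() / 2.0
    if max_lag <= 0:
        raise ParameterError("max_lag must be positive")
    sq = 0.5 * (values[iu[0]] - values[iu[1]]) ** 2
    edges = np.linspace(0.0, max_lag, n_lags + 1)
    idx = np.digitize(dist, edges[1:-1])
    keep = dist <= max_lag
    rows = []
    for b in range(n_lags):
        sel = keep & (idx == b)
        n = int(sel.sum())
        if n == 0:
            continue
        rows.append({
            "lag": float(dist[sel].mean()),
            "semivariance": float(sq[sel].mean()),
            "n_pairs": n,
        })
    return pd.DataFrame(rows)


def fit_variogram(emp: pd.DataFrame, family: str = "spherical") -> VariogramModel:
    """Weighted least-squares fit of (nugget, partial sill, range).

    Weights are the pair counts per bin. A constant (all-zero semivariance)
    field yields a degenerate model with zero nugget and sill.
    """
    if family not in _FAMILIES:
        raise ParameterError(f"unknown variogram family {family!r}")
    if len(emp) < 3:
        raise VariogramFitError("need at least 3 non-empty lag bins")
    h = emp["lag"].to_numpy(dtype=float)
    gamma = emp["semivariance"].to_numpy(dtype=float)
    w = np.sqrt(emp["n_pairs"].to_numpy(dtype=float))
    if np.allclose(gamma, 0.0):
        return VariogramModel(family, 0.0, 0.0, float(h.max()), degenerate=True)

    def resid(p):
        m = VariogramModel(family, p[0], p[1], p[2])
        return w * (m(h) - gamma)

    g_max = gamma.max()
    h_max = h.max()
    x0 = np.array([min(gamma[0], g_max) * 0.5, g_max, h_max * 0.6])
    # a range far beyond the sampled lags is unidentifiable; bounding the
    # parameters to the data's scale keeps flat variograms from drifting
    sol = least_squares(
        resid,
        x0,
        bounds=([0.0, 0.0, 1e-12], [2.0 * g_max, 10.0 * g_max, 10.0 * h_max]),
        max_nfev=5000,
    )
    if not sol.success:
        raise VariogramFitError(
            f"variogram fit did not converge: {sol.message} (x={sol.x})"
        )
    nugget, psill, rng = sol.x
    model = VariogramModel(family, float(nugget), float(psill), float(rng))
    model.wsse = float(np.sum(resid(sol.x) ** 2))  # fit diagnostic
    return model


def _dedupe(x, y, z):
    """Average values at exactly duplicated coordinates."""
    df = pd.DataFrame({"x": x, "y": y, "z": z})
    g = df.groupby(["x", "y"], as_index=False, sort=False).mean()
    return (g["x"].to_numpy(), g["y"].to_numpy(), g["z"].to_numpy())


def _kriging_matrix(x, y, vg: VariogramModel) -> np.ndarray:
    n = x.size
    d = _pair_distances(x, y)
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = vg(d)
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    A[n, n] = 0.0
    return A


def _solve_system(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    n = A.shape[0] - 1
    try:
        return np.linalg.solve(A, B)
    except np.linalg.LinAlgError:
        logger.warning("kriging matrix singular; applying ridge %g", KRIGING_RIDGE)
        A2 = A.copy()
        A2[np.arange(n), np.arange(n)] += KRIGING_RIDGE
        try:
            return np.linalg.solve(A2, B)
        except np.linalg.LinAlgError as exc:
            raise KrigingError(f"kriging system singular even with ridge: {exc}")


def krige_points(
    x: np.ndarray,
    y: np.ndarray,
    values: np.ndarray,
    vg: VariogramModel,
    tx: np.ndarray,
    ty: np.ndarray,
    return_weights: bool = False,
):
    """Ordinary kriging at arbitrary target points.

    Returns (predictions, variances) and, optionally, the (n_targets × n)
    weight matrix. Weights sum to 1 per target.
    """
    x, y, values = (np.asarray(a, dtype=float) for a in (x, y, values))
    if np.unique(np.column_stack([x, y]), axis=0).shape[0] < x.size:
        logger.info("duplicate sample locations found; averaging")
        x, y, values = _dedupe(x, y, values)
    n = x.size
    if n < 4:
        raise ParameterError("kriging needs at least 4 distinct sample points")
    A = _kriging_matrix(x, y, vg)
    d0 = cdist(np.column_stack([tx.ravel(), ty.ravel()]), np.column_stack([x, y]))
    g0 = vg(d0)
    B = np.empty((n + 1, d0.shape[0]))
    B[:n, :] = g0.T
    B[n, :] = 1.0
    sol = _solve_system(A, B)
    W = sol[:n, :]  # n × n_targets
    mu = sol[n, :]
    pred = W.T @ values
    var = np.einsum("ij,ji->i", g0, W) + mu
    neg = (W < -1e-9).any(axis=0)
    if neg.any():
        logger.debug("%d target(s) have negative kriging weights", int(neg.sum()))
    if return_weights:
        return pred, var, W.T
    return pred, var


def krige(
    x: np.ndarray,
    y: np.ndarray,
    values: np.ndarray,
    vg: VariogramModel,
    template: RasterGrid,
) -> tuple[RasterGrid, RasterGrid]:
    """Krige point samples onto the template grid.

    Returns (prediction grid, kriging-variance grid); nodata follows the
    template mask.
    """
    X, Y = template.center_mesh()
    pred, var = krige_points(x, y, values, vg, X.ravel(), Y.ravel())
    p = pred.reshape(template.shape)
    v = var.reshape(template.shape)
    p[~template.mask] = np.nan
    v[~template.mask] = np.nan
    return template.like(p), template.like(v)


def krige_factor(
    samples: pd.DataFrame,
    factor: str,
    template: RasterGrid,
    family: str = "spherical",
    n_lags: int = 12,
) -> tuple[RasterGrid, RasterGrid, VariogramModel]:
    """Semivariogram → fit → krige for one factor column of a sample table.

    ``samples`` needs columns ``x``, ``y`` and ``factor``. A degenerate
    (constant) factor is kriged as its constant value with zero variance.
    """
    x = samples["x"].to_numpy(dtype=float)
    y = samples["y"].to_numpy(dtype=float)
    z = samples[factor].to_numpy(dtype=float)
    emp = empirical_semivariogram(x, y, z, n_lags=n_lags)
    vg = fit_variogram(emp, family=family)
    if vg.degenerate:
        pred = template.like(np.where(template.mask, z.mean(), np.nan))
        var = template.like(np.where(template.mask, 0.0, np.nan))
        return pred, var, vg
    pred, var = krige(x, y, z, vg, template)
    return pred, var, vg


def cross_validate(
    x: np.ndarray,
    y: np.ndarray,
    values: np.ndarray,
    vg: VariogramModel,
    factor: str = "",
) -> CrossValidationReport:
    """Leave-one-out validation of a kriging configuration.

    MPE = mean(pred − obs); RMSSE = √(mean(((pred − obs)/√σ²ₖ)²)).
    Held-out points with zero kriging variance are excluded from the RMSSE
    and counted in ``n_excluded``.
    """
    x, y, values = (np.asarray(a, dtype=float) for a in (x, y, values))
    n = x.size
    if n < 5:
        raise ParameterError("cross-validation needs at least 5 points")
    preds = np.empty(n)
    vars_ = np.empty(n)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        p, v = krige_points(
            x[keep], y[keep], values[keep], vg,
            np.array([x[i]]), np.array([y[i]]),
        )
        preds[i], vars_[i] = p[0], v[0]
    resid = preds - values
    ok = vars_ > 0
    std = np.full(n, np.nan)
    std[ok] = resid[ok] / np.sqrt(vars_[ok])
    report = CrossValidationReport(
        factor=factor,
        mean_prediction_error=float(resid.mean()),
        rms_standardized_error=float(np.sqrt(np.mean(std[ok] ** 2))) if ok.any() else np.nan,
        residuals=pd.DataFrame({
            "observed": values, "predicted": preds,
            "variance": vars_, "std_resid": std,
        }),
        n_excluded=int((~ok).sum()),
    )
    return report
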