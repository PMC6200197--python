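"""Restoration-scenario overlay and habitat-suitability accounting.

The restoration measure modelled here is an arbor–bush–herb mixed
plantation (ABHMP) implemented as contour-aligned level trenches. Its
counterfactual factor stack replaces the soil and microclimate factor
values inside the trench footprints with reference-stand means (the
conditions the plantation creates), leaving every cell outside the
trenches — and the topographic layers everywhere, by default — untouched.

The scenario probability map is then cut into three suitability classes
(unsuitable / sub-suitable / suitable) at configurable probability
thresholds, with full area accounting and a cross-tabulation against the
landform map and the trench footprints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError, ParameterError
from .raster import RasterGrid
from .sdm import FactorStack
from .terrain import rasterize_polygons

__all__ = [
    "ScenarioSpec",
    "SuitabilityMap",
    "SUITABILITY_CODES",
    "apply_scenario",
    "reclassify_suitability",
    "suitability_report",
]

SUITABILITY_CODES = {"unsuitable": 0, "sub-suitable": 1, "suitable": 2}
SUITABILITY_NAMES = {v: k for k, v in SUITABILITY_CODES.items()}


@dataclass
class ScenarioSpec:
    """Trench polygons plus per-factor replacement values.

    ``replacements`` maps factor name → the value imposed inside trench
    footprints (typically reference-stand means). ``factors_replaced``
    defaults to every key of ``replacements``.
    """

    trenches: list            # shapely polygons
    replacements: dict[str, float]
    factors_replaced: list[str] | None = None

    def __post_init__(self):
        if self.factors_replaced is None:
            self.factors_replaced = list(self.replacements)
        missing = [f for f in self.factors_replaced if f not in self.replacements]
        if missing:
            raise ParameterError(f"factors_replaced without values: {missing}")


def apply_scenario(stack: FactorStack, spec: ScenarioSpec) -> FactorStack:
    """Counterfactual stack: replaced factors take their trench value inside
    trench footprints (cell-centre rule); everything else is bit-identical.
    """
    absent = [f for f in spec.factors_replaced if f not in stack]
    if absent:
        raise ContractError(f"scenario names absent factors: {absent}")
    out = stack.copy()
    if not spec.trenches or not spec.factors_replaced:
        return out
    footprint = rasterize_polygons(spec.trenches, stack.template)
    inside = footprint.mask & (footprint.values == 1)
    for name in spec.factors_replaced:
        layer = out[name]
        layer.values[inside & layer.mask] = spec.replacements[name]
    return out


@dataclass
class SuitabilityMap:
    """Three-class suitability raster with its area accounting."""

    grid: RasterGrid          # codes 0/1/2, NaN nodata
    areas: pd.DataFrame       # class, area_m2, percentage
    t_low: float
    t_high: float

    @property
    def total_area(self) -> float:
        return float(self.areas["area_m2"].sum())


def reclassify_suitability(
    prob: RasterGrid, t_low: float = 0.5, t_high: float = 0.75
) -> SuitabilityMap:
    """Cut a probability raster into unsuitable (< t_low), sub-suitable
    ([t_low, t_high)), and suitable (≥ t_high), with area accounting."""
    if not (0.0 <= t_low < t_high <= 1.0):
        raise ParameterError("need 0 ≤ t_low < t_high ≤ 1")
    p = prob.values
    codes = np.full(prob.shape, np.nan)
    m = prob.mask
    codes[m & (p < t_low)] = 0.0
    codes[m & (p >= t_low) & (p < t_high)] = 1.0
    codes[m & (p >= t_high)] = 2.0
    grid = prob.like(codes)
    total = grid.n_valid
    rows = []
    for name, code in SUITABILITY_CODES.items():
        n = int((grid.values == code).sum())
        rows.append({
            "class": name,
            "area_m2": n * prob.cell_area,
            "percentage": 100.0 * n / total if total else np.nan,
        })
    return SuitabilityMap(grid, pd.DataFrame(rows), t_low, t_high)


def suitability_report(
    suit: SuitabilityMap,
    microtopo: RasterGrid,
    trenches,
) -> pd.DataFrame:
    """Cross-tabulate suitability × stratum (in-trench / valley / other).

    Strata partition the valid cells: trench footprints first, remaining
    valley cells (landform code 1) second, everything else third. Returns
    long-form rows (suitability, stratum, area_m2, pct_of_class,
    pct_of_stratum): the share of the suitability class falling in the
    stratum, and the share of the stratum occupied by the class.
    """
    suit.grid.require_alignment(microtopo, "suitability/landform")
    footprint = rasterize_polygons(trenches, suit.grid)
    in_trench = footprint.mask & (footprint.values == 1)
    valley = microtopo.mask & (microtopo.values == 1) & ~in_trench
    valid = suit.grid.mask
    other = valid & ~in_trench & ~valley
    strata = {"trench": in_trench, "valley": valley, "other": other}
    rows = []
    for cname, code in SUITABILITY_CODES.items():
        cls = valid & (suit.grid.values == code)
        cls_n = int(cls.sum())
        for sname, smask in strata.items():
            n = int((cls & smask).sum())
            strat_n = int(smask.sum())
            rows.append({
                "suitability": cname,
                "stratum": sname,
                "area_m2": n * suit.grid.cell_area,
                "pct_of_class": 100.0 * n / cls_n if cls_n else np.nan,
                "pct_of_stratum": 100.0 * n / strat_n if strat_n else np.nan,
            })
    return pd.DataFrame(rows)
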