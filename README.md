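# microsdm

Microscale species distribution modelling on gullied terrain.

`microsdm` is a pipeline for evaluating ecological-restoration measures
with species distribution models (SDMs) at the scale of individual plants
— metres, not kilometres. It was built around the analysis of a degraded
red-soil hillslope colonised by the pioneer fern *Dicranopteris
dichotoma*, where the question is: if contour-aligned level trenches
(an arbor–bush–herb mixed plantation, ABHMP) impose reference-stand soil
and microclimate conditions, how much of the slope becomes suitable
habitat, and where?

The pipeline runs from raw survey data to a suitability map:

1. **Terrain** — scattered GPS elevation points are gridded through a
   Delaunay triangulation into a 0.1 m DEM; slope and aspect come from
   Horn's 3×3 stencil; the topographic position index over a 1 m circular
   neighbourhood, standardised by the neighbourhood elevation SD,
   classifies every cell into six landforms (valley, lower/flat/middle/
   upper slope, ridge).
2. **Interpolation** — 8 soil and 18 microclimate factors sampled at 54
   stratified points are kriged to rasters (spherical variogram, weighted
   least squares fit, ordinary kriging), validated by leave-one-out mean
   prediction error and RMS standardised error.
3. **Habitat model** — a presence–absence binomial GLM on z-scored
   factors,
   `logit P(present) = β₀ + Σⱼ βⱼ zⱼ`,
   scored by the rank-sum AUC and screened by an AUC > 0.9 gate;
   permutation AUC-drop ranks factor importance.
4. **Scenario** — trench footprints overwrite the replaced factors with
   reference-stand values; the refreshed stack is pushed through the
   model and the probability map is cut into unsuitable / sub-suitable /
   suitable classes with full area accounting, cross-tabulated against
   landforms and trench footprints.
5. **Field statistics** — Lilliefors normality, Levene homogeneity,
   one-way ANOVA with LSD pairwise tests and compact letter display for
   the sample-table group comparisons.

A first-class synthetic module generates the whole study system — gullied
terrain, topography-driven factor fields, presence patches from a known
logistic response, sampling designs, trench geometry — so every stage is
testable end to end without field data.

## Worked example

```python
from microsdm.pipeline import PipelineConfig, run_pipeline
from microsdm.synthetic import TerrainSpec

config = PipelineConfig(
    terrain=TerrainSpec(extent_x=12.0, extent_y=12.0, n_points=1200),
    seed=1,
)
result = run_pipeline(config, "demo_run")
print(result.results.summary())
print(result.suitability.areas.to_string(index=False))
```

prints (abridged):

```
Presence-absence GLM (binomial, logit link)
=======================================================
n cells: 13710   presence: 5377   absence: 8333
log-likelihood: -3067.35   converged: True   l2: 0
training AUC: 0.968 (excellent)
-------------------------------------------------------
term                                coef     std err
intercept                        -1.4290      0.0841
altitude                         -6.0584      0.1823
slope                            -1.1408      0.1190
...

       class  area_m2  percentage
  unsuitable    81.14   59.183078
sub-suitable    13.55    9.883297
    suitable    42.41   30.933625
```

The model was calibrated on 13,710 cells (0.1 m grid over a 12 m × 12 m
synthetic gully system) and discriminates presence from absence cells
with AUC 0.968 — "excellent" on the conventional banding, clearing the
0.9 selection gate. Under the trench scenario, 42.41 m² (30.9%) of the
slope is classed suitable; the strata report (`result.strata_report`)
shows 52.1% of in-trench area classed suitable against 5.7% outside
trenches and valleys — the suitable area concentrates in the trench
footprints and valleys, the qualitative signature of the restoration
measure. The run directory carries every intermediate layer
(ESRI ASCII grids), the kriging cross-validation table, the fitted model
as JSON, and a machine-readable `summary.json`.

The same stages are exposed as a CLI for real survey data:

```bash
microsdm simulate --out data --seed 1
microsdm terrain --points data/points.csv --out layers
microsdm interpolate --samples samples.csv --template layers/dem.asc --out kriged
microsdm run --out full_run --seed 1
```

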