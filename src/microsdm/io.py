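"""Readers and writers for the pipeline's standard text formats.

CSV for point tables and sample tables, GeoJSON for polygons, JSON for
scenario configs and model summaries, ESRI ASCII grid for rasters (in
:mod:`microsdm.raster`).
"""

from __future__ import annotations

import json

import pandas as pd
import shapely
from shapely.geometry import shape as shapely_shape

from .errors import SchemaError
from .scenario import ScenarioSpec
from .terrain import ElevationPointSet

__all__ = [
    "read_points_csv",
    "write_points_csv",
    "read_samples_csv",
    "write_samples_csv",
    "read_geojson_polygons",
    "write_geojson_polygons",
    "read_scenario_config",
    "write_scenario_config",
]


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def read_points_csv(path) -> ElevationPointSet:
    """Read an elevation point table (columns x, y, z; header required).

    Rows with non-numeric or missing coordinates are rejected with their
    line numbers.
    """
    df = _read_csv(path, ["x", "y", "z"])
    coerced = df[["x", "y", "z"]].apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna().any(axis=1)
    if bad.any():
        lines = [int(i) + 2 for i in df.index[bad]]  # +2: header + 1-based
        raise SchemaError(f"{path}: malformed rows at lines {lines[:20]}")
    if len(df) == 0:
        raise SchemaError(f"{path}: no data rows")
    return ElevationPointSet.from_dataframe(coerced)


def write_points_csv(points: ElevationPointSet, path) -> None:
    points.to_dataframe().to_csv(path, index=False)


def read_samples_csv(path) -> pd.DataFrame:
    """Read a factor-sample table (x, y, gully_type, microtopo + factors)."""
    return _read_csv(path, ["x", "y", "gully_type", "microtopo"])


def write_samples_csv(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, index=False)


def read_geojson_polygons(path) -> list:
    """Polygons from a GeoJSON FeatureCollection (or bare geometry)."""
    with open(path) as fh:
        data = json.load(fh)
    geoms = []
    if data.get("type") == "FeatureCollection":
        for feat in data.get("features", []):
            geoms.append(shapely_shape(feat["geometry"]))
    elif data.get("type") == "Feature":
        geoms.append(shapely_shape(data["geometry"]))
    else:
        geoms.append(shapely_shape(data))
    out = []
    for g in geoms:
        if g.geom_type == "Polygon":
            out.append(g)
        elif g.geom_type == "MultiPolygon":
            out.extend(g.geoms)
        else:
            raise SchemaError(f"{path}: unsupported geometry type {g.geom_type}")
    return out


def write_geojson_polygons(polys, path, properties: list[dict] | None = None) -> None:
    feats = []
    for i, g in enumerate(polys):
        props = properties[i] if properties else {"id": i}
        feats.append({
            "type": "Feature",
            "properties": props,
            "geometry": json.loads(shapely.to_geojson(g)),
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_scenario_config(path, base_dir=None) -> ScenarioSpec:
    """Scenario config: JSON with a trench GeoJSON path and a factor→value map.

    ::

        {"trenches": "trenches.geojson",
         "replacements": {"organic_matter": 9.0, "pH": 4.4}}
    """
    import os

    with open(path) as fh:
        cfg = json.load(fh)
    if "replacements" not in cfg:
        raise SchemaError(f"{path}: scenario config needs 'replacements'")
    trench_path = cfg.get("trenches")
    trenches = []
    if trench_path:
        if base_dir is None:
            base_dir = os.path.dirname(os.path.abspath(path))
        if not os.path.isabs(trench_path):
            trench_path = os.path.join(base_dir, trench_path)
        trenches = read_geojson_polygons(trench_path)
    return ScenarioSpec(
        trenches=trenches,
        replacements={k: float(v) for k, v in cfg["replacements"].items()},
        factors_replaced=cfg.get("factors_replaced"),
    )


def write_scenario_config(spec: ScenarioSpec, path, trench_path) -> None:
    cfg = {
        "trenches": str(trench_path),
        "replacements": spec.replacements,
        "factors_replaced": spec.factors_replaced,
    }
    with open(path, "w") as fh:
        json.dump(cfg, fh, indent=2)
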