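"""Readers/writers for the yield-measurement table (CSV and GeoJSON points)."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .simulate import GROUPS, MEASUREMENT_COLUMNS


def validate_measurements(df: pd.DataFrame) -> pd.DataFrame:
    """Check the measurement-table contract; returns ``df`` (column-ordered)."""
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement table missing columns: {missing}")
    bad_groups = set(df["group"].unique()) - set(GROUPS)
    if bad_groups:
        raise ValueError(f"unknown group labels: {sorted(bad_groups)}")
    if (df["area_m2"] <= 0).any():
        raise ValueError("polygon areas must be positive")
    if (df["dry_yield_kg_ha"] < 0).any():
        raise ValueError("dry yields must be non-negative")
    per_field = df.groupby("field_id")["group"].nunique()
    mixed = per_field[per_field > 1]
    if not mixed.empty:
        raise ValueError(f"fields with inconsistent group labels: {list(mixed.index)}")
    return df[MEASUREMENT_COLUMNS]


def write_csv(df: pd.DataFrame, path) -> None:
    validate_measurements(df).to_csv(path, index=False)


def read_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"field_id": str, "group": str})
    return validate_measurements(df)


def write_geojson(df: pd.DataFrame, path) -> None:
    """Write measurements as a GeoJSON FeatureCollection of points; polygon
    centroid becomes the geometry, all other fields become properties."""
    df = validate_measurements(df)
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [row.x, row.y]},
            "properties": {
                "field_id": row.field_id,
                "group": row.group,
                "area_m2": row.area_m2,
                "dry_yield_kg_ha": row.dry_yield_kg_ha,
            },
        }
        for row in df.itertuples(index=False)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_geojson(path) -> pd.DataFrame:
    with open(path) as fh:
        collection = json.load(fh)
    if collection.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    records = []
    for feat in collection.get("features", []):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Point":
            raise ValueError("only Point geometries are supported")
        props = feat.get("properties") or {}
        x, y = geom["coordinates"][:2]
        records.append({
            "field_id": str(props["field_id"]),
            "group": str(props["group"]),
            "x": float(x),
            "y": float(y),
            "area_m2": float(props["area_m2"]),
            "dry_yield_kg_ha": float(props["dry_yield_kg_ha"]),
        })
    return validate_measurements(pd.DataFrame(records, columns=MEASUREMENT_COLUMNS))


def read_measurements(path) -> pd.DataFrame:
    """Dispatch on extension: ``.csv`` or ``.geojson``/``.json``."""
    suffix = Path(path).suffix.lower()
    if suffix == ".csv":
        return read_csv(path)
    if suffix in (".geojson", ".json"):
        return read_geojson(path)
    raise ValueError(f"cannot infer measurement format from extension {suffix!r}")
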