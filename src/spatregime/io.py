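"""Reading and writing the package's plain-text data formats.

Hauls and gridded fields travel as delimited text (CSV); region polygons as
GeoJSON FeatureCollections whose features carry ``name`` and ``role``
properties (role is ``region`` or ``nursery``; a nursery's name is its
parent region's name).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .errors import InvalidInputError
from .gridding import GriddedField, RegionSet, prepare_hauls


def read_hauls(path, age_class=None, response: str | None = None) -> pd.DataFrame:
    """Haul table from CSV with columns lon, lat, year and cpue (or a
    ready response column).  ``age_class`` filters an optional ``age``
    column before the response transform."""
    df = pd.read_csv(path)
    required = {"lon", "lat", "year"}
    if not required <= set(df.columns):
        raise InvalidInputError(
            f"haul file missing columns {sorted(required - set(df.columns))}"
        )
    if age_class is not None:
        if "age" not in df.columns:
            raise InvalidInputError("age_class given but no 'age' column")
        df = df[df["age"] == age_class]
    return prepare_hauls(df, response=response)


def write_hauls(records: pd.DataFrame, path) -> None:
    cols = [c for c in ("lon_raw", "lat", "year", "response") if c in records]
    out = records[cols].rename(columns={"lon_raw": "lon"})
    out.to_csv(path, index=False, float_format="%.10g")


def read_gridded_field(path, resolution: float) -> GriddedField:
    """Long-format CSV (lon, lat, year, value; empty/NaN = missing) into a
    :class:`GriddedField`.  Node order follows sorted (lon, lat)."""
    df = pd.read_csv(path)
    needed = {"lon", "lat", "year", "value"}
    if not needed <= set(df.columns):
        raise InvalidInputError(
            f"field file missing columns {sorted(needed - set(df.columns))}"
        )
    nodes = (
        df[["lon", "lat"]].drop_duplicates().sort_values(["lon", "lat"])
    ).to_numpy()
    years = np.sort(df["year"].unique())
    key = {(lo, la): i for i, (lo, la) in enumerate(map(tuple, nodes))}
    yi = {int(y): j for j, y in enumerate(years)}
    values = np.full((len(nodes), len(years)), np.nan)
    for lo, la, y, v in df[["lon", "lat", "year", "value"]].itertuples(False):
        values[key[(lo, la)], yi[int(y)]] = v
    return GriddedField(nodes[:, 0], nodes[:, 1], years, values, resolution)


def write_gridded_field(field: GriddedField, path) -> None:
    field.to_frame().to_csv(path, index=False, float_format="%.10g")


def read_regions(path) -> RegionSet:
    """RegionSet from a GeoJSON FeatureCollection (properties: name, role)."""
    with open(path) as fh:
        gj = json.load(fh)
    regions, nurseries = {}, {}
    for feat in gj.get("features", []):
        props = feat.get("properties", {})
        name, role = props.get("name"), props.get("role", "region")
        if name is None:
            raise InvalidInputError("feature without a 'name' property")
        geom = shape(feat["geometry"])
        if role == "region":
            if name in regions:
                raise InvalidInputError(f"duplicate region name {name!r}")
            regions[name] = geom
        elif role == "nursery":
            nurseries[name] = geom
        else:
            raise InvalidInputError(f"unknown role {role!r}")
    return RegionSet(regions=regions, nurseries=nurseries)


def write_regions(regions: RegionSet, path) -> None:
    features = []
    for name in regions.names:
        features.append(
            {
                "type": "Feature",
                "properties": {"name": name, "role": "region"},
                "geometry": mapping(regions.regions[name]),
            }
        )
        if name in regions.nurseries:
            features.append(
                {
                    "type": "Feature",
                    "properties": {"name": name, "role": "nursery"},
                    "geometry": mapping(regions.nurseries[name]),
                }
            )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def write_dataset(directory, records, regions=None, fields=None, series=None,
                  truth=None) -> None:
    """Write a simulated study system to a directory in the package's
    standard formats (hauls.csv, regions.geojson, field_<name>.csv,
    polygon_series.csv, truth.json)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_hauls(records, directory / "hauls.csv")
    if regions is not None:
        write_regions(regions, directory / "regions.geojson")
    for name, field in (fields or {}).items():
        write_gridded_field(field, directory / f"field_{name}.csv")
    if series is not None:
        series.to_csv(directory / "polygon_series.csv", index=False,
                      float_format="%.10g")
    if truth is not None:
        with open(directory / "truth.json", "w") as fh:
            json.dump(_jsonable(truth), fh, indent=1)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
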