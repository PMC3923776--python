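"""Geometry and gridding utilities.

Survey hauls carry raw longitudes; all planar work happens in *corrected*
longitude, lambda* = lambda * cos(phi * pi / 180), which turns one degree of
longitude into the same ground distance as one degree of latitude.  Distances
are then plain Euclidean in corrected degrees, scaled by 111 km per degree.
This module provides that correction, inverse-distance interpolation onto
regular grids, polygon/nursery membership, and period-averaged lagged
covariate fields.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon

from .errors import (
    AmbiguousRegionError,
    CoverageError,
    InvalidConfigError,
    InvalidInputError,
)

KM_PER_DEGREE = 111.0
#: Two points closer than this (km) are treated as coincident in IDW.
EXACT_HIT_EPS_KM = 1e-9


def mercator_correct(lon_raw, lat):
    """Corrected longitude: ``lon_raw * cos(lat * pi / 180)``.

    Accepts scalars or arrays.  Latitudes must lie in [-90, 90] and all
    inputs must be finite.
    """
    lon_raw = np.asarray(lon_raw, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if not (np.all(np.isfinite(lon_raw)) and np.all(np.isfinite(lat))):
        raise InvalidInputError("non-finite longitude/latitude")
    if np.any(lat < -90.0) or np.any(lat > 90.0):
        raise InvalidInputError("latitude outside [-90, 90]")
    out = lon_raw * np.cos(lat * np.pi / 180.0)
    if out.ndim == 0:
        return float(out)
    return out


def prepare_hauls(df: pd.DataFrame, response: str | None = None) -> pd.DataFrame:
    """Normalise a haul table to the canonical columns.

    Input columns: ``lon``, ``lat``, ``year`` and either ``cpue`` (the
    response becomes log(CPUE + 1)) or a ready-made ``response`` column.
    Returns a new frame with ``lon_raw, lat, lon_corr, year, response``.
    """
    df = df.copy()
    if "lon_raw" not in df.columns:
        df = df.rename(columns={"lon": "lon_raw"})
    if response is not None:
        df["response"] = df[response].astype(float)
    elif "response" not in df.columns:
        cpue = df["cpue"].astype(float)
        if (cpue < 0).any():
            raise InvalidInputError("negative CPUE")
        df["response"] = np.log(cpue + 1.0)
    df["lon_corr"] = mercator_correct(df["lon_raw"].to_numpy(), df["lat"].to_numpy())
    df["year"] = df["year"].astype(int)
    return df[["lon_raw", "lat", "lon_corr", "year", "response"]]


@dataclass
class GriddedField:
    """One variable on a regular lon/lat grid across years.

    ``lons``/``lats`` give node coordinates (cell centres) as flat arrays of
    equal length; ``values`` is (n_nodes, n_years) with NaN at masked nodes.
    """

    lons: np.ndarray
    lats: np.ndarray
    years: np.ndarray
    values: np.ndarray
    resolution: float

    def __post_init__(self):
        self.lons = np.asarray(self.lons, dtype=float)
        self.lats = np.asarray(self.lats, dtype=float)
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.lons.size, self.years.size):
            raise InvalidInputError(
                f"values shape {self.values.shape} does not match "
                f"({self.lons.size} nodes, {self.years.size} years)"
            )

    @property
    def mask(self) -> np.ndarray:
        """Boolean availability flags, True where a value is present."""
        return np.isfinite(self.values)

    @property
    def n_nodes(self) -> int:
        return self.lons.size

    def year_index(self, year: int) -> int:
        idx = np.flatnonzero(self.years == year)
        if idx.size == 0:
            raise CoverageError(f"year {year} not covered by field")
        return int(idx[0])

    def to_frame(self) -> pd.DataFrame:
        """Long-format (lon, lat, year, value) with NaN for masked nodes."""
        n, m = self.n_nodes, self.years.size
        return pd.DataFrame(
            {
                "lon": np.repeat(self.lons, m),
                "lat": np.repeat(self.lats, m),
                "year": np.tile(self.years, n),
                "value": self.values.ravel(),
            }
        )


def regular_grid(lon_range, lat_range, resolution):
    """Cell-centre nodes of a regular grid covering the given extent.

    Returns (lons, lats) flat arrays.  Node coordinates are cell centres:
    the first node sits half a cell inside each range edge.
    """
    if resolution <= 0:
        raise InvalidConfigError("resolution must be positive")
    lon0, lon1 = lon_range
    lat0, lat1 = lat_range
    glons = np.arange(lon0 + resolution / 2.0, lon1, resolution)
    glats = np.arange(lat0 + resolution / 2.0, lat1, resolution)
    lon_m, lat_m = np.meshgrid(glons, glats, indexing="ij")
    return lon_m.ravel(), lat_m.ravel()


def idw_interpolate(
    points_lon_corr,
    points_lat,
    points_value,
    nodes_lon_corr,
    nodes_lat,
    radius_km: float = 50.0,
    power: float = 2.0,
) -> np.ndarray:
    """Inverse-distance-weighted interpolation within a fixed radius.

    Distances are Euclidean in corrected degrees times 111 km/degree.  A node
    with no point inside ``radius_km`` gets NaN; a node coincident with a
    point (closer than ``EXACT_HIT_EPS_KM``) takes that point's value.  The
    default radius of 50 km and power 2 match the gridding used for sparse
    ship-track plankton records.
    """
    if radius_km <= 0:
        raise InvalidConfigError("radius_km must be positive")
    px = np.asarray(points_lon_corr, float) * KM_PER_DEGREE
    py = np.asarray(points_lat, float) * KM_PER_DEGREE
    pv = np.asarray(points_value, float)
    nx = np.asarray(nodes_lon_corr, float) * KM_PER_DEGREE
    ny = np.asarray(nodes_lat, float) * KM_PER_DEGREE
    out = np.full(nx.shape, np.nan)
    if pv.size == 0:
        return out
    tree = cKDTree(np.column_stack([px, py]))
    neighbours = tree.query_ball_point(np.column_stack([nx, ny]), r=radius_km)
    for i, idx in enumerate(neighbours):
        if not idx:
            continue
        idx = np.asarray(idx)
        d = np.hypot(px[idx] - nx[i], py[idx] - ny[i])
        hit = d < EXACT_HIT_EPS_KM
        if hit.any():
            out[i] = pv[idx[hit][0]]
            continue
        w = d ** (-power)
        out[i] = np.sum(w * pv[idx]) / np.sum(w)
    return out


def grid_hauls_idw(
    hauls: pd.DataFrame,
    lon_range,
    lat_range,
    resolution: float,
    radius_km: float = 50.0,
    power: float = 2.0,
) -> GriddedField:
    """Interpolate yearly haul responses onto a regular grid.

    Node coordinates are raw lon/lat cell centres; IDW distances use the
    corrected-longitude plane.
    """
    lons, lats = regular_grid(lon_range, lat_range, resolution)
    node_lc = mercator_correct(lons, lats)
    years = np.sort(hauls["year"].unique())
    values = np.full((lons.size, years.size), np.nan)
    for j, year in enumerate(years):
        sub = hauls[hauls["year"] == year]
        values[:, j] = idw_interpolate(
            sub["lon_corr"].to_numpy(),
            sub["lat"].to_numpy(),
            sub["response"].to_numpy(),
            node_lc,
            lats,
            radius_km=radius_km,
            power=power,
        )
    return GriddedField(lons, lats, years, values, resolution)


@dataclass
class RegionSet:
    """Named region polygons (subpopulation areas) with nursery sub-areas."""

    regions: dict[str, Polygon]
    nurseries: dict[str, Polygon] = field(default_factory=dict)

    def __post_init__(self):
        for name, nursery in self.nurseries.items():
            if name not in self.regions:
                raise InvalidConfigError(f"nursery for unknown region {name!r}")
            if not self.regions[name].covers(nursery):
                warnings.warn(
                    f"nursery of region {name!r} extends outside its region",
                    stacklevel=2,
                )

    @property
    def names(self) -> list[str]:
        return sorted(self.regions)

    def assign(self, lon_raw: float, lat: float) -> str | None:
        return assign_region(lon_raw, lat, self)

    def membership(self, lons, lats) -> np.ndarray:
        """Region name per point (object array, None outside all regions)."""
        out = np.full(len(lons), None, dtype=object)
        for i, (lo, la) in enumerate(zip(lons, lats)):
            out[i] = assign_region(float(lo), float(la), self)
        return out

    def nursery_membership(self, lons, lats) -> np.ndarray:
        """Region name per point for points inside that region's nursery."""
        out = np.full(len(lons), None, dtype=object)
        for i, (lo, la) in enumerate(zip(lons, lats)):
            p = Point(float(lo), float(la))
            for name, nursery in self.nurseries.items():
                if nursery.covers(p):
                    out[i] = name
                    break
        return out


def assign_region(lon_raw: float, lat: float, regions: RegionSet) -> str | None:
    """Unique region whose polygon covers the point; boundary counts inside.

    Raises :class:`AmbiguousRegionError` if two polygons both claim the
    point — region sets are meant to partition space.
    """
    if not regions.regions:
        raise InvalidConfigError("empty region set")
    p = Point(lon_raw, lat)
    claims = [name for name, poly in regions.regions.items() if poly.covers(p)]
    if len(claims) > 1:
        raise AmbiguousRegionError(
            f"point ({lon_raw}, {lat}) claimed by regions {sorted(claims)}"
        )
    return claims[0] if claims else None


@dataclass(frozen=True)
class PeriodPartition:
    """Year -> period mapping induced by an ordered set of turnover years.

    A turnover year is the FIRST year of the new period.
    """

    start_year: int
    end_year: int
    turnover_years: tuple[int, ...]

    @property
    def periods(self) -> list[tuple[int, int]]:
        bounds = [self.start_year, *self.turnover_years, self.end_year + 1]
        return [(bounds[i], bounds[i + 1] - 1) for i in range(len(bounds) - 1)]

    @property
    def n_periods(self) -> int:
        return len(self.turnover_years) + 1

    def period_index(self, years) -> np.ndarray:
        years = np.asarray(years, dtype=int)
        idx = np.zeros(years.shape, dtype=int)
        for t in self.turnover_years:
            idx += years >= t
        return idx

    def labels(self) -> list[str]:
        return [f"{a}-{b}" for a, b in self.periods]


def period_average_lagged(
    field: GriddedField, partition: PeriodPartition, lag_years: int = 1
) -> dict[tuple[int, int], np.ndarray]:
    """Per-node mean of a field over each period's years shifted back by lag.

    The period 1974-1984 with a one-year lag averages the window 1973-1983.
    A node is NaN in a period if no unmasked year contributes.  Raises
    :class:`CoverageError` if the lagged window reaches before the field's
    first available year.
    """
    if lag_years < 0:
        raise InvalidConfigError("lag_years must be >= 0")
    have = set(int(y) for y in field.years)
    out: dict[tuple[int, int], np.ndarray] = {}
    for (a, b) in partition.periods:
        window = list(range(a - lag_years, b - lag_years + 1))
        missing = [y for y in window if y not in have]
        if missing:
            raise CoverageError(
                f"period {a}-{b} with lag {lag_years} needs years "
                f"{missing} not covered by the field"
            )
        cols = [field.year_index(y) for y in window]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN nodes
            out[(a, b)] = np.nanmean(field.values[:, cols], axis=1)
    return out
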