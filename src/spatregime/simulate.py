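"""Synthetic study systems with known ground truth.

Emulates the statistical structure of the real study inputs — bottom-trawl
haul records sampling piecewise-stationary spatial surfaces of log
abundance, gridded environmental covariate fields with regime shifts, a
set of region polygons with nursery sub-areas, and polygon-level
recruitment series driven by lagged covariates — without any oceanographic
realism.  Every output is reproducible from (config, seed), and the ground
truth (surfaces, turnover years, effect coefficients, signal shares) is
returned alongside the data so recovery tests can compute oracle answers.

The default spatial domain is a North Sea survey box (51-61 N, 5 W-9 E) with a
0.5 degree abundance grid and 1 degree covariate grids, so the geometry
code paths run at production shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import box

from .errors import InvalidConfigError
from .gridding import (
    GriddedField,
    RegionSet,
    mercator_correct,
    regular_grid,
)

Surface = dict[tuple[int, int], float]

#: base log-abundance surface (degree 2, in normalised coordinates)
BASE_SURFACE: Surface = {
    (0, 0): 5.0,
    (1, 0): 0.6,
    (0, 1): -0.8,
    (2, 0): -0.4,
    (1, 1): 0.3,
    (0, 2): 0.2,
}
#: unscaled shape of the regime shift (rescaled to a target RMS amplitude)
SHIFT_PATTERN: Surface = {(0, 0): -1.0, (1, 0): -0.5, (0, 1): 0.6}


@dataclass
class GeneratorConfig:
    """Everything needed to simulate one study system."""

    study_years: tuple[int, int] = (1989, 2008)
    lon_range: tuple[float, float] = (-5.0, 9.0)
    lat_range: tuple[float, float] = (51.0, 61.0)
    cod_resolution: float = 0.5
    cov_resolution: float = 1.0
    true_thresholds: tuple[int, ...] = ()
    surfaces: list[Surface] = field(default_factory=list)
    #: ramp width in years per threshold; 0 = instantaneous step at y*
    transitions: dict[int, int] = field(default_factory=dict)
    noise_sd: float = 1.0
    hauls_per_year: int = 150
    placement: str = "uniform"
    #: SST regime: +shift (deg C) from sst_shift_year onwards
    sst_shift_year: int | None = 1998
    sst_shift: float = 1.0
    #: variance shares of the recruitment signal components
    effect_shares: dict[str, float] = field(
        default_factory=lambda: {"ssb": 0.25, "ratio": 0.08, "sst_spring": 0.19}
    )
    lag_years: int = 1

    def __post_init__(self):
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be >= 0")
        y0, y1 = self.study_years
        for t in self.true_thresholds:
            if not (y0 + 2 <= t <= y1 - 1):
                raise InvalidConfigError(
                    f"threshold {t} violates the 2-year-period rule"
                )
        for t, w in self.transitions.items():
            if w < 0:
                raise InvalidConfigError("ramp width must be >= 0")
        if not self.surfaces:
            self.surfaces = default_surfaces(self)
        if len(self.surfaces) != len(self.true_thresholds) + 1:
            raise InvalidConfigError(
                "need one surface per period "
                f"({len(self.true_thresholds) + 1}), got {len(self.surfaces)}"
            )

    # -- normalised surface coordinates ------------------------------------
    def normalise(self, lon_corr, lat):
        """Map (corrected lon, lat) into roughly [-1, 1]^2 over the domain."""
        lat_mid = 0.5 * (self.lat_range[0] + self.lat_range[1])
        lc0 = mercator_correct(self.lon_range[0], lat_mid)
        lc1 = mercator_correct(self.lon_range[1], lat_mid)
        u = (2.0 * (np.asarray(lon_corr, float) - lc0) / (lc1 - lc0)) - 1.0
        v = (
            2.0
            * (np.asarray(lat, float) - self.lat_range[0])
            / (self.lat_range[1] - self.lat_range[0])
        ) - 1.0
        return u, v


def eval_surface(coefs: Surface, u, v) -> np.ndarray:
    out = np.zeros(np.broadcast(np.asarray(u), np.asarray(v)).shape)
    for (a, b), c in coefs.items():
        out = out + c * np.asarray(u) ** a * np.asarray(v) ** b
    return out


def _domain_uv(config: GeneratorConfig, n: int = 40):
    lons = np.linspace(*config.lon_range, n)
    lats = np.linspace(*config.lat_range, n)
    lon_m, lat_m = np.meshgrid(lons, lats)
    lc = mercator_correct(lon_m.ravel(), lat_m.ravel())
    return config.normalise(lc, lat_m.ravel())


def scale_shift_to_rms(
    config: GeneratorConfig, pattern: Surface, target_rms: float
) -> Surface:
    """Rescale a shift pattern so its RMS over the domain is ``target_rms``."""
    u, v = _domain_uv(config)
    vals = eval_surface(pattern, u, v)
    rms = float(np.sqrt(np.mean(vals**2)))
    if rms == 0:
        raise InvalidConfigError("zero shift pattern cannot be scaled")
    f = target_rms / rms
    return {k: c * f for k, c in pattern.items()}


def default_surfaces(config: GeneratorConfig) -> list[Surface]:
    """Base surface plus one 2-sigma RMS shift per threshold."""
    surfaces = [dict(BASE_SURFACE)]
    amp = 2.0 * (config.noise_sd if config.noise_sd > 0 else 1.0)
    for i, _t in enumerate(config.true_thresholds):
        delta = scale_shift_to_rms(config, SHIFT_PATTERN, amp)
        prev = surfaces[-1]
        sgn = 1.0 if i % 2 == 0 else -1.0
        nxt = {
            k: prev.get(k, 0.0) + sgn * delta.get(k, 0.0)
            for k in set(prev) | set(delta)
        }
        surfaces.append(nxt)
    return surfaces


def transition_weight(year, threshold: int, ramp_width: int) -> np.ndarray:
    """Blend weight of the post-threshold surface: 0 before the ramp,
    1 from the turnover year onward, linear across a ramp of given width."""
    year = np.asarray(year, float)
    if ramp_width == 0:
        return (year >= threshold).astype(float)
    return np.clip((year - (threshold - ramp_width)) / ramp_width, 0.0, 1.0)


def surface_value_at(config: GeneratorConfig, lon_corr, lat, year):
    """Ground-truth expected response at points in a given year."""
    u, v = config.normalise(lon_corr, lat)
    val = eval_surface(config.surfaces[0], u, v)
    for i, t in enumerate(config.true_thresholds):
        w = transition_weight(year, t, config.transitions.get(t, 0))
        delta = {
            k: config.surfaces[i + 1].get(k, 0.0) - config.surfaces[i].get(k, 0.0)
            for k in set(config.surfaces[i]) | set(config.surfaces[i + 1])
        }
        val = val + w * eval_surface(delta, u, v)
    return val


def generate_hauls(config: GeneratorConfig, seed: int | None = None):
    """Simulated haul records plus the ground-truth ledger.

    Returns (records, truth): records with columns lon_raw, lat, lon_corr,
    year, response; truth holds the generating surfaces, thresholds,
    transitions, seed and noise level.
    """
    rng = np.random.default_rng(seed)
    y0, y1 = config.study_years
    years = np.arange(y0, y1 + 1)
    frames = []
    for year in years:
        n = config.hauls_per_year
        if config.placement == "uniform":
            lon = rng.uniform(*config.lon_range, n)
            lat = rng.uniform(*config.lat_range, n)
        elif config.placement == "clustered":
            k = max(3, n // 40)
            cx = rng.uniform(*config.lon_range, k)
            cy = rng.uniform(*config.lat_range, k)
            pick = rng.integers(0, k, n)
            lon = np.clip(
                cx[pick] + rng.normal(0, 0.8, n), *config.lon_range
            )
            lat = np.clip(cy[pick] + rng.normal(0, 0.6, n), *config.lat_range)
        else:
            raise InvalidConfigError(f"unknown placement {config.placement!r}")
        lc = mercator_correct(lon, lat)
        mu = surface_value_at(config, lc, lat, year)
        resp = mu + rng.normal(0.0, config.noise_sd, n)
        frames.append(
            pd.DataFrame(
                {
                    "lon_raw": lon,
                    "lat": lat,
                    "lon_corr": lc,
                    "year": year,
                    "response": resp,
                }
            )
        )
    records = pd.concat(frames, ignore_index=True)
    truth = {
        "surfaces": config.surfaces,
        "true_thresholds": config.true_thresholds,
        "transitions": dict(config.transitions),
        "noise_sd": config.noise_sd,
        "seed": seed,
        "study_years": config.study_years,
    }
    return records, truth


def generate_response_grid(
    config: GeneratorConfig, seed: int | None = None, noise_sd: float | None = None
) -> GriddedField:
    """Ground-truth response surface sampled at the abundance-grid nodes."""
    rng = np.random.default_rng(seed)
    lons, lats = regular_grid(
        config.lon_range, config.lat_range, config.cod_resolution
    )
    lc = mercator_correct(lons, lats)
    y0, y1 = config.study_years
    years = np.arange(y0, y1 + 1)
    sd = config.noise_sd if noise_sd is None else noise_sd
    values = np.empty((lons.size, years.size))
    for j, year in enumerate(years):
        values[:, j] = surface_value_at(config, lc, lats, year) + rng.normal(
            0.0, sd, lons.size
        )
    return GriddedField(lons, lats, years, values, config.cod_resolution)


# -- regions ---------------------------------------------------------------


def default_regions(config: GeneratorConfig | None = None) -> RegionSet:
    """Eight rectangular regions (A-H) tiling the study box, each with an
    inset rectangular nursery covering its central quarter."""
    if config is None:
        config = GeneratorConfig()
    lon0, lon1 = config.lon_range
    lat0, lat1 = config.lat_range
    lon_edges = np.linspace(lon0, lon1, 5)
    lat_edges = np.linspace(lat0, lat1, 3)
    names = "ABCDEFGH"
    regions, nurseries = {}, {}
    # regions must partition: shrink the upper edges by a hair so shared
    # boundaries belong to exactly one polygon
    eps = 1e-9
    i = 0
    for r in range(2):
        for c in range(4):
            name = names[i]
            x0, x1 = lon_edges[c], lon_edges[c + 1]
            y0, y1 = lat_edges[r], lat_edges[r + 1]
            regions[name] = box(x0, y0, x1 - eps, y1 - eps)
            dx, dy = (x1 - x0) / 4.0, (y1 - y0) / 4.0
            nurseries[name] = box(x0 + dx, y0 + dy, x1 - dx, y1 - dy)
            i += 1
    return RegionSet(regions=regions, nurseries=nurseries)


# -- covariate fields and polygon series -----------------------------------


@dataclass
class CovariateBundle:
    """Gridded covariate fields, region set, polygon series and truth."""

    fields: dict[str, GriddedField]
    regions: RegionSet
    series: pd.DataFrame
    truth: dict


def _sst_field(config: GeneratorConfig, years, rng) -> GriddedField:
    lons, lats = regular_grid(
        config.lon_range, config.lat_range, config.cov_resolution
    )
    lat0, lat1 = config.lat_range
    grad = (lats - lat0) / (lat1 - lat0)  # 0 south .. 1 north
    values = np.empty((lons.size, years.size))
    for j, year in enumerate(years):
        base = 11.0 - 2.5 * grad
        if config.sst_shift_year is not None and year >= config.sst_shift_year:
            base = base + config.sst_shift
        values[:, j] = base + rng.normal(0.0, 0.3, lons.size)
    return GriddedField(lons, lats, years, values, config.cov_resolution)


def generate_covariate_fields(
    config: GeneratorConfig, seed: int | None = None
) -> CovariateBundle:
    """SST-like and zooplankton-like gridded fields plus a polygon series.

    Zooplankton biomasses are deterministic functions of SST plus noise, so
    SST -> zooplankton regressions are recoverable; the Calanus-community
    ratio goes through a logistic transform and stays in [0, 1].  The
    polygon-level recruitment series follows the configured effect shares
    (see :func:`generate_polygon_series`).
    """
    rng = np.random.default_rng(seed)
    y0, y1 = config.study_years
    years = np.arange(y0 - config.lag_years, y1 + 1)
    sst = _sst_field(config, years, rng)
    spring = GriddedField(
        sst.lons,
        sst.lats,
        years,
        0.9 * sst.values - 1.5 + rng.normal(0.0, 0.2, sst.values.shape),
        config.cov_resolution,
    )
    # log biomass declines with SST; ratio = logistic in -(SST - 10)
    zoop = GriddedField(
        sst.lons,
        sst.lats,
        years,
        3.0 - 0.35 * (sst.values - 10.0) + rng.normal(0.0, 0.25, sst.values.shape),
        config.cov_resolution,
    )
    from scipy.special import expit

    ratio = GriddedField(
        sst.lons,
        sst.lats,
        years,
        expit(-1.2 * (sst.values - 10.0) + rng.normal(0.0, 0.4, sst.values.shape)),
        config.cov_resolution,
    )
    fields = {
        "sst_annual": sst,
        "sst_spring": spring,
        "zoop_total": zoop,
        "calanus_ratio": ratio,
    }
    regions = default_regions(config)
    series, truth = generate_polygon_series(
        config, seed=None if seed is None else seed + 1
    )
    truth["field_models"] = {
        "zoop_total": {"intercept": 3.0, "sst_slope": -0.35},
        "calanus_ratio": {"logit_slope": -1.2, "center": 10.0},
    }
    return CovariateBundle(
        fields=fields, regions=regions, series=series, truth=truth
    )


def generate_polygon_series(
    config: GeneratorConfig, seed: int | None = None
) -> tuple[pd.DataFrame, dict]:
    """Polygon-by-year recruitment series with calibrated covariate effects.

    Covariates (SSB index, spring SST, Calanus ratio, helgolandicus
    biomass, exp(-Fbar)) are drawn per (region, year); the recruitment
    response is

        recruit = const + b_ssb * SSB + quad(ratio) + b_sst * SST + noise

    with coefficients scaled so each term's realised variance share matches
    ``config.effect_shares`` (total response variance 1).  A zero share
    removes the term.  The truth dict records coefficients and the sign of
    each marginal effect at the covariate mean.
    """
    from scipy.special import expit as _expit

    rng = np.random.default_rng(seed)
    y0, y1 = config.study_years
    years = np.arange(y0, y1 + 1)
    region_names = list("ABCDEFGH")
    rows = []
    fbar_by_year = {
        int(y): 0.9 - 0.015 * (y - y0) + 0.05 * np.sin(0.7 * (y - y0))
        for y in years
    }
    for region_i, region in enumerate(region_names):
        base_sst = 8.0 + 0.35 * region_i  # regional thermal gradient
        for year in years:
            shift = (
                config.sst_shift
                if config.sst_shift_year is not None
                and year - config.lag_years >= config.sst_shift_year
                else 0.0
            )
            # anomaly: regime shift + interannual noise; regional bases are
            # absorbed by the polygon factor downstream
            anom = shift + rng.normal(0.0, 0.5)
            sst = base_sst + anom
            # moderate SST coupling so screening finds the links without
            # making the covariates collinear
            ratio = float(_expit(-0.6 * anom + rng.normal(0.0, 0.8)))
            ssb = 2.0 - 0.15 * anom + rng.normal(0.0, 0.8)
            helgo = 1.0 + 0.3 * anom + rng.normal(0.0, 0.5)
            rows.append(
                {
                    "region": region,
                    "year": int(year),
                    "ssb": ssb,
                    "sst_spring": sst,
                    "calanus_ratio": ratio,
                    "c_helgolandicus": helgo,
                    "exp_neg_fbar": float(np.exp(-fbar_by_year[int(year)])),
                }
            )
    df = pd.DataFrame(rows)

    shares = dict(config.effect_shares)
    terms = {}
    # unit-coefficient effect terms on within-region anomalies, so the
    # polygon factor does not absorb any of the configured signal
    def _within_region_center(values: np.ndarray) -> np.ndarray:
        s = pd.Series(values, index=df.index)
        return (s - s.groupby(df["region"]).transform("mean")).to_numpy()

    terms["ssb"] = _within_region_center(df["ssb"].to_numpy())
    r = df["calanus_ratio"].to_numpy()
    quad_raw = (r - 0.5) - 1.5 * (r - 0.5) ** 2  # rises then saturates
    terms["ratio"] = _within_region_center(quad_raw)
    terms["sst_spring"] = _within_region_center(
        -df["sst_spring"].to_numpy()  # warm = bad
    )

    response = np.zeros(len(df))
    coefs = {}
    for name, term in terms.items():
        share = shares.get(name, 0.0)
        if share <= 0:
            coefs[name] = 0.0
            continue
        sd = float(np.std(term))
        scale = np.sqrt(share) / sd if sd > 0 else 0.0
        coefs[name] = scale
        response = response + scale * term
    noise_share = max(0.0, 1.0 - sum(shares.get(k, 0.0) for k in terms))
    response = response + rng.normal(0.0, np.sqrt(noise_share), len(df))
    df["recruitment"] = 5.0 + response

    truth = {
        "coefficients": coefs,
        "effect_shares": shares,
        "noise_share": noise_share,
        "marginal_signs": {
            "ssb": 1 if coefs["ssb"] > 0 else 0,
            # d/dr of coef*(r-0.5-1.5(r-0.5)^2) at mean ratio
            "calanus_ratio": int(
                np.sign(
                    coefs["ratio"]
                    * (1.0 - 3.0 * (float(np.mean(r)) - 0.5))
                )
            ),
            "sst_spring": -1 if coefs["sst_spring"] > 0 else 0,
        },
        "fbar_by_year": fbar_by_year,
        "seed": seed,
    }
    return df, truth


# -- named scenarios -------------------------------------------------------


def scenario_sharp_1998(**overrides) -> GeneratorConfig:
    """Single instantaneous regime shift in 1998 (step RMS = 2 x noise sd)."""
    cfg = GeneratorConfig(
        study_years=(1989, 2008),
        true_thresholds=(1998,),
        transitions={1998: 0},
    )
    return replace(cfg, **overrides) if overrides else cfg


def scenario_ramp_1989_2001(**overrides) -> GeneratorConfig:
    """The same total change as sharp-1998 but spread linearly 1989-2001,
    emulating a gradual, decade-long redistribution."""
    cfg = GeneratorConfig(
        study_years=(1989, 2008),
        true_thresholds=(2001,),
        transitions={2001: 12},
    )
    return replace(cfg, **overrides) if overrides else cfg


def scenario_two_shift(**overrides) -> GeneratorConfig:
    """A major shift (1998, 2 sigma) preceded by a minor one (1988, 0.8 sigma)."""
    cfg = GeneratorConfig(
        study_years=(1980, 2008),
        true_thresholds=(1988, 1998),
        transitions={1988: 0, 1998: 0},
    )
    base = dict(BASE_SURFACE)
    minor = scale_shift_to_rms(cfg, {(0, 0): -1.0, (0, 1): 0.4}, 0.8 * cfg.noise_sd)
    major = scale_shift_to_rms(cfg, SHIFT_PATTERN, 2.0 * cfg.noise_sd)
    s1 = {k: base.get(k, 0.0) + minor.get(k, 0.0) for k in set(base) | set(minor)}
    s2 = {k: s1.get(k, 0.0) + major.get(k, 0.0) for k in set(s1) | set(major)}
    cfg.surfaces = [base, s1, s2]
    return replace(cfg, **overrides) if overrides else cfg


def scenario_no_shift(**overrides) -> GeneratorConfig:
    """Stationary surface: the negative control for threshold detection."""
    cfg = GeneratorConfig(study_years=(1989, 2008), true_thresholds=())
    return replace(cfg, **overrides) if overrides else cfg
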