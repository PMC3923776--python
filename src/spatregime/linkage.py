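"""Polygon-level recruitment vs lagged environmental covariates.

Recruits caught in a region's nursery grounds are assumed to have grown
under that region's environmental conditions during their first year, so
the response for (region, year y) is the mean recruitment index over the
region's nursery grid nodes, and each covariate is the region-wide mean of
its field averaged over the period containing y-1 (one-year lag).

Covariates enter models as polynomials of degree <= 2 with an optional
additive polygon factor and optional polygon-by-covariate or
SST-by-zooplankton interactions.  Model comparison reuses the shared
75/25-replicate cross-validation machinery; the stepwise build fixes the
spawning-stock index (SSB) first, then adds the zooplankton descriptor(s)
with the largest significant cross-validated gain in explained deviance,
and finally spring SST if its residual contribution is still significant.
Gains below 3 percentage points are treated as not significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .errors import InvalidConfigError, InvalidInputError, SingularFitError
from .gridding import GriddedField, PeriodPartition, RegionSet, period_average_lagged
from .selection import (
    CVSummary,
    adjusted_explained_deviance,
    bootstrap_cv,
    gaussian_aic,
    paired_pvalue,
)
from .thresholds import (
    binomial_deviance,
    gaussian_deviances,
    solve_least_squares,
    _fit_binomial,
)

DEFAULT_GAIN_FLOOR_PCT = 3.0


# -- series assembly -------------------------------------------------------


def build_polygon_series(
    recruit_grid: GriddedField,
    covariate_grids: dict[str, GriddedField],
    regions: RegionSet,
    partition: PeriodPartition,
    lag_years: int = 1,
) -> pd.DataFrame:
    """One row per (region, year): nursery-mean response, region-mean lagged
    covariates.

    Recruitment averages over the region's *nursery* nodes for each year;
    covariates average over ALL the region's nodes of the period-averaged
    lagged field (the period containing the year, shifted back by the lag).
    Rows with any missing covariate are flagged ``incomplete``.
    """
    nursery = regions.nursery_membership(recruit_grid.lons, recruit_grid.lats)
    rows = []
    cov_membership = {
        name: regions.membership(g.lons, g.lats)
        for name, g in covariate_grids.items()
    }
    cov_period_means = {
        name: period_average_lagged(g, partition, lag_years)
        for name, g in covariate_grids.items()
    }
    for region in regions.names:
        nursery_nodes = np.flatnonzero(nursery == region)
        if nursery_nodes.size == 0:
            raise InvalidConfigError(
                f"region {region!r} has no nursery grid nodes"
            )
        for (a, b) in partition.periods:
            for year in range(a, b + 1):
                if year not in recruit_grid.years:
                    continue
                j = recruit_grid.year_index(year)
                vals = recruit_grid.values[nursery_nodes, j]
                rec = float(np.nanmean(vals)) if np.isfinite(vals).any() else np.nan
                row = {
                    "region": region,
                    "year": year,
                    "period": f"{a}-{b}",
                    "recruitment": rec,
                }
                for name, g in covariate_grids.items():
                    nodes = np.flatnonzero(cov_membership[name] == region)
                    pm = cov_period_means[name][(a, b)][nodes]
                    row[name] = (
                        float(np.nanmean(pm)) if np.isfinite(pm).any() else np.nan
                    )
                rows.append(row)
    df = pd.DataFrame(rows)
    value_cols = [c for c in df.columns if c not in ("region", "year", "period")]
    df["incomplete"] = df[value_cols].isna().any(axis=1)
    return df


# -- screening -------------------------------------------------------------


def spearman_screen(
    series: pd.DataFrame, pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Spearman rank correlation (average ranks for ties) per variable pair.

    A constant variable yields a flagged row (rho = NaN) rather than an
    exception.  Requires >= 5 paired complete observations.
    """
    rows = []
    for a, b in pairs:
        sub = pd.DataFrame(
            {"_a": series[a].to_numpy(float), "_b": series[b].to_numpy(float)}
        ).dropna()
        if len(sub) < 5:
            raise InvalidInputError(
                f"fewer than 5 paired observations for ({a}, {b})"
            )
        xa, xb = sub["_a"].to_numpy(), sub["_b"].to_numpy()
        if np.ptp(xa) == 0 or np.ptp(xb) == 0:
            rows.append(
                {"var_a": a, "var_b": b, "rho": np.nan, "p_value": np.nan,
                 "n": len(sub), "flag": "constant-variable"}
            )
            continue
        rho, p = stats.spearmanr(xa, xb)
        rows.append(
            {"var_a": a, "var_b": b, "rho": float(rho), "p_value": float(p),
             "n": len(sub), "flag": ""}
        )
    return pd.DataFrame(rows)


# -- covariate model design ------------------------------------------------


@dataclass
class CovariateModel:
    """A fitted polygon + polynomial-covariate model."""

    response: str
    terms: tuple[tuple[str, int], ...]
    polygon_effect: bool
    interactions: tuple[str, ...]
    family: str
    coefficients: np.ndarray
    columns: list[str]
    standardizers: dict[str, tuple[float, float]]
    regions: tuple[str, ...]
    n_obs: int
    dof_used: int
    deviance_null: float
    deviance_resid: float

    @property
    def explained_deviance_pct(self) -> float:
        return 100.0 * (1.0 - self.deviance_resid / self.deviance_null)

    def linear_coefficient(self, covariate: str) -> float:
        """Coefficient of a covariate's (standardised) linear term."""
        col = f"{covariate}^1"
        if col not in self.columns:
            raise InvalidConfigError(f"no linear term for {covariate!r}")
        return float(self.coefficients[self.columns.index(col)])

    def marginal_sign(self, covariate: str) -> int:
        """Sign of d(response)/d(covariate) at the covariate's mean.

        At the mean the standardised covariate is 0, so only the linear
        term's coefficient contributes.
        """
        return int(np.sign(self.linear_coefficient(covariate)))


def _design_matrix(
    series: pd.DataFrame,
    response: str,
    terms,
    polygon_effect: bool,
    interactions,
    standardizers: dict[str, tuple[float, float]],
    regions: tuple[str, ...],
):
    n = len(series)
    cols = [np.ones(n)]
    names = ["intercept"]
    if polygon_effect:
        reg = series["region"].to_numpy()
        for r in regions[1:]:  # first region is the reference level
            cols.append((reg == r).astype(float))
            names.append(f"polygon[{r}]")
    std_values = {}
    for cov, degree in terms:
        m, s = standardizers[cov]
        x = series[cov].to_numpy(float)
        # non-finite scale marks a constant covariate: zero columns,
        # dropped later as aliased
        z = (x - m) / s if np.isfinite(s) else np.zeros(n)
        std_values[cov] = z
        for d in range(1, degree + 1):
            cols.append(z**d)
            names.append(f"{cov}^{d}")
    for inter in interactions:
        kind, *parts = inter.split(":")
        if kind == "polygon":
            (cov,) = parts
            reg = series["region"].to_numpy()
            for r in regions[1:]:
                cols.append(std_values[cov] * (reg == r))
                names.append(f"polygon[{r}]*{cov}")
        elif kind == "product":
            a, b = parts
            cols.append(std_values[a] * std_values[b])
            names.append(f"{a}*{b}")
        else:
            raise InvalidConfigError(f"unknown interaction {inter!r}")
    X = np.column_stack(cols)
    y = series[response].to_numpy(float)
    return X, y, names


def fit_covariate_model(
    series: pd.DataFrame,
    response: str,
    terms: list[tuple[str, int]],
    family: str = "gaussian",
    polygon_effect: bool = True,
    interactions: tuple[str, ...] = (),
    strict: bool = True,
) -> CovariateModel:
    """Fit response ~ [polygon] + sum of covariate polynomials on full data.

    A constant covariate raises :class:`SingularFitError` when ``strict``;
    otherwise its columns are zero and get dropped as aliased (zero
    coefficient, zero contribution).
    """
    sub = series.dropna(subset=[response] + [t[0] for t in terms])
    if len(sub) == 0:
        raise InvalidInputError("no complete rows")
    regions = tuple(sorted(sub["region"].unique()))
    standardizers = {}
    for cov, _deg in terms:
        x = sub[cov].to_numpy(float)
        sd = float(np.std(x))
        if sd == 0:
            if strict:
                raise SingularFitError(f"covariate {cov!r} is constant")
            sd = np.nan  # zero columns below
        standardizers[cov] = (float(np.mean(x)), sd)
    X, y, names = _design_matrix(
        sub, response, terms, polygon_effect, interactions, standardizers, regions
    )
    if family == "gaussian":
        beta, rank, _ = solve_least_squares(X, y)
        null, resid = gaussian_deviances(y, X @ beta)
        dof = rank
    elif family == "binomial":
        res = _fit_binomial(X, y)
        beta = np.asarray(res.params, float)
        mu = expit(X @ beta)
        resid = binomial_deviance(y, mu)
        null = binomial_deviance(y, np.full_like(y, float(np.mean(y))))
        dof = X.shape[1]
    else:
        raise InvalidConfigError(f"unknown family {family!r}")
    return CovariateModel(
        response=response,
        terms=tuple((c, d) for c, d in terms),
        polygon_effect=polygon_effect,
        interactions=tuple(interactions),
        family=family,
        coefficients=beta,
        columns=names,
        standardizers=standardizers,
        regions=regions,
        n_obs=len(sub),
        dof_used=dof,
        deviance_null=null,
        deviance_resid=resid,
    )


class LinkageCandidate:
    """CV adapter for one covariate-model formula on a polygon series."""

    def __init__(
        self,
        response: str,
        terms: list[tuple[str, int]],
        family: str = "gaussian",
        polygon_effect: bool = True,
        interactions: tuple[str, ...] = (),
        label: str | None = None,
    ):
        self.response = response
        self.terms = list(terms)
        self.family = family
        self.polygon_effect = polygon_effect
        self.interactions = tuple(interactions)
        self.label = label or "+".join(f"{c}^{d}" for c, d in terms) or "null"
        self.n_thresholds = 0
        self._X = None
        self._y = None

    @property
    def n_params(self) -> int:
        return 0 if self._X is None else self._X.shape[1]

    def prepare(self, records: pd.DataFrame) -> None:
        regions = tuple(sorted(records["region"].unique()))
        standardizers = {}
        for cov, _d in self.terms:
            x = records[cov].to_numpy(float)
            sd = float(np.std(x))
            # a constant covariate contributes zero columns (zero gain)
            standardizers[cov] = (float(np.mean(x)), sd if sd > 0 else np.nan)
        self._X, self._y, self._names = _design_matrix(
            records,
            self.response,
            self.terms,
            self.polygon_effect,
            self.interactions,
            standardizers,
            regions,
        )

    def period_rows(self):
        return [np.arange(self._y.size)]

    def fit_score(self, train: np.ndarray, val: np.ndarray):
        Xt, yt = self._X[train], self._y[train]
        Xv, yv = self._X[val], self._y[val]
        if self.family == "gaussian":
            beta, rank, _ = solve_least_squares(Xt, yt)
            rss_t = float(np.sum((yt - Xt @ beta) ** 2))
            aic = gaussian_aic(yt.size, rss_t, rank)
            null_v, resid_v = gaussian_deviances(yv, Xv @ beta)
            p_used = rank
        else:
            res = _fit_binomial(Xt, yt)
            beta = np.asarray(res.params, float)
            aic = float(res.aic)
            mu = expit(Xv @ beta)
            null_v = binomial_deviance(yv, np.full_like(yv, float(np.mean(yv))))
            resid_v = binomial_deviance(yv, mu)
            p_used = Xt.shape[1]
        d2, d2_adj = adjusted_explained_deviance(null_v, resid_v, yv.size, p_used)
        return aic, d2, d2_adj, p_used


def fit_single_covariate(
    series: pd.DataFrame,
    covariate: str,
    response: str = "recruitment",
    family: str = "gaussian",
    degree: int = 2,
    polygon_effect: bool = True,
    cv: bool = True,
    n_replicates: int = 50,
    split: float = 0.75,
    seed: int | None = None,
):
    """Single-covariate model with full-data and cross-validated deviance.

    Returns (model, cv_summary) — ``cv_summary`` is None when cv=False.
    Degree is capped at 2: quadratic covariate responses were the best
    supported shape at these sample sizes.
    """
    if degree > 2:
        raise InvalidConfigError("covariate polynomial degree is capped at 2")
    sub = series.dropna(subset=[response, covariate]).reset_index(drop=True)
    model = fit_covariate_model(
        sub, response, [(covariate, degree)], family, polygon_effect
    )
    summary = None
    if cv:
        cand = LinkageCandidate(
            response, [(covariate, degree)], family, polygon_effect
        )
        summary = bootstrap_cv(
            sub, [cand], n_replicates=n_replicates, split=split, seed=seed,
            min_per_period=1,
        )[0]
    return model, summary


# -- stepwise recruitment model --------------------------------------------


@dataclass
class StepwiseStep:
    name: str
    candidates: list[dict]
    selected: str | None
    stopping_reason: str


@dataclass
class StepwiseTrace:
    steps: list[StepwiseStep] = dc_field(default_factory=list)
    seed: int | None = None
    alpha: float = 0.05
    gain_floor_pct: float = DEFAULT_GAIN_FLOOR_PCT

    @property
    def selected_covariates(self) -> list[str]:
        return [s.selected for s in self.steps if s.selected]


def _cv_gain_step(
    series, response, base_terms, additions, family, polygon_effect,
    interactions, n_replicates, split, seed, alpha, gain_floor_pct,
):
    """Cross-validated D2_adj gain of each addition over the base formula,
    on shared splits.  Returns (candidate rows, best addition or None)."""
    cands = [
        LinkageCandidate(
            response, base_terms, family, polygon_effect, interactions,
            label="base",
        )
    ]
    for add in additions:
        cands.append(
            LinkageCandidate(
                response, base_terms + [add], family, polygon_effect,
                interactions, label=add[0],
            )
        )
    summaries = bootstrap_cv(
        series, cands, n_replicates=n_replicates, split=split, seed=seed,
        min_per_period=1,
    )
    common = np.logical_and.reduce([s.ok for s in summaries])
    base_scores = summaries[0].d2_adj[common]
    rows, best, best_gain = [], None, -np.inf
    for add, summ in zip(additions, summaries[1:]):
        scores = summ.d2_adj[common]
        gain = 100.0 * float(np.mean(scores) - np.mean(base_scores))
        sd = 100.0 * float(np.std(scores - base_scores, ddof=1))
        p = paired_pvalue(scores, base_scores)
        passed = gain >= gain_floor_pct and p < alpha
        rows.append(
            {
                "covariate": add[0],
                "gain_pct": gain,
                "gain_sd_pct": sd,
                "p_value": p,
                "significant": bool(passed),
            }
        )
        if passed and gain > best_gain:
            best, best_gain = add, gain
    return rows, best


def stepwise_recruitment_model(
    series: pd.DataFrame,
    zooplankton_candidates: list[str],
    response: str = "recruitment",
    ssb: str = "ssb",
    spring_sst: str = "sst_spring",
    degree: int = 2,
    polygon_effect: bool = True,
    interactions: tuple[str, ...] = (),
    alpha: float = 0.05,
    gain_floor_pct: float = DEFAULT_GAIN_FLOOR_PCT,
    n_replicates: int = 50,
    split: float = 0.75,
    seed: int | None = None,
):
    """Stepwise recruitment model: SSB first, then zooplankton, then SST.

    Step 1 fixes the SSB index (recruit numbers depend on the adult stock);
    subsequent steps add the zooplankton descriptor with the largest
    cross-validated gain in explained deviance, accepted only when the
    paired t-test rejects at ``alpha`` AND the mean gain reaches
    ``gain_floor_pct`` (gains below 3 percentage points count as NS);
    finally spring SST enters iff its residual contribution passes the same
    rule.  Returns (final CovariateModel, StepwiseTrace).
    """
    needed = [response, ssb, spring_sst, *zooplankton_candidates]
    sub = series.dropna(subset=needed).reset_index(drop=True)
    trace = StepwiseTrace(seed=seed, alpha=alpha, gain_floor_pct=gain_floor_pct)

    base_terms: list[tuple[str, int]] = [(ssb, degree)]
    rows, _ = _cv_gain_step(
        sub, response, [], [(ssb, degree)], "gaussian", polygon_effect,
        interactions, n_replicates, split, seed, alpha, 0.0,
    )
    trace.steps.append(
        StepwiseStep(
            name="ssb",
            candidates=rows,
            selected=ssb,
            stopping_reason="fixed first covariate",
        )
    )

    remaining = list(zooplankton_candidates)
    step_i = 0
    while remaining:
        step_i += 1
        rows, best = _cv_gain_step(
            sub, response, base_terms, [(z, degree) for z in remaining],
            "gaussian", polygon_effect, interactions,
            n_replicates, split, seed, alpha, gain_floor_pct,
        )
        if best is None:
            trace.steps.append(
                StepwiseStep(
                    name=f"zooplankton_{step_i}",
                    candidates=rows,
                    selected=None,
                    stopping_reason=(
                        "no candidate passed the significance and "
                        f"{gain_floor_pct}%-gain rule"
                    ),
                )
            )
            break
        base_terms.append(best)
        remaining.remove(best[0])
        trace.steps.append(
            StepwiseStep(
                name=f"zooplankton_{step_i}",
                candidates=rows,
                selected=best[0],
                stopping_reason="largest significant gain",
            )
        )

    rows, best = _cv_gain_step(
        sub, response, base_terms, [(spring_sst, degree)], "gaussian",
        polygon_effect, interactions, n_replicates, split, seed, alpha,
        gain_floor_pct,
    )
    if best is not None:
        base_terms.append(best)
    trace.steps.append(
        StepwiseStep(
            name="sst",
            candidates=rows,
            selected=spring_sst if best is not None else None,
            stopping_reason=(
                "significant residual contribution"
                if best is not None
                else "residual SST contribution not significant"
            ),
        )
    )

    final = fit_covariate_model(
        sub, response, base_terms, "gaussian", polygon_effect, interactions
    )
    return final, trace


def ssb_sst_model(
    series: pd.DataFrame,
    ssb: str = "ssb",
    sst: str = "sst_annual",
    fbar: str | None = None,
    degree: int = 2,
    polygon_effect: bool = True,
    n_replicates: int = 50,
    split: float = 0.75,
    seed: int | None = None,
):
    """Effect of lagged SST (and optionally fishing pressure) on the adult
    stock: SSB ~ polygon + poly(SST) [+ poly(exp(-Fbar))].

    The Fbar covariate is a single annual series broadcast to all polygons
    (fishing mortality is not spatially resolved), entered as exp(-Fbar).
    Returns a dict with the fitted model, full-data explained deviance, and
    the cross-validated gain of each covariate over the polygon-only base.
    """
    terms: list[tuple[str, int]] = [(sst, degree)]
    if fbar is not None:
        terms.append((fbar, degree))
    needed = [ssb] + [t[0] for t in terms]
    sub = series.dropna(subset=needed).reset_index(drop=True)
    model = fit_covariate_model(
        sub, ssb, terms, "gaussian", polygon_effect, strict=False
    )
    rows, _ = _cv_gain_step(
        sub, ssb, [], [(sst, degree)], "gaussian", polygon_effect, (),
        n_replicates, split, seed, 0.05, 0.0,
    )
    gains = {sst: rows[0]}
    if fbar is not None:
        rows, _ = _cv_gain_step(
            sub, ssb, [(sst, degree)], [(fbar, degree)], "gaussian",
            polygon_effect, (), n_replicates, split, seed, 0.05, 0.0,
        )
        gains[fbar] = rows[0]
    return {
        "model": model,
        "explained_deviance_pct": model.explained_deviance_pct,
        "cv_gains": gains,
    }
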