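"""Period-partitioned spatial surface models.

The response (log CPUE + 1 at haul positions) is modelled as a separate
bivariate surface of (corrected longitude, latitude) per *period*, where
periods are delimited by candidate turnover years.  Two engines share the
machinery:

* ``polynomial`` — all monomials lon^a * lat^b with total degree a+b <= k,
  crossed with the period factor (the reference engine; the parametric
  surface family is robust at survey sample sizes);
* ``tensor`` — the full tensor product a <= k and b <= k per period, i.e. an
  unpenalized tensor-product smooth with marginal polynomial bases of
  dimension k+1 (single effects of latitude and longitude plus their
  interaction).

Gaussian fits use pivoted-QR least squares; binomial fits (for bounded
proportion responses such as a Calanus-community ratio) use a logit-link GLM
on the continuous proportion with unit weights.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.special import expit

from .errors import (
    EmptyPeriodError,
    InvalidConfigError,
    InvalidInputError,
    SingularFitError,
)
from .gridding import PeriodPartition

_RANK_TOL = 1e-10


@dataclass(frozen=True)
class ThresholdSpec:
    """An ordered set of 0-4 turnover years within a study window.

    A turnover year is the first year of the new period; every induced
    period must span at least two calendar years.
    """

    start_year: int
    end_year: int
    turnover_years: tuple[int, ...] = ()

    def __post_init__(self):
        object.__setattr__(
            self, "turnover_years", tuple(sorted(int(t) for t in self.turnover_years))
        )
        if len(set(self.turnover_years)) != len(self.turnover_years):
            raise InvalidConfigError("duplicate turnover years")
        for t in self.turnover_years:
            if not (self.start_year < t <= self.end_year):
                raise InvalidConfigError(
                    f"turnover year {t} outside study range "
                    f"({self.start_year}, {self.end_year}]"
                )
        for a, b in self.partition.periods:
            if b - a + 1 < 2:
                raise InvalidConfigError(
                    f"period {a}-{b} spans fewer than 2 years"
                )

    @property
    def partition(self) -> PeriodPartition:
        return PeriodPartition(self.start_year, self.end_year, self.turnover_years)

    @property
    def n_thresholds(self) -> int:
        return len(self.turnover_years)

    @property
    def n_periods(self) -> int:
        return len(self.turnover_years) + 1

    def with_year(self, year: int) -> "ThresholdSpec":
        return ThresholdSpec(
            self.start_year, self.end_year, self.turnover_years + (year,)
        )

    def label(self) -> str:
        inner = ",".join(str(t) for t in self.turnover_years) or "none"
        return f"thr[{inner}]"


def admissible_years(spec: ThresholdSpec) -> list[int]:
    """Interior years that can be added while keeping all periods >= 2 years."""
    out = []
    for y in range(spec.start_year + 1, spec.end_year + 1):
        if y in spec.turnover_years:
            continue
        try:
            spec.with_year(y)
        except InvalidConfigError:
            continue
        out.append(y)
    return out


def enumerate_threshold_specs(
    start_year: int, end_year: int, max_thresholds: int
) -> list[ThresholdSpec]:
    """All admissible threshold sets of size 0..max_thresholds.

    Deterministic lexicographic order: by threshold count, then by the year
    tuple.  Consecutive boundaries (including the study endpoints) must be
    at least two years apart.
    """
    if not (0 <= max_thresholds <= 4):
        raise InvalidConfigError("max_thresholds must be in 0..4")
    if end_year - start_year + 1 < 4 and max_thresholds > 0:
        # the smallest range that can host one threshold is 4 years
        max_thresholds = 0
    interior = range(start_year + 2, end_year)  # first/last period >= 2 years
    specs = [ThresholdSpec(start_year, end_year)]
    for k in range(1, max_thresholds + 1):
        for combo in itertools.combinations(interior, k):
            if all(combo[i + 1] - combo[i] >= 2 for i in range(k - 1)):
                specs.append(ThresholdSpec(start_year, end_year, combo))
    return specs


def polynomial_exponents(degree_k: int, engine: str = "polynomial"):
    """Deterministic (a, b) exponent order for one period's surface basis."""
    if degree_k < 0:
        raise InvalidConfigError("degree must be >= 0")
    if engine == "polynomial":
        pairs = [
            (a, t - a) for t in range(degree_k + 1) for a in range(t, -1, -1)
        ]
    elif engine == "tensor":
        pairs = sorted(
            ((a, b) for a in range(degree_k + 1) for b in range(degree_k + 1)),
            key=lambda ab: (ab[0] + ab[1], -ab[0]),
        )
    else:
        raise InvalidConfigError(f"unknown engine {engine!r}")
    return pairs


@dataclass
class CoordTransform:
    """Affine standardisation of (lon_corr, lat) used inside the basis.

    Raw monomials of coordinates in the fifties (degrees north) are badly
    conditioned at degree 4; centring and scaling fixes that without
    changing the fitted surface.
    """

    x_center: float
    x_scale: float
    y_center: float
    y_scale: float

    @classmethod
    def from_records(cls, records: pd.DataFrame) -> "CoordTransform":
        x = records["lon_corr"].to_numpy()
        y = records["lat"].to_numpy()
        return cls(
            float(np.mean(x)),
            float(np.std(x)) or 1.0,
            float(np.mean(y)),
            float(np.std(y)) or 1.0,
        )

    def apply(self, lon_corr, lat):
        return (
            (np.asarray(lon_corr, float) - self.x_center) / self.x_scale,
            (np.asarray(lat, float) - self.y_center) / self.y_scale,
        )


@dataclass
class Design:
    """Design matrix for a period-partitioned surface model."""

    X: np.ndarray
    y: np.ndarray
    columns: list[str]
    period_idx: np.ndarray
    spec: ThresholdSpec
    engine: str
    degree_k: int
    transform: CoordTransform
    exponents: list[tuple[int, int]]

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def n_cols(self) -> int:
        return self.X.shape[1]


def build_design(
    records: pd.DataFrame,
    spec: ThresholdSpec,
    engine: str = "polynomial",
    degree_k: int = 2,
    transform: CoordTransform | None = None,
    require_nonempty: bool = True,
) -> Design:
    """Design matrix: one surface basis block per period.

    Records need columns ``lon_corr``, ``lat``, ``year``, ``response``.
    Raises :class:`EmptyPeriodError` when a period has no records.
    """
    years = records["year"].to_numpy(int)
    if years.min() < spec.start_year or years.max() > spec.end_year:
        raise InvalidInputError("record years outside the study range")
    part = spec.partition
    pidx = part.period_index(years)
    if require_nonempty:
        counts = np.bincount(pidx, minlength=part.n_periods)
        for p, c in enumerate(counts):
            if c == 0:
                a, b = part.periods[p]
                raise EmptyPeriodError(f"period {a}-{b} contains no records")
    if transform is None:
        transform = CoordTransform.from_records(records)
    x, yc = transform.apply(
        records["lon_corr"].to_numpy(), records["lat"].to_numpy()
    )
    exps = polynomial_exponents(degree_k, engine)
    n = years.size
    n_basis = len(exps)
    X = np.zeros((n, part.n_periods * n_basis))
    columns = []
    # cache powers once, reuse across periods
    xp = {a: x**a for a in {a for a, _ in exps}}
    yp = {b: yc**b for b in {b for _, b in exps}}
    for p in range(part.n_periods):
        rows = pidx == p
        for j, (a, b) in enumerate(exps):
            col = p * n_basis + j
            X[rows, col] = xp[a][rows] * yp[b][rows]
            columns.append(f"P{p}:x^{a}*y^{b}")
    return Design(
        X=X,
        y=records["response"].to_numpy(float),
        columns=columns,
        period_idx=pidx,
        spec=spec,
        engine=engine,
        degree_k=degree_k,
        transform=transform,
        exponents=exps,
    )


def solve_least_squares(X: np.ndarray, y: np.ndarray):
    """Pivoted-QR least squares, dropping aliased columns.

    Returns (beta, rank, kept) where dropped (aliased) columns get a zero
    coefficient and ``kept`` marks the retained ones.  Deterministic.
    """
    n, p = X.shape
    beta, _, rank, _ = scipy.linalg.lstsq(
        X, y, lapack_driver="gelsy", cond=_RANK_TOL
    )
    kept = np.ones(p, dtype=bool)
    if rank < p:
        # identify an explicit maximal independent column subset via
        # pivoted QR so dropped columns are reported, then re-solve
        _, _, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
        keep_idx = np.sort(piv[:rank])
        kept = np.zeros(p, dtype=bool)
        kept[keep_idx] = True
        warnings.warn(
            f"dropping {p - rank} aliased column(s): "
            f"{np.flatnonzero(~kept).tolist()}",
            stacklevel=2,
        )
        beta = np.zeros(p)
        sub, _, _, _ = scipy.linalg.lstsq(
            X[:, kept], y, lapack_driver="gelsy", cond=_RANK_TOL
        )
        beta[kept] = sub
    return beta, int(rank), kept


@dataclass
class FittedThresholdModel:
    """A fitted period-partitioned surface model with its deviance ledger."""

    spec: ThresholdSpec
    engine: str
    degree_k: int
    family: str
    coefficients: np.ndarray
    columns: list[str]
    transform: CoordTransform
    exponents: list[tuple[int, int]] = field(repr=False, default_factory=list)
    n_obs: int = 0
    dof_used: int = 0
    deviance_null: float = float("nan")
    deviance_resid: float = float("nan")

    @property
    def explained_deviance(self) -> float:
        """D^2 = (null - residual) / null deviance, on the training data."""
        return 1.0 - self.deviance_resid / self.deviance_null

    def coefficient_blocks(self) -> dict[str, dict[str, float]]:
        n_basis = len(self.exponents)
        blocks = {}
        for p, (a, b) in enumerate(self.spec.partition.periods):
            sl = slice(p * n_basis, (p + 1) * n_basis)
            blocks[f"{a}-{b}"] = {
                self.columns[p * n_basis + j].split(":", 1)[1]: float(c)
                for j, c in enumerate(self.coefficients[sl])
            }
        return blocks

    def predict(self, lon_corr, lat, period: int) -> np.ndarray:
        return predict_surface(self, lon_corr, lat, period)

    def to_dict(self) -> dict:
        return {
            "spec": {
                "start_year": self.spec.start_year,
                "end_year": self.spec.end_year,
                "turnover_years": list(self.spec.turnover_years),
            },
            "engine": self.engine,
            "family": self.family,
            "degree_k": self.degree_k,
            "transform": vars(self.transform),
            "coefficients": self.coefficients.tolist(),
            "columns": self.columns,
            "exponents": [list(e) for e in self.exponents],
            "n_obs": self.n_obs,
            "dof_used": self.dof_used,
            "deviance_null": self.deviance_null,
            "deviance_resid": self.deviance_resid,
        }

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "FittedThresholdModel":
        return cls(
            spec=ThresholdSpec(
                d["spec"]["start_year"],
                d["spec"]["end_year"],
                tuple(d["spec"]["turnover_years"]),
            ),
            engine=d["engine"],
            family=d["family"],
            degree_k=d["degree_k"],
            coefficients=np.asarray(d["coefficients"], float),
            columns=list(d["columns"]),
            transform=CoordTransform(**d["transform"]),
            exponents=[tuple(e) for e in d["exponents"]],
            n_obs=d["n_obs"],
            dof_used=d["dof_used"],
            deviance_null=d["deviance_null"],
            deviance_resid=d["deviance_resid"],
        )

    @classmethod
    def load(cls, path) -> "FittedThresholdModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def gaussian_deviances(y: np.ndarray, fitted: np.ndarray):
    resid = float(np.sum((y - fitted) ** 2))
    null = float(np.sum((y - np.mean(y)) ** 2))
    return null, resid


def binomial_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    """Deviance for a continuous proportion under the binomial family."""
    mu = np.clip(mu, 1e-10, 1 - 1e-10)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        t2 = np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0.0)
    return float(2.0 * np.sum(t1 + t2))


def _fit_binomial(X: np.ndarray, y: np.ndarray):
    import statsmodels.api as sm

    if np.any(y < 0) or np.any(y > 1):
        raise InvalidInputError("binomial response outside [0, 1]")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # non-integer counts are intentional
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    return res


def fit_threshold_model(
    records: pd.DataFrame,
    spec: ThresholdSpec,
    engine: str = "polynomial",
    degree_k: int = 2,
    family: str = "gaussian",
    transform: CoordTransform | None = None,
) -> FittedThresholdModel:
    """Maximum-likelihood fit of the period-partitioned surface model.

    Gaussian responses use least squares; binomial (proportion) responses a
    logit-link GLM.  The null deviance comes from the per-family
    intercept-only fit on the same data.
    """
    design = build_design(records, spec, engine, degree_k, transform)
    return fit_design(design, family)


def fit_design(design: Design, family: str = "gaussian") -> FittedThresholdModel:
    X, y = design.X, design.y
    if family == "gaussian":
        beta, rank, kept = solve_least_squares(X, y)
        if rank == 0:
            raise SingularFitError("design has no independent columns")
        fitted = X @ beta
        null, resid = gaussian_deviances(y, fitted)
        dof = rank
    elif family == "binomial":
        res = _fit_binomial(X, y)
        beta = np.asarray(res.params, float)
        fitted = expit(X @ beta)
        resid = binomial_deviance(y, fitted)
        null = binomial_deviance(y, np.full_like(y, float(np.mean(y))))
        dof = X.shape[1]
    else:
        raise InvalidConfigError(f"unknown family {family!r}")
    if design.n_obs <= dof:
        raise SingularFitError(
            f"model uses {dof} dof with only {design.n_obs} observations"
        )
    return FittedThresholdModel(
        spec=design.spec,
        engine=design.engine,
        degree_k=design.degree_k,
        family=family,
        coefficients=beta,
        columns=design.columns,
        transform=design.transform,
        exponents=design.exponents,
        n_obs=design.n_obs,
        dof_used=dof,
        deviance_null=null,
        deviance_resid=resid,
    )


def predict_surface(
    model: FittedThresholdModel, lon_corr, lat, period: int
) -> np.ndarray:
    """Evaluate one period's surface at the given node coordinates."""
    n_periods = model.spec.n_periods
    if not (0 <= period < n_periods):
        raise InvalidConfigError(
            f"period {period} not in 0..{n_periods - 1}"
        )
    x, yc = model.transform.apply(lon_corr, lat)
    n_basis = len(model.exponents)
    block = model.coefficients[period * n_basis : (period + 1) * n_basis]
    eta = np.zeros(np.shape(x))
    for (a, b), c in zip(model.exponents, block):
        eta = eta + c * x**a * yc**b
    if model.family == "binomial":
        return expit(eta)
    return np.asarray(eta, float)
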