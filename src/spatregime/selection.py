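"""Model selection by repeated 75/25 split cross-validation.

Each of the (default) 50 replicates draws a random 75% training subsample
WITHOUT replacement; every candidate model is fitted on the same training
rows and scored on the same held-out 25% (paired comparison).  Scores are
the training AIC and the adjusted explained deviance D2_adj on the
validation subsample, using the validation subsample's own null deviance.
Candidate score distributions are compared with a paired t-test; the winner
is the most parsimonious candidate not significantly worse than the best.
D2_adj is the primary criterion; AIC is reported as a secondary diagnostic
(AIC alone tends to overestimate the number of parameters needed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .errors import (
    EmptyPeriodError,
    InvalidConfigError,
    InvalidInputError,
    UndefinedAdjustmentError,
)
from .thresholds import (
    ThresholdSpec,
    binomial_deviance,
    build_design,
    enumerate_threshold_specs,
    gaussian_deviances,
    solve_least_squares,
    _fit_binomial,
)

MAX_SPLIT_RETRIES = 25
#: candidates failing in more than this fraction of replicates are dropped
DISQUALIFY_FRACTION = 0.2


def adjusted_explained_deviance(
    null_dev: float, resid_dev: float, n: int, p: int
) -> tuple[float, float]:
    """Explained deviance D2 and its dof-adjusted version.

    D2 = (null - resid) / null;  D2_adj = 1 - [(n-1)/(n-p)] * (1 - D2).
    """
    if null_dev <= 0:
        raise InvalidInputError("null deviance must be positive")
    if p < 1 or n <= p:
        raise UndefinedAdjustmentError(f"n={n} must exceed p={p} >= 1")
    d2 = (null_dev - resid_dev) / null_dev
    d2_adj = 1.0 - ((n - 1) / (n - p)) * (1.0 - d2)
    return float(d2), float(d2_adj)


def gaussian_aic(n: int, rss: float, p: int) -> float:
    """AIC of a gaussian fit with estimated scale: profile log-likelihood."""
    rss = max(rss, 1e-300)
    return float(n * np.log(2.0 * np.pi * rss / n) + n + 2.0 * (p + 1))


class ThresholdCandidate:
    """CV adapter for one (spec, engine, degree, family) surface model.

    The design is block-diagonal in the period factor: each period's
    surface is fit independently on that period's rows.  Candidates with a
    shared ``cv_shared_cache`` dict (installed by :func:`bootstrap_cv`)
    therefore reuse per-(split, period) gaussian fits across threshold
    sets, which makes enumerating many candidate specs cheap without
    changing any result.
    """

    def __init__(
        self,
        spec: ThresholdSpec,
        engine: str = "polynomial",
        degree_k: int = 2,
        family: str = "gaussian",
    ):
        self.spec = spec
        self.engine = engine
        self.degree_k = degree_k
        self.family = family
        self.label = f"{spec.label()}|{engine}|k={degree_k}"
        self.n_thresholds = spec.n_thresholds
        self.cv_shared_cache: dict | None = None
        self._design = None

    @property
    def n_params(self) -> int:
        from .thresholds import polynomial_exponents

        return self.spec.n_periods * len(
            polynomial_exponents(self.degree_k, self.engine)
        )

    def prepare(self, records: pd.DataFrame) -> None:
        # single-period basis (no period crossing); the crossed design is
        # recovered by fitting it independently on each period's rows
        base = ThresholdSpec(self.spec.start_year, self.spec.end_year)
        self._design = build_design(records, base, self.engine, self.degree_k)
        self._years = records["year"].to_numpy(int)
        self._period_idx = self.spec.partition.period_index(self._years)

    def period_rows(self) -> list[np.ndarray]:
        return [
            np.flatnonzero(self._period_idx == p)
            for p in range(self.spec.n_periods)
        ]

    def _fit_period_gaussian(self, train_mark, a, b, split_key):
        """Fit one period's surface on its training rows; return
        (rank, train RSS, validation SSE), cached per (split, period)."""
        key = (split_key, a, b, self.engine, self.degree_k)
        cache = self.cv_shared_cache
        if cache is not None and key in cache:
            return cache[key]
        B, y = self._design.X, self._design.y
        in_period = (self._years >= a) & (self._years <= b)
        rows_t = np.flatnonzero(in_period & train_mark)
        if rows_t.size == 0:
            raise EmptyPeriodError(
                f"training subsample misses period {a}-{b}"
            )
        rows_v = np.flatnonzero(in_period & ~train_mark)
        Xt, yt = B[rows_t], y[rows_t]
        beta, rank, _ = solve_least_squares(Xt, yt)
        rss_t = float(np.sum((yt - Xt @ beta) ** 2))
        sse_v = float(np.sum((y[rows_v] - B[rows_v] @ beta) ** 2))
        out = (rank, rss_t, sse_v)
        if cache is not None:
            cache[key] = out
        return out

    def fit_score(self, train: np.ndarray, val: np.ndarray):
        """Fit on the training rows, score on the validation rows.

        Returns (aic, d2, d2_adj, p_used).
        """
        d = self._design
        y = d.y
        yv = y[val]
        if self.family == "gaussian":
            train_mark = np.zeros(y.size, bool)
            train_mark[train] = True
            split_key = hash(train.tobytes())
            rank_total, rss_train, resid_v = 0, 0.0, 0.0
            for (a, b) in self.spec.partition.periods:
                rank, rss_t, sse_v = self._fit_period_gaussian(
                    train_mark, a, b, split_key
                )
                rank_total += rank
                rss_train += rss_t
                resid_v += sse_v
            aic = gaussian_aic(train.size, rss_train, rank_total)
            null_v = float(np.sum((yv - np.mean(yv)) ** 2))
            p_used = rank_total
        else:
            Xfull = self._crossed_design()
            Xt, yt = Xfull[train], y[train]
            if np.bincount(
                self._period_idx[train], minlength=self.spec.n_periods
            ).min() == 0:
                raise EmptyPeriodError("training subsample misses a period")
            res = _fit_binomial(Xt, yt)
            beta = np.asarray(res.params, float)
            aic = float(res.aic)
            mu_v = expit(Xfull[val] @ beta)
            null_v = binomial_deviance(yv, np.full_like(yv, float(np.mean(yv))))
            resid_v = binomial_deviance(yv, mu_v)
            p_used = Xt.shape[1]
        d2, d2_adj = adjusted_explained_deviance(
            null_v, resid_v, yv.size, p_used
        )
        return aic, d2, d2_adj, p_used

    def _crossed_design(self) -> np.ndarray:
        """Full period-crossed design (binomial path only)."""
        B = self._design.X
        n_basis = B.shape[1]
        X = np.zeros((B.shape[0], self.spec.n_periods * n_basis))
        for p in range(self.spec.n_periods):
            rows = self._period_idx == p
            X[rows, p * n_basis : (p + 1) * n_basis] = B[rows]
        return X


@dataclass
class CVSummary:
    """Replicate-level scores of one candidate over the shared splits."""

    label: str
    n_thresholds: int
    n_params: int
    aic: np.ndarray
    d2_adj: np.ndarray
    d2: np.ndarray
    ok: np.ndarray
    n_replicates: int
    split_fraction: float
    seed: int | None
    disqualified: bool = False
    disqualify_reason: str | None = None
    split_hashes: tuple[int, ...] = field(default=(), repr=False)

    @property
    def mean_d2_adj(self) -> float:
        return float(np.mean(self.d2_adj[self.ok]))

    @property
    def sd_d2_adj(self) -> float:
        return float(np.std(self.d2_adj[self.ok], ddof=1))

    @property
    def mean_aic(self) -> float:
        return float(np.mean(self.aic[self.ok]))


def _draw_splits(n, n_replicates, split, rng, candidates, min_per_period):
    """Shared train/validation row splits, re-drawn until every candidate's
    periods are sufficiently represented in the training subsample."""
    n_train = int(round(split * n))
    if not (0 < n_train < n):
        raise InvalidConfigError("split leaves an empty train or val set")
    period_rows = [c.period_rows() for c in candidates]
    splits = []
    for _ in range(n_replicates):
        for _attempt in range(MAX_SPLIT_RETRIES):
            perm = rng.permutation(n)
            train = np.sort(perm[:n_train])
            train_mark = np.zeros(n, bool)
            train_mark[train] = True
            ok = all(
                min(int(train_mark[rows].sum()) for rows in rows_list)
                >= min_per_period
                for rows_list in period_rows
            )
            if ok:
                break
        else:
            raise InvalidConfigError(
                "could not draw a split covering every period; "
                "reduce min_per_period or candidate complexity"
            )
        splits.append((train, np.sort(perm[n_train:])))
    return splits


def bootstrap_cv(
    records: pd.DataFrame,
    candidates: list,
    n_replicates: int = 50,
    split: float = 0.75,
    seed: int | None = None,
    min_per_period: int = 2,
) -> list[CVSummary]:
    """Score candidates over shared random 75/25 splits.

    Candidates are duck-typed: ``prepare(records)``, ``fit_score(train,
    val)``, plus ``label``, ``n_thresholds``, ``n_params`` attributes.
    Returns one :class:`CVSummary` per candidate, in input order.  A
    candidate failing in more than 20% of replicates is flagged
    disqualified.  Fully deterministic for a fixed seed.
    """
    if n_replicates < 2:
        raise InvalidConfigError("need at least 2 replicates")
    if not candidates:
        raise InvalidConfigError("no candidates")
    shared_cache: dict = {}
    for c in candidates:
        c.prepare(records)
        if hasattr(c, "cv_shared_cache"):
            c.cv_shared_cache = shared_cache
    n = len(records)
    rng = np.random.default_rng(seed)
    splits = _draw_splits(
        n, n_replicates, split, rng, candidates, min_per_period
    )
    split_hashes = tuple(
        int(hash((tuple(t[:5].tolist()), t.size))) for t, _ in splits
    )
    out = []
    for c in candidates:
        aic = np.full(n_replicates, np.nan)
        d2a = np.full(n_replicates, np.nan)
        d2 = np.full(n_replicates, np.nan)
        ok = np.zeros(n_replicates, bool)
        reasons = []
        for r, (train, val) in enumerate(splits):
            try:
                aic[r], d2[r], d2a[r], _ = c.fit_score(train, val)
                ok[r] = np.isfinite(d2a[r]) and np.isfinite(aic[r])
            except Exception as exc:  # logged, replicate excluded
                reasons.append(f"replicate {r}: {exc}")
        summary = CVSummary(
            label=c.label,
            n_thresholds=c.n_thresholds,
            n_params=c.n_params,
            aic=aic,
            d2_adj=d2a,
            d2=d2,
            ok=ok,
            n_replicates=n_replicates,
            split_fraction=split,
            seed=seed,
            split_hashes=split_hashes,
        )
        fail_frac = 1.0 - ok.mean()
        if fail_frac > DISQUALIFY_FRACTION:
            summary.disqualified = True
            summary.disqualify_reason = (
                f"failed in {fail_frac:.0%} of replicates; first: "
                + (reasons[0] if reasons else "non-finite scores")
            )
        out.append(summary)
    return out


def paired_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided paired t-test p-value; identical samples give p = 1."""
    diff = np.asarray(a, float) - np.asarray(b, float)
    if np.allclose(diff, 0.0, atol=1e-12):
        return 1.0
    res = stats.ttest_rel(a, b)
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def select_model(summaries: list[CVSummary], alpha: float = 0.05):
    """Most parsimonious candidate not significantly worse than the best.

    Candidates are ranked by mean validation D2_adj.  Walking candidates in
    parsimony order (fewest parameters, then fewest thresholds, then label),
    the winner is the first whose paired t-test against the best-scoring
    candidate does not reject at ``alpha`` (or whose mean is at least the
    best).  Returns (winner, trace) where the trace records every pairwise
    test.
    """
    if not summaries:
        raise InvalidConfigError("no CV summaries to select from")
    live = [s for s in summaries if not s.disqualified]
    if not live:
        raise InvalidConfigError("all candidates disqualified")
    common = np.logical_and.reduce([s.ok for s in live])
    if common.sum() < 2:
        raise InvalidConfigError("fewer than 2 jointly valid replicates")
    best = max(live, key=lambda s: float(np.mean(s.d2_adj[common])))
    order = sorted(live, key=lambda s: (s.n_params, s.n_thresholds, s.label))
    trace = {
        "alpha": alpha,
        "best": best.label,
        "n_common_replicates": int(common.sum()),
        "tests": [],
        "disqualified": [
            {"label": s.label, "reason": s.disqualify_reason}
            for s in summaries
            if s.disqualified
        ],
    }
    winner = best
    for s in order:
        mean_s = float(np.mean(s.d2_adj[common]))
        mean_b = float(np.mean(best.d2_adj[common]))
        p = paired_pvalue(s.d2_adj[common], best.d2_adj[common])
        worse = mean_s < mean_b and p < alpha
        trace["tests"].append(
            {
                "label": s.label,
                "mean_d2_adj": mean_s,
                "mean_aic": float(np.mean(s.aic[common])),
                "p_vs_best": p,
                "significantly_worse": bool(worse),
            }
        )
        if not worse:
            winner = s
            break
    trace["winner"] = winner.label
    return winner, trace


def select_threshold_model(
    records: pd.DataFrame,
    start_year: int,
    end_year: int,
    max_thresholds: int = 2,
    degree_k: int = 2,
    engine: str = "polynomial",
    family: str = "gaussian",
    n_replicates: int = 50,
    split: float = 0.75,
    seed: int | None = None,
    alpha: float = 0.05,
):
    """Enumerate threshold sets, cross-validate, and pick the winner.

    Convenience wrapper chaining :func:`enumerate_threshold_specs`,
    :func:`bootstrap_cv` and :func:`select_model` at a fixed degree.
    Returns (winning ThresholdSpec, summaries, trace).
    """
    specs = enumerate_threshold_specs(start_year, end_year, max_thresholds)
    candidates = [
        ThresholdCandidate(s, engine, degree_k, family) for s in specs
    ]
    summaries = bootstrap_cv(
        records, candidates, n_replicates=n_replicates, split=split, seed=seed
    )
    winner, trace = select_model(summaries, alpha=alpha)
    win_spec = next(
        c.spec for c in candidates if c.label == winner.label
    )
    return win_spec, summaries, trace


def select_degree(
    records: pd.DataFrame,
    spec: ThresholdSpec,
    engine: str = "polynomial",
    family: str = "gaussian",
    max_degree: int = 4,
    n_replicates: int = 50,
    split: float = 0.75,
    seed: int | None = None,
    alpha: float = 0.05,
):
    """Smallest degree k whose increment to k+1 yields no significant gain.

    Degrees 0..max_degree are cross-validated on shared splits; k is
    accepted when k+1 does not significantly improve mean D2_adj (paired
    t-test at ``alpha`` with a positive mean gain).  Returns
    (k, gain_table, capped) where ``capped`` flags a still-significant gain
    at the maximum tested degree.
    """
    degrees = list(range(0, max_degree + 1))
    candidates = [
        ThresholdCandidate(spec, engine, k, family) for k in degrees
    ]
    summaries = bootstrap_cv(
        records, candidates, n_replicates=n_replicates, split=split, seed=seed
    )
    common = np.logical_and.reduce([s.ok for s in summaries])
    gains = []
    chosen = degrees[-1]
    capped = True
    for k in degrees[:-1]:
        a = summaries[k].d2_adj[common]
        b = summaries[k + 1].d2_adj[common]
        gain = float(np.mean(b) - np.mean(a))
        p = paired_pvalue(b, a)
        significant = gain > 0 and p < alpha
        gains.append(
            {"from_k": k, "to_k": k + 1, "mean_gain": gain, "p": p,
             "significant": bool(significant)}
        )
        if not significant:
            chosen = k
            capped = False
            break
    return chosen, gains, capped
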