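# Methods

## The model

`spatregime` detects *turnover years* — years at which the spatial
distribution of a surveyed population reorganises — and relates the
resulting period structure to lagged environmental covariates.

The response is a haul-level abundance index, X = log(CPUE + 1), at
position (λ, Φ) in year y. Longitudes are first corrected to
latitude-equivalent degrees, λ* = λ·cos(Φπ/180), so that one degree is the
same ground distance (111 km) in both axes and plain Euclidean geometry
applies throughout. No other projection or geodesic machinery is used.

Given an ordered set of candidate turnover years y*₁ < … < y*ₜ inside a
study window, the window splits into T+1 periods (a turnover year is the
*first* year of the new regime; every period must span at least two
calendar years). The threshold model fits one bivariate surface of
(λ*, Φ) per period:

    X ~ Σ_periods 1{y ∈ period_p} · f_p(λ*, Φ)

Two surface engines share all machinery:

* **polynomial** (reference): f_p is the full bivariate polynomial of
  total degree ≤ k (monomials λ*^a Φ^b, a+b ≤ k), giving (k+1)(k+2)/2
  coefficients per period. This parametric family is the one whose results
  the pipeline reports; it is robust at survey sample sizes.
* **tensor**: the full tensor product a ≤ k and b ≤ k — an unpenalized
  tensor-product smooth with marginal polynomial bases of dimension k+1,
  covering the main effects of latitude and longitude and their
  interaction. It is optional; every selection result is obtainable with
  the polynomial engine alone.

Coordinates are centred and scaled (by the sample mean/SD of λ* and Φ)
inside the basis; degree-4 monomials of raw degrees-north coordinates are
numerically ill-conditioned, and the affine change does not alter the
fitted surface. Gaussian fits use pivoted-QR least squares (LAPACK
`gelsy`); aliased columns are dropped with a warning and zero coefficient
(losing every column is an error). Binomial responses — continuous
proportions such as a *Calanus*-community ratio in [0, 1] — use a
logit-link GLM with unit weights, i.e. a quasi-likelihood fit, because no
trial denominators exist for such ratios.

## Model selection

Candidate threshold sets are enumerated exhaustively (0 up to a maximum of
4 thresholds, subject to the two-year-period rule). Degree and threshold
set are chosen by repeated split cross-validation:

* each of 50 replicates draws a random 75% training subsample *without
  replacement*; the same split is applied to every candidate (paired
  comparison), and splits are re-drawn (bounded retries) if any candidate
  period would lose all its training records;
* the training fit yields an AIC (gaussian: n·ln(2πRSS/n) + n + 2(p+1),
  with the scale counted as a parameter);
* the held-out 25% yields the explained deviance D² = (D₀ − D)/D₀ and its
  adjusted form D²_adj = 1 − [(n−1)/(n−p)](1 − D²), where D₀ is the
  *validation subsample's own* null deviance, n the validation count and p
  the training degrees of freedom.

D²_adj on validation data is the primary criterion; AIC is carried as a
secondary diagnostic because AIC alone tends to overestimate the number of
parameters needed. Score distributions over replicates are compared with a
paired t-test. The winner is the most parsimonious candidate (fewest
parameters, then fewest thresholds) whose mean D²_adj is not significantly
worse than the best candidate's (two-sided paired p ≥ α, default α = 0.05,
or a mean at least as high). At the boundaries this rule degenerates as
expected: α = 0 accepts the most parsimonious candidate outright, α = 1
keeps the highest mean. Degree selection walks k upward from 0 and stops
at the first k whose increment to k+1 brings no significant paired
improvement; if the gain is still significant at the cap (k = 4) the cap
is returned with a flag.

A candidate failing in more than 20% of replicates is disqualified with a
logged reason; replicate failures are otherwise excluded pairwise.

Implementation note: the period factor makes the gaussian design block
diagonal, so each period's surface is fitted independently on that
period's rows; per-(split, period) fits are cached and shared across
candidate threshold sets during cross-validation. This changes no numbers
(a unit test verifies equality with the direct crossed-design fit) but
makes exhaustive enumeration cheap.

## Turnover-year uncertainty

With the degree fixed at the selected k, thresholds are added greedily one
at a time. At each step, every admissible candidate year is fitted on the
full data and its gain in (unadjusted) explained deviance over the current
model is recorded in percentage points; n is fixed across candidates at a
step, so the dof adjustment would shift all gains together without
changing the ranking. The peak gain measures a threshold's *importance*;
the *speed of change* is summarised as the span of candidate years whose
gain reaches 80% of the peak (config-exposed fraction). A sharp step
concentrates the gain near one year; a gradual ramp of the same total size
produces a broad plateau. This plateau-width statistic is this package's
operationalisation of a qualitative idea — profiles that stay high across
a decade indicate gradual change — and is labelled as such in reports.
Ties in the argmax break toward the earliest year.

## Recruitment–environment linkage

Spatial drift during the pelagic stages makes node-by-node regression of
recruitment on local covariates meaningless, so the linkage works at the
level of region polygons (eight subpopulation regions, A–H, each with a
nursery sub-area). For each (region, year):

* the response is the mean recruitment index over the region's *nursery*
  grid nodes in that year;
* each covariate is the mean over *all* the region's nodes of the
  period-averaged field, where the averaging window is the period
  containing the year shifted back by one year (the period 1974–1984 pairs
  with the covariate window 1973–1983). Covariates enter as
  period-averaged values, not annual values.

Candidate covariates are screened with Spearman rank correlation (average
ranks for ties; constant variables are flagged, not fatal). Models take
the form

    response ~ polygon + poly(covariate₁, ≤2) + … [+ interactions]

with the covariate polynomial capped at degree 2 (the best-supported shape
at these sample sizes), an optional additive polygon factor, and optional
polygon×covariate or covariate×covariate interaction terms. Covariates are
standardised before powers are taken; the sign of a covariate's marginal
effect is read off the linear term (the derivative at the covariate mean).

The final recruitment model is built stepwise:

1. the spawning-stock index (SSB) enters first, unconditionally — recruit
   numbers depend on the adult stock;
2. zooplankton descriptors are added one at a time, each step keeping the
   candidate with the largest cross-validated gain in D²_adj, accepted
   only if the paired t-test rejects at α *and* the mean gain is at least
   3 percentage points (gains below 3% are reported as not significant);
3. spring SST enters last iff its residual contribution passes the same
   combined rule.

Whether "significant" should mean the t-test, the 3% floor, or both is
genuinely open; the combined rule is used and logged in the trace. The
SSB-vs-SST model (SSB ~ polygon + poly(SST, 2) [+ poly(exp(−Fbar), 2)])
uses the same machinery; the fishing-mortality index Fbar is accepted as a
single annual series broadcast to all polygons, since it is not spatially
resolved. A constant Fbar produces zero columns that are dropped as
aliased, contributing exactly zero gain.

## Gridding

Point observations are interpolated to regular cell-centre grids (0.5° for
the abundance index, 1° for covariates) by inverse-distance weighting
within a 50 km radius: value = Σ d⁻²vᵢ / Σ d⁻² over points with d ≤ 50 km,
distances Euclidean in corrected degrees × 111 km/degree. The power (2)
is the conventional default and config-exposed; the radius dominates the
result. A node with no point in radius is missing; a node within 10⁻⁹ km
of a point takes that point's value exactly (avoids division by zero with
a stated contract). A node with a single distant in-radius point takes
that point's value (the weighted mean of one point); both this and the
power are config-exposed decisions. Point-in-polygon membership is
boundary-inclusive, and a point claimed by two region polygons is an
error, not a silent first match — region sets are meant to partition.

## Synthetic study systems

The generator emulates the *statistical* structure of real survey inputs,
none of the oceanography. Defaults mirror a North Sea survey box (51–61°N, 5°W–9°E,
0.5° abundance grid, 1° covariate grids) so geometry code paths run at
production shapes.

* **Hauls**: per year, locations uniform (or clustered) over the box;
  response = period surface value + N(0, σ²), σ = 1 by default. Period
  surfaces are degree-2 polynomials in normalised corrected coordinates;
  regime shifts add a fixed spatial pattern rescaled so its RMS amplitude
  over the box is 2σ (a signal-to-noise ratio of 2, large enough that
  detection power is saturated at any realistic survey size). Transitions
  are either steps or linear ramps of configured width.
* **Named scenarios**: `sharp-1998` (single step, 20-year window
  1989–2008), `ramp-1989-2001` (the same total change spread linearly over
  12 years), `two-shift` (a 2σ step in 1998 preceded by a 0.8σ step in
  1988), `no-shift` (negative control).
* **Covariate fields**: an SST-like field with a south–north gradient and
  an optional +1 °C step in 1998; zooplankton log-biomass declining in
  SST; a ratio field passed through a logistic transform (bounded in
  [0, 1] by construction). Fields cover one extra year before the study
  window so lag-1 averaging never runs out of data.
* **Polygon series**: covariates drawn per (region, year) with regional
  baselines and *within-region anomalies*; recruitment = constant +
  β·SSB + quadratic(ratio) + β·SST + noise, with coefficients calibrated
  at generation time so each term's realised variance share matches the
  configured shares (defaults 25% SSB, 8% ratio, 19% SST, remainder
  noise). Effects act on within-region anomalies so the polygon factor in
  downstream models absorbs none of the configured signal. Cross-covariate
  coupling (ratio and SSB respond moderately to the SST anomaly) is kept
  weak enough that each effect's residual contribution stays identifiable.
  The truth ledger records coefficients, variance shares and marginal
  effect signs, sufficient to compute oracle answers for recovery tests.

Everything is reproducible from (config, seed); a single seed drives a
per-replicate seed sequence in cross-validation.

What the generator does *not* emulate: spatial autocorrelation of
residuals beyond the smooth surface, survey gear changes, ship-track
sampling heterogeneity, advection, or plankton phenology. Passing recovery
tests therefore show that the estimator correctly inverts its own model
class at realistic sizes and noise levels — not that real survey data meet
those assumptions.

## Problem sizes and defaults

| quantity | default | why |
|---|---|---|
| hauls per year | 150 | ~3,000 records over a 20-year window; detection power for a 2σ step is saturated far above this, and enumeration over two-threshold sets stays interactive |
| CV replicates | 50 | convergence/compute compromise for the score distributions |
| split fraction | 0.75 | fit on 75%, validate on 25% |
| max thresholds | 4 (2 in the shipped scenarios) | period rule caps useful counts on short windows |
| degree cap k | 4 (surfaces), 2 (covariates) | supported complexity at these ns |
| IDW radius / power | 50 km / 2 | radius from the gridding convention for ship-track data; power conventional |
| α | 0.05 | config-exposed |
| gain floor | 3 pct points | reporting convention for "not significant" gains |
| exact-hit ε | 10⁻⁹ km | coincident-point rule |

Acceptance-style simulation studies in the test suite use 50 seeds for the
detection/control rates and 20 seeds for paired-plateau and covariate
recovery; `scripts/acceptance.py` uses 25 seeds for the detection rates.

## Known limitations

* Threshold search is greedy in the uncertainty profiles (no backtracking)
  and exhaustive only in the selection stage; the two can disagree on
  marginal data.
* No spatial autocorrelation modelling of residuals; standard errors of
  surface coefficients are not reported, and uncertainty about turnover
  years is expressed only through the gain-profile width.
* The binomial path is quasi-likelihood on continuous proportions; its
  AIC is the GLM's working value and only comparable within a family.
* The tensor engine is an unpenalized product basis, not a penalized
  thin-plate/tensor smooth; at equal k it is rougher than a GAM smooth.
* Recruitment–environment results are correlational; the deviance
  partition does not separate direct from indirect temperature effects.
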