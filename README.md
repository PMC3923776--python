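# spatregime

Threshold spatially-explicit models for detecting **turnover years** in
spatio-temporal survey data, and for relating the resulting regime
structure to lagged environmental covariates.

The package is aimed at fisheries and marine-ecology analysts working
with haul-level survey indices (e.g. bottom-trawl CPUE per age class),
gridded environmental fields (SST, plankton biomass) and subpopulation
region polygons — anyone asking "*in which year did this population's
spatial distribution reorganise, how sharp was the change, and which
environmental drivers track it?*"

## The method

The response X = log(CPUE + 1) at corrected longitude λ* = λ·cos(Φπ/180)
and latitude Φ is modelled with one bivariate polynomial surface per
*period*, where periods are delimited by candidate turnover years y*
(every period ≥ 2 years; a turnover year opens the new regime):

    X_{λ*,Φ,y} = f_{period(y)}(λ*, Φ) + ε,   f of total degree ≤ k

* **Selection.** All threshold sets (0–4 years) and degrees k = 0–4 are
  scored by 50-replicate 75/25 split cross-validation: training AIC and
  validation adjusted explained deviance
  D²_adj = 1 − [(n−1)/(n−p)](1 − D²), D² = (D₀ − D)/D₀.
  Paired t-tests on the replicate scores pick the most parsimonious
  candidate not significantly worse than the best.
* **Uncertainty.** Thresholds are then re-added greedily; the gain in
  explained deviance of every candidate year at every step gives each
  threshold an importance (peak gain) and a speed-of-change summary (the
  width of the 80%-of-peak plateau — wide plateau, gradual change).
* **Linkage.** Recruitment averaged over each region's nursery grid nodes
  is regressed on region-mean covariates averaged over the matching
  lagged period (lag 1 year), via a stepwise build: spawning-stock index
  first, then the zooplankton descriptors with the largest significant
  cross-validated gain (paired test at α = 0.05 *and* a 3-percentage-point
  floor), then spring SST if its residual contribution survives the same
  rule.

Gridding utilities (Mercator-corrected coordinates, 50 km-radius
inverse-distance interpolation onto regular grids, boundary-inclusive
point-in-polygon membership) and a fully seeded synthetic-data generator
with known regime shifts and effect sizes round out the pipeline. See
`docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
from spatregime.simulate import scenario_sharp_1998, generate_hauls
from spatregime.selection import select_threshold_model
from spatregime.uncertainty import gain_profiles, rank_thresholds

# a 20-year survey (1989-2008) whose spatial surface steps in 1998,
# step amplitude twice the haul noise
records, truth = generate_hauls(scenario_sharp_1998(), seed=42)

spec, summaries, trace = select_threshold_model(
    records, 1989, 2008, max_thresholds=2, degree_k=2,
    n_replicates=50, seed=42,
)
print("selected turnover years:", list(spec.turnover_years))

profiles = gain_profiles(records, 1989, 2008, n_thresholds=1)
print(rank_thresholds(profiles).to_string(index=False))
```

prints

```
selected turnover years: [1998]
 rank  year  step  importance_gain_pct  plateau_width_years
    1  1998     1            48.212273                    3
```

The cross-validation kept exactly one threshold and placed it at the true
year: splitting the series at 1998 raises the explained deviance of the
spatial model by 48 percentage points, and the near-peak plateau spans
only 3 years — a sharp change (the same analysis on the
`scenario_ramp_1989_2001` fixture, whose change is spread over twelve
years, widens the plateau to ~7 years). The winning candidate's validated
D²_adj was 0.485 ± 0.018 across the 50 replicates.

The same workflow is available from the shell:

```sh
spatregime simulate --scenario sharp-1998 --seed 1 --out sim/
spatregime select  --hauls sim/hauls.csv --start-year 1989 --end-year 2008
spatregime profile --hauls sim/hauls.csv --start-year 1989 --end-year 2008
spatregime link    --series sim/polygon_series.csv \
                   --zooplankton calanus_ratio,c_helgolandicus
```

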