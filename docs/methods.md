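# Methods

This note documents the models, algorithms and numerical choices behind
`borealrings`, and what the synthetic-data tests do and do not
demonstrate about real tree-ring data.

## Ring-width model and RCS detrending

Ring widths are treated as multiplicative:

    w(tree, y) = f_g(a) · C(y) · H(tree) · ε,

where `a` is cambial age (ring number from the pith, including any
estimated missing rings), `f_g` the age-related width decline of the
tree's growth-rate class `g`, `C(y)` the shared year signal, `H` a
tree-level factor (growth rate, habitat level) and `ε` multiplicative
noise. Ratio indices `w / f_g(a)` are therefore estimates of
`C(y) · H · ε`, and the chronology — the Tukey biweight robust mean of
indices per calendar year — estimates `C(y)` up to a constant, which
the final rescale pins to mean 1.0 over the retained span.

**Regional curves.** Widths are aligned by cambial age, reduced by a
per-age biweight mean, and smoothed by a cubic smoothing spline whose
50% frequency cutoff is 10% of the maximum cambial age (weighted by
per-age sample depth; ages with no data are interpolated through the
spline's smoothness penalty). The spline is the penalized
second-difference smoother with transfer function
`H(f) = 1 / (1 + 16 λ sin⁴(πf))`, so `λ = 1 / (16 sin⁴(π/T))` puts the
half-power point at period `T`. A three-parameter negative-exponential
fit (`α·e^(−βa) + κ`) is available as an alternative; it is stiffer and
preferable when the age trend is known to be monotone. Curves are
floored at 0.001 mm so indices stay finite and positive.

**Growth-rate classes.** Multi-curve RCS fits one regional curve per
growth-rate class (default 4 classes; the class count is reduced until
every class exceeds 40 series). Classes are formed by ranking series on
their *age-adjusted* growth rate — the mean ratio to a preliminary
one-curve RCS fit — rather than on raw mean ring width. Raw mean width
confounds growth rate with tree age (a young tree carries only wide
juvenile rings), which couples class membership to calendar time; in
cohorts with correlated age and calendar year that coupling injects
spurious low-frequency trends into the chronology and destabilizes the
signal-free iteration.

**Signal-free iteration.** Fitting curves on raw measurements absorbs
part of `C(y)` into `f_g`, biasing the chronology toward 1 (trend
distortion). The signal-free loop divides each raw width by the current
(untruncated, mean-1) chronology value for its year, refits the curves
from these signal-free measurements, then recomputes indices and the
chronology from the *raw* widths against the refit curves. Iteration
stops when the maximum per-year chronology change falls below 0.002, or
after 9 iterations with a warning (the last iterate is returned). The
iteration is alternating projection onto the age and year axes: with
strongly overlapping age structure it converges in 3–6 iterations; when
age and calendar year are nearly collinear the joint decomposition is
weakly identified and the 9-iteration cap acts as early-stopping
regularization.

**Chronology.** Per-year biweight mean (tuning constant c = 9, MAD
scale, iterated to 1e-9, median fallback for n ≤ 3 or zero MAD); years
with fewer than 50 trees (25 for subgroup chronologies, matching the
smaller strata) are trimmed from the ends only — interior dips are kept
and flagged; the 95% band is a percentile bootstrap over trees within
each year (1000 replicates, seeded); a final multiplicative rescale
makes the retained-span mean exactly 1.0. No variance stabilization is
applied.

## Pith correction and quality control

Cores that miss the pith but show a complete innermost arc yield the
missing radius by circle geometry, `r = c²/(8h) + h/2` (chord `c`, arc
height `h`), exact for true circular arcs. The missing ring count is
`round(r / mean width of the innermost ten rings)`, rounded half to
even; it is approximate to a few rings because juvenile widths differ
from the unmeasured rings. Series without pith and without a usable arc
are excluded. Post-fire rings (the fire year onward) are removed on
plots with a known fire history. The crossdating QC statistic high-pass
filters each series (ratio to a 32-year spline) and correlates it with
the biweight mean of all other filtered series over at least 20 years
of overlap.

## Climate–growth analysis

The variable set is monthly mean temperature and monthly precipitation
for May–August of the growth year and the previous year, plus seasonal
precipitation totals (May–August; October–April assigned to the later
year). Precipitation is transformed `log(x + 0.1 mm)` before any
correlation (monthly totals are positively skewed; the offset keeps
zero-precipitation months representable).

**Significance.** A correlation is significant when the observed r
falls outside the central 95% band of a null distribution built by
resampling the growth series in stationary blocks (mean length 5 years,
reflecting the modest autocorrelation of ring-width indices) against
the fixed climate series. Resampling under the independence null keeps
the test at its nominal size (measured 4.6% on white-noise pairs at
n = 98, 4.7% under AR(1) φ = 0.4); percentile-interval constructions
from pair resampling measured 7.5% at this sample size and were
rejected for that reason.

**Moving windows.** 25-year windows advancing by 1 year, each window's
r computed exactly as in the static analysis. The low-frequency test
takes the variance of the moving-r series as its statistic and builds
the null by recomputing moving correlations for surrogate growth series
resampled in circular 5-year blocks; p is the fraction of null
variances at least as large as the observed one. The test is
conservative under a strong stationary relation (the null, built under
independence, has larger moving-r variance than a stable strong
correlation) — measured rejection 0% at true r = 0.5 stationary, 98%
power for a mid-record sign flip of r = ±0.5 at n = 98.

**Boosted regression trees.** scikit-learn gradient boosting with tree
depth 2, learning rate 0.001, bag fraction 0.5; the tree count is the
10-fold cross-validation minimum up to a 30 000 cap, with a floor of
1000 trees (the standard BRT reliability convention; with very few
trees relative influence on noise targets concentrates spuriously).
Relative influence is normalized to sum to 100 and aggregated over the
one-hot columns of categorical predictors. Partial dependence averages
predictions over the data with one variable fixed; pairwise interaction
strength is Friedman's H² on a subsample.

## Isotope physiology

Discrimination: `Δ¹³C = (δₐ − δ_tree)/(1 + δ_tree/1000)`. Ci/Ca:
`(Δ − 4.4)/(27 − 4.4)`, after shifting cellulose δ¹³C by −1.33‰ to the
leaf-tissue scale on which the relation was developed (the shift is
applied on the δ scale to the *age-adjusted* value; raw Δ¹³C is
reported without it). iWUE: `(Ca − Ci)/1.6`. Period-level atmospheric
δ¹³Cₐ and Ca are arithmetic means of annual values within each period;
2003–2012 values are linear extrapolations of the 1993–2002 trend
(ordinary least squares per series), flagged as extrapolated.

**Ring-age adjustment.** Young rings show elevated Δ¹³C (soil-respired
CO₂, shading, low hydraulic resistance). A random forest (500 trees,
`min_samples_leaf = 5` — the regression default of the reference R
implementation; a leaf size of 1 overfits measurement noise and
inflates the period estimates' variance) regresses Δ¹³C on ring age and
period midpoint year; the adjusted period value is the model's
prediction at a ring age of 100 years, and predictor importance is
20-repeat permutation importance. Estimates are reliable only when
every period contains trees spanning ring ages around the held age;
the isotope study conditions therefore use a cohort with a 1750–2013
recruitment history.

**Atmospheric reference.** The package ships a parametric synthetic
stand-in for the published atmospheric record (δ¹³Cₐ from −6.3‰ with an
accelerating decline, Ca from 284 µmol/mol rising to ~372 by 2002, flat
before 1850), labelled `synthetic` in name and provenance column. Its
magnitudes and curvature match the ice-core/flask era at the precision
the period-mean workflow needs; analyses of real data should substitute
the published annual series.

## Habitat analysis

Per-tree mean ring-width index over 2003–2012 (trees with no rings in
the span are excluded) joined to plot covariates; the BRT engine above
relates growth to them. Habitat classes use fixed thresholds with
strict inequalities — white spruce good: moss cover < 50% *and* duff
depth < 10 cm, poor: moss > 50% *and* duff > 10 cm; black spruce good:
slope > 15% *and* moss > 60%, poor: slope < 15% *and* moss < 60% —
with boundary equality, mixed combinations and missing fields all
`unclassified`. Stratified chronologies run the full signal-free RCS
pipeline per stratum (≥ 25 trees, truncation 25) and are correlated
with the 16 monthly climate variables.

## Synthetic data: what it emulates and what it does not

The generator produces monthly climate (Fairbanks-like climatology,
AR(1) year anomalies with φ = 0.3 and σ = 0.9 °C, independent 1.2 °C
month noise, a 0.04 °C/yr warming trend from 1965, lognormal monthly
precipitation with σ = 0.55), and cohorts whose year signal is a
decreasing sigmoid of May–August mean temperature (midpoint 0.5 °C
above climatology, steepness 1.5/°C — the decline plays out over
~2–3 °C — floor 0.5) times a saturating ramp of August precipitation
(limited below 40 mm, saturated above 80 mm, floor 0.65), with
previous-year carry-over exponents of 0.4 (temperature) and 0.3
(precipitation). Habitat classes modulate the level (±10%) and the
temperature-sensitivity exponent (0.8 / 1.0 / 1.3 by default). Age
trends are `α e^(−0.03a) + 0.25` mm with per-tree lognormal α
(σ = 0.12); index noise is lognormal with σ = 0.2; 30% of trees lose
3–11 innermost rings with arc geometry generated from the true missing
radius. The default cohort is 150 trees over 1864–2013 with
germination uniform over the first 90 years — deliberately retaining
enough age–calendar collinearity that single-pass RCS measurably
shrinks low-frequency signal, which is the regime the signal-free
method exists for. Isotope records add a juvenile Δ¹³C decline
(`depth · e^(−(a−1)/25)`, depth 1.5‰ white / 0.5‰ black spruce), a slow
rise of 0.25‰ per century of ring age, configurable period effects and
0.15‰ measurement noise.

Ground truth shipped with every dataset includes the realized expected
chronology (the mean class signal over trees alive each year — exactly
what an unbiased chronology estimates), per-class signals, per-tree
curve parameters, habitat labels and arc geometry. All randomness
derives from a single seed through per-stage PCG64 seed sequences;
datasets are bit-identical under a fixed seed.

What passing tests do *not* show about real data: the generator has no
dating errors (so the QC statistic is only sanity-checked), no locally
absent or partially missing rings, no disturbance except the optional
fire truncation, no spatial autocorrelation between plots, habitat
acts through two clean covariates rather than a correlated field
complex, and the climate record has no inhomogeneities. Inter-series
correlations of synthetic cohorts (~0.7–0.8) are higher than typical
field values because the common signal is strong and undisturbed.

## Problem sizes

Default test and acceptance runs use the 150-tree/150-year cohort (ten
seeds for the detrending comparison), a 240-tree cohort for the habitat
contrast, the 1750–2013 isotope cohort (150 trees sampled), 1000 trials
for significance-test calibration and 100/50 replicates for the
low-frequency size/power checks; these sizes give Monte-Carlo standard
errors comfortably inside the asserted tolerances. The `analysis/`
drivers run the full 339 + 213 tree study.

## Known limitations

- The signal-free fixed point is weakly identified when germination is
  tightly clustered; the 9-iteration cap then matters, and results
  should be read as regularized estimates.
- The low-frequency test is conservative under strong stationary
  relations; its p-values are not uniform in that regime.
- The random-forest age adjustment extrapolates poorly outside the
  observed ring-age range of a period; designs lacking old trees in
  early periods bias the adjusted series.
- Missing-ring counts from the first-ten-ring rule are accurate to a
  few rings, not exact; cambial ages inherit that error.
- The BRT "tree complexity 2" is mapped to scikit-learn `max_depth=2`,
  which is close to, but not identical with, gbm's interaction-depth
  semantics.
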