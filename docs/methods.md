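# Methods

## Scope and data model

The unit of observation is one ovitrap-censused egg with a collection
date, an assay outcome and optional triplicate length/width measurements.
Hatched (H) and embryonated-unhatched (E) eggs are *viable*; partially
embryonated (P) and unfertilised (U) eggs are dead; eggs already hatched,
dried or damaged at collection are `EXCLUDED` and kept visible in files
but never enter a denominator.  All time indexing uses ISO 8601 week
dates (weeks start Monday; week 1 holds the year's first Thursday), and
the stored week-year may differ from the calendar year around 1 January.

## Rates and their identities

Per cohort, hatching success and diapause incidence are complementary
percentages over viable eggs, viability and mortality over all tested
eggs.  Both identities hold exactly by construction and are enforced by
property tests.  A cohort with no viable egg has *undefined* incidence
and raises an explicit error — reporting 0% would fabricate a
measurement.  Weekly series pool all traps in a week; cohorts below
`min_n = 6` tested eggs are omitted (a five-egg week cannot carry an
incidence estimate; the value is configurable).

## Cutoff detection

`detect_cutoff` returns the earliest week at or above the threshold
(default 50%, equality counts) whose next `sustain = 2` observed weeks —
or all remaining weeks, if fewer — also stay at or above it.  Field
incidence series are binomially noisy, so a bare first crossing would
often fire one or two weeks early on a single aberrant cohort; requiring
a sustained rise makes the detected week stable without smoothing the
series.  "No sustained crossing" is a result, not an error.

## Photoperiod and the CPP

Day length is the classical sunrise-equation duration with solar
declination from the Meeus low-accuracy solar-position series (error
well below 0.01°, i.e. sub-minute in day length at temperate latitudes);
declination is evaluated once per day, since intra-day drift changes the
duration by far less than the minute-level rounding of published tables.
Weekly photoperiod is the mean of the seven Monday–Sunday durations.

The horizon convention is a zenith-angle parameter: 90° (geometric),
90.833° (apparent upper limb, the civil-table convention) and the
default **90.567°** — 34′ of atmospheric refraction applied to the solar
disc centre.  The default was chosen because it reproduces the published
weekly day lengths used in the CPP computation for Strasbourg (six
values spanning weeks 34–37 of 2019–2020) within about 2 minutes,
whereas the upper-limb convention runs ~3–6 min long and the geometric
one ~5–8 min short; all three remain available.  An independent check
against the Forsythe day-length model (R `geosphere`) at the upper-limb
convention agrees within ±3 min across the seasons of interest.

The CPP at maternal delay *d* is the weekly photoperiod at
`cutoff_week − d`.  The default delay is 1 week: egg cohorts are
labelled by collection week, while the photoperiod that set their
diapause fate acted on their mothers roughly one oviposition cycle
earlier; the delay is exposed as an argument (0–2 are all reported by
the season report) because its physiological value is uncertain.

## Morphometry

Triplicate measurements are averaged per axis before any analysis; the
egg is treated as a prolate spheroid, `V = (π/6)·L·W²`, reported in
10⁻³ mm³.  Seasonal trends are fitted by OLS **on weekly median values**
(per-egg fits are available): medians match the boxplot-per-week way
such data are summarised and damp the heavy subsampling imbalance across
weeks.  The season is split into an early regime (weeks 20–24, eggs from
overwintered mothers) and a late regime (weeks 26–43) and fitted per
regime, because a single line across both is badly specified.

Group contrasts use the cutoff week *n*: ND (< n−1), M (n−1…n+1, the
mixed window), D (> n+1).  The one-tailed Wilcoxon rank-sum test is
computed with average ranks for ties; for pooled samples of ≤ 12 the
p-value is exact by enumerating all group labelings, otherwise the
tie-corrected normal approximation (with continuity correction) is used.
The reported statistic is the Mann–Whitney U of the first sample, the
same quantity R's `wilcox.test` prints as W.  The direction is fixed as
D > ND (late-season eggs are expected wider/larger).  Percent effects
are computed on group means.  Kruskal–Wallis (tie-corrected, χ² on k−1
df) checks within-group homogeneity; an all-tied input returns H = 0
with a degenerate flag rather than an error.

## Logistic diapause model

Per viable measured egg, `y = 1` iff embryonated unhatched.  The linear
predictor contains week (x1), width in µm (x2), optionally their product
and an additive categorical year effect; predictors are deliberately
unstandardised so coefficients read in natural units.  Fitting is
Newton/IRLS from β = 0; convergence requires both a stationary
log-likelihood (relative change < 10⁻⁸, ≤ 100 iterations) and vanishing
score `‖Xᵀ(y − p̂)‖∞ < 10⁻⁸·n`, so the estimating equations hold to
numerical precision.  Quasi-complete separation (|η| > 25) is detected
and flagged, never silently absorbed.  Frequency weights make the
grouped-binomial formulation exactly equivalent to the expanded
Bernoulli one (asserted by test).  Model selection fits every subset of
the candidate terms that respects marginality (the product only with
both main effects), drops non-converged candidates with a warning, and
ranks by `AIC = 2k − 2·logLik`.

## Seasonality utilities

Weekly weather aggregation produces the eight temperature summaries
(mean/min/max of daily minima and maxima) plus average and cumulative
sunshine and rainfall; partial weeks are aggregated over available days
and flagged, not dropped.  The activity threshold is the mean of the two
seasonal minima (of avTmin and of avTmax) over egg-positive weeks.
Spearman's ρ is the Pearson correlation of average ranks; its p-value
uses the t approximation on n−2 df for n ≥ 10 and the exact permutation
distribution below that, where the approximation is poorest.  Abundance
series bin counts per 1 or 2 weeks from the first observed week of each
season; binning conserves totals by construction.

## Synthetic season generator

The generator is first-class, tested code.  Per week *w*:

* intensity λ(w) = base + two Gaussian bumps (defaults: peaks near weeks
  28 and 40, heights 1500 and 600 eggs across 12 traps) — the bimodal
  seasonal pattern; trap-week counts are Poisson(λ/n_traps);
* each egg dies with probability m = 0.17 (split evenly between P and
  U), otherwise it is in diapause with probability

      p(w) = p0 + (1 − p0)·expit(k·(w − w* + ½) + c),
      c = logit((½ − p0)/(1 − p0)),

  a constitutive floor p0 = 0.10 plus a logistic rise (k = 0.9/week,
  w* = 36).  The offset places the 50% point of the continuous curve at
  the boundary w* − ½, so **w\* is the first integer week at or above
  50%** (p(35) ≈ 0.40, p(36) ≈ 0.60 at the defaults) and, in the
  infinitely steep limit, every egg before w* hatches and every egg from
  w* on is dormant.  Anchoring p(w*) = 0.5 instead would make the
  crossing week undetectable in principle: with exactly 50% probability
  at w*, any finite cohort crosses the threshold there only on a coin
  flip;
* a 10% subsample carries triplicate morphometry: true width
  `151.24 + 0.7474·w` (+ 8 µm for weeks ≤ 24, the early regime) with
  6 µm egg-level and 2 µm replicate-level Gaussian noise; length is
  N(616, 30²) µm, uncorrelated with week;
* weather is a seasonal sinusoid plus noise, promising only the ordering
  invariants (tmin ≤ tmax, non-negative sunshine/rain), not
  climatological realism.

Week number, not photoperiod, is the logistic axis: within one season
the two are monotonically linked, and week keeps the truth ledger
independent of the astronomy module.  Identical seeds give byte-identical
CSV output.  What passing recovery tests show is that the *pipeline* is
correct and calibrated under the assumed structure — they cannot show
that real seasons follow that structure (no trap heterogeneity, no
weather-driven abundance coupling, no measurement drift).

## Problem sizes and numerical choices

The default synthetic season (~36 000 eggs over two years) runs the full
pipeline in a few seconds; recovery suites use 200 replicate seasons of
200 viable eggs per week for cutoff detection, 200 replicate
weekly-median series for the regression recoveries, and n = 5000 for GLM
parameter recovery — sizes at which Monte-Carlo error is far below every
tolerance asserted.  Ties get average ranks everywhere.  Degenerate
inputs (all-tied rank tests, zero-variance correlations, single-week
SDs) return flagged results where a value is still meaningful and raise
errors where it is not.  Slope-recovery tests assert the estimator's
calibration over replicates (centred on truth, nominal 2-SE coverage)
rather than one draw, since any single seeded series misses its own 2-SE
band ~5% of the time by construction.

## Known limitations

* The CPP depends on the maternal-delay assumption; the package reports
  delays 0–2 side by side rather than committing to one.
* The published day-length convention behind the reproduced values is
  not documented at the source; the 90.567° default is an inference from
  agreement, and minute-level differences between conventions translate
  to ~0.2 weeks of maternal timing.
* Incidence pools traps within weeks; trap-level heterogeneity and
  overdispersion are not modelled (no mixed-effects variant).
* The logistic model is per-egg Bernoulli; batch-level correlation
  within traps would shrink its standard errors artificially on real
  data.
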