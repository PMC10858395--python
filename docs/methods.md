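# Methods

This note documents the models, numerical conventions and design choices
behind `exposure-weave`, and what the synthetic-data tests do and do not
demonstrate about real study data.

## The analysis unit

Everything is keyed by the **wristband sampling period**: one ~24-hour wear
interval for one participant, joining the wristband's chemical panel with
the GPS fixes, monitor AQI values, smoke polygons and the evening
questionnaire of that day.  A three-season study with ~35 participants and
7 daily wristbands per season yields a few hundred analysable periods after
quality control, which is the scale all defaults target.

## Inclusion rules and their conventions

A wristband period is kept when (a) wear duration is within ±8 h of 24 h,
i.e. in [16 h, 32 h]; (b) on/off times were recorded; (c) the band arrived
in its airtight bag; (d) it was put on between 00:01 and 11:59 local; and
(e) it lies in the participant-season's 7-day study window, anchored at that
participant-season's first recorded on-date.  All interval boundaries are
treated as closed — the permissive reading where the rule itself does not
say otherwise.  Exclusion reasons are assigned by the first failing rule in
the order above, so tallies are reproducible; a period without recorded
times cannot be assessed for duration and is logged as `times-not-recorded`.
Questionnaires count when answered between 16:00 and 04:00 local (closed at
both ends, spanning midnight).  GPS pairing drops periods where the phone
was neither carried nor left in the participant's general location, and
periods with no fix inside the wear interval.

Fix-level GPS quality control is a pluggable hook; the default drops fixes
whose implied speed from the last kept fix exceeds 120 mph.  This is a
stand-in for device-level QC, not a reconstruction of any particular
device's filter.

## Time-weighted AQI and smoke exposure

Wear time is partitioned at the fix timestamps.  Each inter-fix interval is
attributed to its **starting** fix (a left-constant rule; leading and
trailing slack go to the first and last fix).  Intervals crossing local
midnight are split so every piece uses the monitor values and smoke
polygons of its own calendar day; timestamps are timezone-aware in a single
configured zone (default US/Pacific).  The period's weighted AQI is then
the time-weighted average of the nearest monitor's daily mean AQI, where
"nearest" is the great-circle (haversine) distance on a sphere of radius
3958.8 mi, restricted to monitors with data that day (missing monitor-days
are excluded from the search, never imputed) and with ties broken by
monitor id.  The same interval machinery classifies smoke exposure by
point-in-polygon tests of the starting fix, resolving overlapping polygons
to the highest density.  Tests verify the interval computation against an
independent per-second integration oracle to 1e-6.

The HMS Index compresses the four wear-time proportions to
`(0·None + 1·Light + 2·Medium + 3·Heavy)/3`; it is 0 with no smoke, 1 for
a period entirely in heavy smoke, and monotone under moving time from a
lower to a higher density.

Distance traveled sums consecutive-fix haversine distances.  Quartile
categories use right-closed intervals — a value exactly at a cutpoint goes
to the lower category — with cutpoints either estimated from the data
(type-7 quantiles) or pinned at 4/15/35 mi.

## Concentration scale and tertiles

Concentrations convert from ng/g wristband to log2 pmol/g as
`log2(raw/MW × 1000)`.  Matrix-interference values are missing throughout
and never enter any denominator.  For the tertile outcome with X% of
observations below the LOD:

* X ≤ 33.33 (inclusive): thresholds at the 33.33rd and 66.67th empirical
  percentiles of all observations, with nondetects ranked below every
  detect.  Percentiles are type-7 (linear interpolation); ties at a
  threshold go to the lower category.
* X > 33.33: all nondetects are Low; detects split Medium/High at the
  [X + (100 − X)/2]th percentile of all observations.

For threshold *reporting* nondetects are placed at a sentinel one log2 unit
below the smallest detect; category assignments are invariant to the
sentinel.  Because the percentile rule is rank-based, computing it on the
raw or log2 scale yields identical categories; thresholds are reported on
the log2 scale.  Restricting models to chemicals with ≤ 50% nondetect
bounds the largest:smallest class ratio at 2:1 (plus one observation of
rounding slack).

## Mixed models and seasonal contrasts

Detection (above-LOD indicator) is modelled as logistic with a participant
random intercept.  No frequentist logistic mixed model exists in the Python
scientific stack, so the marginal likelihood is maximised directly using
25-node Gauss–Hermite quadrature over the random effect, BFGS on
(β, log σ), and standard errors from the numerical observed information;
the fit matches lme4's `glmer` to three decimals on test data, and a test
cross-checks the quadrature likelihood against dense numerical integration.
Convergence requires a small gradient and positive-definite information;
non-convergent chemicals are flagged and excluded.  Concentration contrasts
(detects only) use a Gaussian mixed model (statsmodels `MixedLM`, REML).

Pairwise season contrasts use the single-step Tukey (studentized-range)
adjustment with the normal-approximation (large-df) reference — adequate at
a few hundred observations and verified by a null simulation holding the
familywise error at the nominal 0.05 within Monte-Carlo error.  Seasonal
behaviour/environment comparisons follow each variable's scale: one-way
ANOVA with Tukey HSD on log(distance + 0.1 mi) (the offset admits
zero-travel days), pairwise Welch t-tests with Holm adjustment for weighted
AQI, and pairwise Wilcoxon rank-sum with Holm for the bounded HMS Index.
Spearman correlations exclude nondetects; constant vectors yield a flagged
undefined correlation rather than a silent zero.

## Predictive model comparison

Per chemical (restricted to ≤ 50% nondetect), four models predict the
Low/Medium/High outcome:

* **AQI-only**, **HMS-only** — quadratic discriminant analysis on the
  single feature.  A class with singular within-class variance (e.g. an
  all-zero HMS class) falls back to majority-class prediction with a
  logged warning.
* **Standard** — a classification tree on weighted AQI, HMS Index, the
  three smoke proportions, season, distance category and time indoors.
* **Interaction** — the Standard features plus explicit per-season copies
  of AQI and HMS (zero off-season).

Trees use minimum leaf size 7 and cost-complexity pruning; the pruning
alpha is chosen once per bootstrap repetition by internal 10-fold CV on the
resample, from a grid of at most 8 alphas along the pruning path, taking
the minimum-CV-error alpha (1-SE rule off; ties prefer the simpler tree).
Each repetition draws a bootstrap resample of records (participant-level
resampling is available as an option), then scores pooled held-out accuracy
over stratified 10-fold CV **assigned by original record**: all copies of a
duplicated record stay on one side of every train/test split.  Without this
grouping, duplicates leak across folds and a null model scores ~0.53
instead of ~1/3, which would invalidate every baseline comparison.  Master
seed → per-repetition child seeds, so results are bit-reproducible.

Mean accuracies are compared with a pooled two-proportion z-test using an
effective n equal to the number of analysis records (configurable); the
Interaction tree replaces the Standard tree as the final "multivariate
model" only when its one-sided advantage is significant at α = 0.05.
Confidence intervals are normal-approximation proportion intervals clipped
to [0, 1].  Variable importance is mean Gini impurity decrease across
repetitions, folded back from encoded columns to source features (season
is one-hot encoded; ordered categories are integer codes; features are
encoded in sorted-name order so results do not depend on how the feature
list was written) and rescaled so the top feature per chemical equals 1.
Correlated features can mask one another's importance, as in any
CART-based importance.

Because the two tree models are evaluated on the same data, their accuracy
estimates are strongly positively correlated and the two-sample z-test
(which assumes independent arms) is conservative for the selection rule:
under a null generator the Interaction model is selected in at most ~5% of
runs, typically fewer.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the analysis relies on:
seasonal AQI regimes with AR(1) day-to-day noise (ρ = 0.6) and additive
spikes at monitors covered by smoke polygons (scaled by density/3); smoke
events shared between the polygon and monitor generators so the two proxies
correlate through a common driver (the winter season has none); movement as
piecewise dwell-and-transit with 5-minute fixes, log-normal daily
round-trip distance with median 15.4 mi and a stay-home probability, which
spans the distance quartiles; questionnaires with configurable missingness,
window violations and phone-carry failures; and chemical concentrations
from an explicit linear model on the log2 pmol/g scale with participant
random effects, left-censoring spanning roughly 0–80% across a 25-chemical
panel, and 1.3% matrix interference.  LODs are placed by a normal
approximation to each chemical's marginal, so realised censoring fractions
are approximate.  Nondetects are stored as flags plus the LOD — never as a
substituted value; substitution policy is a downstream choice.

It does **not** emulate real geography, satellite artifacts (cloud cover,
night gaps), GPS measurement noise by default (enabling it inflates summed
path length at a 5-minute cadence), or mechanistically realistic chemical
mixtures.  Passing tests therefore demonstrate that the *procedures* are
correct and calibrated under the assumed structure, not that any particular
real-world effect size is recovered.

Two purpose-built scenario generators serve the model-framework studies:
`simulate_modeling_table` draws features with the study's marginal
structure and an outcome from a configurable latent linear model (its
interaction term is season-centred so a pure sign flip carries no marginal
AQI effect), and `simulate_crossing_interaction_table` rotates the
within-season AQI tertile by season (a Latin square).  The rotation is the
three-class analogue of a crossing interaction with *zero* marginal signal
in either season or AQI: a plain slope sign flip still lets a greedy tree
exploit "extreme AQI ⇒ not Medium", whereas under the rotation only
season-specific AQI splits — the explicit interaction columns — expose the
structure.  This is the regime in which explicitly coded interaction
features are known to matter for CART-type learners.

## Problem sizes used in the checks

The acceptance-style checks run at the study's modeling scale, n = 364
records: 20 seeded replicates × 20 bootstrap repetitions for the
multivariate-vs-baseline ordering; 100 null runs × 10 repetitions for
selection-rule calibration plus 10 planted-interaction runs; 200 simulated
panels for the familywise-error check of the seasonal contrasts; 50
randomized trajectories for the integration-oracle comparison; and 100,000
draws for the random-prediction baseline.  Unit tests use smaller seeded
configurations (e.g. 6 participants × 3 days).

## Known limitations

* The logistic GLMM uses non-adaptive quadrature; very large random-effect
  variances (σ ≳ 4 on the logit scale) would need more nodes.
* QDA on a single feature assumes class-conditional normality; for
  zero-inflated HMS it often degrades to the majority-class fallback,
  which is itself informative about how little the proxy explains.
* Tree importances inherit CART's masking of correlated features.
* The per-second oracle equivalence holds exactly only for fix times on
  whole seconds; sub-second fix timestamps are handled by the interval
  implementation but tested only through the convergence property.
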