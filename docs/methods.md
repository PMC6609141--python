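# Methods

This note documents the models, numerical choices and known limitations of
the `trialcea` pipeline. Defaults describe the study conditions the
package emulates: a two-arm cluster-randomised trial of a school-based
alcohol-prevention programme in ~105 schools, a binary heavy-episodic-
drinking (HED) outcome at 33 months, and public-sector costs built from
pupil-reported service use.

## Costing

**Windows and anchors.** Service use is recalled over four 6-month
windows: 6 months pre-baseline and months 7–12, 19–24 and 28–33. Each
observed window total (counts × unit costs) is converted to a monthly rate
(÷6) anchored at the window midpoint: months −3, 9.5, 21.5 and 30.5.
The monthly rate at each month centre m − 0.5 (m = 1…33) is the linear
interpolation between the bracketing anchors, held constant beyond the
last anchor. Interpolating *rates at midpoints* (rather than raw window
totals) handles the unequal gaps — two 6-month gaps and one 3-month gap —
with a single rule. The pre-baseline window never contributes its own six
months to totals, but it anchors the interpolated rates for months 1–6, so
it carries a small positive weight (≈0.60 per £1 of window cost at 3.5 %
discounting) in the 33-month total; pupils missing it are incomplete.

**Blank items vs missing waves.** A blank field inside an otherwise
completed questionnaire means the service was not used (count 0). A wave
is missing only when the entire instrument is absent; any missing wave
makes the pupil's total incomputable (complete-case flag false), because
all four anchors are needed for the interpolation.

**Discounting.** Study-year boundaries, indexed from baseline: months
1–12 undiscounted, 13–24 divided by (1 + r), 25–33 by (1 + r)²; r = 0.035
in the primary analysis, 0.015 in a sensitivity variant. Monetary values
are carried at full floating precision; rounding to whole pounds happens
only in report rendering.

**Linearity.** Interpolation and discounting are both linear in the
window totals, so the discounted total is an exact weighted sum of the
four window costs (`costing.window_weights`). The vectorised cohort path
uses this identity; sector decompositions use the same weights and
therefore sum exactly to the pupil total.

## Programme costing

The intervention ledger has stage 1 (planning/preparation: materials,
training) and stage 2 (delivery: classroom teaching, the parental-
component facilitator), valued at opportunity cost; development costs that
would not recur are excluded by construction. Scenarios: `full`,
`no_parental` (minus the facilitator), `classroom_only` (stage 1 only,
the case where classroom delivery displaces existing curriculum time).
Per-school and per-pupil denominators are the intervention-arm schools
(105) and pupils present at baseline in them (5 749). The per-pupil cost
added to intervention pupils in the CEA is the whole-pound report value
(£15), matching how such figures are carried into analyses in practice.

## Incremental cost and effect models

Both estimands come from linear models with a school random intercept,
fitted on complete cases:

* cost: `total_cost ~ arm + location + fsm_band + school_type +
  baseline_cost`;
* effect: `hed33 ~ arm + location + fsm_band + school_type +
  baseline_hed`, a linear probability model, so the arm coefficient is the
  adjusted risk difference; it is negated so that Δe counts *cases
  avoided* (positive favours the intervention).

**Estimator.** Variance components are estimated by a Swamy–Arora-type
moment decomposition (within-school residual variance from the demeaned
regression; between-school variance from the school-means regression),
followed by the random-effects partial-demeaning transform and OLS — a
feasible-GLS random-intercept fit. It is equivalent to a REML mixed model
up to variance-component estimation error and roughly an order of
magnitude faster, which matters inside the bootstrap; the test suite
cross-checks the arm contrast against `statsmodels` MixedLM (REML) and
requires agreement to a small fraction of the standard error. When the
between-variance estimate is non-positive the fit reduces to OLS. The
model-based covariance returned for pooling is a cluster-robust (CR1)
sandwich over schools.

**Degenerate designs.** The arm effect must not lie in the span of the
covariates (e.g. a stratum present in one arm only): that raises an
explicit error. Covariates that are aliased among themselves — which
routinely happens when a bootstrap resample loses a stratum — are dropped,
as standard regression software does with aliased terms.

**Bootstrap.** Uncertainty comes from resampling schools (the
randomisation and clustering unit) with replacement, stratified by arm,
refitting both models per resample so each replicate is a correlated
(Δc_b, Δe_b) pair; 95 % intervals are the 2.5th/97.5th percentiles of
B = 1000 replicates. Each resample draws G_a − 1 of the G_a observed
schools in arm a: the with-replacement bootstrap of all G_a clusters
understates sampling variance by the factor (G_a − 1)/G_a, and drawing
one fewer cluster is the standard small-sample correction. Simulation at
20 schools × 30 pupils (600 replicate trials) puts the empirical coverage
of these intervals at ≈0.95 for both Δc and Δe, versus ≈0.92–0.93 without
the correction. Replicates with a degenerate resampled design are redrawn
(capped, with a logged warning). Percentile rather than BCa intervals: a
deliberate, simple choice consistent with how such trials are analysed.

## Decision outputs

Conventions are fixed and documented: effect on the x axis, cost on the y
axis; tie rules Δc = 0 → southern side, Δe = 0 → western side; strict
net-monetary-benefit rule λ·Δe − Δc > 0 (a replicate exactly on the
boundary counts as not cost-effective). An ICER is reported only for
genuine trade-offs (NE/SW quadrants); when Δc and Δe have opposite signs
the ICER's magnitude is meaningless and is suppressed. Dominance
downgrades to *weak* dominance when either CI spans zero. The default
willingness-to-pay grid is £0–£2 000 in £5 steps per HED case avoided.

## Sensitivity analyses

* **Multiple imputation** (all randomised pupils): chained equations over
  the analysis and auxiliary variables (baseline cost, months-7–12 cost,
  total cost; baseline, 12-month and 33-month drinking). Costs use
  predictive mean matching — type-1 matching, k = 5 donors, posterior
  coefficient draws with a non-informative prior — so imputed costs are
  always observed values; binary variables use a posterior-draw logistic
  model. 10 cycles, m = 5 datasets, combined by Rubin's rules with
  Rubin–Satterthwaite degrees of freedom. Cluster membership enters the
  imputation models through the school-level strata (location, FSM band,
  school type) rather than per-school dummies. PMM donor count and cycle
  count are package choices.
* **1.5 % discounting**: costs re-priced end to end at 1.5 %; the
  33-month outcome (realised in study year 3) is additionally discounted
  by (1.015)⁻². The primary analysis discounts costs only.
* **Cluster-only adjustment**: both models drop baseline covariates but
  keep the school random intercept and the school bootstrap.
* **±5 % costs**: every pupil's total cost (programme cost included) is
  scaled; by linearity Δc and its CI scale exactly while Δe is untouched —
  asserted bit-exactly in the tests.

## Synthetic-data generator

The generator emulates the trial's statistical structure with known ground
truth; it does not reproduce the real trial's school-size distribution,
country imbalance, or exact cost magnitudes beyond order of magnitude.

* **Schools**: 105 by default, allocated ~1:1; location NI with
  probability 0.67; FSM band uniform over {low, moderate, high}; school
  type (boys/girls/coed) = (0.15, 0.15, 0.70). Pupils per school:
  negative binomial, mean 108 (pupils present at baseline).
* **Costs via counts**: per-service, per-wave zero-inflated negative
  binomial counts (defaults chosen for plausible early-adolescent service
  use, ≈£400 expected per 6-month window), priced by the costing module so
  the full chain — including the blank-item rule — is exercised. A
  lognormal pupil frailty (log-sd 0.8) induces within-pupil correlation
  across waves and heavy tails; a lognormal school multiplier carries the
  cost ICC, its variance solved in closed form from the configured ICC and
  the count-model moments of the discounted 33-month total (infeasible
  combinations raise a named error). The intervention's true incremental
  cost (default −£30) is embedded by scaling post-baseline count means so
  the expected discounted total differs by exactly that amount.
* **Outcome**: school prevalences are normal perturbations of the arm
  prevalences (0.23 control, 0.15 intervention → true Δe = 0.08) on the
  probability scale with variance icc·p(1 − p), clipped to (0, 1); pupils
  add +0.30 probability if they drank at baseline (prevalence 0.05),
  mean-preserving. An optional mode derives HED from simulated episode
  units against the sex-specific thresholds (6 / 4.5 units), calibrated to
  coincide with the direct draw.
* **Missingness**: wave- and outcome-level, default MNAR — odds shifted
  by high-FSM school (×1.5), baseline drinking (×1.8) and the pupil's own
  latent service-use frailty (×1.3 per SD), so complete cases are
  systematically lighter service users. Base rates (0.06 per wave, 0.09
  outcome) leave roughly two-thirds of pupils complete, matching the
  study conditions. MCAR and MAR variants are available; zeros give a
  fully complete cohort.

**What passing tests show.** Recovery and coverage results demonstrate
that the estimation chain is unbiased and correctly calibrated *under the
generator's assumptions* (log-additive school effects, ZINB counts,
probability-scale outcome heterogeneity, the configured MNAR form). They
do not certify behaviour under real-data features the generator omits:
item-level cost reporting error, time-varying ICCs, school-size/covariate
confounding, or outcome-dependent missingness differing by arm.

## Problem sizes

Simulation studies run at two scales: default (105 schools × ~108 pupils,
B = 1000; a full simulate+analyse pass takes well under a minute) and a
reduced recovery scale of 20 schools × 30 pupils with B = 200 across 200
replicate trials, which keeps the full recovery-plus-coverage study to a
few minutes while leaving Monte-Carlo error small relative to the
quantities checked. The reduced scale occasionally realises strata that
make the arm effect non-identifiable; such trials have no defined estimate
and are redrawn (counted in the study output).

## Known limitations

* The FGLS fit assumes a single school-level variance component; crossed
  or nested structures (classes within schools) are out of scope.
* The linear probability model can produce fitted probabilities outside
  [0, 1]; a logistic effect model with marginal standardisation is
  available behind a flag (`fit_effect_model(..., model="logistic")`) but
  is not used inside the bootstrap, where the linear model's speed and
  exactness (its coefficient *is* the risk difference) are preferred.
* MI's imputation models are fixed-effect approximations; they do not
  carry a school random intercept.
* Percentile intervals are first-order accurate; with very few clusters
  (<6 per arm) no bootstrap variant is reliable.
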