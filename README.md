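# trialcea

Trial-based cost-effectiveness analysis (CEA) for cluster-randomised
public-health trials, built around the economic evaluation of a
school-based alcohol-misuse prevention programme: a classroom curriculum
plus a brief parental intervention, compared with education as normal, in
~105 high schools (~12 000 pupils aged 11–12), with heavy episodic
drinking (HED) at 33 months as the binary outcome and costs taken from a
public-sector perspective (education, health, criminal justice).

The package is aimed at health economists and trial statisticians who need
a tested, reproducible pipeline from raw inputs to decision-analytic
outputs:

* **costing** — per-pupil 33-month discounted public-sector costs from
  four 6-month service-use recall windows priced against a unit-cost
  ledger (2013–14 GBP), with the blank-item-means-zero rule, midpoint-rate
  linear interpolation across survey gaps, 3.5 % discounting and
  complete-case flagging;
* **programme costing** — the intervention's resource ledger (stage 1
  planning/preparation, stage 2 delivery) aggregated to total, per-school
  and per-pupil costs under three delivery scenarios, plus national
  extrapolation;
* **inference** — incremental cost Δc and incremental effect Δe (HED cases
  avoided, control minus intervention) from linear models with a
  school-level random intercept, adjusted for location, free-school-meals
  (FSM) band, school type and the pupil's baseline cost / baseline
  drinking; uncertainty by a school-level bootstrap stratified by arm;
* **decision outputs** — dominance classification with conventional ICER
  rules, cost-effectiveness plane, and acceptability curves (CEAC) over
  willingness-to-pay λ via net monetary benefit λ·Δe − Δc;
* **sensitivity analyses** — multiple imputation by chained equations
  (PMM for costs, logistic for the outcome, Rubin's rules), 1.5 %
  discounting, cluster-only adjustment, ±5 % cost perturbation;
* **synthetic data** — a cluster-RCT generator with known ground truth
  (overdispersed service counts, configurable ICCs, informative
  missingness) so every stage is testable without access to trial data.

## The model

For pupil *i* in school *s(i)*, with treatment indicator `arm`:

```
cost_i  = α + δc·arm + β'x_i + u_s(i) + ε_i        (x: location, FSM band,
hed33_i = α + δe·arm + γ'z_i + v_s(i) + η_i          school type, baseline
                                                     cost / baseline HED)
```

Both are random-intercept linear models (the outcome model is a linear
probability model, so −δe is directly the adjusted risk difference,
reported as *cases avoided*). Fitting is by moment-based feasible GLS
(within/between variance decomposition, then the random-effects partial
demeaning transform); a REML mixed model is the independent cross-check in
the tests. Confidence intervals are percentile intervals over B = 1000
joint bootstrap replicates (Δc_b, Δe_b), resampling schools within arm.
The CEAC at threshold λ is the share of replicates with λ·Δe_b − Δc_b > 0.

## Worked example

```python
from trialcea import (GeneratorConfig, TrialData, generate,
                      build_analysis_dataset, complete_cases,
                      add_programme_cost, aggregate, ProgrammeCostLedger,
                      cluster_bootstrap, classify)

trial = generate(GeneratorConfig(seed=1))          # 105 schools, ~11k pupils
data = build_analysis_dataset(TrialData(waves=trial.waves, pupils=trial.pupils))
cc = complete_cases(data)                          # ~2/3 of pupils
per_pupil = round(aggregate(ProgrammeCostLedger.default()).per_pupil)  # 15
cc = add_programme_cost(cc, per_pupil)
est = cluster_bootstrap(cc, B=1000, seed=1)
res = classify(est.delta_c, est.delta_e, est.ci_c, est.ci_e)
print(round(est.delta_c, 2), [round(x, 2) for x in est.ci_c])
print(round(est.delta_e, 3), [round(x, 3) for x in est.ci_e])
print(res.label, res.quadrant, round(res.icer))
```

prints

```
142.99 [-32.78, 328.78]
0.092 [0.066, 0.116]
trade_off NE 1555
```

i.e. in this simulated replicate of the study conditions the intervention
point estimate is £143 more per pupil (CI spanning zero) while avoiding
HED in about 9 pupils per 100 (CI excluding zero): a north-east trade-off
with an ICER of roughly £1 555 per case avoided. The generator's embedded
truth is Δc = −30 + £15 programme cost = −£15 (covered by the cost CI)
and Δe = 0.08; school-level cost variation is wide, exactly the
cost-uncertainty pattern the method is built to quantify, and other seeds
land in the south-east quadrant (weak dominance, no ICER reported).

The same run from a shell:

```bash
trialcea all --seed 1 --out results/ --bootstrap 1000
trialcea programme-cost --scenario no_parental
```

## Input formats

* `unit_costs.csv` — `service_id,label,sector,unit_cost`; the shipped
  default is the 2013–14 ledger (17 services: 5 education, 10 health, 2
  criminal justice).
* `service_use.csv` — long format `pupil_id,wave,service_id,count` with
  waves `pre_baseline,m7_12,m19_24,m28_33`; an *empty* count is a blank
  item (costed as zero use); a (pupil, wave) with *no rows at all* is a
  missing wave (pupil excluded from complete-case totals).
* `programme_costs.csv` — `stage,label,amount,parental`.
* `pupils.csv` — pupil id, school id, arm, strata, baseline drinking,
  outcome.

See `docs/methods.md` for the full methodological account.
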