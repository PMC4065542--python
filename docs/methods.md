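# Methods

## Model structure

The model is a cohort decision tree for a hypothetical population of
chest-pain presenters. Disease status (acute myocardial infarction, AMI) is
Bernoulli at prevalence 0.30. Each diagnostic strategy applies a biomarker
test at ≤6 h from symptom onset and repeats it at ≤12 h in stage-1
negatives; patients negative at both stages are regarded as AMI-free and
discharged. The two stages are treated as conditionally independent given
disease status, with the printed ≤12 h sensitivity/specificity used as the
stage-2 conditional accuracies (the *conditional* reading). An alternative
*cumulative* reading — the ≤12 h figures describe the probability of having
tested positive (or never positive) at least once by 12 h — is available via
`ModelConfig(stage2_reading="cumulative")` and is converted internally to
conditional stage-2 probabilities se₂ = (Se₁₂−Se₆)/(1−Se₆),
sp₂ = Sp₁₂/Sp₆.

Terminal pathways and their in-hospital death probabilities:

| pathway | event | death probability |
|---|---|---|
| TP_EARLY | AMI treated after stage-1 detection (PPCI within 4 h) | 1−(1−0.062)(1−0.0072) |
| TP_LATE | AMI treated after stage-2 detection (delayed PPCI) | 1−(1−0.103)(1−0.0072) |
| FN_MISSED | AMI discharged undiagnosed | 1.9 × 0.062 |
| FP_EARLY / FP_LATE | no AMI, false positive | 0 (no PPCI by default) |
| TN | no AMI, correctly ruled out | 0 |

Disease and procedural mortality combine multiplicatively on survival
(independent risks); an additive option exists. The missed-AMI risk ratio
multiplies the *early*-treatment baseline by default (the source comparison
was discharged vs hospitalized patients); the delayed baseline is a config
option.

## Outcomes and costs

In-hospital deaths accrue zero life years. Surviving AMI patients live the
post-AMI life expectancy of 8.3 years; life years are discounted at
1.5%/year in annual cycles with the first year undiscounted and the
fractional final year pro-rated (no half-cycle correction — the simplest
defensible convention, and configurable only through the parameter file's
discount rates). QALYs are life years × the constant post-AMI utility
0.725, so QALY/LY = 0.725 holds identically for every strategy and every
parameter draw. Non-AMI patients contribute zero life years and QALYs by
default (effectiveness is defined over AMI patients); a config knob can
credit them a fixed horizon instead.

Costs: every patient pays for the tests actually taken (stage 1, plus
stage 2 for retested stage-1 negatives) at time zero, undiscounted. Treated
AMI accrues €12,446 in the first year and €2,092 in each subsequent year of
survival, discounted at 4%/year on the same cycle convention. Missed-AMI
patients accrue the same treatment stream by default (they have the disease
and are assumed eventually treated; `missed_accrue_costs=False` turns this
off). In-hospital deaths still accrue the first-year cost by default
(treatment was delivered). False positives accrue no PPCI, no procedural
risk and no downstream cost by default; `fp_gets_ppci` and
`fp_workup_cost` expose the alternatives.

Two printed inputs required interpretation and are package-level choices:

* the discount rates are printed as "0.4" and "0.15" and are read as the
  Dutch guideline values 4% (costs) and 1.5% (effects); both are ordinary
  config parameters;
* the high-sensitive assay's unit cost is taken as €21.50 (the bottom-up
  costing figure, consistent with the reported €4.39 increment over the
  €17.11 conventional assay) rather than the €31.5 appearing in the input
  table; the latter remains a one-line config edit. The H-FABP marginal
  cost is published nowhere and defaults to a clearly flagged €10
  placeholder; the combination strategy's per-stage cost is the hsTnT cost
  plus this margin.

## Parameter uncertainty

Printed (min–max) ranges are read as 95% intervals, sd = range/3.92.
Probabilities and the utility use method-of-moments Beta fits (support
[0,1]); treatment costs use moment-matched Gamma; parameters whose sources
reported no interval (prevalence, mortalities, risk ratio, life expectancy,
unit costs) use classical Beta-PERT (λ = 4) on their printed range. Both
fits reproduce the point estimate as the distribution mean to 1e−9
relative; PERT has mean (low+4·mode+high)/6 by construction. The PSA draws
all non-fixed parameters independently (sensitivities and specificities of
the same assay included — a documented simplification) with one joint draw
shared by the three strategies per iteration; draws violating probability
constraints (risk ratio × baseline > 1) are rejected and redrawn with a
10⁴-rejection cap. Acceptability curves use the net-monetary-benefit
criterion on a 0–20,000 €/QALY grid in €500 steps; exact NMB ties split
equally (they have measure zero under continuous draws). The one-way
analysis sets each non-fixed parameter to its printed range endpoints — the
CI-or-±25% rule is already baked into those columns — and reports the
hsTnT-vs-cTnT cost-per-QALY ratio by default, ranked by span in the tornado
table.

## Microsimulation oracle

The patient-level simulator draws each patient's pathway from the tree's
joint pathway distribution (one multinomial draw equivalent to the
disease → test 1 → retest → test 2 Bernoulli cascade), then a Bernoulli
in-hospital death at the pathway's death probability, and accrues costs and
outcomes through the *same* functions the tree uses. Divergence beyond
sampling noise is therefore impossible by construction, which is exactly
what makes it a useful oracle: cohort means must approach the tree's
expectations at rate 1/√n, and the validation report checks |z| ≤ 3 for
cost, life years and QALYs per strategy (plus a χ² goodness-of-fit on
pathway frequencies in the test suite, n = 2×10⁵). Survivor life
expectancy is fixed at 8.3 years in the simulator, matching the tree's
expected-value use. Cohorts below 10⁴ patients are flagged low-power.

## Problem sizes and determinism

The default analyses are desk-scale: the tree is closed-form (18 terminal
pathways across three strategies, <1 ms), the PSA runs 1,000 iterations in
about a second, the one-way sweep is 48 model evaluations, and the
validation cohorts use 2×10⁵ patients per strategy. Every stochastic
routine is a pure function of (inputs, seed) via `numpy.random.default_rng`;
identical seeds give bit-identical draws, CSVs and JSON reports.

## Reproducibility of the published results

This package re-implements a previously published evaluation, and its
acceptance checks compare against that evaluation's printed base-case
table. The comparison exposes an irreconcilable inconsistency in the
source: the printed increments (Δcost €30.70, ΔLYG 0.006, ICERs
€4,945/LYG and €7,370/QALY for hsTnT vs cTnT) are mutually consistent only
if one additional hospital survivor contributes ≈1.0 discounted life years.
Under the accounting stated above — a survivor lives 8.3 years, discounted
to 7.86 — the same parameter inventory gives ΔLY = 0.30 × 0.0207 × 7.86 ≈
0.0487 and Δcost ≈ €79.4, i.e. ICERs of €1,628/LYG and €2,246/QALY. The
survival-probability increment itself matches the published effect
increment almost exactly (0.30 × 0.02065 = 0.00620 vs 30.70/4945 =
0.00621), which strongly suggests the original effect column recorded
survival probabilities rather than life years; the published absolute
totals (2.286 LY at a cost of €15,115.62) cannot be back-derived from the
published inputs under any accounting variant this package exposes
(conditional/cumulative stage-2 reading, missed-cost accrual,
first-year-cost handling, false-positive handling, either discount-rate
reading, either hsTnT unit cost). The published combination-arm increments
(0.0037 LYG over hsTnT) are likewise ~9× larger than the survival shift
its printed accuracies permit (0.0004). The defaults therefore stay at the
documented values, the affected acceptance checks are left failing rather
than calibrated to pass, and all numbers this package reports are produced
by the faithful accounting. Directionally every published conclusion is
reproduced — and strengthened: hsTnT is *more* cost-effective here than
originally reported.

One structural consequence: because the H-FABP combination's small extra
survival costs only ≈€7,300/QALY under this accounting (the source implies
≈€22,800/QALY), the combination — not hsTnT alone — attains the highest
acceptability above that threshold, so the published acceptability-curve
ordering is not reproduced either. With the H-FABP marginal cost unknown,
this ordering is entirely driven by the €10 placeholder; users with a real
H-FABP cost estimate should set `hfabp_marginal_cost` before interpreting
the combination arm.

## Known limitations

* No ECG/symptom triage, no ST-elevation stratification, no continuous
  treatment-delay function — only the two printed delay classes.
* No age- or sex-dependent mortality, utility or costs; a single constant
  utility weight.
* The synthetic cohorts emulate the model's stated stochastic structure
  only; they contain no patient heterogeneity, no correlation between test
  errors within a patient beyond disease status, and no re-presentation of
  missed cases. Passing oracle checks shows the analytic and stochastic
  layers agree — not that either matches clinical reality.
* Strategy definitions are data (config), so further strategies can be
  added without code changes, but the frontier logic is only exercised for
  small strategy counts.
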