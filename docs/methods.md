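# Methods

## The screening rule

The tool is an unweighted boolean rule over tri-state risk factors. A
participant is classified **high lifetime T2DM risk** when every *core*
factor is present and at least one *plus-one* factor is present; otherwise
low. There is no score, no weighting and no probability — the design goal
is a questionnaire parents can complete unaided, and the trade-off (equal
weighting may be statistically sub-optimal) is accepted deliberately.

Twenty-three variants ship as data (`data/rulesets.yaml`): the initial
tool (core = overweight/obese + high screen time, plus-one = thirteen
further factors), twelve variants produced by cumulative removal of
plus-one factors in the published order (AN, FLD, PCOS, SI, MS, FH, PDM,
ETH, OP, BF, SGA, WG04 — an order the original investigators describe as
arbitrary), and nine stakeholder-amended variants ending in the final tool
(core = overweight/obese; plus-one = WC, FH2, OP, BF, SI, ST, LPA, LFV).
High waist circumference is never removed at any rung. The `final` name
aliases `tool20`.

## Factor thresholds

Every cut point is configurable (`ThresholdConfig`); the defaults are the
tool's published values with the printed inequality direction — "high"
factors inclusive (≥), "low" factors strict (<):

| factor | rule | default |
|---|---|---|
| OO  | BMI z-score ≥ cut (85th percentile) | 1.04 |
| WC  | waist ≥ age/sex cut (cm) | 84.5/81.2, 87.9/84.1, 91.3/86.9 (12/13/14, M/F) |
| ST  | screen time ≥ cut (h/day) | 2 |
| LPA | physical activity < cut (min/day) | 60 |
| LFV | fruit & veg < cut (portions/day) | 5 |
| SI  | sugary drinks ≥ cut (ml/day) | 532 (1.5 cans) |
| OP  | either parent BMI ≥ 30 (White European) / ≥ 27 (other) | 30 / 27 |
| WG04| infant weight gain ≥ cut (g/month) | 908 (2 lb) |
| BP  | mean of last two readings ≥ 120 systolic AND ≥ 80 diastolic | 120 ∧ 80 |
| glucose | ≥ 7.0 fasting / ≥ 11.1 non-fasting (mmol/L) | 7.0 / 11.1 |
| PDM | HbA1c in [6.0 %, 6.5 %) or an explicit clinician flag | — |
| MS  | ≥ 3 of {high BP, high cholesterol, high triglycerides, high non-diabetic glucose} | 3 of 4 |

Unknown raw values propagate to unknown factors under Kleene three-valued
logic: a factor is never declared present or absent when every
contributing field is missing. Composite factors use three-valued
counting — metabolic syndrome is absent only when present + unknown
components cannot reach the minimum.

Assumptions made where the tool's definition is silent, all overridable:

- **Metabolic-syndrome component cuts are not published.** Defaults:
  total cholesterol ≥ 6.0 mmol/L or LDL ≥ 3.0 mmol/L (the study's own
  high-risk reporting cuts), triglycerides ≥ 1.7 mmol/L (standard adult
  criterion), and "high glucose but not in the diabetes range" as fasting
  glucose in [5.6, 7.0) — the standard impaired-fasting band. For
  non-fasting or unknown-status samples this band is unknowable, so the
  component is unknown unless the glucose is below the band (absent) or in
  the diabetes range (absent, excluded by definition).
- **Waist cut points are treated as inclusive (≥)**, consistent with
  every other "high" threshold; the published list gives no inequality
  symbols.
- **Unknown fasting status uses the non-fasting glucose cut** —
  participants were not required to fast, so unknown status is most
  plausibly non-fasting, and the higher cut is conservative.
- **A parent with known BMI but unknown ethnicity** is obese if at/above
  the stricter cut (30), non-obese below the laxer cut (27), unknown
  between them.
- **The rapid-weight-gain window label** ("first year" vs "0–4 months"
  in different parts of the source) does not change the computation: the
  input is a g/month rate and the 908 g/month cut applies either way.
- **BMI status is consumed as a z-score** (`bmi_z`); no growth-reference
  tables are bundled. Callers derive z externally (or supply their own LMS
  reference); z = 1.04 ≡ 85th percentile.

## Classification with missing data

The default `unknown_policy="absent"` mirrors the study: blank responses
could not be used as evidence, so unknown factors cannot satisfy the rule.
Replacing any unknown with absent provably never changes a default-policy
classification. A `strict` policy is available for sensitivity analyses:
the rule is monotone in factor presence, so evaluating the two extremes
(all unknowns absent / all present) bounds every completion; if they
disagree the record is `INDETERMINATE`, and evaluation excludes such
records with an explicit count rather than dropping them silently.

## Evaluation

The reference standard is a clinician consensus: two independent raters,
with a third adjudicating disagreements. Accuracy is summarised by
sensitivity, specificity, PPV and NPV with binomial intervals —
Clopper–Pearson exact by default (the published intervals are consistent
with it), Wilson selectable. Percentages are rounded half-away-from-zero
to 1 decimal, AUROC to 2 decimals, matching the printed precision.

A single-threshold test has a one-point ROC polygon, so its trapezoidal
AUROC is exactly `(sensitivity + specificity)/2`. The AUROC interval is
obtained by pushing the two binomial interval endpoints through the same
identity — a documented approximation (the published interval method is
unknown).

**Reconstruction from marginals.** The study published marginal counts
(n = 636; 241 clinician-high; 214 tool-high) and rounded metrics, not the
2×2 table. `reconstruct_from_marginals` searches the feasible
true-positive range `[max(0, ref⁺+pred⁺−n), min(ref⁺, pred⁺)]` for the tp
minimising the distance to the published sensitivity (ties to the smaller
tp). This is exact whenever the published value was computed from an
integer table with those marginals; for the initial tool it returns
tp = 154 and reproduces all four published metrics to the printed decimal.
The refined tool's published marginals are *not* mutually consistent with
a single complete 2×2 on n = 636 (the per-metric denominators evidently
differed), so reconstruction is only guaranteed for the initial tool.

## Synthetic cohorts

Because the study data are request-only, the generator emulates their
statistical skeleton:

- **Country strata** at the recruited sizes (UK 81, Germany 100,
  Portugal 226, Spain 129, Greece 100), each with its published sex split,
  age mean, overweight/obese proportion and measurement moments.
- **Threshold-defined factors are generated indicator-first**: a
  Gaussian copula draws each indicator at its target prevalence — the
  published refined-tool prevalence table (OO 55.8 %, WC 31.5 %, ST
  55.2 %, LPA 6.8 %, LFV 55.2 %, FH 11.5 %, SI 14.0 %, BF 17.6 %, OP
  34.4 %) — and the underlying measurement is then drawn from a truncated
  normal on the matching side of the cut. A shared adiposity latent gives
  positive dependence between BMI z, waist and parental obesity
  (ρ defaults 0.7 and 0.3). The family-history prevalence is targeted as
  the 1st-or-2nd-degree union, since that is the factor the refined tool
  uses. Factors absent from the published prevalence table (AN 3 %, FLD
  1.5 %, PCOS 2 % of females, SGA 5 %, WG04 10 %) use plausible
  paediatric prevalences chosen once.
- **The BMI quota bands** of the study's sampling frame (midpoints
  17.5 % normal / 37.5 % overweight / 40 % obese) set the overweight:obese
  split within the overweight/obese group (z in [1.04, 2) vs ≥ 2).
- **Missingness** is injected completely at random per field at the
  published missing-value rates (e.g. LDL 285/636, HbA1c 34/636, waist
  1/636); ethnicity is structurally unknown in the Greece and Portugal
  strata, where it could not legally be collected.
- **Clinicians** are simulated by a latent-score threshold: log-odds
  `−2.0 + 1.5·OO + 0.3·(each final-tool plus-one factor present)`, so an
  overweight/obese adolescent with ≥ 2 further factors is judged high —
  weight-dominant, reflecting the investigators' description of their
  raters, since no decision data were recorded. This model is an explicit
  assumption. Each of the three raters independently flips the shared base
  judgement with probability ε ∈ [0, 0.5); expected pairwise agreement is
  1 − 2ε(1 − ε), strictly decreasing in ε, so `calibrate_agreement`
  bisection-tunes ε to the published 76 % (ε ≈ 0.14). A rater model can
  instead threshold exactly on a rule set — the zero-noise identity case
  in which the full pipeline returns sensitivity = specificity = 1.

What passing tests on synthetic cohorts do **not** show: the generator
matches published *marginals*, not the unpublished joint distribution, so
intermediate-rung AUROCs, the refined-tool count (343) and the exact
country-by-country tool counts are not reproducible from it; tests assert
structural properties instead (monotone high-risk counts along removal and
addition segments, the AUROC identity at every rung, parameter recovery of
prevalences and strata). Country-level numeric *moments* are only
approximate, because measurements are drawn conditionally on their factor
indicators.

## Numerical choices

- Rounding half away from zero on the decimal representation (`Decimal`),
  because binary-float `round()` misplaces printed ties such as
  0.7965 → 0.80.
- Truncated normals are sampled by inverse-CDF on a seeded generator:
  vectorised, reproducible, and exact for one-sided and two-sided bands.
- Marginal reconstruction breaks ties toward the smaller tp count.
- Degenerate evaluation denominators (e.g. no reference-positives) flag
  the metric undefined rather than reporting 0.
- All randomness flows through `numpy.random.default_rng(seed)`; the same
  spec and seed yield byte-identical cohort files.

## Problem sizes used in the checks

The shipped test-suite and reproduction script use the study-scale cohort
(n = 636) for pipeline and identity checks, n ≈ 20 000 for prevalence
recovery (Monte-Carlo tolerance ±1.5 percentage points, ≈3σ), 1 000
replicates per setting for interval-coverage checks, and exhaustive
enumeration (2⁹ profiles) for the final rule's truth table.

## Known limitations

- The clinician model is a stipulated assumption; real raters saw the
  full record and may weigh factors differently, non-independently, or
  by country.
- No growth-reference data are bundled; `bmi_z` quality is the caller's
  responsibility.
- The refined tool's published marginals cannot be reconciled into one
  complete 2×2; per-metric denominators are reported to make the same
  issue visible in user analyses.
- The simulator's inter-field correlations beyond the adiposity copula
  are not calibrated (unpublished); they are exposed as knobs.
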