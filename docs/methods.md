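# Methods

This note documents the statistical model, the design decisions behind
it, the defaults, and what the synthetic-data experiments do and do not
demonstrate.

## The risk engine

The package deliberately does not re-implement a full pedigree-based
segregation model. Published multifactorial carrier-risk tools delegate
the absolute-risk computation to a large genetic model whose internals
(pedigree peeling, birth-cohort incidences, mammographic density) are
out of scope here. Instead the engine uses a transparent cause-specific
competing-risk formulation on a piecewise-constant age grid:

- hazard: `λ(t|x) = λ₀(t) · exp(β_PV(t) + z·β_PRS(t) + Σ_f β_QRF[f] +
  fh·β_FH)`, with 5-year bands from age 20 to 80 by default;
- absolute risk over `[s, e)` conditional on being event-free at `s`:
  `P(s,e) = ∫ λ(u) exp(−∫[λ+μ]) du`, evaluated exactly segment by
  segment (a band occupied for duration `d` with rates `λ_k, μ_k`
  contributes `S_k · λ_k/(λ_k+μ_k) · (1 − e^{−(λ_k+μ_k)d})`).

Two properties motivated this choice. First, it reproduces the
*analysis mechanics* of a prospective validation exactly — landmarking,
horizon clamping, competing mortality, variant toggling. Second, it is
the exact inverse of the cohort generator: simulated event times come
from the same hazards by inverse-transform sampling, so on synthetic
data the predicted risks are the true event probabilities and
calibration statistics have known expectations. Every closed-form value
is checked against fine-grid product integration (1e−9) and
Monte-Carlo simulation (3 MC SEs), and Chapman–Kolmogorov consistency
across band edges holds to 1e−12.

Mortality is the only competing event inside the predictor. Mastectomy
and RRSO are treated as censoring, not competing risks, mirroring the
validation design being modelled. Predictions condition on surviving
event-free to the landmark (entry + 1 year); women exiting earlier are
excluded upstream rather than predicted.

## Cohort preparation

Follow-up endpoints are resolved in the order BC/DCIS diagnosis,
mastectomy, (RRSO when the sensitivity toggle is on), last follow-up,
death, baseline + landmark + horizon, age 80; ties are broken by that
listing order and affect only measure-zero configurations. "No history
of cancer" is implemented as any BC or mastectomy age strictly before
baseline. The ">1 year follow-up" filter is applied *after* deriving
censored follow-up (the alternative order is not distinguishable in the
design being emulated). Exclusions are logged with the first failing
rule: `age`, `prior-event`, `follow-up`, `missing-data`, then
`pre-landmark exit` for women whose derived exit precedes the landmark.

## Prediction windows and censoring

The default prediction window is `[baseline+1, baseline+6)` for
everyone. The `predict_to_censoring` option instead truncates the
window at the exit age for women censored inside it, mirroring the
practice of predicting healthy women's risks only to their censoring
age. Two subtleties discovered during development are worth recording:

1. **Death never truncates the window.** The competing-risk integral
   already marginalizes over mortality; truncating at an observed death
   age would double-count it (the truncated integral uses
   `e^{−(Λ+M)}` *and* conditions on the death time).
2. **Truncation makes the predictor outcome-dependent.** Cases keep
   their full windows while censored women get truncated (smaller)
   predictions, so with appreciable in-window censoring the calibration
   slope is biased upward (≈ +0.13 at ~11% in-window censoring in our
   experiments) even when the model is exactly right, and E/O acquires
   a small (+2%) upward bias. This reproduces the direction of
   published slope estimates sitting slightly above 1. Exact
   self-consistency (E[yᵢ] = pᵢ individually, slope → 1) holds only
   with full-horizon predictions and complete within-window follow-up;
   the calibration-by-construction test is therefore run in that
   regime, while the IPW and FH experiments keep realistic censoring
   because the effects they measure are an order of magnitude larger
   than the truncation bias.

## Sampling weights

The inclusion model is a maximum-likelihood logistic fit with exactly
six terms (intercept, baseline age, follow-up duration, incident BC
status, BC×age, BC×follow-up), fitted per country group; Austria,
Germany and Poland are pooled in the default grouping, and any group
below `min_group_size` (default 200) is merged into a pooled group.
Follow-up duration is the censored span `exit_age − baseline_age`, so
the weighting covariates are observable for every woman. Weights are
inverse fitted probabilities with a configurable probability floor
(default 0.01, i.e. weights capped at 100) to bound variance; the
uncapped probabilities are reported alongside. Single-class groups and
separation raise a fitting error naming the group rather than returning
divergent weights.

## Validation metrics

All metrics take per-woman weights and reduce to the classical
unweighted forms at unit weights (asserted to 1e−12).

- **E/O**: `Σwp / Σwy`; the 95% CI is log-normal with the Poisson-type
  standard error `sqrt(Σw²y)/O`. The CI method for this ratio is not
  canonical in the literature being emulated; the choice is recorded in
  the report metadata.
- **Calibration slope**: weighted logistic fit of the outcome on
  logit(p), predictions clipped to [1e−6, 1−1e−6]; Wald CI, robust
  (HC1) covariance when weights are supplied.
- **Quantile calibration**: bins at weighted quantiles of predicted
  risk (switchable to unweighted); ties on an edge go to the lower bin;
  per-bin expected counts partition the total exactly.
- **AUC**: weighted probability that a random case outranks a random
  non-case, ties counted half, computed by sorted cumulative weights in
  O(n log n); CI by stratified bootstrap (default 2000 replicates).
- **Harrell's C**: comparable pairs are those whose strictly earlier
  time is an event; pair weight is the product of member weights;
  prediction ties count half. Computed with a Fenwick tree over
  prediction ranks in O(n log n) and verified against O(n²) brute-force
  enumeration to 1e−12 (including ties and weights); CI by grouped
  jackknife (default 50 groups), which keeps the cost linear in the
  number of groups rather than in n.
- **Stratification**: weighted proportions below 1.65%/3%/5% predicted
  5-year risk, NPV among those below, composition of the low-risk
  groups by entry age (<30, 30–50, ≥50) and gene, and the weighted
  fraction of incident cases captured by the top predicted-risk half.

Discrimination metrics are weight-aware by default (whether the
original analyses weighted them is not documented; a config switch
covers both readings). No multiplicity adjustment is applied — the
report carries per-metric CIs only.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
not any specific real cohort:

- **Ascertainment**: FH burden is a Poisson(0.4) count of affected
  first-degree relatives; candidates enter the cohort with probability
  `logistic(logit(0.3) + 1.0·fh)`, giving clinic-style FH enrichment.
  The strength is a free parameter, not an estimate — quantitative
  ascertainment of real carrier cohorts is not published.
- **PRS**: raw scores are Normal(−0.424, 0.611²) so the standardized
  PRS is standard normal by construction; the constants are defaults,
  not hard-coded.
- **Hazards**: the default truth uses general-population-scale baseline
  incidence with PV relative hazards shaped so BRCA1 risk peaks early
  and declines while BRCA2 peaks in mid-life, a per-SD PRS effect
  attenuating from ~1.6 to ~1.25 across age, modest QRF effects
  (0.9–1.2) and 1.3 per affected relative. These give carrier-level
  absolute risks (≈8% mean 5-year risk at the cohort's age mix).
- **Censoring**: mastectomy (1.2%/yr), RRSO (2%/yr, censoring only in
  the sensitivity analysis) and loss to follow-up (1%/yr) are constant
  rates independent of the BC hazard; death follows the age-banded
  mortality curve so the generator and engine agree about the competing
  risk. Follow-up questionnaires end 8 years after baseline.
- **Sizes**: simulated cohorts of 20,000–50,000 are used in the
  acceptance experiments (large enough that Monte-Carlo error is well
  below the effects tested); the interval-coverage experiment uses 100
  replicates of 5,000.

What passing these tests shows: the pipeline's algebra, filtering,
weighting and metrics are correct against known truth. What it does not
show: anything about real carrier cohorts — the generator has no
pedigree structure, no genotype-level PRS, no country-specific
follow-up behaviour, no correlation between risk factors and
censoring, and its FH summary is a count rather than a pedigree.

## Known limitations

- The engine's absolute-risk formulation is declared, not inferred from
  any production genetic tool; a validation of such a tool would
  substitute its risk outputs at the `PredictionSet` boundary.
- Constant-rate censoring cannot represent informative censoring;
  consequently the weighting module corrects only outcome-dependent
  *inclusion*, not outcome-dependent *censoring*.
- Left truncation beyond the landmark and recurrent events are not
  modelled.
- The grouped-jackknife C-index CI and the bootstrap AUC CI are
  first-order methods; at very small n (tens of events) their coverage
  degrades with all such estimators.
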