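# Methods

`snfdid` implements a quasi-experimental analysis of diagnosis coding
intensity in skilled nursing facility (SNF) claims around the announcement
of Medicare's Patient-Driven Payment Model (PDPM), together with a
synthetic claims generator that reproduces the statistical structure the
analysis relies on. This note documents the models, the generator, the
numerical choices, and what the synthetic results do and do not show.

## The design

PDPM ties SNF reimbursement to documented patient complexity. Its Final
Rule became effective on 2018-10-01 (the *announcement*), and payment
changed on 2019-10-01 (the *implementation*); the year in between is the
*anticipation period*. Because the policy applied to every SNF at once,
there is no untreated facility group. The design instead uses a
non-equivalent dependent variable (NEDV) control: each analysis unit is a
hospital-to-SNF care episode — a hospital claim linked to a SNF claim for
the same beneficiary within three days of hospital discharge — and the
*hospital* claim's complexity measures serve as the control outcome for
the *SNF* claim's. Both claims describe the same person days apart, so
patient-level confounding differences are eliminated by construction, and
hospital coding is not subject to PDPM.

Outcomes, computed once from each claim's ICD-10 codes:

1. **Diagnosis count** — number of codes on the claim (1–25).
2. **Weighted Elixhauser score** — Elixhauser comorbidity flags from the
   Quan ICD-10 prefix mapping, weighted with the Van Walraven integers.
   Attainable range −19..89 (sum of the negative and positive weights).
3. **Five documentation-sensitive condition indicators** — chronic
   pulmonary disease, complicated diabetes, heart failure, obesity,
   weight loss: common chronic conditions that raise reimbursement but may
   go unrecorded without an incentive.

## Estimating equation

For claim outcome `y_ijt` of episode i at facility j in year-month t:

```
y_ijt = b1·Treat_j + b3·(Treat_j × Post_t) + b4'X_jt + a_j + l_t + e_ijt
```

with facility fixed effects `a_j`, year-month (of SNF admission, for both
rows of an episode) fixed effects `l_t`, and row-specific facility
covariates `X_jt` (hospital VBP/ACO participation, profit status,
rurality, affiliated SNFs on hospital rows; SNF chain status, star rating,
rurality on SNF rows; county COVID-19 case rate matched to the row's
stay). `Treat = 1` for the SNF row. Because every facility is purely
hospital or purely SNF, `Treat` is collinear with the facility effects;
likewise `Post` with the time effects. Both are reported as *absorbed*
rather than estimated. The coefficient of interest is `b3`, the
difference-in-differences effect of the announcement on SNF-recorded
complexity. Triple-difference (DDD) models add `Post × ForProfit` and
`Treat × Post × ForProfit`, the latter measuring the extra response of
for-profit SNFs; stratified models re-fit the two-way model within each
profit stratum. Relative percent changes are `100 · b3 / baseline` with
the pre-announcement SNF mean as baseline, printed to one decimal below
100% and to the nearest integer above.

Fixed effects are absorbed by alternating-projection demeaning (tolerance
1e-8 on the largest within-group mean, at most 500 sweeps; with two
groupings convergence is typically a handful of sweeps). Covariate columns
that are constant within every facility (or every month) are structurally
absorbed by the fixed effects; they are removed up front and listed in the
result's `dropped` field. Remaining rank deficiency raises a
`SingularityError` naming the dependent columns (or drops them when
`on_collinear="drop"`).

Binary condition outcomes use a logit with *explicit* facility and month
dummies (feasible at synthetic facility counts), maximum likelihood with
Newton steps (tolerance 1e-8, 100 iterations, L-BFGS fallback).
Facility/month groups without outcome variation are dropped first — the
standard separation guard for fixed-effects logits. The reported quantity
is the average marginal effect (AME): the mean over SNF rows of
`P(y=1 | Treat×Post=1) − P(y=1 | Treat×Post=0)` holding everything else at
observed values. A linear-probability fit on the same sample is reported
alongside (the two agree to a fraction of a percentage point here);
interval estimates are taken from the linear-probability fit — delta-method
AME standard errors are deliberately out of scope.

## Inference

Standard errors are multiway cluster-robust over beneficiary, facility,
and year-month, combined with the Cameron–Gelbach–Miller
inclusion–exclusion rule: for every nonempty subset of the cluster
dimensions, a sandwich clustered on the intersection of those dimensions
is computed and added with sign `(−1)^(|S|+1)`. Each sandwich carries the
`G/(G−1) · (N−1)/(N−K)` small-sample factor, where K counts the regressors
plus all absorbed fixed effects (this makes the singleton-cluster limit
equal the HC1 sandwich of the explicit-dummy regression). The combined
matrix is not guaranteed positive semidefinite; negative eigenvalues are
truncated at zero and the repair is logged. Confidence intervals use the
normal 1.96 critical value (cluster counts in the emulated study are
large); the critical value is a `ModelSpec` option. A dimension with a
single cluster raises an error advising its removal.

**Event-study clustering.** The event study replaces `Treat × Post` with
`Treat × month` dummies (the last pre-announcement month is the omitted
reference) and tests the pre-announcement coefficients jointly (Wald,
reported as F = W/q against F(q, G_min − 1) with G_min the smallest
cluster count). Its default clustering is beneficiary-only, a deliberate
departure from the pooled model: each `Treat × month` regressor is
non-zero inside exactly one time cluster, so a time-clustered variance
component is not identified for it, and with month-dummy counts close to
the facility count the facility-cluster sandwich is badly conditioned. In
Monte-Carlo checks the three-way-clustered event study rejected a true
null far above its nominal size while beneficiary clustering — exact under
the generator's independence structure — is correctly calibrated. Any
cluster set can still be requested explicitly.

## The synthetic generator

The generator emulates the tables the analysis consumes — MedPAR-style
wide claims (25 diagnosis columns), beneficiary and facility files — under
the study conditions:

* **Episodes.** Each beneficiary contributes 1 + Geometric(mean 0.5)
  episodes over 2018-01..2021-09; hospital discharge is uniform over the
  window, the transfer gap is 0–3 days with the mode at 1–2 days. A small
  configurable minority of records violate the inclusion rules (age < 18,
  < 3 months of Part A coverage, discharge against medical advice, gap
  > 3 days, hospital-based SNF ~3% of facilities) to exercise the filters.
* **Latent comorbidity.** Each beneficiary draws a set of latent
  Elixhauser conditions, independently per category, with prevalences
  chosen so that at the baseline documentation probability (0.645 per
  condition per claim) the documented pre-period SNF moments match the
  emulated study: mean 11.7 diagnoses, mean weighted Elixhauser 6.49, and
  the five condition prevalences (0.238, 0.223, 0.104, 0.048, 0.038).
* **Documentation.** A latent condition appears on a claim with
  probability `q_setting + trend·t + [SNF]·[post]·delta_c`, clamped to
  [0,1]. Each documented condition contributes one representative ICD-10
  code that maps to exactly its category. Non-comorbidity "acute" filler
  codes — drawn from a fixed pool mapping to no Elixhauser category — are
  added (1 principal + negative-binomial extras, dispersion 4) to reach
  the target mean count; comorbidity codes are placed before fillers so
  the 25-code cap truncates fillers first.
* **Effect injection.** The announcement effect is specified in *outcome*
  units and translated to the probability scale as
  `delta_c = a + b·w_c` (`w_c` the Van Walraven weight), with (a, b)
  solving the two-moment system so the expected extra diagnoses AND the
  expected extra Elixhauser points match their targets simultaneously.
  Defaults inject the emulated study's structure: +0.70 diagnoses / +0.75
  points as the not-for-profit base effect and +0.15 / +0.16 extra in
  for-profit SNFs (so the pooled all-SNF effect is the 73/27 mixture).
  The effect switches on at the announcement date, indexed by SNF
  admission (hospital-admission indexing is available as an option); by
  default it is constant through anticipation and post periods. Only the
  two continuous outcomes are targeted; the implied per-condition
  percentage-point increases follow from `delta_c` times the category's
  latent prevalence and are not separately calibrated.
* **Calibration.** `calibrate_generator` refines the closed-form settings
  by simulation: a common documentation-probability scale targets the
  Elixhauser mean, the filler mean targets the diagnosis count, and (a, b)
  are updated by Newton steps on the moment system against *realised*
  increments measured by coupled same-seed simulation with and without the
  effect — so probability clamping and the 25-code cap are automatically
  accounted for. Default tolerance 2% relative, at most 8 iterations,
  failure raises with the trace.
* **Nuisance structure.** County-month COVID-19 case rates are zero before
  2020-03-01 and seeded log-normal (median 400/100k) afterwards, attached
  to each claim's county and stay month; they do not affect documentation,
  serving purely as a covariate. A small secular trend (+0.0015/month on
  every documentation probability) affects both settings equally.

All randomness flows from a single integer seed; identical configurations
give byte-identical tables.

### What the generator does not emulate

Within-month common shocks (facility- or month-level random effects),
serial correlation in a facility's coding behaviour, readmission chains,
multi-claim SNF stays, Medicare Advantage, code-level correlation beyond
the latent-condition structure, and COVID effects on documentation.
Passing tests therefore demonstrate that the estimators recover known
effects and that inference is calibrated *under independence across
episodes*; they do not validate the clustering scheme against real
facility-level dependence, which is why the full three-way clustering is
retained for the pooled models even though the generator alone would not
require it. Dispersion of the diagnosis count (SD ~5.1) is somewhat below
the emulated study's 6.06 because filler counts are negative-binomial
around a common mean rather than patient-severity driven.

## Monte-Carlo problem sizes

Chosen once, as the package's own desk-scale conditions:

* Recovery suites: 80 replicates of ~12,300 drawn episodes (>=10,000 after
  filters), calibration on 120,000-episode draws at 1% tolerance; 80
  replicates keep the Monte-Carlo error of the mean near 2% of the
  injected effect.
* Null size/coverage suites: 200 replicates; the coverage suite uses
  ~3,000-episode replicates (where the empirical SD of the estimate and
  the mean clustered SE agree to under 1%); the pre-trend size suite uses
  ~9,000-episode replicates so each month cell holds a few hundred
  episodes, keeping the 8-restriction Wald statistic in its calibrated
  regime (with thin month cells the estimated restriction covariance is
  noisy and the test over-rejects — the familiar few-effective-clusters
  problem).
* The default pipeline scale is 50,000 episodes, 60 hospitals, 120 SNFs,
  45 months.

## Known limitations

* The Quan prefix table is the adopted operationalisation of "the
  Elixhauser ICD-10 mapping"; a study's exact internal code lists could
  differ at the margins. The mapping ships as a versioned data file so a
  different dialect can be swapped in.
* The NEDV design identifies *relative* changes in SNF coding; it cannot
  distinguish newly accurate documentation from inflation, and neither can
  the synthetic experiments.
* AME standard errors are not computed (point recovery is the tested
  surface); intervals for condition outcomes come from the
  linear-probability companion fit.
* The CGM combination can be indefinite in small samples; the spectral
  repair guarantees a usable covariance but slightly conservative
  intervals in the repaired directions.
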