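# Methods

This note documents the statistical procedures implemented in `emusurv`,
their assumptions, the defaults that matter, and the design choices made
where the design was genuinely open.

## Estimand and pipeline

The package emulates a two-arm trial protocol on claims data.  The target is
the marginal effect of treatment (endovascular vs open aneurysm repair) on
two time-to-event outcomes measured from the treatment date:

* **short-term (perioperative) mortality** — death during the index
  hospitalization or within 30 days of discharge; survivors are censored at
  discharge + 30 days, and a subject whose overall follow-up ends earlier
  (disenrollment or study end) is censored then, which keeps the short-term
  time bounded by the long-term time for every subject;
* **long-term (all-cause) mortality** — death at any time, censored at
  disenrollment or the administrative study end, whichever is first.

Identification rests on the usual assumptions of IPT weighting: no unmeasured
confounding given the encoded covariates, positivity (every subject has a
non-degenerate probability of either treatment), and correct enough a
propensity model that the weighted pseudo-population is exchangeable.  None
of these are testable from the data; the synthetic generator satisfies them
by construction, which is precisely what makes parameter-recovery tests
meaningful.

## Cohort assembly

Eligibility is applied as an ordered cascade with a conservation-checked log:
unparseable dates; identification (rupture diagnosis + exactly one repair
procedure code set, admission inside the enrollment window); age < 65 at the
index admission (the claim is treated as the diagnosis event); conversion
(both procedure code sets on one claim); concurrent excluded diagnoses;
concurrent excluded procedures (both checked on the index claim only);
< 365 calendar days of enrollment before admission; and first-eligible-claim
per beneficiary (ordered by admission date, ties by file order — stable and
logged).  Missing treatment dates are imputed with the admission date, on the
grounds that a ruptured aneurysm is treated essentially on arrival; the
imputed fraction is reported.

Descriptive (Table-1-style) summaries report count (percentage) per arm for
categoricals — with percentage denominators excluding missing values of that
covariate, which is required to reproduce published race percentages — and
mean (sd) for continuous covariates, with two-sample t-tests and Pearson
chi-squared tests (full contingency table, no continuity correction).
Zero-variance covariates yield an undefined (NaN) p-value rather than an
exception.

## Propensity step

Continuous covariates are z-scored with the population standard deviation;
categoricals are one-hot encoded against the most frequent level; the 20
condition indicators pass through.  The propensity network has one rectifier
hidden layer (default width 16; width 0 gives a logistic-regression-exact
linear model, used as an oracle in tests) and a sigmoid output trained under
binary cross-entropy with mini-batch SGD plus Nesterov momentum
(momentum 0.9, batch 128, 200 epochs with patience-20 early stopping on a
20% validation split).  The learning rate is grid-searched over six
log-spaced values in [0.001, 0.05] by validation cross-entropy, then the
network is refit on all data.

IPT weights are `1/e` (treated) and `1/(1-e)` (untreated) after clipping
scores to `[eps, 1-eps]`, default `eps = 0.01`; `eps = 0` reproduces the
unclipped rule.  Balance is diagnosed with standardized mean differences per
encoded column, weighted and unweighted sharing the pooled *unweighted*
standard deviation as denominator so the two columns are comparable; the
conventional threshold 0.1 is used in tests.

## Weighted survival network

The loss is

    l(theta) = -(1 / sum_i d_i) * sum_i d_i w_i [ g_i - log sum_{j in R_i} exp(g_j) ]

with `R_i = {j : Y_j >= Y_i}` on observed times and Breslow tie handling.
The strict inequality `{j : Y_j > Y_i}` breaks the partial-likelihood
structure (the event subject leaves its own risk set, and the largest event
time has an empty risk set); it is available behind `strict_risk=True` for
the loss value, dropping empty-risk-set terms.  The IPT weight multiplies
only the event contribution; the risk-set sum is unweighted.  The weighted
Cox comparator maximizes the same objective so the zero-hidden-layer network
and the Cox fit share an optimum exactly (verified to 1e-3 relative in tests,
and to machine precision in development).  Consequences worth knowing: the
loss is shift-invariant in g, scales linearly under weight rescaling (same
optimum), and with unit weights is exactly the standard Breslow partial
likelihood.

The default architecture is two rectifier hidden layers of widths (32, 16)
with a linear output.  Optimization is full-batch Adam with a triangular
cyclical learning rate oscillating in [lr/4, lr] with a 20-epoch period, 300
epochs by default; the base rate is grid-searched on a 20% validation split
when not supplied.  Gradients of the loss with respect to g are computed
analytically with cumulative-sum identities (O(n log n) per epoch) and
backpropagated through the network.

Curves: a weighted Breslow baseline puts increment
`(sum of w over events at t) / (sum of w exp(g) over subjects at risk)` at
each distinct event time.  Marginal arm curves use counterfactual
standardization — every subject's treatment input is forced to the arm and
the individual survival functions `exp(-H0(t) exp(g))` are averaged — rather
than plugging in mean covariates, because the marginal estimand is what IPT
weighting targets.  "Expected survival" is the restricted mean survival
time, computed as the exact integral of the right-continuous step curve up
to a horizon (default: the last observed time in the analysis set), which
is the natural reading for step curves and matches the closed-form
geometry of step-function examples.

Per-input effect weights are the product of the layer weight matrices
(biases and activations dropped).  This linearization is cheap and
interpretable but noisy at the single-fit level: different random
initializations of the same data can flip its sign even when the fitted
curves agree, and training longer amplifies whichever direction the
initialization found.  The package therefore treats the bootstrap median
across replicates (below) as the reported effect summary, which is also what
the forest-plot output contains.

## Weighted Cox comparator and proportionality diagnostic

`WeightedCoxPH` maximizes the same outer-weighted Breslow partial likelihood
by Newton-Raphson with step-halving (tolerance 1e-9 on the step and score,
60 iterations max), reporting naive (inverse-information) and robust
sandwich standard errors from weighted score residuals — the sandwich form
is the appropriate one under estimated IPT weights, and both are emitted.

The proportional-hazards diagnostic is the scaled-Schoenfeld trend score
test: per covariate, a linear trend of the weighted Schoenfeld residuals in
the rank of event time; globally, a chi-squared combination with p degrees
of freedom.  Two variance conventions are provided for the per-event
residual covariance: the classic information/d (used for unit weights,
calibrated at ~4-5% empirical size at nominal 5% in simulation) and the
empirical sample covariance of the weighted residuals, which is the default
under non-unit weights because the information-based variance grossly
understates the weighted score variance (near-certain false rejection on
correctly specified data).  Ultra-rare binary covariates (fewer than ~5
carriers) destabilize both the fit and the diagnostic; the pipeline excludes
indicators below that support from the Cox comparator (`drop_degenerate
(min_count=5)`) while the networks still receive all columns.

## Subsample bootstrap

Each of B replicates draws `floor(0.632 n)` subjects uniformly without
replacement (the expected distinct-subject count of with-replacement
resampling, without ties), refits the propensity network, recomputes
weights, refits the survival network, and records accumulated weights and
both arms' curves on a common grid (the distinct event times of the full
cohort).  Hyperparameters are the full-data tuned values, reused rather than
re-tuned per replicate; refitting only the survival step is available as a
clearly non-default fast mode.  Replicate seeds derive deterministically
from a base seed; failed replicates (degenerate subsamples, divergence) are
skipped and counted, and more than 10% failures aborts.  Summaries are
empirical quantiles with the type-7 (linear-interpolation) convention:
median and 25/75% for the weights, 5/95% pointwise for the curves (90%
bands).

## Synthetic claims generator

The generator emulates: covariate marginals matching the pooled descriptive
statistics of the reference cohort (age normal mean 77.3 sd 7.2 truncated to
[65, 105]; 74.2% male; race 91/5.5/3.3%; repair-year distribution drifting
toward the treated arm over 2011-2015; 20 condition prevalences from 0.05%
to 30%); confounded assignment through a logistic model on the encoded scale
whose default coefficients make the treated arm older, sicker and later —
the direction of imbalance in the reference cohort — with ~50% treated
overall; and event times from per-arm Weibull proportional-hazards models
with log-linear covariate effects.

The all-cause event-time model defaults to Weibull shape 0.22, scale 2800
days: the low shape gives the heavy early hazard characteristic of ruptured
aneurysm repair, so the *single* claims-level death process yields ~35%
mortality within the 35-day perioperative window and ~64% all-cause
mortality over the 2011-2019 follow-up — both matching the reference
incidences — with default treatment log-hazard ratio log(0.85).  The
directly simulated short-term outcome is an independent Weibull (shape 0.55,
scale 115, effect log(0.7)) administratively censored at 35 days, used when
an analysis-ready cohort is drawn without the claims layer.  Long-term
censoring combines an exponential loss-to-follow-up hazard (4e-5 per day,
~5% lost) with administrative censoring at the study end; a
`nonproportional()` config variant gives the arms crossing hazards (shapes
1.4 vs 0.7, zero treatment effect) for diagnostic power studies.  Claims
records add admission/discharge dates (Poisson length of stay), a 0/1-day
admission-to-treatment lag (mean 0.53 days), enrollment periods, stand-in
diagnosis/procedure code strings, planted ineligible records for every
exclusion criterion, and exact-count missingness (5.35% blank treatment
dates, 0.2% missing covariates) — all seed-deterministic to the byte.

What the generator does *not* emulate: real ICD-9-CM code semantics,
correlated comorbidity structure (conditions are independent given the
marginals), billing/transfer structure, outpatient settings, competing
risks, or unmeasured confounding.  Passing tests therefore demonstrate that
the pipeline recovers known effects under its stated assumptions, not that
those assumptions hold in any particular real dataset.

## Problem sizes and numerical choices

Test and reproduction runs use cohorts of 300-20,000 subjects (50,000 for
marginal-fidelity checks), 12-50 bootstrap replicates, and 20-200 simulation
seeds per calibration check; the reproduction script defaults to n = 5000
and B = 40.  Risk-set computations subtract the maximum of g before
exponentiation; ties use Breslow handling throughout; quantiles are type-7;
subsample sizes use floor.  Degenerate inputs are handled explicitly:
single-arm inputs, zero-event outcomes, unseen categorical levels and
diverging learning rates raise informative errors; zero-variance covariates
are flagged rather than fatal except in the Cox fit, which refuses constant
columns.

## Known limitations

* The accumulated-weight linearization ignores rectifier gating; single-fit
  values are initialization-noisy (hence bootstrap medians).
* The empirical-variance proportionality test under weighting is mildly
  anti-conservative (~8% at nominal 5% in simulation) and, like any
  residual-trend test, has no power against non-monotone departures.
* The bootstrap quantiles describe variability across subsample refits; no
  theoretical coverage guarantee is claimed for network weights.
* RMST values depend on the horizon, which defaults to the last observed
  time of the analysis set and therefore differs between datasets.
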