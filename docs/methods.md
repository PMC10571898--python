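# Methods

`tdroc` implements a time-dependent (cumulative/dynamic) ROC analysis for a
baseline biomarker measured once, with a right-censored time-to-event
outcome.  The motivating application is late breast fibrosis (grade >=2)
after adjuvant radiotherapy, predicted from the RILA radiosensitivity assay
(radiation-induced CD8 T-lymphocyte apoptosis, in %), alone or combined
with tobacco smoking status and adjuvant hormonotherapy through a Cox
model.  This note records the models, the estimators, the numerical
choices, and what the synthetic cohorts do and do not emulate.

## The cumulative/dynamic framing

At a horizon `t`, a *case* is a subject whose event time `T <= t` and a
*control* is a subject with `T > t`.  For a marker `M` and threshold `c`,

    Se(c, t) = P(M > c | T <= t),      Sp(c, t) = P(M <= c | T > t).

Censoring before `t` leaves a subject's case/control status unknown, so Se
and Sp are identified via the joint survivor function
`S(c, t) = P(M > c, T > t)`:

    Se(c, t) = [P(M > c) - S(c, t)] / [1 - S(t)]
    Sp(c, t) = [S(t) - S(c, t)] / S(t).

Subjects lost to follow-up therefore contribute until their censoring time
instead of being excluded, which is the approach's advantage over a fixed-
window binary ROC.

## Estimators of S(c, t)

**Naive product-limit ("km").**  `S(c, t)` is estimated by an ordinary
Kaplan-Meier among subjects with `M > c`, scaled by the empirical
`P(M > c)`; `S(t)` is the all-subject Kaplan-Meier.  The marginals are not
estimated consistently with the joint, so the implied Se/Sp need not be
monotone in `c` nor stay inside `[0, 1]`, and the estimator is biased under
marker-dependent censoring.  The implementation deliberately returns these
estimates unrepaired, raising `EstimatorWarning` on violations, so the
failure mode remains observable (the test suite constructs a 5-subject
instance with censoring concentrated among high-marker subjects on which
the km specificity is exactly -0.2).

**Nearest-neighbor ("nne", default).**  For each subject, a conditional
survival `S(t | M = m)` is estimated by a Kaplan-Meier restricted to the
neighborhood `{ j : |F(M_j) - F(m)| < span }`, a 0/1 kernel of half-width
`span` on the empirical marker CDF.  Mid-ranks are used for the CDF so tied
marker values share neighborhoods symmetrically.  Averaging
`1{M_i > c} S(t | M_i)` over subjects yields a genuine bivariate survivor
function whose marginals are internally consistent, so Se/Sp are bounded
and valid even under marker-dependent censoring.

Default `span = 0.25 * n**(-0.20)`, the convention that accompanies this
estimator in common practice; it is always recorded in outputs.  A
`minimal_span(n) = 1/(2n)` helper shrinks every neighborhood to tied ranks
only; on censoring-free data this reproduces the classical empirical ROC
*exactly* (machine precision), which is the suite's strongest oracle check.

**Grid and repairs.**  The threshold grid is the set of unique observed
marker values plus `-inf`/`+inf` sentinels; both estimators are step
functions in `c`, so nothing is lost by evaluating there.  NNE output is
clamped to `[0, 1]` and then monotonized along the grid (cumulative-min for
Se, cumulative-max for Sp), a finite-sample repair of neighborhood wiggle;
this sweep can propagate float round-off of order 1e-16, which is why
"exact" comparisons in the tests use a 1e-12 band.  AUC is the trapezoidal
integral of Se over 1-Sp after sorting by the false-positive rate, so
backtracking km curves still integrate over a well-ordered abscissa.

**Youden threshold.**  The cutpoint maximizes `Se + Sp - 1` over finite
grid points; ties break toward higher specificity (the larger threshold),
matching the application's emphasis on correctly clearing low-risk
patients.  Markers carry an orientation flag: RILA is analyzed negated
(low RILA = high risk), and thresholds are reported back on the raw
percentage scale.

## Cox composite marker

The composite score is `exp(b1*(-RILA) + b2*tobacco + b3*HT)` with
coefficients from partial-likelihood maximization (Efron tie handling,
delegated to `lifelines.CoxPHFitter` with tightened convergence:
`precision 1e-9`, `r_precision 1e-12`, up to 500 steps).  The exponential
is retained so thresholds live on the published composite scale; AUC is
invariant to it.  Wald standard errors, 95% CIs and p-values are reported,
as in the source analysis.  Design validation rejects constant covariates
and event-free data; monotone or quasi-monotone likelihood (complete
separation, or a coefficient drifting past magnitude 8 with an exploding
step norm) is flagged as non-convergence rather than raised, since the
likelihood then has no interior maximum.  Complete cases only: patients
missing tobacco or hormonotherapy are excluded from composite analyses and
the exclusion count is logged (RILA-alone analyses use everyone).

A caveat the acceptance suite quantifies: with ~13% events and an 80%
hormonotherapy prevalence, a cohort of 456 leaves only ~4-5 events in the
HT-reference group, and the partial-likelihood MLE of that log hazard
ratio carries a small-sample bias of about +0.17 (it falls to +0.03 when
the cohort is scaled 8x).  This is a property of the estimator at these
study conditions, not of the implementation — single fits agree with an
independent engine to six decimals — and Wald CI coverage remains nominal.

## Performance metrics under censoring

Confusion cells at `t` cannot be counted directly because censored-before-t
subjects have unknown status.  The default **expected** mode allocates all
`n` subjects from the estimated Se/Sp and the Kaplan-Meier prevalence
`p = 1 - S(t)`:

    TP = n p Se,  FN = n p (1-Se),  TN = n (1-p) Sp,  FP = n (1-p) (1-Sp),

which is internally consistent with the time-dependent estimators and
defined at every horizon; PPV/NPV computed from these cells satisfy the
Bayes identities exactly.  A **determinate** mode instead counts only
subjects whose status at `t` is known.  Both are provided because the
convention behind published count-based tables is rarely stated; the two
agree when censoring before `t` is negligible.

`km_survival` (all-subject product-limit with Greenwood variance and a
log-log CI) supplies the prevalence.  A horizon beyond the last observed
time carries the last estimate forward and is flagged.

The expected misclassification cost is
`C = (0*TP + 2*FN + 1*FP - 1*TN) / n` by default: a missed high-risk
patient costs twice a false alarm, and correctly clearing a low-risk
patient is rewarded, because the clinical aim is to treat no-risk patients
at the full irradiation dose.  `C` ranges over `[-1, 2]`; lower is better.
Undefined PPV/NPV (no predicted positives/negatives) is reported as
missing with a warning, never silently 0 or 1.

## Cross-validation

Monte Carlo cross-validation is the headline scheme: 500 unstratified
random splits into 2/3 training and 1/3 validation.  Per split and horizon,
the training set supplies the Cox coefficients (composite marker) and the
Youden threshold; the validation set is scored with those trained
quantities — its own ROC curve gives AUC, the trained threshold is read off
the validation step functions for Se/Sp, and the validation Kaplan-Meier
prevalence feeds the expected confusion matrix.  Metrics are averaged over
valid splits; the reported "threshold" row is the mean of per-split trained
thresholds and is labelled as such.  Validation splits with no events by a
horizon, and training refits that fail or quasi-separate, are skipped *and
counted* rather than redrawn, keeping the split distribution honest (at the
default study conditions roughly 5-10% of composite-marker splits skip
this way).  Each split draws from its own stream derived from (seed, split
index), so results are reproducible and independent of the horizon list.

K-fold (K=5) behaves identically with folds as validation sets.
Leave-one-out cannot form a per-fold ROC from one subject, so out-of-fold
predictions are pooled into a single marker vector and evaluated once,
with the Youden threshold taken on the pooled curve; this is a necessary
deviation and is reported as such.

## Synthetic cohorts

The generator emulates the statistical anatomy of the motivating trial
(n=456, 61 events by 50 months):

- RILA ~ Gamma(shape 2.524, scale 6.591), clipped to [0, 100]: median
  14.5% and 99th percentile 50%, matching the published medians and ranges;
  the true distributional form is unpublished.
- tobacco ~ Bernoulli(0.35), hormonotherapy ~ Bernoulli(0.80): prevalences
  are unpublished; these are plausible values for an adjuvant
  breast-cancer cohort and are configurable.
- Event times from a Weibull proportional-hazards model, shape 1.3 (mildly
  increasing hazard, as late fibrosis accrues over years), coefficients
  (0.04, 0.44, 1.15) on (-RILA, tobacco, HT) — the published multivariate
  estimates — via closed-form inversion sampling.
- Censoring: administrative Uniform(36, 50) months (end-of-study visits
  scatter up to ~50 months) plus 5% early dropout Uniform(0, 36].
- The Weibull scale default (289.0) was frozen once from
  `calibrate_baseline`: bisection on the scale until a 100,000-subject
  simulation reproduces the 61/456 observed-event fraction by 50 months
  within +/-0.005.

Not emulated: visit-grid assessment times (times are continuous),
competing risks (deaths/recurrences are plain censoring, as in the source
analysis), longitudinal RILA measurements, between-center heterogeneity,
and any real marker-censoring dependence.  Passing tests therefore
demonstrate correctness of the estimators and procedure under a faithful
proportional-hazards world, not the trial's actual numbers — the trial
data are confidential, and its printed AUCs cannot be reproduced from any
synthetic cohort.

## Numerical conventions and degenerate inputs

- Ties between an event and a censoring time rank the event first.
- A horizon with no cases (or no survivors) raises a named error rather
  than returning NaN; cross-validation converts these into counted skips.
- A constant marker yields the diagonal curve, AUC 0.5, Youden 0 with a
  warning, and the specificity-maximal endpoint as cutpoint.
- Reports print three decimals; hazard ratios two.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; a config plus seed reproduces any artifact
  byte-for-byte (the CLI writes both into a manifest).

## Problem sizes used by the checks

The statistical suites run at deliberately chosen sizes: estimator-oracle
agreement on 100 instances of n <= 50; null-marker calibration on 50
cohorts of n = 2000 (~20% censored); parameter recovery on 200 cohorts of
n = 456; the full Monte Carlo procedure at its native 500 splits of an
n = 456 cohort.  These match the sizes of the procedures they validate
while keeping the whole suite in the minutes range on one CPU.
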