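# tdroc

Time-dependent ROC analysis for right-censored biomarker data.

## The problem

A baseline biomarker is measured once; the outcome it should predict — here
grade >=2 late breast fibrosis after adjuvant radiotherapy — develops over
years, and follow-up ends at different times for different patients.  A
standard ROC analysis at a fixed window must discard every patient censored
before the window closes.  The *cumulative/dynamic* time-dependent ROC
framework keeps everyone: at a horizon `t`, cases are patients with event
time `T <= t` and controls are patients with `T > t`, and

```
Se(c, t) = P(M > c | T <= t)        Sp(c, t) = P(M <= c | T > t)
```

are estimated through the joint survivor function `S(c, t) = P(M > c, T > t)`
so that censored patients contribute up to their censoring time.

`tdroc` implements the full analysis pipeline around this idea, for
biostatisticians evaluating prognostic markers under right censoring:

- **Estimators** — the naive Kaplan-Meier estimator of `S(c, t)` (kept
  unrepaired so its known defects stay visible) and the nearest-neighbor
  estimator (0/1 kernel of half-width `span` on the marker's empirical CDF),
  which guarantees bounded, monotone Se/Sp even under marker-dependent
  censoring.  Default span `0.25 n^-0.20`.
- **Summaries per horizon** — ROC curve, trapezoidal AUC, Youden-optimal
  threshold (`max Se + Sp - 1`), censoring-aware confusion matrix from the
  Kaplan-Meier prevalence, PPV/NPV, and an expected misclassification cost
  `C = (2 FN + FP - TN)/N` that rewards correctly cleared low-risk patients.
- **Composite marker** — a Cox proportional-hazards score
  `exp(b1 (-RILA) + b2 tobacco + b3 HT)` fitted by partial likelihood
  (Efron ties), so several baseline factors act as one scalar marker.
- **Cross-validation** — Monte Carlo (500 random 2/3-1/3 splits with
  threshold and coefficient transfer), K-fold (K=5) and leave-one-out.
- **Synthetic cohorts** — a Weibull proportional-hazards generator
  calibrated to the motivating trial's anatomy (n=456, ~13% events by 50
  months, gamma-distributed RILA), since the original clinical dataset is
  confidential.

## Worked example

```python
from tdroc import (SimulationConfig, generate_cohort, fit_cox,
                   composite_score, evaluate_marker, negate_marker)

cohort = generate_cohort(SimulationConfig(seed=7))   # 456 patients, 67 events
fit = fit_cox(cohort)                                # -RILA, tobacco, HT
print(fit.summary_frame().to_string(index=False))

marker, sub = composite_score(fit, cohort)           # exp(beta . Z), complete cases
report = evaluate_marker(sub, marker, [12, 24, 36, 50])
print(report.round().to_string(index=False))
```

prints

```
                                     variable  coefficient   hr  hr_ci_lower  hr_ci_upper  p_value
                         Baseline RILA (x -1)         0.03 1.03         1.00         1.06    0.075
Tobacco smoking status (active/former vs. no)         0.61 1.84         1.14         2.98    0.012
              Adjuvant HT status (yes vs. no)         0.15 1.16         0.62         2.17    0.634
 time  threshold  threshold_original   auc    se    sp   ppv   npv   cost
   12      0.772               0.772 0.540 0.818 0.277 0.030 0.982  0.445
   24      1.569               1.569 0.575 0.283 0.867 0.129 0.946 -0.594
   36      1.025               1.025 0.642 0.564 0.669 0.202 0.912 -0.181
   50      0.896               0.896 0.620 0.691 0.520 0.225 0.893  0.070
```

The Cox table reads as hazard ratios with Wald 95% CIs: in this simulated
cohort a one-point drop in RILA multiplies the fibrosis hazard by 1.03, and
smoking by 1.84.  Each performance row is one horizon: `threshold` is the
Youden-optimal cutoff on the composite scale, `auc` the time-dependent AUC
(0.5 = uninformative, 1 = perfect), and `cost` the expected
misclassification cost (lower is better; -1 would mean everyone is a
correctly cleared true negative).  With ~13% prevalence, NPV is high and
PPV low at every horizon, as expected for a rule-out marker.  For the assay
alone, `evaluate_marker(cohort, negate_marker(cohort.rila), ...)` reports
thresholds back on the raw RILA % scale via `threshold_original`.

The same pipeline runs from the shell:

```
tdroc simulate --n 456 --seed 7 --out run/
tdroc fit      --cohort run/cohort.csv --out run/cox
tdroc evaluate --cohort run/cohort.csv --marker composite --out run/eval
tdroc crossval --cohort run/cohort.csv --marker rila --repeats 500 --out run/cv
tdroc pipeline --seed 7 --out run/all     # everything, with manifests
```

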