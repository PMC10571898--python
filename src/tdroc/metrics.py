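"""Censoring-aware confusion matrices, PPV/NPV, misclassification cost, and
per-horizon performance reports.

Under right censoring the fibrosis status at a horizon t is unknown for
subjects censored before t, so confusion-matrix cells cannot simply be
counted.  The default ``expected`` mode allocates all n subjects from the
estimated Se/Sp and the Kaplan-Meier prevalence p = 1 - S(t):

    TP = n p Se,   FN = n p (1 - Se),   TN = n (1-p) Sp,   FP = n (1-p) (1-Sp)

which is consistent with the time-dependent estimators and defined at every
horizon.  A ``determinate`` mode instead counts only subjects whose status
at t is known (events by t, or still under follow-up after t).

The expected misclassification cost is a weighted mean of the cells,

    C = (w_tp TP + w_fn FN + w_fp FP + w_tn TN) / n,

with default weights (0, 2, 1, -1): missing a high-risk patient (FN) costs
twice a false alarm, and correctly clearing a low-risk patient (TN) is
rewarded, reflecting the clinical goal of treating no-risk patients at the
full irradiation dose.  Lower cost is better.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .cohort import Cohort, MarkerSeries
from .estimators import RocCurve, time_dependent_roc, youden_threshold

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CostMatrix:
    """Misclassification weights (order: TP, FN, FP, TN)."""

    w_tp: float = 0.0
    w_fn: float = 2.0
    w_fp: float = 1.0
    w_tn: float = -1.0

    def __post_init__(self) -> None:
        for name in ("w_tp", "w_fn", "w_fp", "w_tn"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if (self.w_tp, self.w_fn, self.w_fp, self.w_tn) != (0.0, 2.0, 1.0, -1.0):
            logger.info("non-default cost matrix in use: %s", self)


@dataclass(frozen=True)
class ConfusionAtTime:
    """Confusion-matrix cells at a horizon (expected counts, possibly
    fractional).  In ``expected`` mode the cells sum to n; in
    ``determinate`` mode subjects of unknown status are left out."""

    tp: float
    fn: float
    fp: float
    tn: float
    n: int
    horizon: float
    mode: str = "expected"

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            if getattr(self, name) < -1e-9:
                raise ValueError(f"{name} must be nonnegative")
        total = self.tp + self.fn + self.fp + self.tn
        if self.mode == "expected" and abs(total - self.n) > 1e-6 * max(self.n, 1):
            raise ValueError(f"expected-mode cells sum to {total}, not n={self.n}")
        if total > self.n * (1 + 1e-9):
            raise ValueError(f"cells sum to {total} > n={self.n}")


@dataclass(frozen=True)
class KMEstimate:
    """Kaplan-Meier survival at a horizon with a log-log 95% CI."""

    horizon: float
    survival: float
    ci_lower: float
    ci_upper: float
    #: True when the horizon lies beyond the last observed time
    extrapolated: bool = False


def km_survival(cohort: Cohort, horizon: float) -> KMEstimate:
    """Product-limit fibrosis-free survival at `horizon` with Greenwood
    variance and a log-log (exponential Greenwood) 95% CI.

    Beyond the last observed time the last estimate is carried forward and
    flagged as extrapolated.
    """
    kmf = KaplanMeierFitter()
    kmf.fit(cohort.times, cohort.events)
    last_time = float(cohort.times.max())
    extrapolated = horizon > last_time
    at = min(horizon, last_time)
    surv = float(kmf.predict(at))
    ci = kmf.confidence_interval_survival_function_
    idx = ci.index.to_numpy()
    pos = int(np.searchsorted(idx, at, side="right")) - 1
    lo, hi = (float(ci.iloc[pos, 0]), float(ci.iloc[pos, 1])) if pos >= 0 else (1.0, 1.0)
    if extrapolated:
        logger.info("km_survival: horizon %g beyond last observed time %g; "
                    "carrying the last estimate forward", horizon, last_time)
    return KMEstimate(horizon=horizon, survival=surv, ci_lower=min(lo, hi),
                      ci_upper=max(lo, hi), extrapolated=extrapolated)


def expected_confusion(
    se: float, sp: float, survival_at_t: float, n: int, horizon: float
) -> ConfusionAtTime:
    """Allocate all n subjects to confusion cells from Se/Sp and the KM
    prevalence p = 1 - S(t)."""
    for name, v in (("se", se), ("sp", sp), ("survival_at_t", survival_at_t)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    p = 1.0 - survival_at_t
    return ConfusionAtTime(
        tp=n * p * se,
        fn=n * p * (1.0 - se),
        tn=n * (1.0 - p) * sp,
        fp=n * (1.0 - p) * (1.0 - sp),
        n=n,
        horizon=horizon,
        mode="expected",
    )


def determinate_confusion(
    marker: MarkerSeries, cohort: Cohort, threshold: float, horizon: float
) -> ConfusionAtTime:
    """Count only subjects whose status at the horizon is determinate:
    events by t are cases; subjects observed beyond t are controls;
    subjects censored before t without an event are left out."""
    times, events, m = cohort.times, cohort.events, marker.values
    case = (events == 1) & (times <= horizon)
    control = times > horizon
    positive = m > threshold
    return ConfusionAtTime(
        tp=float(np.sum(case & positive)),
        fn=float(np.sum(case & ~positive)),
        fp=float(np.sum(control & positive)),
        tn=float(np.sum(control & ~positive)),
        n=cohort.n,
        horizon=horizon,
        mode="determinate",
    )


def ppv_npv(conf: ConfusionAtTime) -> tuple[Optional[float], Optional[float]]:
    """PPV = TP/(TP+FP), NPV = TN/(TN+FN).

    A zero denominator (no predicted positives or negatives) yields ``None``
    with a warning — never a silent 0 or 1.
    """
    ppv: Optional[float]
    npv: Optional[float]
    if conf.tp + conf.fp > 0:
        ppv = conf.tp / (conf.tp + conf.fp)
    else:
        warnings.warn(f"no predicted positives at horizon {conf.horizon}; PPV undefined",
                      UserWarning, stacklevel=2)
        ppv = None
    if conf.tn + conf.fn > 0:
        npv = conf.tn / (conf.tn + conf.fn)
    else:
        warnings.warn(f"no predicted negatives at horizon {conf.horizon}; NPV undefined",
                      UserWarning, stacklevel=2)
        npv = None
    return ppv, npv


def misclassification_cost(conf: ConfusionAtTime, weights: CostMatrix = CostMatrix()) -> float:
    """Expected cost C = (w_tp TP + w_fn FN + w_fp FP + w_tn TN) / n."""
    if conf.n < 1:
        raise ValueError("confusion matrix has n < 1")
    return float(
        (weights.w_tp * conf.tp + weights.w_fn * conf.fn
         + weights.w_fp * conf.fp + weights.w_tn * conf.tn) / conf.n
    )


@dataclass(frozen=True)
class PerformanceReport:
    """Per-horizon marker performance (one row per horizon).

    Columns: time, threshold (analysis scale), threshold_original
    (raw marker scale), auc, se, sp, ppv, npv, cost.
    """

    rows: pd.DataFrame
    estimator: str
    span: Optional[float]
    marker_label: str
    weights: CostMatrix = field(default_factory=CostMatrix)

    def round(self, decimals: int = 3) -> pd.DataFrame:
        out = self.rows.copy()
        num = out.select_dtypes("number").columns
        out[num] = out[num].round(decimals)
        return out


def evaluate_marker(
    cohort: Cohort,
    marker: MarkerSeries,
    horizons: Sequence[float],
    estimator: str = "nne",
    span: Optional[float] = None,
    weights: CostMatrix = CostMatrix(),
    mode: str = "expected",
) -> PerformanceReport:
    """Full per-horizon evaluation of a marker on one cohort.

    For each horizon: ROC curve and AUC, Youden-optimal threshold, Se/Sp at
    the threshold, confusion matrix (``expected`` from KM prevalence by
    default, or ``determinate``), PPV/NPV, and expected cost.
    """
    if mode not in ("expected", "determinate"):
        raise ValueError(f"mode must be 'expected' or 'determinate', got {mode!r}")
    records = []
    for t in horizons:
        curve = time_dependent_roc(marker, cohort, t, estimator=estimator, span=span)
        cut = youden_threshold(curve, marker)
        if mode == "expected":
            km = km_survival(cohort, t)
            conf = expected_confusion(cut.se_at, cut.sp_at, km.survival, cohort.n, t)
        else:
            conf = determinate_confusion(marker, cohort, cut.threshold_marker_scale, t)
        ppv, npv = ppv_npv(conf)
        cost = misclassification_cost(conf, weights)
        records.append(
            {
                "time": t,
                "threshold": cut.threshold_marker_scale,
                "threshold_original": cut.threshold_original_scale,
                "auc": curve.auc,
                "se": cut.se_at,
                "sp": cut.sp_at,
                "ppv": np.nan if ppv is None else ppv,
                "npv": np.nan if npv is None else npv,
                "cost": cost,
            }
        )
    used_span = span
    if estimator == "nne" and span is None:
        from .estimators import default_span

        used_span = default_span(cohort.n)
    return PerformanceReport(
        rows=pd.DataFrame.from_records(records),
        estimator=estimator,
        span=used_span,
        marker_label=marker.label,
        weights=weights,
    )
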