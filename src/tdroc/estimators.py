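"""Time-dependent sensitivity/specificity, ROC curves, AUC and Youden cutpoints.

Cumulative/dynamic definition: at horizon t, cases are subjects whose event
time T <= t and controls are subjects with T > t, so for a threshold c

    Se(c, t) = P(M > c | T <= t)
    Sp(c, t) = P(M <= c | T > t).

Under right censoring these are identified through the joint survivor
function S(c, t) = P(M > c, T > t):

    Se(c, t) = [P(M > c) - S(c, t)] / [1 - S(t)]
    Sp(c, t) = [S(t) - S(c, t)] / S(t).

Two estimators of S(c, t) are provided:

* ``km`` — the naive product-limit estimator: a Kaplan-Meier curve among
  subjects with M > c, scaled by the empirical P(M > c).  It is simple but
  does not guarantee Se and Sp to be monotone or bounded in [0, 1], and it
  breaks down under marker-dependent censoring.  Outputs are returned
  unrepaired, with warnings, so the failure mode stays visible.
* ``nne`` — the nearest-neighbor estimator: a weighted Kaplan-Meier within a
  sliding neighborhood of the marker's empirical CDF (0/1 kernel of
  half-width ``span``) gives a conditional survival S(t | M = m); averaging
  1{M_i > c} * S(t | M_i) over subjects yields a proper bivariate survivor
  function.  Se/Sp are clamped to [0, 1] and monotonized along the
  threshold grid.

With a span small enough that each neighborhood holds only tied-rank
subjects and no censoring, the NNE reduces exactly to the classical
empirical ROC at the horizon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import rankdata

from .cohort import Cohort, MarkerSeries


class EstimatorWarning(UserWarning):
    """Emitted when the KM estimator leaves [0, 1] or loses monotonicity."""


def default_span(n: int) -> float:
    """Neighborhood half-width 0.25 * n**(-0.20), the usual NNE default."""
    return 0.25 * n ** (-0.20)


def minimal_span(n: int) -> float:
    """Span so small each neighborhood holds only tied-rank subjects."""
    return 0.5 / n


def _km_at(times: np.ndarray, events: np.ndarray, horizon: float) -> float:
    """Product-limit survival at `horizon` (unit weights).

    Beyond the last observed time the last value is carried forward.
    """
    et = times[(events == 1) & (times <= horizon)]
    if et.size == 0:
        return 1.0
    event_times, deaths = np.unique(et, return_counts=True)
    order = np.sort(times)
    at_risk = times.size - np.searchsorted(order, event_times, side="left")
    return float(np.prod(1.0 - deaths / at_risk))


@dataclass(frozen=True)
class JointSurvival:
    """Estimated joint survivor S(c, t) on the grid of observed markers.

    ``thresholds`` are the ascending unique marker values; ``s_joint[k]``
    estimates P(M > thresholds[k], T > horizon); ``p_gt[k]`` is the
    empirical P(M > thresholds[k]); ``s_marginal`` estimates S(horizon).
    """

    horizon: float
    thresholds: np.ndarray
    s_joint: np.ndarray
    p_gt: np.ndarray
    s_marginal: float
    estimator: str
    n: int
    span: Optional[float] = None
    #: per-subject conditional survival S(t | M_i) (NNE only), cohort order
    cond_surv: Optional[np.ndarray] = None
    marker: Optional[MarkerSeries] = None

    def se_sp(self) -> tuple[np.ndarray, np.ndarray]:
        """Se(c, t) and Sp(c, t) on the threshold grid (raw, unrepaired)."""
        prevalence = 1.0 - self.s_marginal
        if prevalence <= 0:
            raise ValueError(f"no cases by horizon {self.horizon}: sensitivity undefined")
        if self.s_marginal <= 0:
            raise ValueError(f"no survivors at horizon {self.horizon}: specificity undefined")
        se = (self.p_gt - self.s_joint) / prevalence
        sp = (self.s_marginal - self.s_joint) / self.s_marginal
        return se, sp

    def se_sp_at(self, c: float) -> tuple[float, float]:
        """Se/Sp at an arbitrary threshold c (step-function evaluation).

        Both are right-continuous step functions of c with jumps at the
        observed marker values, so the value at c equals the value at the
        largest grid threshold <= c (or the (1, 0) endpoint below the grid).
        """
        se, sp = self.se_sp()
        k = int(np.searchsorted(self.thresholds, c, side="right")) - 1
        if k < 0:
            return 1.0, 0.0
        if self.estimator == "nne":
            se = np.minimum.accumulate(np.clip(se, 0.0, 1.0))
            sp = np.maximum.accumulate(np.clip(sp, 0.0, 1.0))
        return float(se[k]), float(sp[k])


def km_joint_survival(marker: MarkerSeries, cohort: Cohort, horizon: float) -> JointSurvival:
    """Naive product-limit estimator of S(c, t).

    For each threshold c, S(c, t) = P_hat(M > c) * KM_{M > c}(t); the
    marginal S(t) is the all-subject Kaplan-Meier.  No bounding or
    monotonicity repair is applied (the estimator's documented drawback).
    """
    _check_inputs(marker, cohort)
    times, events, m = cohort.times, cohort.events, marker.values
    thresholds = np.unique(m)
    n = cohort.n
    s_marg = _km_at(times, events, horizon)
    s_joint = np.empty_like(thresholds)
    p_gt = np.empty_like(thresholds)
    for k, c in enumerate(thresholds):
        above = m > c
        p_gt[k] = above.mean()
        s_joint[k] = 0.0 if not above.any() else p_gt[k] * _km_at(times[above], events[above], horizon)
    return JointSurvival(
        horizon=horizon, thresholds=thresholds, s_joint=s_joint, p_gt=p_gt,
        s_marginal=s_marg, estimator="km", n=n, marker=marker,
    )


def nne_joint_survival(
    marker: MarkerSeries, cohort: Cohort, horizon: float, span: Optional[float] = None
) -> JointSurvival:
    """Nearest-neighbor estimator of S(c, t).

    A conditional survival S(t | M_i) is computed for every subject by a
    Kaplan-Meier restricted to the neighborhood
    { j : |F_hat(M_j) - F_hat(M_i)| < span } (0/1 kernel on the mid-rank
    empirical CDF, so tied markers share neighborhoods symmetrically), and

        S(c, t) = (1/n) * sum_i 1{M_i > c} * S(t | M_i),
        S(t)    = S(-inf, t) = (1/n) * sum_i S(t | M_i).

    Averaging conditional survivals keeps S(c, t) a genuine bivariate
    survivor function, so Se/Sp are bounded and (after the grid sweep in
    :func:`roc_curve`) monotone, even under marker-dependent censoring.
    """
    _check_inputs(marker, cohort)
    n = cohort.n
    if span is None:
        span = default_span(n)
    if not 0.0 < span < 0.5:
        raise ValueError(f"span must lie in (0, 0.5), got {span}")
    times, events, m = cohort.times, cohort.events, marker.values

    cdf = rankdata(m, method="average") / n  # mid-rank empirical CDF
    order = np.argsort(cdf, kind="stable")
    cdf_sorted = cdf[order]
    t_sorted = times[order]
    e_sorted = events[order]

    # conditional survival per subject; tied-CDF subjects share a window,
    # so compute once per unique CDF value
    uniq_cdf, inverse = np.unique(cdf_sorted, return_inverse=True)
    cond_uniq = np.empty(len(uniq_cdf))
    for u, fval in enumerate(uniq_cdf):
        lo = int(np.searchsorted(cdf_sorted, fval - span, side="right"))
        hi = int(np.searchsorted(cdf_sorted, fval + span, side="left"))
        if hi <= lo:  # unreachable: own CDF value is inside the open window
            raise AssertionError("empty NNE neighborhood")
        cond_uniq[u] = _km_at(t_sorted[lo:hi], e_sorted[lo:hi], horizon)
    cond_sorted = cond_uniq[inverse]
    cond = np.empty(n)
    cond[order] = cond_sorted

    thresholds = np.unique(m)
    s_marg = float(cond.mean())
    # sort subjects by marker once; S(c,t) is a suffix mean of cond survs
    m_order = np.argsort(m, kind="stable")
    m_sorted = m[m_order]
    cond_by_m = cond[m_order]
    suffix = np.concatenate([np.cumsum(cond_by_m[::-1])[::-1], [0.0]])
    idx = np.searchsorted(m_sorted, thresholds, side="right")
    s_joint = suffix[idx] / n
    p_gt = (n - idx) / n
    return JointSurvival(
        horizon=horizon, thresholds=thresholds, s_joint=s_joint, p_gt=p_gt,
        s_marginal=s_marg, estimator="nne", n=n, span=span, cond_surv=cond,
        marker=marker,
    )


def _check_inputs(marker: MarkerSeries, cohort: Cohort) -> None:
    if len(marker) != cohort.n:
        raise ValueError(f"marker length {len(marker)} != cohort size {cohort.n}")


@dataclass(frozen=True)
class RocCurve:
    """Time-dependent ROC curve at one horizon.

    Points are ordered by ascending threshold; the grid carries -inf/+inf
    sentinels so the curve runs from (1-Sp, Se) = (1, 1) down to (0, 0).
    For the NNE estimator Se/Sp are clamped to [0, 1] and monotone in the
    threshold; KM output is reported as-is (warnings flag violations).
    """

    horizon: float
    thresholds: np.ndarray
    se: np.ndarray
    sp: np.ndarray
    auc: float
    estimator: str
    n: int
    span: Optional[float] = None
    n_cases: float = 0.0
    n_controls: float = 0.0
    marker: Optional[MarkerSeries] = None

    @property
    def fpr(self) -> np.ndarray:
        return 1.0 - self.sp

    def at_threshold(self, c: float) -> tuple[float, float]:
        """(Se, Sp) of the step curve at an arbitrary threshold c."""
        k = int(np.searchsorted(self.thresholds[1:-1], c, side="right"))
        return float(self.se[k]), float(self.sp[k])

    def plot(self, ax=None, **kwargs):
        """Draw the curve (Se against 1-Sp) on a matplotlib axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        order = np.argsort(self.fpr, kind="stable")
        label = kwargs.pop("label", f"t={self.horizon:g} ({self.estimator}, AUC={self.auc:.3f})")
        ax.plot(self.fpr[order], self.se[order], label=label, **kwargs)
        ax.plot([0, 1], [0, 1], ls=":", color="grey", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend()
        return ax


@dataclass(frozen=True)
class ThresholdResult:
    """Youden-optimal cutpoint with Se/Sp at the cut.

    ``threshold_original_scale`` undoes marker negation so RILA cutpoints
    read as percentages.
    """

    threshold_marker_scale: float
    threshold_original_scale: float
    youden: float
    se_at: float
    sp_at: float


def roc_curve(joint: JointSurvival) -> RocCurve:
    """Assemble the ROC curve from a joint-survivor estimate.

    NNE output is clamped to [0, 1], then made monotone along the ascending
    threshold grid (cumulative-min for Se, cumulative-max for Sp) — a
    finite-sample repair of neighborhood wiggle.  KM output is passed
    through unrepaired; violations raise :class:`EstimatorWarning`.
    """
    se, sp = joint.se_sp()
    if joint.estimator == "nne":
        se = np.minimum.accumulate(np.clip(se, 0.0, 1.0))
        sp = np.maximum.accumulate(np.clip(sp, 0.0, 1.0))
    else:
        if (se < -1e-12).any() or (se > 1 + 1e-12).any() or (sp < -1e-12).any() or (sp > 1 + 1e-12).any():
            warnings.warn(
                f"KM estimator produced Se/Sp outside [0, 1] at horizon {joint.horizon} "
                "(possible marker-dependent censoring); values returned unclamped",
                EstimatorWarning, stacklevel=2,
            )
        if (np.diff(se) > 1e-12).any() or (np.diff(sp) < -1e-12).any():
            warnings.warn(
                f"KM estimator produced non-monotone Se/Sp at horizon {joint.horizon}; "
                "values returned unrepaired",
                EstimatorWarning, stacklevel=2,
            )
    thresholds = np.concatenate([[-np.inf], joint.thresholds, [np.inf]])
    se_full = np.concatenate([[1.0], se, [0.0]])
    sp_full = np.concatenate([[0.0], sp, [1.0]])
    prevalence = 1.0 - joint.s_marginal
    curve = RocCurve(
        horizon=joint.horizon,
        thresholds=thresholds,
        se=se_full,
        sp=sp_full,
        auc=np.nan,
        estimator=joint.estimator,
        n=joint.n,
        span=joint.span,
        n_cases=joint.n * prevalence,
        n_controls=joint.n * joint.s_marginal,
        marker=joint.marker,
    )
    return RocCurve(**{**curve.__dict__, "auc": auc_trapezoid(curve)})


def auc_trapezoid(curve: RocCurve) -> float:
    """Area under Se vs (1 - Sp) by the trapezoidal rule.

    Points are sorted by ascending false-positive rate (Se breaking ties)
    before integration, so KM curves that backtrack still integrate over a
    well-ordered abscissa.
    """
    if len(curve.se) < 2:
        raise ValueError("need at least two curve points")
    order = np.lexsort((curve.se, curve.fpr))
    x = curve.fpr[order]
    y = curve.se[order]
    return float(np.trapezoid(y, x))


def youden_threshold(curve: RocCurve, marker: Optional[MarkerSeries] = None) -> ThresholdResult:
    """Cutpoint maximizing Youden's index Se + Sp - 1 over the finite grid.

    Ties are broken toward the threshold with the higher Sp (the largest
    tying threshold).  If no finite threshold beats the trivial endpoints
    (e.g. a constant marker), the Sp-maximal endpoint is returned with a
    Youden index of 0 and a warning.
    """
    finite = np.isfinite(curve.thresholds)
    youden = curve.se + curve.sp - 1.0
    y_fin = youden[finite]
    t_fin = curve.thresholds[finite]
    sp_fin = curve.sp[finite]
    if len(y_fin) == 0 or np.max(y_fin) <= 0:
        warnings.warn("degenerate ROC curve: Youden index is 0 everywhere", UserWarning,
                      stacklevel=2)
        best_t = t_fin[-1] if len(t_fin) else np.inf
        se_at, sp_at = (curve.se[finite][-1], sp_fin[-1]) if len(t_fin) else (0.0, 1.0)
        result_youden = float(se_at + sp_at - 1.0)
    else:
        y_max = np.max(y_fin)
        tied = np.flatnonzero(np.abs(y_fin - y_max) <= 1e-12)
        best = tied[np.argmax(sp_fin[tied])]
        best_t = float(t_fin[best])
        se_at = float(curve.se[finite][best])
        sp_at = float(sp_fin[best])
        result_youden = float(se_at + sp_at - 1.0)
    ref = marker if marker is not None else curve.marker
    original = ref.to_original_scale(best_t) if ref is not None else best_t
    return ThresholdResult(
        threshold_marker_scale=float(best_t),
        threshold_original_scale=float(original),
        youden=result_youden,
        se_at=se_at,
        sp_at=sp_at,
    )


def time_dependent_roc(
    marker: MarkerSeries,
    cohort: Cohort,
    horizon: float,
    estimator: str = "nne",
    span: Optional[float] = None,
) -> RocCurve:
    """One-call ROC curve at a horizon with either estimator."""
    if estimator == "nne":
        joint = nne_joint_survival(marker, cohort, horizon, span=span)
    elif estimator == "km":
        joint = km_joint_survival(marker, cohort, horizon)
    else:
        raise ValueError(f"estimator must be 'nne' or 'km', got {estimator!r}")
    return roc_curve(joint)
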