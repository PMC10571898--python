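"""Cox proportional-hazards fitting and the composite-score marker.

The composite marker combines baseline RILA (negated so that larger values
mean higher risk), tobacco smoking status and adjuvant hormonotherapy into
a single scalar risk score

    score_i = exp(b1 * (-RILA_i) + b2 * tobacco_i + b3 * ht_i)

with coefficients estimated by partial-likelihood maximization (Efron tie
handling).  The exponential is retained so that reported thresholds live on
the same scale as the published composite-marker cutoffs; because exp is
strictly increasing, ROC curves and AUCs are identical either way.

Fitting is delegated to :class:`lifelines.CoxPHFitter`; this module adds
design validation (constant covariates, monotone-likelihood detection),
complete-case handling and a compact summary container.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning

from .cohort import Cohort, MarkerSeries

logger = logging.getLogger(__name__)

#: default design: negated RILA plus the two binary cofactors
DEFAULT_COVARIATES = ("rila_neg", "tobacco", "ht")

COVARIATE_DISPLAY = {
    "rila_neg": "Baseline RILA (x -1)",
    "tobacco": "Tobacco smoking status (active/former vs. no)",
    "ht": "Adjuvant HT status (yes vs. no)",
}


class DegenerateDesignError(ValueError):
    """Raised when the design matrix cannot identify the coefficients."""


@dataclass(frozen=True)
class CoxFit:
    """Result of a proportional-hazards fit.

    ``hr`` is ``exp(coefficients)`` elementwise with Wald 95% confidence
    intervals; ``converged`` is False under monotone likelihood (perfect
    separation), in which case ``diagnostic`` explains why.
    """

    coefficients: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    hr_ci_lower: np.ndarray
    hr_ci_upper: np.ndarray
    p_values: np.ndarray
    loglik: float
    loglik_null: float
    converged: bool
    tie_method: str
    covariate_labels: tuple[str, ...]
    n_used: int
    n_events: int
    n_excluded: int
    diagnostic: str = ""

    def summary_frame(self) -> pd.DataFrame:
        """Coefficient / HR [95% CI] / p table (2-decimal HRs, Wald p)."""
        return pd.DataFrame(
            {
                "variable": [COVARIATE_DISPLAY.get(c, c) for c in self.covariate_labels],
                "coefficient": np.round(self.coefficients, 2),
                "hr": np.round(self.hr, 2),
                "hr_ci_lower": np.round(self.hr_ci_lower, 2),
                "hr_ci_upper": np.round(self.hr_ci_upper, 2),
                "p_value": np.round(self.p_values, 3),
            }
        )


def hr_from_coef(coefficient: float) -> float:
    """Hazard ratio for a log hazard-ratio coefficient: ``exp(coef)``."""
    return float(np.exp(coefficient))


def design_frame(cohort: Cohort, covariates: Sequence[str] = DEFAULT_COVARIATES) -> pd.DataFrame:
    """Design matrix plus time/event columns, complete cases only.

    ``rila_neg`` is the negated RILA column; other names are looked up as
    patient fields.
    """
    cols: dict[str, np.ndarray] = {}
    for cov in covariates:
        if cov == "rila_neg":
            cols[cov] = -cohort.rila
        else:
            cols[cov] = cohort.covariate(cov)
    df = pd.DataFrame(cols)
    df["time"] = cohort.times
    df["event"] = cohort.events
    complete = df.dropna()
    n_excluded = len(df) - len(complete)
    if n_excluded:
        logger.info("fit_cox: excluded %d of %d patients with missing covariates",
                    n_excluded, len(df))
    return complete


def fit_cox(
    cohort: Cohort,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    tie_method: str = "efron",
) -> CoxFit:
    """Maximize the Cox partial likelihood on the cohort's complete cases.

    Raises
    ------
    DegenerateDesignError
        If a covariate is constant (flat likelihood direction) or there are
        no events.
    ValueError
        For an unsupported tie-handling method.

    Notes
    -----
    Monotone likelihood (perfect separation) does not raise: the fit is
    returned with ``converged=False`` and a diagnostic message, since the
    partial likelihood then has no interior maximum.
    """
    if tie_method != "efron":
        raise ValueError(
            f"unsupported tie method {tie_method!r}; this implementation uses Efron tie handling"
        )
    df = design_frame(cohort, covariates)
    n_excluded = cohort.n - len(df)
    if df["event"].sum() < 1:
        raise DegenerateDesignError("no events among complete cases; cannot fit")
    for cov in covariates:
        if df[cov].nunique() <= 1:
            raise DegenerateDesignError(f"covariate {cov!r} is constant; coefficients not identifiable")

    cph = CoxPHFitter(penalizer=0.0)
    diagnostics: list[str] = []
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(
                df, duration_col="time", event_col="event",
                fit_options={"precision": 1e-9, "r_precision": 1e-12, "max_steps": 500},
            )
        except ConvergenceError as exc:
            raise DegenerateDesignError(f"partial-likelihood maximization failed: {exc}") from exc
    for w in caught:
        if not issubclass(w.category, ConvergenceWarning):
            continue
        msg = str(w.message)
        # lifelines also emits pre-fit data-quality cautions (e.g. "low
        # variance") as ConvergenceWarning; only genuine maximization
        # failures flip the converged flag
        if "failed to converge" in msg or "norm(delta) is still high" in msg:
            converged = False
            diagnostics.append(msg.split("\n")[0])
        else:
            logger.debug("fit_cox caution: %s", msg.split("\n")[0])
    # monotone / quasi-monotone likelihood: the estimate drifts to the edge
    # of the parameter space with an exploding standard error
    if converged and (np.abs(cph.params_.to_numpy()) > 8.0).any():
        converged = False
        diagnostics.append(
            "coefficient magnitude exceeds 8; likelihood is (quasi-)monotone "
            "(possible complete separation)"
        )

    ci = cph.confidence_intervals_.to_numpy()
    # a non-converged (separated) fit can have huge coefficients; exp -> inf is fine
    np_err = np.errstate(over="ignore")
    with np_err:
        fit = CoxFit(
        coefficients=cph.params_.to_numpy(),
        se=cph.standard_errors_.to_numpy(),
        hr=np.exp(cph.params_.to_numpy()),
        hr_ci_lower=np.exp(ci[:, 0]),
        hr_ci_upper=np.exp(ci[:, 1]),
        p_values=cph.summary["p"].to_numpy(),
        loglik=float(cph.log_likelihood_),
        loglik_null=float(_null_loglik(cph)),
        converged=converged,
        tie_method=tie_method,
        covariate_labels=tuple(covariates),
        n_used=len(df),
        n_events=int(df["event"].sum()),
        n_excluded=n_excluded,
        diagnostic="; ".join(diagnostics),
    )
    if not converged:
        logger.warning("fit_cox: non-convergence flagged: %s", fit.diagnostic)
    return fit


def _null_loglik(cph: CoxPHFitter) -> float:
    try:
        return cph.log_likelihood_ - cph.log_likelihood_ratio_test().test_statistic / 2.0
    except Exception:  # pragma: no cover - defensive
        return float("nan")


def composite_score(fit: CoxFit, cohort: Cohort) -> tuple[MarkerSeries, Cohort]:
    """Per-patient composite risk score ``exp(beta . Z)``.

    Patients with a missing covariate are excluded (and logged); the
    returned cohort is the complete-case sub-cohort aligned with the marker.
    """
    if not fit.converged:
        raise ValueError(f"refusing to score from a non-converged fit: {fit.diagnostic}")
    fields = [c for c in fit.covariate_labels if c != "rila_neg"]
    sub = cohort.complete_cases(fields) if fields else cohort
    lp = np.zeros(sub.n)
    for beta, cov in zip(fit.coefficients, fit.covariate_labels):
        col = -sub.rila if cov == "rila_neg" else sub.covariate(cov)
        lp += beta * col
    marker = MarkerSeries(np.exp(lp), orientation="raw", label="composite")
    return marker, sub
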