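"""Resampling-based performance estimation with threshold/model transfer.

The headline scheme is Monte Carlo cross-validation: repeatedly split the
cohort at random into a training set (2/3) and a validation set (1/3); on
the training set fit the Cox model (composite marker only) and pick the
Youden-optimal threshold per horizon; on the validation set apply the
trained coefficients and threshold and recompute AUC, Se, Sp, PPV, NPV and
cost.  Metrics are averaged over splits.  K-fold (K=5) and leave-one-out
are provided as variants; leave-one-out necessarily pools out-of-fold
predictions before computing Se/Sp, since a single-subject fold admits no
ROC curve.

Splits are unstratified simple random draws.  A validation split with no
events by a horizon is skipped for that horizon and counted, rather than
redrawn, so the split distribution stays honest.  Each split has its own
random stream derived from the master seed and the split index, making
results reproducible and independent of the horizon list.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, MarkerSeries, negate_marker
from .cox import DegenerateDesignError, composite_score, fit_cox
from .estimators import time_dependent_roc, youden_threshold
from .metrics import (
    CostMatrix,
    expected_confusion,
    km_survival,
    misclassification_cost,
    ppv_npv,
)

logger = logging.getLogger(__name__)

_SCHEMES = ("monte_carlo", "kfold", "loo")


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation settings.

    ``marker`` selects RILA alone (``"rila"``, negated before analysis) or
    the Cox composite score (``"composite"``, refitted on every training
    set).  Defaults mirror the published procedure: 500 Monte Carlo
    repeats with a 2/3 training fraction, or 5 folds.
    """

    scheme: str = "monte_carlo"
    n_repeats: int = 500
    train_fraction: float = 2.0 / 3.0
    k: int = 5
    horizons: tuple[float, ...] = (12.0, 24.0, 36.0, 50.0)
    estimator: str = "nne"
    span: Optional[float] = None
    marker: str = "rila"
    weights: CostMatrix = field(default_factory=CostMatrix)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in _SCHEMES:
            raise ValueError(f"scheme must be one of {_SCHEMES}, got {self.scheme!r}")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError(f"train_fraction must lie in (0, 1), got {self.train_fraction}")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.marker not in ("rila", "composite"):
            raise ValueError(f"marker must be 'rila' or 'composite', got {self.marker!r}")


@dataclass(frozen=True)
class CVResult:
    """Per-split rows, their per-horizon means, and bookkeeping."""

    per_split: pd.DataFrame
    summary: pd.DataFrame
    n_valid_splits: dict[float, int]
    n_skipped: dict[float, int]
    skip_reasons: tuple[str, ...]
    config: CVConfig


def _marker_for(cohort: Cohort, config: CVConfig, fit=None) -> MarkerSeries:
    if config.marker == "rila":
        return negate_marker(cohort.rila, label="rila")
    marker, sub = composite_score(fit, cohort)
    if sub.n != cohort.n:  # callers pre-filter to complete cases
        raise ValueError("composite marker requires complete cases")
    return marker


def _prepare(cohort: Cohort, config: CVConfig) -> Cohort:
    if config.marker == "composite":
        sub = cohort.complete_cases(("tobacco", "ht"))
        if sub.n < cohort.n:
            logger.info("cross-validation on %d complete cases of %d", sub.n, cohort.n)
        return sub
    return cohort


def _evaluate_split(
    train: Cohort, val: Cohort, config: CVConfig, split_id: int,
    records: list, skip_reasons: list,
) -> None:
    """Train on `train`, evaluate on `val`; append one record per horizon."""
    fit = None
    if config.marker == "composite":
        try:
            fit = fit_cox(train)
        except DegenerateDesignError as exc:
            skip_reasons.append(f"split {split_id}: degenerate training design ({exc})")
            return
        if not fit.converged:
            skip_reasons.append(f"split {split_id}: Cox fit did not converge ({fit.diagnostic})")
            return
    marker_train = _marker_for(train, config, fit)
    marker_val = _marker_for(val, config, fit)
    for t in config.horizons:
        try:
            curve_train = time_dependent_roc(
                marker_train, train, t, estimator=config.estimator, span=config.span
            )
            cut = youden_threshold(curve_train, marker_train)
            curve_val = time_dependent_roc(
                marker_val, val, t, estimator=config.estimator, span=config.span
            )
        except ValueError as exc:
            skip_reasons.append(f"split {split_id}, t={t:g}: {exc}")
            continue
        se_at, sp_at = curve_val.at_threshold(cut.threshold_marker_scale)
        km = km_survival(val, t)
        conf = expected_confusion(se_at, sp_at, km.survival, val.n, t)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            ppv, npv = ppv_npv(conf)
        records.append(
            {
                "split": split_id,
                "time": t,
                "threshold": cut.threshold_marker_scale,
                "threshold_original": cut.threshold_original_scale,
                "auc": curve_val.auc,
                "se": se_at,
                "sp": sp_at,
                "ppv": np.nan if ppv is None else ppv,
                "npv": np.nan if npv is None else npv,
                "cost": misclassification_cost(conf, config.weights),
            }
        )


def _summarize(records: list, skip_reasons: list, config: CVConfig) -> CVResult:
    cols = ["split", "time", "threshold", "threshold_original", "auc",
            "se", "sp", "ppv", "npv", "cost"]
    per_split = pd.DataFrame.from_records(records, columns=cols)
    if len(per_split):
        summary = (
            per_split.drop(columns="split").groupby("time", as_index=False).mean()
        )
    else:
        summary = pd.DataFrame(columns=[c for c in cols if c != "split"])
    n_valid = {t: int((per_split["time"] == t).sum()) for t in config.horizons}
    total = _n_planned(config)
    n_skipped = {t: total - n_valid[t] for t in config.horizons}
    for reason in skip_reasons:
        logger.info("skipped: %s", reason)
    return CVResult(
        per_split=per_split,
        summary=summary,
        n_valid_splits=n_valid,
        n_skipped=n_skipped,
        skip_reasons=tuple(skip_reasons),
        config=config,
    )


def _n_planned(config: CVConfig) -> int:
    if config.scheme == "monte_carlo":
        return config.n_repeats
    if config.scheme == "kfold":
        return config.k
    return 1  # loo: one pooled evaluation


def mc_cross_validate(cohort: Cohort, config: CVConfig) -> CVResult:
    """Monte Carlo cross-validation (repeated random 2/3-1/3 splitting)."""
    if config.scheme != "monte_carlo":
        raise ValueError(f"config.scheme is {config.scheme!r}, expected 'monte_carlo'")
    cohort = _prepare(cohort, config)
    n = cohort.n
    n_train = math.ceil(config.train_fraction * n)
    if not 2 <= n_train <= n - 2:
        raise ValueError(f"train fraction {config.train_fraction} leaves too few "
                         f"subjects (n={n}, train={n_train})")
    records: list = []
    skip_reasons: list = []
    for r in range(config.n_repeats):
        rng = np.random.default_rng([config.seed, r])
        perm = rng.permutation(n)
        train = cohort.subset(perm[:n_train])
        val = cohort.subset(perm[n_train:])
        _evaluate_split(train, val, config, r, records, skip_reasons)
    return _summarize(records, skip_reasons, config)


def kfold_cross_validate(cohort: Cohort, config: CVConfig) -> CVResult:
    """K-fold cross-validation; ``k == n`` gives leave-one-out.

    For k < n each fold serves once as the validation set with threshold
    transfer from the complementary training set, exactly as in the Monte
    Carlo scheme.  For k == n the out-of-fold predictions are pooled into a
    single marker vector and evaluated once (a per-fold ROC does not exist
    for a single subject); the Youden threshold is then taken on the pooled
    curve.
    """
    if config.scheme not in ("kfold", "loo"):
        raise ValueError(f"config.scheme is {config.scheme!r}, expected 'kfold' or 'loo'")
    cohort = _prepare(cohort, config)
    n = cohort.n
    k = n if config.scheme == "loo" else config.k
    if k > n:
        raise ValueError(f"k={k} exceeds cohort size {n}")
    rng = np.random.default_rng([config.seed, 0])
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    records: list = []
    skip_reasons: list = []
    if k == n:
        return _loo_pooled(cohort, config, folds, skip_reasons)
    for fold_id, val_idx in enumerate(folds):
        train_idx = np.setdiff1d(perm, val_idx, assume_unique=True)
        train = cohort.subset(train_idx)
        val = cohort.subset(val_idx)
        _evaluate_split(train, val, config, fold_id, records, skip_reasons)
    return _summarize(records, skip_reasons, config)


def _loo_pooled(cohort: Cohort, config: CVConfig, folds, skip_reasons: list) -> CVResult:
    n = cohort.n
    pooled = np.empty(n)
    for val_idx in folds:
        i = int(val_idx[0])
        p = cohort.patients[i]
        if config.marker == "rila":
            pooled[i] = -p.rila  # marker needs no training data
            continue
        train_idx = np.setdiff1d(np.arange(n), val_idx, assume_unique=True)
        fit = fit_cox(cohort.subset(train_idx))
        if not fit.converged:
            skip_reasons.append(f"loo fold for subject {p.id}: Cox fit did not converge")
            raise ValueError("leave-one-out Cox fit failed to converge")
        z = {"rila_neg": -p.rila, "tobacco": p.tobacco, "ht": p.ht}
        lp = sum(b * z[c] for b, c in zip(fit.coefficients, fit.covariate_labels))
        pooled[i] = float(np.exp(lp))
    orientation = "negated" if config.marker == "rila" else "raw"
    marker = MarkerSeries(pooled, orientation=orientation, label=f"{config.marker}-loo")
    records: list = []
    for t in config.horizons:
        try:
            curve = time_dependent_roc(marker, cohort, t, estimator=config.estimator,
                                       span=config.span)
            cut = youden_threshold(curve, marker)
        except ValueError as exc:
            skip_reasons.append(f"loo, t={t:g}: {exc}")
            continue
        km = km_survival(cohort, t)
        conf = expected_confusion(cut.se_at, cut.sp_at, km.survival, n, t)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            ppv, npv = ppv_npv(conf)
        records.append(
            {
                "split": 0,
                "time": t,
                "threshold": cut.threshold_marker_scale,
                "threshold_original": cut.threshold_original_scale,
                "auc": curve.auc,
                "se": cut.se_at,
                "sp": cut.sp_at,
                "ppv": np.nan if ppv is None else ppv,
                "npv": np.nan if npv is None else npv,
                "cost": misclassification_cost(conf, config.weights),
            }
        )
    return _summarize(records, skip_reasons, config)


def cross_validate(cohort: Cohort, config: CVConfig) -> CVResult:
    """Dispatch on ``config.scheme``."""
    if config.scheme == "monte_carlo":
        return mc_cross_validate(cohort, config)
    return kfold_cross_validate(cohort, config)
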