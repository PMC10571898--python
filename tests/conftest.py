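"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's estimation code paths:
the binary ROC oracle counts cases and controls directly, and the partial
log-likelihood is written out from its definition and maximized by scalar
search.  They serve as ground truth for the estimator tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from tdroc.cohort import Cohort, MarkerSeries, Patient


def build_cohort(times, events, rila=None, tobacco=None, ht=None) -> Cohort:
    """Assemble a cohort from parallel arrays (rila defaults to 50%)."""
    n = len(times)
    rila = np.full(n, 50.0) if rila is None else np.asarray(rila, float)
    patients = []
    for i in range(n):
        patients.append(
            Patient(
                id=f"p{i}",
                time=float(times[i]),
                event=int(events[i]),
                rila=float(rila[i]),
                tobacco=None if tobacco is None else int(tobacco[i]),
                ht=None if ht is None else int(ht[i]),
            )
        )
    return Cohort(tuple(patients))


def binary_roc_oracle(marker: np.ndarray, times: np.ndarray, horizon: float):
    """Empirical Se/Sp/AUC for censoring-free data at a horizon.

    Cases are subjects with T <= t, controls T > t.  AUC is the
    Mann-Whitney statistic with ties counted 1/2.
    """
    marker = np.asarray(marker, float)
    case = times <= horizon
    ctrl = ~case
    thresholds = np.unique(marker)
    se = np.array([(marker[case] > c).mean() for c in thresholds])
    sp = np.array([(marker[ctrl] <= c).mean() for c in thresholds])
    cmp = marker[case][:, None] - marker[ctrl][None, :]
    auc = float(np.mean(np.where(cmp > 0, 1.0, np.where(cmp == 0, 0.5, 0.0))))
    return thresholds, se, sp, auc


def breslow_partial_loglik(beta: float, times, events, z) -> float:
    """Partial log-likelihood for one covariate, untied event times."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    z = np.asarray(z, float)
    ll = 0.0
    for i in np.flatnonzero(events == 1):
        risk = times >= times[i]
        ll += beta * z[i] - np.log(np.sum(np.exp(beta * z[risk])))
    return ll


def bruteforce_cox_beta(times, events, z, lo=-10.0, hi=10.0) -> float:
    """1-D maximizer of the written partial likelihood: coarse grid plus
    golden-section refinement."""
    from scipy.optimize import minimize_scalar

    grid = np.linspace(lo, hi, 2001)
    vals = [breslow_partial_loglik(b, times, events, z) for b in grid]
    b0 = grid[int(np.argmax(vals))]
    res = minimize_scalar(
        lambda b: -breslow_partial_loglik(b, times, events, z),
        bounds=(max(lo, b0 - 0.05), min(hi, b0 + 0.05)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)


@pytest.fixture(scope="session")
def default_cohort():
    """One synthetic cohort at the study's default conditions."""
    from tdroc.simulate import SimulationConfig, generate_cohort

    return generate_cohort(SimulationConfig(seed=20230922))


@pytest.fixture()
def tmp_csv(tmp_path):
    return tmp_path / "cohort.csv"
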