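"""Time-dependent ROC estimators against the empirical binary oracle."""

import numpy as np
import pytest

from tdroc.cohort import Cohort, MarkerSeries, Patient, negate_marker
from tdroc.estimators import (
    EstimatorWarning,
    auc_trapezoid,
    km_joint_survival,
    minimal_span,
    nne_joint_survival,
    roc_curve,
    time_dependent_roc,
    youden_threshold,
)

from conftest import binary_roc_oracle, build_cohort


def _roc(marker_vals, times, horizon, **kw):
    cohort = build_cohort(times, np.ones(len(times), int))
    return time_dependent_roc(MarkerSeries(np.asarray(marker_vals, float)),
                              cohort, horizon, **kw)


class TestKmEstimator:
    def test_four_subject_worked_instance(self):
        """Times 1,3,5,7 all events, markers 4,3,2,1, t=4: cases are the
        subjects with markers {4,3}, controls {2,1}; the threshold between
        the groups separates them perfectly."""
        cohort = build_cohort([1, 3, 5, 7], [1, 1, 1, 1])
        marker = MarkerSeries(np.array([4.0, 3.0, 2.0, 1.0]))
        joint = km_joint_survival(marker, cohort, 4.0)
        se, sp = joint.se_sp_at(2.5)
        assert se == pytest.approx(1.0, abs=1e-12)
        assert sp == pytest.approx(1.0, abs=1e-12)
        ths, se_o, sp_o, auc_o = binary_roc_oracle(marker.values, cohort.times, 4.0)
        se_all, sp_all = joint.se_sp()
        np.testing.assert_allclose(se_all, se_o, atol=1e-12)
        np.testing.assert_allclose(sp_all, sp_o, atol=1e-12)
        assert roc_curve(joint).auc == pytest.approx(auc_o, abs=1e-12)

    def test_horizon_before_first_event_errors(self):
        cohort = build_cohort([5, 6, 7], [1, 1, 1])
        marker = MarkerSeries(np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError, match="no cases"):
            roc_curve(km_joint_survival(marker, cohort, 2.0))

    def test_marker_dependent_censoring_breaks_bounds(self):
        """Concentrating censoring in the high-marker subjects before the
        low-marker events drives the KM specificity below zero — the
        documented drawback of the naive estimator.  The NNE stays in
        bounds on the same data."""
        cohort = Cohort((
            Patient("a", 10.0, 0, 50.0),
            Patient("b", 1.0, 1, 50.0),
            Patient("c", 0.5, 0, 50.0),
            Patient("d", 0.5, 0, 50.0),
            Patient("e", 0.5, 0, 50.0),
        ))
        marker = MarkerSeries(np.array([0.0, 1.0, 3.0, 4.0, 5.0]))
        with pytest.warns(EstimatorWarning):
            curve = roc_curve(km_joint_survival(marker, cohort, 1.5))
        assert curve.sp.min() < -1e-9
        nne = time_dependent_roc(marker, cohort, 1.5, estimator="nne")
        assert (nne.se >= 0).all() and (nne.se <= 1).all()
        assert (nne.sp >= 0).all() and (nne.sp <= 1).all()


class TestNneEstimator:
    def test_minimal_span_reproduces_empirical_roc(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(4, 40))
            times = rng.uniform(0.5, 60, n)
            marker = rng.normal(size=n)
            horizon = float(np.quantile(times, 0.5))
            curve = _roc(marker, times, horizon, span=minimal_span(n))
            ths, se_o, sp_o, auc_o = binary_roc_oracle(marker, times, horizon)
            np.testing.assert_allclose(curve.se[1:-1], se_o, atol=1e-12)
            np.testing.assert_allclose(curve.sp[1:-1], sp_o, atol=1e-12)
            assert curve.auc == pytest.approx(auc_o, abs=1e-12)

    def test_bounded_on_random_censored_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            n = int(rng.integers(5, 40))
            times = rng.exponential(10, n) + 0.01
            events = rng.integers(0, 2, n)
            marker = rng.normal(size=n)
            cohort = build_cohort(times, events)
            horizon = float(np.quantile(times, rng.uniform(0.3, 0.9)))
            try:
                curve = time_dependent_roc(MarkerSeries(marker), cohort, horizon)
            except ValueError:
                continue  # no cases or no survivors at this horizon
            assert (curve.se >= -1e-12).all() and (curve.se <= 1 + 1e-12).all()
            assert (curve.sp >= -1e-12).all() and (curve.sp <= 1 + 1e-12).all()
            assert (np.diff(curve.se) <= 1e-12).all()
            assert (np.diff(curve.sp) >= -1e-12).all()

    def test_span_out_of_range_rejected(self):
        cohort = build_cohort([1, 2, 3], [1, 1, 1])
        marker = MarkerSeries(np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError, match="span"):
            nne_joint_survival(marker, cohort, 2.0, span=0.7)

    def test_ties_share_neighborhoods(self):
        # tied markers must get identical conditional survival
        cohort = build_cohort([1, 2, 3, 4], [1, 1, 0, 1])
        marker = MarkerSeries(np.array([2.0, 2.0, 1.0, 3.0]))
        joint = nne_joint_survival(marker, cohort, 2.5, span=0.3)
        assert joint.cond_surv[0] == joint.cond_surv[1]


class TestCurveShape:
    def test_endpoints_and_sentinels(self):
        for estimator in ("nne", "km"):
            curve = _roc([3.0, 1.0, 2.0], [1, 5, 9], 4.0, estimator=estimator)
            assert curve.thresholds[0] == -np.inf and curve.thresholds[-1] == np.inf
            assert (curve.se[0], curve.sp[0]) == (1.0, 0.0)
            assert (curve.se[-1], curve.sp[-1]) == (0.0, 1.0)

    def test_perfect_marker_passes_through_corner(self):
        curve = _roc([-1.0, -2.0, -3.0, -4.0], [1, 2, 3, 4], 2.5,
                     span=minimal_span(4))
        corner = [(f, s) for f, s in zip(curve.fpr, curve.se)]
        assert (0.0, 1.0) in corner
        assert curve.auc == pytest.approx(1.0, abs=1e-12)

    def test_constant_marker_is_diagonal(self):
        with pytest.warns(UserWarning, match="degenerate"):
            curve = _roc([5.0, 5.0, 5.0, 5.0], [1, 2, 3, 4], 2.5)
            cut = youden_threshold(curve)
        assert curve.auc == pytest.approx(0.5, abs=1e-12)
        assert cut.youden == pytest.approx(0.0, abs=1e-12)
        assert cut.sp_at == pytest.approx(1.0)

    def test_nested_horizons_have_nested_case_sets(self):
        """Censoring-free cumulative/dynamic cases at t1 < t2 are nested, so
        Se at any threshold can only gain mass from new cases."""
        rng = np.random.default_rng(11)
        n = 60
        times = rng.uniform(1, 50, n)
        marker = rng.normal(size=n)
        c1 = set(np.flatnonzero(times <= 20))
        c2 = set(np.flatnonzero(times <= 35))
        assert c1 <= c2
        for t, cases in ((20.0, c1), (35.0, c2)):
            curve = _roc(marker, times, t, span=minimal_span(n))
            _, se_o, _, _ = binary_roc_oracle(marker, times, t)
            np.testing.assert_allclose(curve.se[1:-1], se_o, atol=1e-12)


class TestAucProperties:
    @pytest.mark.parametrize(
        "points,expected",
        [
            (([0.0, 1.0], [0.0, 1.0]), 0.5),
            (([0.0, 0.0, 1.0], [0.0, 1.0, 1.0]), 1.0),
            (([0.0, 0.5, 1.0], [0.0, 0.8, 1.0]), 0.65),
        ],
    )
    def test_trapezoid_on_fixed_curves(self, points, expected):
        fpr, se = points
        from tdroc.estimators import RocCurve

        curve = RocCurve(
            horizon=1.0, thresholds=np.arange(len(se), dtype=float),
            se=np.array(se[::-1]), sp=1.0 - np.array(fpr[::-1]),
            auc=np.nan, estimator="nne", n=len(se),
        )
        assert auc_trapezoid(curve) == pytest.approx(expected, abs=1e-12)

    def test_invariance_under_monotone_transforms(self):
        rng = np.random.default_rng(21)
        n = 50
        times = rng.uniform(1, 40, n)
        m = rng.normal(size=n)
        base = _roc(m, times, 15.0).auc
        assert _roc(np.exp(m), times, 15.0).auc == pytest.approx(base, abs=1e-12)
        assert _roc(3.0 * m + 7.0, times, 15.0).auc == pytest.approx(base, abs=1e-12)

    def test_sign_reversal_maps_auc_to_complement(self):
        rng = np.random.default_rng(22)
        n = 30
        times = rng.uniform(1, 40, n)
        m = rng.normal(size=n)  # continuous, so ties have measure zero
        a = _roc(m, times, 15.0, span=minimal_span(n)).auc
        b = _roc(-m, times, 15.0, span=minimal_span(n)).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)


class TestYouden:
    def test_interior_maximum_matches_exhaustive_scan(self):
        rng = np.random.default_rng(31)
        n = 25
        times = rng.uniform(1, 40, n)
        m = rng.normal(size=n) + 1.5 * (times < 15)
        curve = _roc(m, times, 15.0, span=minimal_span(n))
        cut = youden_threshold(curve)
        finite = np.isfinite(curve.thresholds)
        youden_all = curve.se[finite] + curve.sp[finite] - 1.0
        assert cut.youden == pytest.approx(youden_all.max(), abs=1e-12)

    def test_tie_broken_toward_higher_specificity(self):
        from tdroc.estimators import RocCurve

        curve = RocCurve(
            horizon=1.0,
            thresholds=np.array([-np.inf, 1.0, 2.0, np.inf]),
            se=np.array([1.0, 0.9, 0.6, 0.0]),
            sp=np.array([0.0, 0.4, 0.7, 1.0]),
            auc=np.nan, estimator="nne", n=4,
        )
        cut = youden_threshold(curve)  # both finite points have youden 0.3
        assert cut.threshold_marker_scale == 2.0
        assert cut.sp_at == pytest.approx(0.7)

    def test_threshold_reported_on_rila_scale(self):
        cohort = build_cohort([1, 3, 5, 7], [1, 1, 1, 1],
                              rila=[8.0, 10.0, 14.0, 20.0])
        marker = negate_marker(cohort.rila)
        curve = time_dependent_roc(marker, cohort, 4.0, span=minimal_span(4))
        cut = youden_threshold(curve, marker)
        assert cut.threshold_original_scale == -cut.threshold_marker_scale
        assert cut.threshold_original_scale in cohort.rila
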