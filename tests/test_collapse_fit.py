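"""Tanh collapse: evaluation, fitting, and curve comparison."""

import numpy as np
import pytest

from nasalair.collapse_fit import (
    HyperbolicFit,
    compare_curves,
    efficiency_improvement,
    evaluate_hyperbola,
    fit_hyperbola,
)
from nasalair.errors import FitConvergenceError, ValidationError
from nasalair.profile_io import load_fixture

D9 = np.array([0.0, 0.1806, 0.2977, 0.4147, 0.5318, 0.6488, 0.7659, 0.8829, 1.0])


class TestEvaluate:
    def test_closed_form_points(self):
        assert evaluate_hyperbola(0.0, 0.3, 0.0) == pytest.approx(-1.0)
        assert evaluate_hyperbola(0.05, 0.25, 0.2) == pytest.approx(np.tanh(1.0) - 1.0)
        assert evaluate_hyperbola(0.05, 0.25, 0.2) == pytest.approx(-0.238406, abs=1e-6)
        # asymptote toward full acclimatization
        assert evaluate_hyperbola(0.0, 0.25, 50.0) == pytest.approx(0.0, abs=1e-12)

    def test_strictly_increasing_and_bounded(self):
        d = np.linspace(0, 1, 50)
        vals = evaluate_hyperbola(-0.1, 0.2, d)
        assert np.all(np.diff(vals) > 0)
        assert np.all((vals > -2) & (vals < 0))

    def test_beta_must_be_positive(self):
        with pytest.raises(ValidationError):
            evaluate_hyperbola(0.0, -0.1, 0.5)


class TestFit:
    def test_exact_parameter_recovery(self):
        theta = evaluate_hyperbola(0.05, 0.25, D9)
        fit = fit_hyperbola(D9, theta)
        assert fit.alpha == pytest.approx(0.05, abs=1e-5)
        assert fit.beta == pytest.approx(0.25, abs=1e-5)
        assert fit.sse < 1e-10

    def test_constant_profile_flagged(self):
        with pytest.raises(FitConvergenceError) as exc:
            fit_hyperbola(D9, np.full_like(D9, -1.0))
        assert isinstance(exc.value.best, HyperbolicFit)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            fit_hyperbola([0.0, 1.0], [-1.0, 0.0])

    def test_point_order_invariance(self):
        theta = evaluate_hyperbola(-0.02, 0.3, D9) + 0.01 * np.sin(10 * D9)
        fit1 = fit_hyperbola(D9, theta)
        perm = np.array([3, 0, 8, 1, 7, 2, 6, 4, 5])
        fit2 = fit_hyperbola(D9[perm], theta[perm])
        assert fit1.alpha == pytest.approx(fit2.alpha, abs=1e-9)
        assert fit1.beta == pytest.approx(fit2.beta, abs=1e-9)

    def test_duplicated_points_keep_optimum_and_scale_sse(self):
        theta = evaluate_hyperbola(0.0, 0.25, D9) + 0.01 * np.cos(7 * D9)
        fit1 = fit_hyperbola(D9, theta)
        fit2 = fit_hyperbola(np.tile(D9, 2), np.tile(theta, 2))
        assert fit2.alpha == pytest.approx(fit1.alpha, abs=1e-6)
        assert fit2.beta == pytest.approx(fit1.beta, abs=1e-6)
        assert fit2.sse == pytest.approx(2 * fit1.sse, rel=1e-6)

    def test_slope_at_origin_formula(self):
        fit = HyperbolicFit(alpha=0.1, beta=0.25, sse=0.0, n_points=9)
        expected = (1 / 0.25) / np.cosh(0.1 / 0.25) ** 2
        assert fit.slope_at_origin == pytest.approx(expected)
        assert fit.slope_at_origin > 0


class TestCompare:
    def test_identical_fits_are_coincident(self):
        f = HyperbolicFit(0.02, 0.25, 0.0, 9)
        rec = compare_curves(f, f)
        assert rec["verdict"] == "coincident"
        assert rec["signed_area"] == pytest.approx(0.0, abs=1e-12)
        assert rec["slope_ratio"] == pytest.approx(1.0)

    def test_faster_acclimatization_lies_above(self):
        fast = HyperbolicFit(0.0, 0.2, 0.0, 9)
        slow = HyperbolicFit(0.0, 0.4, 0.0, 9)
        rec = compare_curves(fast, slow)
        assert rec["verdict"] == "above"
        assert rec["signed_area"] > 0
        d = np.linspace(0, 1, 21)[1:]
        assert np.all(fast(d) > slow(d))

    def test_operated_case01_above_preop(self):
        """Surgery moves the subadult's temperature collapse curve upward."""
        pre = load_fixture("T1")
        post = load_fixture("T2")
        fit_pre = fit_hyperbola(pre.distance, pre.average)
        fit_post = fit_hyperbola(post.distance, post.average)
        rec = compare_curves(fit_post, fit_pre)
        assert rec["verdict"] == "above"
        assert efficiency_improvement(fit_pre, fit_post) > 0

    def test_efficiency_improvement_examples(self):
        a = HyperbolicFit(0.0, 0.5, 0.0, 9)  # slope 2
        b = HyperbolicFit(0.0, 0.25, 0.0, 9)  # slope 4
        assert efficiency_improvement(a, b) == pytest.approx(100.0)
        assert efficiency_improvement(a, a) == 0.0

    def test_obstructed_recovery_after_surgery_positive(self):
        obstructed = load_fixture("T4")
        operated = load_fixture("T5")
        f_obs = fit_hyperbola(obstructed.distance, obstructed.average)
        f_op = fit_hyperbola(operated.distance, operated.average)
        assert efficiency_improvement(f_obs, f_op) > 0
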