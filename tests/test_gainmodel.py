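"""Sigmoid nonlinearities and the dual-condition contrast-gain model."""

import numpy as np
import pytest

from contrastgain.gainmodel import (
    SigmoidParams,
    fit_dual_condition_model,
    fit_output_nonlinearity,
    sigmoid_eval,
    summarize_changes,
)
from contrastgain.strf import predict
from contrastgain.synthetic import UnitSpec, generate_unit, simulate_responses


class TestSigmoid:
    def test_midpoint_and_asymptotes(self):
        p = SigmoidParams(a=2.0, b=10.0, c=1.5, d=0.7)
        assert sigmoid_eval(1.5, p) == pytest.approx(2.0 + 5.0)
        assert sigmoid_eval(1e6, p) == pytest.approx(12.0)
        assert sigmoid_eval(-1e6, p) == pytest.approx(2.0)

    def test_slope_at_midpoint(self):
        p = SigmoidParams(a=0.0, b=8.0, c=0.0, d=2.0)
        h = 1e-6
        slope = (sigmoid_eval(h, p) - sigmoid_eval(-h, p)) / (2 * h)
        assert slope == pytest.approx(p.b / (4 * p.d), rel=1e-6)

    def test_monotone_increasing(self):
        p = SigmoidParams(a=1.0, b=5.0, c=0.0, d=1.0)
        z = np.linspace(-10, 10, 101)
        assert np.all(np.diff(sigmoid_eval(z, p)) > 0)

    @pytest.mark.parametrize("bad", [dict(b=-1.0), dict(b=0.0), dict(d=-2.0),
                                     dict(d=0.0)])
    def test_invalid_parameters_rejected(self, bad):
        kwargs = dict(a=0.0, b=1.0, c=0.0, d=1.0)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            SigmoidParams(**kwargs)

    def test_gain_is_inverse_slope_parameter(self):
        assert SigmoidParams(0, 1, 0, 0.25).gain == 4.0


class TestFitNonlinearity:
    def test_exact_recovery_without_noise(self, rng):
        true = SigmoidParams(a=3.0, b=12.0, c=0.5, d=1.2)
        z = rng.normal(0.5, 2.0, 800)
        y = sigmoid_eval(z, true)
        fit = fit_output_nonlinearity(z, y)
        for name in "abcd":
            assert getattr(fit, name) == pytest.approx(
                getattr(true, name), rel=1e-4, abs=1e-4)

    def test_constant_response_collapses_range(self, rng):
        z = rng.normal(0, 1, 200)
        with pytest.warns(RuntimeWarning, match="collapsed"):
            fit = fit_output_nonlinearity(z, np.full(200, 6.0))
        assert fit.a + fit.b / 2 == pytest.approx(6.0, abs=0.1)
        assert fit.b < 1e-6

    def test_gain_recovered_under_moderate_noise(self):
        true = SigmoidParams(a=2.0, b=10.0, c=0.0, d=0.8)
        gains = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            z = rng.normal(0.0, 1.6, 1600)
            y = sigmoid_eval(z, true) + rng.normal(0, 0.05 * true.b, 1600)
            fit = fit_output_nonlinearity(z, y)
            gains.append(fit.gain)
        assert np.all(np.abs(np.array(gains) / true.gain - 1.0) < 0.05)

    def test_degenerate_z_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_output_nonlinearity(np.ones(100), np.ones(100))

    def test_too_few_pairs_rejected(self, rng):
        with pytest.raises(ValueError, match="at least"):
            fit_output_nonlinearity(rng.normal(0, 1, 10), rng.normal(0, 1, 10))

    def test_fixed_parameter_mask(self, rng):
        true = SigmoidParams(a=3.0, b=12.0, c=0.5, d=1.2)
        z = rng.normal(0.5, 2.0, 500)
        y = sigmoid_eval(z, true)
        pinned = SigmoidParams(a=3.0, b=12.0, c=0.0, d=1.0)
        fit = fit_output_nonlinearity(z, y, free=(False, False, True, True),
                                      init=pinned)
        assert fit.a == 3.0 and fit.b == 12.0
        assert fit.c == pytest.approx(0.5, abs=1e-3)
        assert fit.d == pytest.approx(1.2, abs=1e-3)


class TestDualConditionModel:
    def test_noiseless_gain_change_within_one_point(self, design_pair, grid):
        d_low, d_high = design_pair
        unit = generate_unit(UnitSpec(gain_change_pct=-50.0), seed=3,
                             grid=grid)
        y_low, y_high = simulate_responses(unit, d_low, d_high, seed=4,
                                           noise_sd=0.0)
        fit = fit_dual_condition_model(d_low, y_low, d_high, y_high)
        change = summarize_changes(fit)
        assert change.gain_change_pct == pytest.approx(-50.0, abs=1.0)

    def test_identical_conditions_give_zero_changes(self, design_pair, grid):
        d_low, _ = design_pair
        unit = generate_unit(UnitSpec(), seed=5, grid=grid)
        y, _ = simulate_responses(unit, d_low, d_low, seed=6, noise_sd=2.0)
        fit = fit_dual_condition_model(d_low, y, d_low, y)
        change = summarize_changes(fit)
        assert abs(change.gain_change_pct) < 1.0
        assert fit.c_low == pytest.approx(fit.c_high, abs=1e-6)

    def test_threshold_only_shift_recovered(self, design_pair, grid, rng):
        d_low, d_high = design_pair
        unit = generate_unit(UnitSpec(gain_change_pct=-50.0), seed=7,
                             grid=grid)
        delta = 0.5 * unit.sigmoid_low.c
        shifted = SigmoidParams(unit.sigmoid_low.a, unit.sigmoid_low.b,
                                unit.sigmoid_low.c + delta,
                                unit.sigmoid_low.d)
        z_l = predict(unit.true_strf, d_low)
        z_h = predict(unit.true_strf, d_high)
        y_l = sigmoid_eval(z_l, unit.sigmoid_low) + rng.normal(0, 0.5, 1600)
        y_h = sigmoid_eval(z_h, shifted) + rng.normal(0, 0.5, 1600)
        fit = fit_dual_condition_model(d_low, y_l, d_high, y_h)
        change = summarize_changes(fit)
        assert abs(change.gain_change_pct) < 5.0
        # the drive of the estimated STRF is an affine rescaling of the true
        # one, so the threshold shift is compared in slope units (delta / d),
        # which is invariant to that rescaling
        recovered = (fit.c_high - fit.c_low) / fit.d_low
        assert recovered == pytest.approx(delta / unit.sigmoid_low.d, rel=0.05)

    def test_shared_parameters_are_shared(self, design_pair, grid):
        d_low, d_high = design_pair
        unit = generate_unit(UnitSpec(), seed=8, grid=grid)
        y_low, y_high = simulate_responses(unit, d_low, d_high, seed=9,
                                           noise_sd=2.0)
        fit = fit_dual_condition_model(d_low, y_low, d_high, y_high)
        assert fit.sigmoid_low.a == fit.sigmoid_high.a
        assert fit.sigmoid_low.b == fit.sigmoid_high.b

    def test_gain_invariant_to_affine_drive_rescaling(self, rng):
        # rescaling z with matching (c, d) leaves gain change untouched:
        # the d-ratio is what the model reports
        true_l = SigmoidParams(2.0, 10.0, 1.0, 1.0)
        true_h = SigmoidParams(2.0, 10.0, 1.0, 2.0)
        z = rng.normal(1.0, 2.0, 1000)
        for scale in (1.0, 3.0):
            fl = fit_output_nonlinearity(scale * z,
                                         sigmoid_eval(z, true_l))
            fh = fit_output_nonlinearity(scale * z,
                                         sigmoid_eval(z, true_h))
            change = 100.0 * (fl.d / fh.d - 1.0)
            assert change == pytest.approx(-50.0, abs=0.5)


class TestChangeSummary:
    def test_gain_change_arithmetic(self):
        from contrastgain.gainmodel import DualConditionFit
        from contrastgain.strf import SeparableSTRF
        strf = SeparableSTRF(0.0, np.ones(2), np.array([1.0, 0.0]))
        fit = DualConditionFit(strf=strf, a=0.0, b=1.0, c_low=1.0, d_low=0.5,
                               c_high=1.006, d_high=1.0, fit_error=0.0)
        change = summarize_changes(fit)
        assert change.gain_change_pct == pytest.approx(-50.0)
        assert change.threshold_change_pct == pytest.approx(0.6)

    def test_baseline_change_from_free_fits(self):
        from contrastgain.gainmodel import DualConditionFit
        from contrastgain.strf import SeparableSTRF
        strf = SeparableSTRF(0.0, np.ones(2), np.array([1.0, 0.0]))
        fit = DualConditionFit(strf=strf, a=0.0, b=1.0, c_low=1.0, d_low=1.0,
                               c_high=1.0, d_high=1.0, fit_error=0.0)
        low = SigmoidParams(10.0, 1.0, 0.0, 1.0)
        high = SigmoidParams(10.129, 1.0, 0.0, 1.0)
        change = summarize_changes(fit, low, high)
        assert change.baseline_change_pct == pytest.approx(1.29)
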