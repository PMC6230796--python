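"""Separable STRF estimation: design tensors, ALS, screening, tuning metrics."""

import numpy as np
import pytest

from contrastgain.stimgen import LevelDistributionSpec, draw_chord_levels, \
    make_tone_grid
from contrastgain.strf import (
    SeparableSTRF,
    build_design_tensor,
    cross_condition_cc,
    cross_validated_cc,
    fit_separable_strf,
    predict,
    tuning_metrics,
)
from contrastgain.synthetic import UnitSpec, generate_unit


def _toy_strf(F=25, H=16, k0=5.0, peak=0.6):
    k_f = peak * np.exp(-0.5 * ((np.arange(F) - F // 2) / 2.0) ** 2)
    k_h = np.exp(-np.arange(H) / 1.6)
    k_h = k_h / np.linalg.norm(k_h)
    return SeparableSTRF(k0=k0, k_f=k_f, k_h=k_h)


class TestDesignTensor:
    def test_lag_structure_by_enumeration(self):
        levels = np.array([[1.0], [2.0], [3.0]])
        d = build_design_tensor(levels, history_steps=2, exclude_chords=0)
        assert np.array_equal(d.X[2, 0, :], [3.0, 2.0])
        assert np.array_equal(d.X[1, 0, :], [2.0, 1.0])

    def test_constant_stimulus_rows_identical(self):
        d = build_design_tensor(np.full((30, 4), 80.0), history_steps=5,
                                exclude_chords=0)
        rows = d.X[d.mask].reshape(d.mask.sum(), -1)
        assert np.all(rows == rows[0])

    def test_paper_scale_shape(self, drc_pair):
        d = build_design_tensor(drc_pair[0].levels)
        assert d.X.shape == (1600, 25, 16)
        assert not d.mask[:40].any() and d.mask[40:].all()

    def test_history_too_long_rejected(self):
        with pytest.raises(ValueError):
            build_design_tensor(np.zeros((10, 3)), history_steps=10)


class TestFitSeparable:
    def test_noiseless_recovery(self, rng):
        levels = rng.uniform(70, 90, (500, 25))
        d = build_design_tensor(levels)
        true = _toy_strf()
        y = predict(true, d)
        strf, rep = fit_separable_strf(d, y)
        cos = np.sum(strf.k_fh * true.k_fh) / (
            np.linalg.norm(strf.k_fh) * np.linalg.norm(true.k_fh))
        assert cos > 0.999
        z = predict(strf, d)
        assert np.corrcoef(z[d.mask], y[d.mask])[0, 1] > 0.999
        assert strf.k0 == pytest.approx(true.k0, abs=1e-6)

    def test_constant_response(self, rng):
        levels = rng.uniform(70, 90, (300, 10))
        d = build_design_tensor(levels, history_steps=4)
        strf, _ = fit_separable_strf(d, np.full(300, 7.0))
        assert strf.k0 == pytest.approx(7.0, abs=1e-8)
        assert np.max(np.abs(strf.k_fh)) < 1e-8

    def test_rank_one_property(self, rng):
        levels = rng.uniform(70, 90, (400, 12))
        d = build_design_tensor(levels, history_steps=8)
        y = rng.normal(10, 3, 400)
        strf, _ = fit_separable_strf(d, y)
        s = np.linalg.svd(strf.k_fh, compute_uv=False)
        assert s[1] < 1e-8 * s[0]
        assert np.linalg.norm(strf.k_h) == pytest.approx(1.0)
        assert strf.k_h[np.argmax(np.abs(strf.k_h))] > 0

    def test_error_nonincreasing_over_alternations(self, rng):
        levels = rng.uniform(70, 90, (300, 8))
        d = build_design_tensor(levels, history_steps=6)
        y = rng.normal(10, 3, 300)
        errs = []
        for k in (1, 2, 3, 5, 10):
            with np.errstate(all="ignore"):
                import warnings
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    _, rep = fit_separable_strf(d, y, max_iter=k)
            errs.append(rep.error)
        assert all(a >= b - 1e-9 for a, b in zip(errs, errs[1:]))

    def test_scale_invariance_of_prediction(self, rng):
        base = rng.uniform(-10, 10, (400, 6))
        true = SeparableSTRF(0.0, rng.normal(0, 1, 6),
                             np.eye(4)[0].astype(float))
        d1 = build_design_tensor(base, history_steps=4, exclude_chords=0)
        y = predict(true, d1)
        d2 = build_design_tensor(3.0 * base, history_steps=4, exclude_chords=0)
        s1, _ = fit_separable_strf(d1, y)
        s2, _ = fit_separable_strf(d2, y)
        assert np.allclose(s2.k_fh, s1.k_fh / 3.0, atol=1e-8)
        assert np.allclose(predict(s2, d2), predict(s1, d1), atol=1e-8)

    def test_als_matches_brute_force_rank1_of_full_ls(self, rng):
        # tiny noiseless rank-1 problem: the unconstrained LS kernel is the
        # true kernel, so its best rank-1 approximation must equal the ALS fit
        levels = rng.uniform(0, 1, (50, 2))
        d = build_design_tensor(levels, history_steps=2, exclude_chords=2)
        true = SeparableSTRF(1.0, np.array([2.0, -1.0]),
                             np.array([0.8, 0.6]))
        y = predict(true, d)
        strf, _ = fit_separable_strf(d, y)
        rows = d.X[d.mask].reshape(d.mask.sum(), -1)
        coef, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(len(rows)), rows]), y[d.mask], rcond=None)
        U, S, Vt = np.linalg.svd(coef[1:].reshape(2, 2))
        rank1 = S[0] * np.outer(U[:, 0], Vt[0])
        assert np.allclose(strf.k_fh, rank1, atol=1e-8)

    def test_too_few_rows_rejected(self, rng):
        levels = rng.uniform(70, 90, (30, 25))
        d = build_design_tensor(levels, history_steps=16, exclude_chords=0)
        with pytest.raises(ValueError, match="fewer"):
            fit_separable_strf(d, np.zeros(30))


class TestPredict:
    def test_zero_kernels_give_bias(self, rng):
        d = build_design_tensor(rng.uniform(0, 1, (20, 3)), history_steps=2,
                                exclude_chords=0)
        strf = SeparableSTRF(2.5, np.zeros(3), np.array([1.0, 0.0]))
        assert np.allclose(predict(strf, d), 2.5)

    def test_single_coefficient(self, rng):
        levels = rng.uniform(0, 1, (20, 3))
        d = build_design_tensor(levels, history_steps=2, exclude_chords=0)
        strf = SeparableSTRF(1.0, np.array([0.0, 4.0, 0.0]),
                            np.array([1.0, 0.0]))
        assert np.allclose(predict(strf, d), 1.0 + 4.0 * levels[:, 1])

    def test_hand_computed_toy(self):
        levels = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        d = build_design_tensor(levels, history_steps=2, exclude_chords=0)
        strf = SeparableSTRF(1.0, np.array([1.0, 2.0]), np.array([0.6, 0.8]))
        # row 2: X = [[5, 3], [6, 4]]; z = 1 + 1*(5*.6+3*.8) + 2*(6*.6+4*.8)
        assert predict(strf, d)[2] == pytest.approx(1.0 + 5.4 + 2 * 6.8)

    def test_shape_mismatch_rejected(self, rng):
        d = build_design_tensor(rng.uniform(0, 1, (20, 3)), history_steps=2)
        with pytest.raises(ValueError):
            predict(SeparableSTRF(0.0, np.zeros(4), np.array([1.0, 0.0])), d)


class TestScreening:
    def test_noiseless_linear_unit_is_predictive(self, design_pair):
        d, _ = design_pair
        y = predict(_toy_strf(), d)
        _, rep = cross_validated_cc(d, y)
        assert rep.cc_test > 0.999 and rep.predictive

    def test_null_ccs_centred_on_zero(self, design_pair, rng):
        # responses independent of the stimulus: CCs scatter around zero with
        # SD ~ 1/sqrt(n_test); the 0.04 criterion flags a modest fraction of
        # such units, consistent with the normal null
        d, _ = design_pair
        ccs = []
        for _ in range(30):
            y = rng.normal(40, 10, 1600).clip(0)
            _, rep = cross_validated_cc(d, y)
            ccs.append(rep.cc_test)
        ccs = np.array(ccs)
        n_test = d.mask.sum() - int(0.9 * d.mask.sum())
        assert abs(np.mean(ccs)) < 3.0 / np.sqrt(n_test * len(ccs))**0.5 + 0.05
        assert np.std(ccs) < 3.0 / np.sqrt(n_test)
        assert (ccs > 0.04).mean() < 0.6

    def test_anticorrelated_prediction_not_predictive(self, design_pair):
        d, _ = design_pair
        y = predict(_toy_strf(), d)
        strf_neg = SeparableSTRF(0.0, -_toy_strf().k_f, _toy_strf().k_h)
        z = predict(strf_neg, d)
        rows = np.flatnonzero(d.mask)
        test = rows[int(0.9 * len(rows)):]
        cc = np.corrcoef(z[test], y[test])[0, 1]
        assert cc == pytest.approx(-1.0, abs=1e-9)
        assert not (cc > 0.04)

    def test_zero_variance_test_marked_nonpredictive(self, design_pair):
        d, _ = design_pair
        rows = np.flatnonzero(d.mask)
        y = np.ones(1600)
        y[rows[: int(0.9 * len(rows))]] = np.random.default_rng(0).normal(
            5, 1, int(0.9 * len(rows)))
        _, rep = cross_validated_cc(d, y)
        assert np.isnan(rep.cc_test) and not rep.predictive


class TestCrossCondition:
    def test_pure_gain_change_preserves_cross_cc(self, design_pair, grid):
        d_low, d_high = design_pair
        unit = generate_unit(UnitSpec(noise_sd=0.0), seed=2, grid=grid)
        from contrastgain.gainmodel import sigmoid_eval
        y_high = sigmoid_eval(predict(unit.true_strf, d_high),
                              unit.sigmoid_high)
        strf_low, rep_low = cross_validated_cc(
            d_low, sigmoid_eval(predict(unit.true_strf, d_low),
                                unit.sigmoid_low))
        cc_cross = cross_condition_cc(strf_low, d_high, y_high)
        assert cc_cross == pytest.approx(rep_low.cc_test, abs=0.05)

    def test_unrelated_strf_gives_null_cc(self, design_pair, rng):
        d_low, d_high = design_pair
        true = _toy_strf()
        y_high = predict(true, d_high)
        shuffled = SeparableSTRF(true.k0, rng.permutation(true.k_f),
                                 true.k_h)
        # a shuffled frequency kernel shares no tuning with the generator
        cc = cross_condition_cc(shuffled, d_high, y_high)
        assert abs(cc) < 0.25


class TestTuningMetrics:
    def test_bf_is_argmax_frequency(self, grid):
        k_f = np.zeros(25)
        k_f[10] = 1.0
        strf = SeparableSTRF(0.0, k_f, np.eye(16)[0].astype(float))
        assert tuning_metrics(strf, grid).bf == grid.frequencies[10]

    def test_triangular_halfmax_bandwidth(self, grid):
        k_f = np.zeros(25)
        k_f[9:12] = [0.5, 1.0, 0.5]
        strf = SeparableSTRF(0.0, k_f, np.eye(16)[0].astype(float))
        assert tuning_metrics(strf, grid).bandwidth == pytest.approx(0.5)

    def test_integration_time_single_lag(self, grid):
        k_h = np.zeros(16)
        k_h[1] = 1.0
        k_f = np.zeros(25)
        k_f[5] = 1.0
        strf = SeparableSTRF(0.0, k_f, k_h)
        assert tuning_metrics(strf, grid).integration_time == pytest.approx(25.0)

    def test_largest_coeff(self, grid):
        strf = _toy_strf()
        m = tuning_metrics(strf, grid)
        assert m.largest_coeff == pytest.approx(np.max(np.abs(strf.k_fh)))

    def test_all_zero_kernel_rejected(self, grid):
        strf = SeparableSTRF(0.0, np.zeros(25), np.eye(16)[0].astype(float))
        with pytest.raises(ValueError, match="all-zero"):
            tuning_metrics(SeparableSTRF(0.0, np.zeros(25), np.zeros(16)),
                           grid)
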