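import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from mumri import pc_recovery as pc
from mumri import synthetic as syn
from mumri.core import DynamicSeries, MuscleMask


def curve_from_model(a, b, c, d, n=120, t_max=1200.0, noise_sd=0.0, seed=0):
    x = np.linspace(0.0, t_max, n)
    y = pc.gompertz(x, a, b, c, d)
    if noise_sd:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, y.shape)
    return pc.RecoveryCurve(x, y, np.arange(n), np.zeros(n))


class TestPhaseToVelocity:
    def test_linear_map(self):
        v, aliased = pc.phase_to_velocity(np.array([[np.pi / 2]]), venc=6.0)
        assert v[0, 0] == pytest.approx(3.0)
        assert not aliased

    def test_zero_phase(self):
        v, aliased = pc.phase_to_velocity(np.zeros((3, 3)), venc=6.0)
        assert np.all(v == 0.0) and not aliased

    def test_aliasing_flag(self):
        _, aliased = pc.phase_to_velocity(np.array([[1.1 * np.pi]]), venc=6.0)
        assert aliased

    def test_missing_venc(self):
        with pytest.raises(ValueError, match="venc"):
            pc.phase_to_velocity(np.zeros((2, 2)), venc=0.0)


class TestFindPeakLatency:
    @staticmethod
    def latency_velocity_series(center, axis=None):
        axis = np.arange(0.0, 121.0, 5.0) if axis is None else axis
        kernel = syn.latency_response_kernel(axis - center)
        data = np.zeros((6, 6, len(axis)))
        mask = np.zeros((6, 6), dtype=bool)
        mask[2:4, 2:4] = True
        data[mask, :] = 3.0 * kernel
        return DynamicSeries(data, axis, modality="pc_velocity"), MuscleMask(mask)

    def test_peak_at_kernel_centre(self):
        series, mask = self.latency_velocity_series(60.0)
        assert pc.find_peak_latency(series, mask) == pytest.approx(60.0, abs=2.5)

    def test_off_grid_peak_refined(self):
        series, mask = self.latency_velocity_series(62.0)
        assert pc.find_peak_latency(series, mask) == pytest.approx(62.0, abs=2.5)

    def test_tie_takes_earlier_latency(self):
        axis = np.arange(0.0, 100.0, 5.0)
        data = np.zeros((4, 4, len(axis)))
        data[:, :, 4] = 2.0
        data[:, :, 10] = 2.0
        series = DynamicSeries(data, axis, modality="pc_velocity")
        mask = MuscleMask(np.ones((4, 4), dtype=bool))
        with pytest.warns(UserWarning, match="earliest"):
            t = pc.find_peak_latency(series, mask)
        assert t == pytest.approx(axis[4])

    def test_all_zero_raises(self):
        axis = np.arange(0.0, 100.0, 5.0)
        series = DynamicSeries(np.zeros((4, 4, len(axis))), axis, modality="pc_velocity")
        with pytest.raises(ValueError, match="all-zero"):
            pc.find_peak_latency(series, MuscleMask(np.ones((4, 4), dtype=bool)))


class TestExtractCyclePeaks:
    def test_600_frames_give_120_samples(self):
        series, mask, _ = syn.simulate_pc_recovery_series(
            (5.0, 3.0, 0.01, 0.5), n_dynamics=600, grid_size=(8, 8)
        )
        curve = pc.extract_cycle_peaks(series, mask)
        assert curve.n_samples == 120

    def test_constant_series(self):
        axis = np.arange(25, dtype=float)
        data = np.full((4, 4, 25), 2.5)
        series = DynamicSeries(data, axis, time_unit="s", modality="pc_velocity")
        curve = pc.extract_cycle_peaks(series, MuscleMask(np.ones((4, 4), dtype=bool)))
        np.testing.assert_allclose(curve.values, 2.5)

    def test_noiseless_phantom_matches_truth_within_1pct(self):
        # d=0 keeps the per-frame relative growth of V below the latency
        # kernel falloff, so the central frame carries every cycle peak
        series, mask, truth = syn.simulate_pc_recovery_series(
            (5.0, 3.0, 0.01, 0.0), n_dynamics=300, grid_size=(8, 8)
        )
        curve = pc.extract_cycle_peaks(series, mask)
        np.testing.assert_allclose(curve.times, truth.time)
        sel = truth.v_true > 0
        np.testing.assert_allclose(
            curve.values[sel], truth.v_true[sel], rtol=0.01
        )

    def test_incomplete_trailing_cycle_dropped(self):
        axis = np.arange(23, dtype=float)
        data = np.random.default_rng(0).random((4, 4, 23))
        series = DynamicSeries(data, axis, time_unit="s", modality="pc_velocity")
        with pytest.warns(UserWarning, match="incomplete trailing cycle"):
            curve = pc.extract_cycle_peaks(series, MuscleMask(np.ones((4, 4), dtype=bool)))
        assert curve.n_samples == 4

    def test_cycle_longer_than_series_raises(self):
        axis = np.arange(3, dtype=float)
        series = DynamicSeries(np.zeros((4, 4, 3)), axis, time_unit="s")
        with pytest.raises(ValueError, match="cycle_length"):
            pc.extract_cycle_peaks(series, MuscleMask(np.ones((4, 4), dtype=bool)))

    @given(n=st.integers(5, 200), cycle=st.integers(1, 5))
    @settings(max_examples=20, deadline=None)
    def test_sample_count_is_floor_of_frames_over_cycle(self, n, cycle):
        axis = np.arange(n, dtype=float)
        data = np.zeros((2, 2, n))
        series = DynamicSeries(data, axis, time_unit="s", modality="pc_velocity")
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            curve = pc.extract_cycle_peaks(
                series, MuscleMask(np.ones((2, 2), dtype=bool)), cycle_length=cycle
            )
        assert curve.n_samples == n // cycle


class TestFitGompertz:
    def test_noiseless_exact_recovery(self):
        truth = (5.0, 3.0, 0.01, 0.5)
        fit = pc.fit_gompertz(curve_from_model(*truth))
        assert fit.converged
        for got, want in zip((fit.a, fit.b, fit.c, fit.d), truth):
            assert abs(got - want) / want < 1e-6
        assert fit.adjusted_r2 == pytest.approx(1.0, abs=1e-9)

    def test_constant_curve_flagged(self):
        x = np.linspace(0, 1200, 50)
        curve = pc.RecoveryCurve(x, np.full(50, 3.0), np.arange(50), np.zeros(50))
        fit = pc.fit_gompertz(curve)
        assert not fit.converged
        assert fit.a is None

    def test_too_few_samples_raises(self):
        with pytest.raises(ValueError, match="at least 8"):
            pc.fit_gompertz(curve_from_model(5, 3, 0.01, 0.5, n=5))

    def test_monte_carlo_recovery_under_noise(self):
        truth = (5.0, 3.0, 0.01, 0.5)
        thm_true = pc.half_max_time(*truth)
        a_err, thm_err = [], []
        for i in range(60):
            fit = pc.fit_gompertz(
                curve_from_model(*truth, noise_sd=0.05 * truth[0], seed=i), seed=i
            )
            a_err.append(abs(fit.a - truth[0]) / truth[0])
            thm_err.append(abs(fit.t_half_max - thm_true) / thm_true)
        assert np.median(a_err) < 0.05
        assert np.median(thm_err) < 0.10

    def test_bias_shrinks_with_noise(self):
        truth = (5.0, 3.0, 0.01, 0.5)
        thm_true = pc.half_max_time(*truth)
        med = []
        for noise in (0.2, 0.05, 0.0125):
            errs = [
                abs(
                    pc.fit_gompertz(
                        curve_from_model(*truth, noise_sd=noise, seed=i), seed=i
                    ).t_half_max
                    - thm_true
                )
                for i in range(25)
            ]
            med.append(np.median(errs))
        assert med[2] < med[0]

    def test_fitted_curve_monotone_when_bc_positive(self):
        fit = pc.fit_gompertz(curve_from_model(4.0, 2.0, 0.005, 0.1, noise_sd=0.1))
        xx = np.linspace(0, 1500, 2000)
        assert np.all(np.diff(fit.predict(xx)) >= 0)

    def test_five_parameter_variant(self):
        truth = (5.0, 3.0, 0.01, 0.5)
        fit = pc.fit_gompertz(curve_from_model(*truth), with_time_shift=True)
        assert fit.converged
        xx = np.linspace(0, 1200, 300)
        np.testing.assert_allclose(fit.predict(xx), pc.gompertz(xx, *truth), atol=1e-6)


class TestHalfMaxTime:
    def test_b_ln2_gives_zero(self):
        assert pc.half_max_time(1.0, np.log(2.0), 1.0, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_unit_params_match_frozen_numeric_value(self):
        # brentq oracle for a=b=c=1, d=0: y(T) = 1/2
        oracle = brentq(lambda t: pc.gompertz(t, 1, 1, 1, 0) - 0.5, -5, 10, xtol=1e-14)
        assert oracle == pytest.approx(0.36651292, abs=1e-8)
        assert pc.half_max_time(1.0, 1.0, 1.0, 0.0) == pytest.approx(oracle, abs=1e-10)

    def test_doubling_c_halves_time(self):
        t1 = pc.half_max_time(2.0, 5.0, 0.01, 0.0)
        t2 = pc.half_max_time(2.0, 5.0, 0.02, 0.0)
        assert t2 == pytest.approx(t1 / 2.0)

    def test_target_outside_range_raises(self):
        with pytest.raises(ValueError, match="outside"):
            pc.half_max_time(1.0, 1.0, 1.0, d=1.5)

    @given(
        a=st.floats(0.5, 10.0),
        b=st.floats(0.5, 20.0),
        c=st.floats(1e-3, 1e-1),
        frac=st.floats(0.0, 0.95),
        definition=st.sampled_from(["plateau_half", "range_half"]),
    )
    @settings(max_examples=60, deadline=None)
    def test_closed_form_matches_root_finder(self, a, b, c, frac, definition):
        d = frac * a / 2.0
        T = pc.half_max_time(a, b, c, d, definition=definition)
        if definition == "plateau_half":
            target = (a - d) / 2.0
        else:
            target = (pc.gompertz(0.0, a, b, c, d) + (a - d)) / 2.0
        lo, hi = -1e5, 1e6
        oracle = brentq(
            lambda t: pc.gompertz(t, a, b, c, d) - target, lo, hi, xtol=1e-12, rtol=8.9e-16
        )
        assert abs(T - oracle) <= 1e-9 / c + 1e-9 * abs(oracle)


class TestNormalizeCurve:
    def test_plateau_ends_near_one(self):
        curve = curve_from_model(4.0, 3.0, 0.01, 0.0)
        norm = pc.normalize_curve(curve)
        assert norm.normalization == "end_normalized"
        assert norm.values[-1] == pytest.approx(1.0, abs=0.01)

    def test_idempotent(self):
        curve = curve_from_model(4.0, 3.0, 0.01, 0.0)
        once = pc.normalize_curve(curve)
        twice = pc.normalize_curve(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-12)

    def test_phantom_gompertz_plateau_within_1pct(self):
        curve = curve_from_model(5.0, 3.0, 0.005, 0.2, n=120, t_max=1500.0)
        norm = pc.normalize_curve(curve)
        tail = norm.values[-12:]
        assert np.all(np.abs(tail - 1.0) < 0.01)

    def test_nonpositive_end_mean_raises(self):
        x = np.arange(10, dtype=float)
        curve = pc.RecoveryCurve(x, -np.ones(10), np.arange(10), np.zeros(10))
        with pytest.raises(ValueError, match="not positive"):
            pc.normalize_curve(curve)

    def test_too_few_samples_raises(self):
        x = np.arange(4, dtype=float)
        curve = pc.RecoveryCurve(x, np.ones(4), np.arange(4), np.zeros(4))
        with pytest.raises(ValueError, match="at least 5"):
            pc.normalize_curve(curve)


class TestMonoExponential:
    @staticmethod
    def series_from(rate, y_end=10.0, amp=5.0, n=60, t_max=300.0, noise_sd=0.0, seed=0):
        t = np.linspace(0.0, t_max, n)
        y = y_end - amp * np.exp(-rate * t)
        if noise_sd:
            y = y + np.random.default_rng(seed).normal(0, noise_sd, y.shape)
        return t, y

    def test_exact_parameter_recovery(self):
        t, y = self.series_from(0.02)
        fit = pc.fit_monoexponential(t, y)
        assert fit.recovering
        assert fit.rate == pytest.approx(0.02, abs=1e-9)
        assert fit.y_end == pytest.approx(10.0, abs=1e-9)
        assert fit.amplitude == pytest.approx(5.0, abs=1e-9)

    def test_metabolite_scale_half_time(self):
        t, y = self.series_from(0.0107, n=80, t_max=400.0)
        fit = pc.fit_monoexponential(t, y)
        assert fit.half_time == pytest.approx(np.log(2) / 0.0107, rel=1e-6)
        assert 38.0 < fit.half_time < 92.0  # healthy-control scale (65 +/- 27 s)

    def test_monte_carlo_recovery(self):
        errs = []
        for i in range(100):
            t, y = self.series_from(0.02, noise_sd=0.25, seed=i)  # 5% of amplitude
            fit = pc.fit_monoexponential(t, y)
            errs.append(abs(fit.rate - 0.02) / 0.02)
        assert np.median(errs) < 0.05

    def test_non_recovering_flagged(self):
        t = np.linspace(0, 300, 30)
        y = 10.0 - 0.01 * t  # declining series
        fit = pc.fit_monoexponential(t, y)
        assert not fit.recovering
        assert fit.rate is None and fit.half_time is None

    def test_too_few_samples_raises(self):
        with pytest.raises(ValueError, match="at least 6"):
            pc.fit_monoexponential([0, 1, 2], [1, 2, 3])


class TestEndToEndRecovery:
    def test_pipeline_recovers_t_half_max_at_5pct_noise(self):
        truth = (5.0, 3.0, 0.01, 0.2)
        thm_true = pc.half_max_time(*truth)
        series, mask, _ = syn.simulate_pc_recovery_series(
            truth, n_dynamics=600, noise_sd=0.05 * truth[0], rng_seed=21,
            grid_size=(16, 16),
        )
        curve = pc.extract_cycle_peaks(series, mask)
        fit = pc.fit_gompertz(curve, seed=0)
        assert fit.converged
        assert abs(fit.t_half_max - thm_true) / thm_true < 0.10
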