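"""Unit tests for the accelerometer gait-parameter pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitmix.errors import (
    DegenerateInputError,
    InconsistentEventsError,
    InsufficientStepsError,
    NoPeriodicityError,
    ParameterError,
)
from gaitmix.sensor import (
    Autocorrelation,
    acceleration_rms,
    autocorr_unbiased,
    detect_steps,
    extract_sensor_features,
    regularity_symmetry,
    resample_uniform,
    temporal_features,
    vertical_component,
)
from gaitmix.synthetic import PULSE_WIDTH_FRAC, GaitSimParams, simulate_accelerometer
from gaitmix.types import AccelerometerRecording, UniformSignal


def make_recording(t, cols):
    return AccelerometerRecording(timestamps=t, acceleration=np.column_stack(cols))


class TestResample:
    def test_uniform_input_is_identity_on_shared_grid(self):
        t = np.arange(0, 10.0, 0.01)
        x = np.sin(t)
        rec = make_recording(t, [x, x, x])
        res = resample_uniform(rec, 100.0)
        np.testing.assert_allclose(res.samples[:, 0], x[: res.samples.shape[0]], atol=1e-12)

    def test_grid_point_count_inclusive_endpoints(self):
        t = np.linspace(0.0, 30.0, 1100)
        rec = make_recording(t, [t, t, t])
        res = resample_uniform(rec, 100.0)
        assert res.samples.shape[0] == 3001

    def test_linear_ramp_exact(self):
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 10, 400))
        t[0], t[-1] = 0.0, 10.0
        rec = make_recording(t, [2 * t, 3 * t, -t])
        res = resample_uniform(rec, 100.0)
        grid = res.origin + np.arange(res.samples.shape[0]) / res.rate
        np.testing.assert_allclose(res.samples[:, 0], 2 * grid, atol=1e-9)

    def test_non_monotonic_timestamps_rejected(self):
        from gaitmix.errors import FormatError

        with pytest.raises(FormatError):
            make_recording(np.array([0.0, 1.0, 0.5]), [np.zeros(3)] * 3)


class TestVerticalComponent:
    def test_picks_gravity_dominant_channel_and_demeans(self):
        t = np.arange(0, 10.0, 0.01)
        rec = make_recording(
            t, [0.01 * np.cos(t), 0.02 * np.sin(3 * t), 9.81 + np.sin(2 * t)]
        )
        res = resample_uniform(rec, 100.0)
        vert, axis = vertical_component(res)
        assert axis == "az"
        assert abs(vert.samples.mean()) < 1e-12

    def test_constant_gravity_gives_zero_signal(self):
        t = np.arange(0, 10.0, 0.025)
        rec = make_recording(t, [np.full_like(t, 9.81)] * 3)
        vert, _ = vertical_component(resample_uniform(rec, 100.0))
        np.testing.assert_allclose(vert.samples, 0.0, atol=1e-9)

    def test_all_zero_channels_rejected(self):
        t = np.arange(0, 10.0, 0.025)
        rec = make_recording(t, [np.zeros_like(t)] * 3)
        with pytest.raises(DegenerateInputError):
            vertical_component(resample_uniform(rec, 100.0))

    def test_generator_vertical_axis_always_selected(self):
        for seed in range(20):
            sim = simulate_accelerometer(GaitSimParams(seed=seed))
            _, axis = vertical_component(resample_uniform(sim.recording, 100.0))
            assert axis == sim.vertical_axis


class TestRms:
    def test_sine_rms_closed_form(self):
        t = np.arange(0, 30.0, 0.01)
        a = 2.5
        sig = UniformSignal(rate=100.0, samples=a * np.sin(2 * np.pi * 2 * t))
        assert acceleration_rms(sig) == pytest.approx(a / np.sqrt(2), rel=0.01)

    def test_zero_signal(self):
        sig = UniformSignal(rate=100.0, samples=np.zeros(100))
        assert acceleration_rms(sig) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(DegenerateInputError):
            acceleration_rms(UniformSignal(rate=100.0, samples=np.array([])))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_invariant_to_time_reversal_and_sign_flip(self, seed):
        x = np.random.default_rng(seed).standard_normal(256)
        r = acceleration_rms(UniformSignal(rate=50.0, samples=x))
        assert acceleration_rms(UniformSignal(rate=50.0, samples=x[::-1])) == pytest.approx(r)
        assert acceleration_rms(UniformSignal(rate=50.0, samples=-x)) == pytest.approx(r)


class TestDetectSteps:
    def test_sine_one_peak_per_cycle(self):
        t = np.arange(0, 10.0, 0.01)
        sig = UniformSignal(rate=100.0, samples=np.sin(2 * np.pi * 2 * t))
        events = detect_steps(sig)
        assert 19 <= events.size <= 20
        np.testing.assert_allclose(np.diff(events), 0.5, atol=0.02)

    def test_generator_truth_recovered_within_50ms(self):
        hits, total = 0, 0
        for seed in range(10):
            sim = simulate_accelerometer(GaitSimParams(seed=seed))
            vert, _ = vertical_component(resample_uniform(sim.recording, 100.0))
            events = detect_steps(vert)
            d = np.min(np.abs(events[:, None] - sim.step_times[None, :]), axis=1)
            hits += int((d <= 0.05).sum())
            total += events.size
        assert hits / total >= 0.95

    def test_white_noise_fails_detection_or_downstream_sanity(self):
        from gaitmix.errors import GaitmixError

        for seed in range(5):
            rng = np.random.default_rng(seed)
            t = np.arange(0, 30.0, 0.025)
            rec = make_recording(
                t,
                [rng.standard_normal(t.size) for _ in range(2)]
                + [9.81 + rng.standard_normal(t.size)],
            )
            try:
                res = extract_sensor_features(rec)
            except GaitmixError:
                continue  # detection or periodicity stage rejected the noise
            # if events were found, the gait metrics must flag the signal
            f = res.features
            assert f.step_regularity < 0.3 or f.step_variability > 0.25


class TestTemporalFeatures:
    def test_exact_regular_events(self):
        events = np.arange(0.0, 10.01, 0.5)
        freq, cv = temporal_features(events)
        assert freq == pytest.approx(2.0)
        assert cv == pytest.approx(0.0)

    def test_too_few_events(self):
        with pytest.raises(InsufficientStepsError):
            temporal_features(np.array([0.0, 1.0]))

    def test_non_increasing_events(self):
        with pytest.raises(InconsistentEventsError):
            temporal_features(np.array([0.0, 1.0, 1.0, 2.0]))

    def test_recovers_injected_interval_cv(self):
        cvs = []
        for seed in range(10):
            sim = simulate_accelerometer(
                GaitSimParams(timing_jitter_cv=0.12, seed=seed)
            )
            vert, _ = vertical_component(resample_uniform(sim.recording, 100.0))
            _, cv = temporal_features(detect_steps(vert))
            cvs.append(cv)
        assert np.mean(cvs) == pytest.approx(0.12, abs=0.03)


def acf_bruteforce(x: np.ndarray, k_max: int) -> np.ndarray:
    """O(N^2) double-loop unbiased normalized autocorrelation (oracle)."""
    x = np.asarray(x, float)
    x = x - x.mean()
    n = x.size
    r = np.empty(k_max + 1)
    for k in range(k_max + 1):
        s = 0.0
        for i in range(n - k):
            s += x[i] * x[i + k]
        r[k] = s / (n - k)
    return r / np.mean(x * x)


class TestAutocorr:
    def test_lag_zero_is_exactly_one(self, default_gait_sim):
        vert, _ = vertical_component(resample_uniform(default_gait_sim.recording, 100.0))
        acf = autocorr_unbiased(vert, 2.0)
        assert acf.coef[0] == 1.0

    def test_periodic_signal_peak_at_period(self):
        t = np.arange(0, 30.0, 0.01)
        sig = UniformSignal(rate=100.0, samples=np.sin(2 * np.pi * 2 * t))
        acf = autocorr_unbiased(sig, 1.0)
        assert acf.coef[50] >= 0.99  # one period = 0.5 s = 50 lags

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(8)
        x = np.cumsum(rng.standard_normal(300))
        sig = UniformSignal(rate=100.0, samples=x)
        acf = autocorr_unbiased(sig, 1.0)
        expected = acf_bruteforce(x, 100)
        np.testing.assert_allclose(acf.coef, expected, atol=1e-10)

    def test_white_noise_coefficients_small_beyond_quarter_second(self):
        # sampling theory: sd ~ 1/sqrt(N - k) ~ 0.019, so 0.05 is ~2.6 sigma;
        # at least 95% of coefficients beyond 0.25 s must stay inside it
        inside, total = 0, 0
        for seed in range(20):
            x = np.random.default_rng(seed).standard_normal(3000)
            acf = autocorr_unbiased(UniformSignal(rate=100.0, samples=x), 3.0)
            inside += int((np.abs(acf.coef[25:]) < 0.05).sum())
            total += acf.coef[25:].size
        assert inside / total >= 0.95

    def test_max_lag_bounds_enforced(self):
        sig = UniformSignal(rate=100.0, samples=np.sin(np.arange(1000) * 0.1))
        with pytest.raises(ParameterError):
            autocorr_unbiased(sig, 6.0)  # span ~10 s, limit is span/2

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            autocorr_unbiased(UniformSignal(rate=100.0, samples=np.ones(1000)), 2.0)


class TestRegularitySymmetry:
    def test_clean_periodic_signal_near_one(self, clean_gait_sim):
        res = extract_sensor_features(clean_gait_sim.recording)
        assert res.features.step_regularity == pytest.approx(1.0, abs=0.02)
        assert res.features.step_symmetry == pytest.approx(1.0, abs=0.02)

    def test_no_periodicity_raises(self):
        # an aperiodic, quickly-decaying acf has no peak in the step window
        coef = np.exp(-np.arange(400) / 5.0)
        acf = Autocorrelation(rate=100.0, coef=coef)
        with pytest.raises(NoPeriodicityError):
            regularity_symmetry(acf, 0.57)

    def test_symmetry_bounded_in_unit_interval(self):
        for seed in range(10):
            sim = simulate_accelerometer(GaitSimParams(asymmetry=0.4, seed=seed))
            res = extract_sensor_features(sim.recording)
            assert 0.0 <= res.features.step_symmetry <= 1.0
            assert res.features.step_regularity <= 1.0 + 1e-9


class TestExtractSensorFeatures:
    def test_clean_trace_composition(self, clean_gait_params, clean_gait_sim):
        res = extract_sensor_features(clean_gait_sim.recording)
        f = res.features
        assert f.step_frequency == pytest.approx(clean_gait_params.step_frequency, rel=0.02)
        assert f.step_variability == pytest.approx(0.0, abs=0.02)
        assert f.step_regularity == pytest.approx(1.0, abs=0.02)
        assert f.step_symmetry == pytest.approx(1.0, abs=0.02)
        # analytic RMS of a mean-removed Gaussian pulse train
        fstep = clean_gait_params.step_frequency
        sigma = PULSE_WIDTH_FRAC / fstep
        a = clean_gait_params.step_amplitude
        ex2 = fstep * sigma * np.sqrt(np.pi) * a**2
        ex = fstep * sigma * np.sqrt(2 * np.pi) * a
        assert f.rms == pytest.approx(np.sqrt(ex2 - ex**2), rel=0.05)

    def test_short_recording_rejected(self):
        sim = simulate_accelerometer(GaitSimParams(duration=8.0, seed=1))
        with pytest.raises(DegenerateInputError):
            extract_sensor_features(sim.recording)

    def test_qc_reports_step_lag_consistent_with_cadence(self, default_gait_sim):
        res = extract_sensor_features(default_gait_sim.recording)
        assert res.qc.ad1_lag_s == pytest.approx(1 / res.features.step_frequency, rel=0.25)
        assert res.qc.vertical_axis == "az"
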