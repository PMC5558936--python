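"""Kinematic extraction: filtering, differentiation, segmentation, parameters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import imitkin as ik
from imitkin.kinematics import SegmentationError, exclude_errors

from conftest import minjerk_series


def _sine_traj(freq, rate=120.0, seconds=2.0):
    t = np.arange(int(seconds * rate)) / rate
    x = np.sin(2 * np.pi * freq * t)
    return ik.Trajectory(t, x, np.zeros_like(t), np.zeros_like(t), rate)


class TestLowpassFilter:
    def test_dc_passthrough(self):
        t = np.arange(120) / 120.0
        const = np.full(120, 7.5)
        traj = ik.Trajectory(t, const, const, const)
        out = ik.lowpass_filter(traj)
        assert np.allclose(out.x, const, atol=1e-9)

    @pytest.mark.parametrize(
        "freq,check",
        [
            (2.0, lambda amp: abs(amp - 1.0) < 0.01),  # passband: gain 1/(1+(f/fc)^4) = 0.9984
            (50.0, lambda amp: amp < 0.05),  # stopband: gain 1/626
        ],
    )
    def test_band_gains(self, freq, check):
        out = ik.lowpass_filter(_sine_traj(freq), cutoff=10.0, order=2)
        amp = np.abs(out.x[60:-60]).max()  # steady-state portion
        assert check(amp)

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="cutoff"):
            ik.lowpass_filter(_sine_traj(2.0), cutoff=60.0)


class TestDifferentiate:
    def test_linear_ramp_velocity(self):
        t = np.arange(48) / 120.0
        traj = ik.Trajectory(t, 100.0 * t, np.zeros_like(t), np.zeros_like(t))
        v, _, _ = ik.differentiate(traj)
        assert np.allclose(v, 100.0)

    def test_quadratic_acceleration(self):
        t = np.arange(48) / 120.0
        traj = ik.Trajectory(t, t**2, np.zeros_like(t), np.zeros_like(t))
        _, a, _ = ik.differentiate(traj)
        # first/last interior points inherit the one-sided endpoint estimates
        assert np.allclose(a[2:-2], 2.0)

    def test_minjerk_peak_velocity_closed_form(self):
        D, A = 1.25, 150.0
        t, x = minjerk_series(D, A)
        traj = ik.Trajectory(t, x, np.zeros_like(t), np.zeros_like(t))
        v, _, _ = ik.differentiate(traj)
        assert np.abs(v).max() == pytest.approx(1.875 * A / D, rel=0.01)


def oracle_bounds(velocity, threshold_fraction=0.1, run_length=6):
    """Exhaustive window-scan oracle for onset/offset detection."""
    speed = np.abs(np.asarray(velocity, float))
    thr = threshold_fraction * speed.max()
    above = speed > thr
    n = len(above)
    onsets = [i for i in range(n - run_length + 1) if above[i : i + run_length].all()]
    if not onsets:
        raise SegmentationError("oracle: no onset")
    peak = int(np.argmax(speed))
    belows = [
        i for i in range(peak + 1, n - run_length + 1) if (~above[i : i + run_length]).all()
    ]
    if not belows:
        raise SegmentationError("oracle: no offset")
    return onsets[0], belows[0] - 1


class TestDetectBounds:
    def test_triangular_profile_matches_oracle(self):
        v = np.concatenate([np.linspace(0, 100, 61), np.linspace(100, 0, 61)[1:]])
        got = ik.detect_bounds(v)
        assert got == oracle_bounds(v)
        onset, offset = got
        assert onset < np.argmax(v) <= offset

    def test_all_zero_velocity_fails(self):
        with pytest.raises(SegmentationError):
            ik.detect_bounds(np.zeros(120))

    def test_short_spikes_before_onset_ignored(self):
        v = np.zeros(240)
        v[120:181] = np.sin(np.linspace(0, np.pi, 61)) * 100.0  # true movement
        clean = ik.detect_bounds(v)
        rng = np.random.default_rng(5)
        for start in rng.choice(np.arange(5, 100, 12), 5, replace=False):
            v[start : start + 3] = 40.0  # isolated 3-sample spikes, sub-run-length
        assert ik.detect_bounds(v) == clean == oracle_bounds(v)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(0, 10_000))
    def test_random_profiles_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        v = np.convolve(rng.normal(size=150), np.ones(8) / 8, mode="same")
        try:
            expected = oracle_bounds(v)
        except SegmentationError:
            with pytest.raises(SegmentationError):
                ik.detect_bounds(v)
        else:
            assert ik.detect_bounds(v) == expected


class TestExtractKinematics:
    def test_symmetric_profile_peak_at_half_time(self, tn_noiseless):
        kv = ik.extract_kinematics(tn_noiseless)
        tol = 100.0 / (kv.duration * 120.0)  # one sample of slack
        assert abs(kv.percent_time_before_peak_velocity - 50.0) <= tol + 1e-9
        assert kv.percent_time_before_peak_velocity + kv.percent_time_after_peak_velocity == 100.0

    def test_window_matches_threshold_crossing_analytics(self, tn_noiseless):
        # 10% crossing of the min-jerk speed profile: tau(1-tau) = sqrt(0.1*1.875/30)
        root = (1 - np.sqrt(1 - 4 * np.sqrt(0.1 * 1.875 / 30))) / 2
        D = 1.25
        expected_duration = (1 - 2 * root) * D
        kv = ik.extract_kinematics(tn_noiseless)
        assert abs(kv.duration - expected_duration) <= 2 / 120.0
        assert kv.peak_velocity == pytest.approx(1.875 * 150.0 / D, rel=0.01)

    def test_dimensionless_jerk_matches_integration_oracle(self, tn_noiseless):
        # numeric oracle: -(Dw^3/v^2) * integral of squared min-jerk jerk over
        # the analytic 10%-threshold window
        D, A = 1.25, 150.0
        root = (1 - np.sqrt(1 - 4 * np.sqrt(0.1 * 1.875 / 30))) / 2
        tau = np.linspace(root, 1 - root, 20001)
        j = A / D**3 * (60 - 360 * tau + 360 * tau**2)
        Dw = (1 - 2 * root) * D
        oracle = -(Dw**3) / (1.875 * A / D) ** 2 * np.trapezoid(j**2, tau * D)
        kv = ik.extract_kinematics(tn_noiseless)
        assert kv.dimensionless_jerk == pytest.approx(oracle, rel=0.02)

    def test_ordering_invariant(self, tn_noiseless):
        kv = ik.extract_kinematics(tn_noiseless)
        assert 0 < kv.time_to_peak_velocity <= kv.duration
        assert 0.0 <= kv.percent_peak_velocity_location <= 100.0

    def test_central_vertical_bump_recovered(self):
        # y is a narrow raised-cosine bump (height h) over the central third;
        # zero at onset, so the extracted vertical amplitude is exactly h.
        t, x = minjerk_series(1.25, 150.0)
        n = len(t)
        y = np.zeros(n)
        mid = slice(n // 3, 2 * n // 3)
        h = 42.0
        y[mid] = h * 0.5 * (1 - np.cos(np.linspace(0, 2 * np.pi, y[mid].size)))
        pad = np.zeros(36)
        t_full = np.arange(n + 72) / 120.0
        traj = ik.Trajectory(
            t_full, np.concatenate([pad, x, pad + x[-1]]),
            np.concatenate([pad, y, pad]), np.zeros(n + 72),
        )
        kv = ik.extract_kinematics(traj)
        assert kv.vertical_amplitude == pytest.approx(h, rel=0.02)
        assert kv.percent_location_of_peak_vertical_amplitude == pytest.approx(50.0, abs=3.0)
        assert kv.percent_time_of_peak_vertical_amplitude == pytest.approx(50.0, abs=3.0)

    def test_filter_idempotence_on_bandlimited_input(self, tn_noiseless):
        once = ik.lowpass_filter(tn_noiseless)
        twice = ik.lowpass_filter(once)
        kv1 = ik.extract_kinematics(once, prefiltered=True)
        kv2 = ik.extract_kinematics(twice, prefiltered=True)
        assert np.allclose(kv1.as_array(), kv2.as_array(), rtol=0.005, atol=0.9)

    def test_zero_phase_preserves_peak_time(self, tn_noiseless):
        raw = ik.extract_kinematics(tn_noiseless, prefiltered=True)
        filt = ik.extract_kinematics(tn_noiseless)
        assert abs(raw.time_to_peak_velocity - filt.time_to_peak_velocity) <= 1 / 120.0 + 1e-9


class TestDimensionlessJerk:
    def test_minjerk_attains_analytic_optimum(self):
        D, A = 1.25, 150.0
        tau = np.linspace(0, 1, 5001)
        j = A / D**3 * (60 - 360 * tau + 360 * tau**2)
        # closed form: -(D^3/v^2) * 720 A^2/D^5 = -720/1.875^2 = -204.8
        assert ik.dimensionless_jerk(j, D, 1.875 * A / D) == pytest.approx(-204.8, rel=1e-3)

    def test_zero_jerk_gives_zero(self):
        assert ik.dimensionless_jerk(np.zeros(100), 1.0, 100.0) == 0.0

    def test_more_noise_is_less_smooth(self):
        spec = ik.make_condition_spec("TN")
        deltas = []
        for seed in range(50):
            vals = []
            for noise in (0.5, 1.0):
                traj = ik.simulate_trial(
                    spec, noise_sd=noise, rng=np.random.default_rng(seed), jitter_scale=0.0
                )
                vals.append(ik.extract_kinematics(traj).dimensionless_jerk)
            deltas.append(vals[1] - vals[0])
        assert np.mean(deltas) < 0  # doubling noise decreases (more negative) on average

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            ik.dimensionless_jerk(np.ones(10), 0.0, 100.0)
        with pytest.raises(ValueError):
            ik.dimensionless_jerk(np.ones(10), 1.0, 0.0)


class TestAggregate:
    def test_identical_vectors_zero_sd(self, tn_noiseless):
        kv = ik.extract_kinematics(tn_noiseless)
        agg = ik.aggregate([kv] * 8, "P1", "control", "TN")
        assert np.allclose(agg.sd_vector, 0.0)
        assert agg.n_trials_used == 8

    def test_hand_arithmetic(self, tn_noiseless):
        kvs = []
        for d in (1.0, 2.0, 3.0):
            kv = ik.extract_kinematics(tn_noiseless)
            kv.duration = d
            kvs.append(kv)
        agg = ik.aggregate(kvs)
        assert agg.mean_vector[0] == pytest.approx(2.0)
        assert agg.sd_vector[0] == pytest.approx(1.0)

    def test_against_streaming_oracle(self, tn_noiseless):
        rng = np.random.default_rng(3)
        kvs = []
        for _ in range(8):
            kv = ik.extract_kinematics(tn_noiseless)
            for f in ik.kinematics.PARAMETER_FIELDS:
                setattr(kv, f, float(rng.normal()))
            kvs.append(kv)
        agg = ik.aggregate(kvs)
        # Welford's streaming mean/variance as the independent check
        mean = np.zeros(20)
        m2 = np.zeros(20)
        for i, kv in enumerate(kvs, start=1):
            x = kv.as_array()
            delta = x - mean
            mean += delta / i
            m2 += delta * (x - mean)
        assert np.allclose(agg.mean_vector, mean, atol=1e-12)
        assert np.allclose(agg.sd_vector, np.sqrt(m2 / (len(kvs) - 1)), atol=1e-12)

    def test_too_few_trials_rejected(self, tn_noiseless):
        with pytest.raises(ValueError, match=">= 2"):
            ik.aggregate([ik.extract_kinematics(tn_noiseless)])


class _FakeTrial:
    def __init__(self, group, flag, tid):
        self.group, self.error_flag, self.trial_id = group, flag, tid


class TestExcludeErrors:
    def test_reported_percentages(self):
        trials = [_FakeTrial("ASC", "recording" if i < 6 else None, ("A", "TN", i)) for i in range(100)]
        trials += [_FakeTrial("control", None, ("C", "TN", i)) for i in range(50)]
        kept, report = exclude_errors(trials)
        assert report["ASC"]["percent_excluded"] == pytest.approx(6.0)
        assert report["control"]["percent_excluded"] == 0.0
        assert len(kept) == 144

    def test_no_flags_is_identity(self):
        trials = [_FakeTrial("ASC", None, ("A", "TN", i)) for i in range(10)]
        kept, _ = exclude_errors(trials)
        assert kept == trials

    def test_segmentation_failures_also_excluded(self):
        trials = [_FakeTrial("ASC", None, ("A", "TN", i)) for i in range(10)]
        kept, report = exclude_errors(trials, extra_failed_ids={("A", "TN", 0)})
        assert len(kept) == 9
        assert report["ASC"]["n_excluded"] == 1
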