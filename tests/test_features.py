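"""The descriptive-variable battery: per-operation oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import coordkin as ck
from coordkin.features import (
    DegenerateSegmentError,
    Segment,
    anchoring_index,
    angular_speed_stats,
    count_peaks,
    dtw_distance,
    head_torso_correlation,
    iqr_amplitude,
    reject_discontinuities,
    spectral_arc_length,
    speed_ratio,
    split_segments,
    xcorr_peak_time,
)
from coordkin.io_model import SAMPLE_PERIOD

from conftest import make_series

DT = SAMPLE_PERIOD


def dtw_oracle(a, b):
    """Exhaustive top-down DP over all warping paths (independent of the
    wavefront implementation)."""
    import functools

    a = list(map(float, a))
    b = list(map(float, b))

    @functools.lru_cache(maxsize=None)
    def rec(i, j):
        c = abs(a[i] - b[j])
        if i == 0 and j == 0:
            return c
        best = float("inf")
        if i > 0:
            best = min(best, rec(i - 1, j))
        if j > 0:
            best = min(best, rec(i, j - 1))
        if i > 0 and j > 0:
            best = min(best, rec(i - 1, j - 1))
        return c + best

    return rec(len(a) - 1, len(b) - 1)


class TestSegmentation:
    def test_26_coin_course_gives_25_segments(self):
        course = ck.generate_course(26, seed=2)
        trial = ck.simulate_flight_trial(ck.SynthConfig(seed=2, noise_sd=0.5), course)
        segs = split_segments(trial, course)
        assert len(segs) == 25

    def test_durations_partition_the_course_time(self, small_course, clean_flight):
        segs = split_segments(clean_flight, small_course)
        total = segs[-1].t_end - segs[0].t_start
        assert sum(s.duration for s in segs) == pytest.approx(total, abs=1e-9)

    def test_straight_constant_speed_spans_take_58_over_12_s(self, straight_course):
        trial = ck.simulate_flight_trial(
            ck.SynthConfig(seed=0, noise_sd=0.0, lag_tau=0.15), straight_course
        )
        segs = split_segments(trial, straight_course)
        for s in segs[1:]:
            assert s.duration == pytest.approx(58.0 / 12.0, rel=0.03)


class TestRejection:
    def _segment(self, head, torso):
        t = DT * np.arange(len(head))
        return Segment(
            head=make_series(t, roll=head),
            torso=make_series(t, roll=torso),
            t_start=0.0, t_end=float(t[-1]), coin_index=1,
            error=0.0, missed=False,
        )

    def test_smooth_traces_kept(self):
        x = 10 * np.sin(np.linspace(0, 6 * np.pi, 200))  # max step ~ 1 deg
        assert reject_discontinuities(self._segment(x, x)).valid

    def test_injected_25_degree_jump_rejected(self):
        x = np.zeros(50)
        x[20:] += 25.0
        assert not reject_discontinuities(self._segment(x, np.zeros(50))).valid

    def test_exact_20_degree_step_kept(self):
        x = np.zeros(50)
        x[20:] += 20.0
        assert reject_discontinuities(self._segment(x, np.zeros(50))).valid

    def test_torso_jump_also_rejects(self):
        x = np.zeros(50)
        x[10:] += 30.0
        assert not reject_discontinuities(self._segment(np.zeros(50), x)).valid


class TestAmplitudeAndSpeed:
    def test_iqr_constant_trace_is_zero(self):
        assert iqr_amplitude(np.full(10, 3.3)) == 0.0

    def test_iqr_linear_ramp_0_100(self):
        # sorted 0..100: Q3 - Q1 = 75 - 25 with interpolation quantiles
        assert iqr_amplitude(np.arange(101.0)) == pytest.approx(50.0)

    def test_iqr_offset_invariant(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 5, 50)
        assert iqr_amplitude(x + 17.0) == pytest.approx(iqr_amplitude(x), abs=1e-12)

    def test_iqr_needs_four_samples(self):
        with pytest.raises(DegenerateSegmentError):
            iqr_amplitude(np.array([1.0, 2.0]))

    def test_speed_of_constant_trace_is_zero(self, grid):
        s = angular_speed_stats(make_series(grid, roll=np.full(grid.size, 4.0)))
        assert s["mean_roll"] == 0.0 and s["max_roll"] == 0.0

    def test_speed_of_ramp_is_slope(self, grid):
        s = angular_speed_stats(make_series(grid, yaw=5.0 * grid))
        assert s["mean_yaw"] == pytest.approx(5.0)
        assert s["max_yaw"] == pytest.approx(5.0)

    def test_sinusoid_max_rate_near_2pifA(self):
        f, A = 1.0, 10.0
        t = DT * np.arange(int(5.0 / DT))
        s = angular_speed_stats(make_series(t, pitch=A * np.sin(2 * np.pi * f * t)))
        assert s["max_pitch"] == pytest.approx(2 * np.pi * f * A, rel=0.02)

    def test_norm_combines_axes(self, grid):
        s = angular_speed_stats(
            make_series(grid, pitch=3.0 * grid, roll=4.0 * grid)
        )
        assert s["mean_norm"] == pytest.approx(5.0)


class TestCorrelationAndAnchoring:
    def test_identical_traces_correlate_fully(self):
        x = np.sin(np.linspace(0, 10, 100))
        assert head_torso_correlation(x, x) == pytest.approx(1.0)

    def test_sign_flip_still_one(self):
        x = np.sin(np.linspace(0, 10, 100))
        assert head_torso_correlation(x, -x) == pytest.approx(1.0)

    def test_orthogonal_sin_cos_near_zero(self):
        t = np.linspace(0, 4 * 2 * np.pi, 4 * 360, endpoint=False)
        r = head_torso_correlation(np.sin(t), np.cos(t))
        assert r == pytest.approx(0.0, abs=1e-6)

    def test_flat_trace_gives_nan(self):
        assert np.isnan(head_torso_correlation(np.zeros(10), np.arange(10.0)))

    def test_head_fixed_in_space_gives_plus_one(self):
        torso = np.sin(np.linspace(0, 10, 200))
        assert anchoring_index(np.zeros(200), torso) == pytest.approx(1.0)

    def test_head_locked_to_torso_gives_minus_one(self):
        torso = 10 * np.sin(np.linspace(0, 10, 200))
        assert anchoring_index(torso + 5.0, torso) == pytest.approx(-1.0)

    def test_equal_variability_gives_zero(self):
        # head = torso/2: sd(head) = sd(head - torso) exactly
        torso = np.sin(np.linspace(0, 10, 500))
        head = torso / 2
        assert anchoring_index(head, torso) == pytest.approx(0.0, abs=1e-12)

    def test_shared_offset_invariance(self):
        rng = np.random.default_rng(1)
        head, torso = rng.normal(0, 3, (2, 100))
        a0 = anchoring_index(head, torso)
        assert anchoring_index(head + 30.0, torso + 30.0) == pytest.approx(a0, abs=1e-12)


class TestCrossCorrelation:
    def test_identical_traces_peak_at_zero(self):
        x = np.sin(np.linspace(0, 20, 300))
        assert xcorr_peak_time(x, x, DT) == 0.0

    def test_torso_delayed_5_samples_gives_minus_034(self):
        rng = np.random.default_rng(3)
        base = np.convolve(rng.normal(0, 1, 400), np.ones(15) / 15, mode="same")
        head = base[5:305]
        torso = base[:300]  # torso lags head by 5 samples
        assert xcorr_peak_time(head, torso, DT) == pytest.approx(-5 * DT, abs=1e-12)

    def test_swapping_inputs_flips_sign(self):
        rng = np.random.default_rng(4)
        base = np.convolve(rng.normal(0, 1, 400), np.ones(15) / 15, mode="same")
        a, b = base[5:305], base[:300]
        assert xcorr_peak_time(a, b, DT) == pytest.approx(-xcorr_peak_time(b, a, DT))


class TestDtw:
    def test_identical_traces_give_zero(self):
        x = np.sin(np.linspace(0, 10, 50))
        assert dtw_distance(x, x) == 0.0

    def test_small_example_matches_path_oracle(self):
        a, b = [0.0, 1.0, 2.0], [0.0, 2.0, 2.0]
        assert dtw_distance(a, b, target_length=None) == dtw_oracle(a, b)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 40), rng.normal(0, 1, 40)
        assert dtw_distance(a, b) == pytest.approx(dtw_distance(b, a), abs=1e-12)

    def test_target_length_must_be_at_least_two(self):
        with pytest.raises(ValueError):
            dtw_distance([1.0, 2.0], [1.0, 2.0], target_length=1)

    @given(
        st.lists(st.integers(0, 2), min_size=1, max_size=6),
        st.lists(st.integers(0, 2), min_size=1, max_size=6),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_matches_oracle_on_integer_traces(self, a, b):
        assert dtw_distance(a, b, target_length=None) == pytest.approx(
            dtw_oracle(a, b), abs=1e-12
        )


class TestSmoothness:
    def _gauss_pulse(self, t, mu, sig):
        return np.exp(-0.5 * ((t - mu) / sig) ** 2)

    def test_second_pulse_increases_jerkiness(self):
        t = DT * np.arange(int(4.0 / DT))
        one = self._gauss_pulse(t, 1.5, 0.25)
        two = one + self._gauss_pulse(t, 3.0, 0.25)
        assert abs(spectral_arc_length(two, DT)) > abs(spectral_arc_length(one, DT))

    def test_amplitude_invariance(self):
        t = DT * np.arange(int(3.0 / DT))
        v = self._gauss_pulse(t, 1.5, 0.3)
        assert spectral_arc_length(5.0 * v, DT) == pytest.approx(
            spectral_arc_length(v, DT), abs=1e-9
        )

    def test_time_rescaling_with_matched_cutoff(self):
        # slowing the profile by 2x while halving the cutoff leaves the
        # normalized spectrum shape unchanged
        t = DT * np.arange(512)
        v = self._gauss_pulse(t, 1.5, 0.25)
        slow = np.repeat(v, 2)  # same shape over doubled support
        fast_sal = spectral_arc_length(v, DT, cutoff_hz=10.0)
        slow_sal = spectral_arc_length(slow, DT, cutoff_hz=5.0)
        assert slow_sal == pytest.approx(fast_sal, rel=0.05)

    def test_all_zero_speed_undefined(self):
        assert np.isnan(spectral_arc_length(np.zeros(64), DT))

    def test_sal_is_negative(self):
        t = DT * np.arange(200)
        assert spectral_arc_length(self._gauss_pulse(t, 5.0, 1.0), DT) < 0


class TestPeaksAndSpeedRatio:
    def test_monotone_ramp_has_no_peaks(self):
        assert count_peaks(np.linspace(0, 30, 100), duration=5.0) == 0.0

    def test_1hz_sinusoid_over_10s(self):
        t = DT * np.arange(int(10.0 / DT))
        rate = count_peaks(10 * np.sin(2 * np.pi * 1.0 * t), duration=10.0)
        assert rate == pytest.approx(1.0, abs=0.1)

    def test_subthreshold_ripple_suppressed(self):
        t = np.linspace(0, 5, 200)
        x = 6.0 * t + 0.1 * np.sin(2 * np.pi * 8 * t)  # 0.1 deg ripple
        assert count_peaks(x, duration=5.0) == 0.0

    def test_constant_rate_ramp_ratio_one(self, grid):
        assert speed_ratio(4.0 * grid, DT) == pytest.approx(1.0)

    def test_half_sine_rate_gives_2_over_pi(self):
        T = 2.0
        t = np.linspace(0, T, 2001)
        x = (T / np.pi) * (1 - np.cos(np.pi * t / T))  # rate = sin(pi t / T)
        assert speed_ratio(x, t[1] - t[0]) == pytest.approx(2 / np.pi, rel=0.01)

    def test_ratio_never_exceeds_one(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            x = np.cumsum(rng.normal(0, 1, 50))
            assert speed_ratio(x, DT) <= 1.0 + 1e-12


class TestFeatureVector:
    def test_rigid_coupling_composition(self, small_course):
        trial = ck.simulate_flight_trial(
            ck.SynthConfig(seed=3, coupling=1.0, head_comp_gain=0.0, noise_sd=0.0),
            small_course,
        )
        fv = ck.feature_vector(trial, small_course)
        assert fv.values["corr_roll_roll"] == pytest.approx(1.0)
        assert fv.values["dtw_roll"] == pytest.approx(0.0, abs=1e-9)
        assert fv.values["dtw_pitch"] == pytest.approx(0.0, abs=1e-9)

    def test_artifact_injection_excludes_exactly_those_segments(self, small_course):
        trial = ck.simulate_flight_trial(
            ck.SynthConfig(seed=8, noise_sd=0.5), small_course
        )
        segs = split_segments(trial, small_course)
        # inject one 30-degree jump into segments 1, 4, 7
        head = trial.head.roll.copy()
        for si in (1, 4, 7):
            t_mid = 0.5 * (segs[si].t_start + segs[si].t_end)
            idx = int(np.searchsorted(trial.t, t_mid))
            head[idx] += 30.0
        tampered = ck.TrialRecording(
            ck.AngleSeries(trial.t, trial.head.pitch, head, trial.head.yaw),
            trial.torso, trial.position, trial.meta,
        )
        fv = ck.feature_vector(tampered, small_course)
        assert fv.n_rejected == 3
        assert fv.n_segments == small_course.n_coins - 1

    def test_deterministic_recomputation(self, small_course, clean_flight):
        a = ck.feature_vector(clean_flight, small_course)
        b = ck.feature_vector(clean_flight, small_course)
        assert a.values == b.values

    def test_all_segments_rejected_raises(self, small_course):
        trial = ck.simulate_flight_trial(
            ck.SynthConfig(seed=8, noise_sd=0.5), small_course
        )
        head = trial.head.roll.copy()
        head[::2] += 50.0  # jumps everywhere
        tampered = ck.TrialRecording(
            ck.AngleSeries(trial.t, trial.head.pitch, head, trial.head.yaw),
            trial.torso, trial.position, trial.meta,
        )
        with pytest.raises(ValueError, match="no valid segments"):
            ck.feature_vector(tampered, small_course)


class TestFeatureBounds:
    """Every battery bound holds on randomized synthetic trials."""

    @pytest.mark.parametrize("seed", range(8))
    def test_bounds_on_random_trial(self, seed, small_course):
        rng = np.random.default_rng(seed)
        cfg = ck.SynthConfig(
            seed=seed,
            coupling=float(rng.uniform(0, 1)),
            overshoot_gain=float(rng.uniform(0.8, 1.8)),
            head_comp_gain=float(rng.uniform(0, 0.5)),
            noise_sd=float(rng.uniform(0.1, 2.0)),
        )
        fv = ck.feature_vector(
            ck.simulate_flight_trial(cfg, small_course), small_course
        )
        v = fv.values
        for ax in ("pitch", "roll", "yaw"):
            if np.isfinite(v[f"ai_{ax}"]):
                assert -1.0 <= v[f"ai_{ax}"] <= 1.0
            assert v[f"dtw_{ax}"] >= 0.0
            if np.isfinite(v[f"torso_speed_ratio_{ax}"]):
                assert 0.0 < v[f"torso_speed_ratio_{ax}"] <= 1.0
        for a, b in (("pitch", "pitch"), ("roll", "roll"), ("roll", "yaw")):
            if np.isfinite(v[f"corr_{a}_{b}"]):
                assert 0.0 <= v[f"corr_{a}_{b}"] <= 1.0
        assert v["path_ratio"] > 0.0
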