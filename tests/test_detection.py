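import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from chairstand import (Cycle, DataError, DegenerateSpectrumError,
                        DetectionConfig, DetectionState, MagnitudeSeries,
                        Peak, SimConfig, accept_peaks,
                        compute_amplitude_threshold, compute_time_threshold,
                        detect_trial, estimate_dominant_frequency,
                        find_candidate_peaks, segment_cycles, split_subphases,
                        synthesize_trial)
from chairstand.simulate import CyclePlan

from conftest import make_trial


def mag_series(t, x):
    return MagnitudeSeries(time=np.asarray(t, float), a_mag=np.asarray(x, float))


class TestDominantFrequency:
    def test_sine_frequency_recovered_within_one_bin(self):
        fs, f0 = 400.0, 0.6
        t = np.arange(int(30 * fs)) / fs
        mag = mag_series(t, 10.0 + np.sin(2 * np.pi * f0 * t))
        df = estimate_dominant_frequency(mag, band=(0.1, 2.5))
        bin_width = fs / (8 * fs)
        assert abs(df - f0) <= bin_width + 1e-12

    def test_burst_train_rate_matches_periodogram_oracle(self):
        fs, period = 100.0, 2.0
        t = np.arange(int(30 * fs)) / fs
        x = np.zeros_like(t)
        for c in np.arange(1.0, 29.0, period):
            m = np.abs(t - c) <= 0.25
            x[m] += 0.5 * (1 + np.cos(2 * np.pi * (t[m] - c) / 0.5))
        mag = mag_series(t, x)
        df = estimate_dominant_frequency(mag, band=(0.1, 2.5))
        # independent oracle: raw periodogram argmax over the same band
        freqs = np.fft.rfftfreq(t.size, 1 / fs)
        power = np.abs(np.fft.rfft(x - x.mean())) ** 2
        in_band = (freqs >= 0.1) & (freqs <= 2.5)
        oracle = freqs[in_band][np.argmax(power[in_band])]
        assert oracle == pytest.approx(1.0 / period, abs=1 / 30)
        assert abs(df - oracle) <= 0.125 + 1 / 30

    def test_constant_signal_is_degenerate(self):
        t = np.arange(4000) / 400.0
        with pytest.raises(DegenerateSpectrumError):
            estimate_dominant_frequency(mag_series(t, np.full_like(t, 9.81)))

    def test_short_signal_rejected(self):
        t = np.arange(400) / 400.0  # 1 s
        with pytest.raises(DataError, match="8"):
            estimate_dominant_frequency(mag_series(t, np.sin(t)))


class TestThresholds:
    def test_amplitude_threshold_from_observed_range(self):
        # alpha 0.2 on a 1.7..22.3 m/s² magnitude range
        t = np.linspace(0, 1, 101)
        x = np.linspace(1.7, 22.3, 101)
        assert compute_amplitude_threshold(mag_series(t, x), 0.2) == \
            pytest.approx(4.12)

    def test_zero_for_constant_signal(self):
        t = np.linspace(0, 1, 11)
        assert compute_amplitude_threshold(mag_series(t, np.full(11, 5.0)), 0.3) == 0.0

    def test_scales_linearly_with_signal(self, rng):
        t = np.linspace(0, 1, 101)
        x = rng.uniform(1, 20, 101)
        th1 = compute_amplitude_threshold(mag_series(t, x), 0.2)
        th3 = compute_amplitude_threshold(mag_series(t, 3.0 * x), 0.2)
        assert th3 == pytest.approx(3.0 * th1)

    @pytest.mark.parametrize("df,gamma,expected",
                             [(1.0, 1.0, 1.0), (0.5, 0.75, 1.5), (2.0, 1.0, 0.5)])
    def test_time_threshold(self, df, gamma, expected):
        assert compute_time_threshold(df, gamma) == pytest.approx(expected)

    def test_time_threshold_needs_positive_df(self):
        with pytest.raises(ValueError):
            compute_time_threshold(0.0, 1.0)


class TestCandidatePeaks:
    def test_monotone_ramp_has_none(self):
        t = np.arange(1000) / 100.0
        assert find_candidate_peaks(mag_series(t, t)) == []

    def test_single_triangular_bump(self):
        t = np.arange(1001) / 100.0
        x = np.maximum(0.0, 1.0 - np.abs(t - 5.0))
        peaks = find_candidate_peaks(mag_series(t, x))
        assert len(peaks) == 1
        assert peaks[0].t == pytest.approx(5.0)

    def test_plateau_contributes_centre_sample(self):
        t = np.arange(101) / 10.0
        x = np.zeros_like(t)
        x[50:53] = 1.0  # 3-sample plateau
        peaks = find_candidate_peaks(mag_series(t, x))
        assert len(peaks) == 1
        assert peaks[0].index == 51

    def test_edge_exclusion(self):
        t = np.arange(1001) / 100.0
        x = np.zeros_like(t)
        x[10] = 1.0  # 0.1 s from the start: inside the exclusion zone
        x[500] = 1.0
        peaks = find_candidate_peaks(mag_series(t, x))
        assert [p.index for p in peaks] == [500]


def state(th_amp=1.0, th_time=1.0, smin=0.0):
    return DetectionState(th_amp=th_amp, th_time=th_time, df=1.0,
                          signal_min=smin, signal_max=smin + 10.0)


class TestAcceptPeaks:
    def test_empty_candidates(self):
        assert accept_peaks([], state()) == []

    def test_time_guard_rejects_close_followers(self):
        cands = [Peak(0, 1.0, 5.0), Peak(1, 1.4, 5.0), Peak(2, 3.0, 5.0)]
        accepted = accept_peaks(cands, state(th_amp=1.0, th_time=1.0))
        assert [p.t for p in accepted] == [1.0, 3.0]

    def test_threshold_equality_is_accepted(self):
        cands = [Peak(0, 1.0, 4.0)]
        accepted = accept_peaks(cands, state(th_amp=4.0, th_time=1.0, smin=0.0))
        assert len(accepted) == 1

    def test_baseline_none_uses_absolute_amplitude(self):
        cands = [Peak(0, 1.0, 9.0)]
        st_ = state(th_amp=8.0, smin=5.0)
        cfg = DetectionConfig(baseline_correction="none")
        assert len(accept_peaks(cands, st_, cfg)) == 1  # 9 >= 8
        cfg = DetectionConfig(baseline_correction="min_offset")
        assert accept_peaks(cands, st_, cfg) == []  # 9 - 5 < 8

    def test_dropping_guard_keeps_fast_peaks(self):
        cands = [Peak(0, 1.0, 5.0), Peak(1, 1.4, 5.0)]
        cfg = DetectionConfig(use_df_guard=False)
        assert len(accept_peaks(cands, state(), cfg)) == 2

    def test_rejected_candidate_does_not_reset_clock(self):
        # the 1.8 s candidate is within th_time of the *accepted* 1.0 s peak
        # even though a candidate at 1.4 s was seen in between
        cands = [Peak(0, 1.0, 5.0), Peak(1, 1.4, 5.0), Peak(2, 1.8, 5.0),
                 Peak(3, 2.1, 5.0)]
        accepted = accept_peaks(cands, state(th_time=1.0))
        assert [p.t for p in accepted] == [1.0, 2.1]

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_bruteforce_on_random_instances(self, data):
        n = data.draw(st.integers(0, 10))
        times = sorted(data.draw(st.lists(
            st.floats(0, 10, allow_nan=False), min_size=n, max_size=n)))
        amps = data.draw(st.lists(
            st.floats(0, 10, allow_nan=False), min_size=n, max_size=n))
        th_amp = data.draw(st.floats(0, 8))
        th_time = data.draw(st.floats(0, 3))
        cands = [Peak(i, t, a) for i, (t, a) in enumerate(zip(times, amps))]
        st_ = state(th_amp=th_amp, th_time=th_time, smin=0.0)
        accepted = accept_peaks(cands, st_)
        assert [p.index for p in accepted] == brute_force_accept(
            cands, th_amp, th_time)


def brute_force_accept(cands, th_amp, th_time):
    """Lexicographically earliest maximal admissible subsequence, by
    exhaustive enumeration (independent of the greedy scan)."""
    n = len(cands)
    eligible = [i for i in range(n) if cands[i].amplitude >= th_amp]

    def admissible(subset):
        return all(cands[b].t - cands[a].t >= th_time
                   for a, b in zip(subset, subset[1:]))

    def maximal(subset):
        subset_set = set(subset)
        for extra in eligible:
            if extra in subset_set:
                continue
            trial = sorted(subset + [extra])
            if admissible(trial):
                return False
        return True

    best = None
    for mask in range(1 << len(eligible)):
        subset = [eligible[i] for i in range(len(eligible)) if mask >> i & 1]
        if admissible(subset) and maximal(subset):
            if best is None or subset < best:
                best = subset
    return best or []


class TestSegmentAndSplit:
    def test_consecutive_peaks_make_cycles(self):
        peaks = [Peak(0, 1.0, 5.0), Peak(1, 2.5, 5.0), Peak(2, 4.6, 5.0)]
        cycles = segment_cycles(peaks)
        assert [c.T for c in cycles] == pytest.approx([1.5, 2.1])
        assert segment_cycles(peaks[:2])[0].T == pytest.approx(1.5)

    def test_single_peak_yields_no_cycle(self):
        assert segment_cycles([Peak(0, 2.0, 5.0)]) == []
        assert segment_cycles([]) == []

    def test_symmetric_valley_splits_in_half(self):
        t = np.arange(1001) / 100.0
        x = 10.0 - np.exp(-((t - 5.0) ** 2))  # symmetric dip at 5 s
        cycle = split_subphases(Cycle(start_t=2.0, end_t=8.0), mag_series(t, x))
        assert abs(cycle.rise_time - cycle.sit_time) <= 2 / 100.0

    def test_apex_at_constructed_fraction(self):
        t = np.arange(1001) / 100.0
        apex = 2.0 + 0.40 * 4.0
        x = 10.0 - np.exp(-((t - apex) ** 2) / 0.1)
        cycle = split_subphases(Cycle(start_t=2.0, end_t=6.0), mag_series(t, x))
        assert cycle.rise_time / cycle.T == pytest.approx(0.40, abs=1 / 100.0 / 4.0)
        assert not cycle.degenerate_split

    def test_monotone_segment_halved_with_flag(self):
        t = np.arange(1001) / 100.0
        cycle = split_subphases(Cycle(start_t=2.0, end_t=6.0), mag_series(t, t))
        assert cycle.degenerate_split
        assert cycle.rise_time == pytest.approx(2.0)
        assert cycle.sit_time == pytest.approx(2.0)


def noise_free_trial(n_cycles=10, T=2.0, cohort="older", seed=0):
    plans = [CyclePlan(strategy="MT", duration=T, rise_fraction=0.5,
                       pitch_excursion=0.5) for _ in range(n_cycles)]
    config = SimConfig(noise_sd_acc=0.0, noise_sd_gyr=0.0, tilt=0.0,
                       trial_len=n_cycles * T + 2.0, p_echo=0.0, seed=seed)
    return synthesize_trial(plans, config, cohort,
                            np.random.default_rng(seed), trial_id="clean")


class TestDetectTrial:
    def test_recovers_all_embedded_cycles(self):
        trial, truth = noise_free_trial()
        result = detect_trial(trial)
        assert result.n_cycles == truth.n_cycles
        det_starts = np.array([c.start_t for c in result.cycles])
        assert np.max(np.abs(det_starts - truth.annotations.starts)) < 0.025

    def test_pure_noise_yields_no_cycles(self, rng):
        t = np.arange(12000) / 400.0
        acc = np.column_stack([9.81 + rng.normal(0, 0.4, t.size),
                               rng.normal(0, 0.4, t.size),
                               rng.normal(0, 0.4, t.size)])
        trial = make_trial(t).replace(acc=acc)
        result = detect_trial(trial)
        assert result.n_cycles == 0

    def test_flat_signal_degenerate_spectrum_warning(self):
        t = np.arange(12000) / 400.0
        trial = make_trial(t, acc_x=np.full_like(t, 9.81))
        with pytest.warns(UserWarning, match="degenerate"):
            result = detect_trial(trial)
        assert result.n_cycles == 0
        assert np.isnan(result.detection_state.df)

    def test_increasing_alpha_never_adds_peaks(self):
        trial, _ = noise_free_trial(seed=3)
        counts = []
        for alpha in (0.05, 0.1, 0.2, 0.3, 0.4, 0.6):
            result = detect_trial(trial, DetectionConfig(alpha=alpha))
            counts.append(result.n_cycles)
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_detection_invariant_under_sensor_rotation(self, rng):
        trial, _ = noise_free_trial(seed=4)
        base = detect_trial(trial)
        rot = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
        rotated = trial.replace(acc=trial.acc @ rot.T, gyr=trial.gyr @ rot.T)
        other = detect_trial(rotated)
        assert other.n_cycles == base.n_cycles
        assert [c.T for c in other.cycles] == pytest.approx(
            [c.T for c in base.cycles], abs=1e-9)

    def test_accepted_spacing_respects_time_guard(self, sim_cohort):
        for trial, _ in sim_cohort[:5]:
            result = detect_trial(trial)
            starts = [c.start_t for c in result.cycles]
            gaps = np.diff(starts + [result.cycles[-1].end_t])
            assert np.all(gaps >= result.detection_state.th_time - 1e-9)
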