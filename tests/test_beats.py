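import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulsegaze import beats
from pulsegaze import synthetic as syn
from pulsegaze.metrics import mean_abs_error


class TestDerivative:
    def test_constant_maps_to_zero(self):
        # stencil coefficients sum to zero, up to float rounding
        np.testing.assert_allclose(beats.five_point_derivative(np.full(10, 4.2)), 0.0, atol=1e-14)

    def test_exact_on_ramp(self):
        y = beats.five_point_derivative(np.arange(20.0))
        np.testing.assert_allclose(y[2:-2], 1.0)

    def test_exact_on_quadratic(self):
        i = np.arange(20.0)
        y = beats.five_point_derivative(i**2)
        np.testing.assert_allclose(y[2:-2], 2 * i[2:-2])

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            beats.five_point_derivative(np.zeros(4))


class TestNormalizeAndEnergy:
    def test_normalize_scales_by_max_magnitude(self):
        np.testing.assert_allclose(beats.normalize(np.array([2.0, -4.0])), [0.5, -1.0])

    def test_normalize_is_idempotent_and_sign_preserving(self):
        x = np.array([0.25, -1.0, 0.5])
        np.testing.assert_allclose(beats.normalize(x), x)
        assert np.all(np.sign(beats.normalize(np.array([3.0, -1.0]))) == [1, -1])

    def test_normalize_rejects_all_zero(self):
        with pytest.raises(ValueError):
            beats.normalize(np.zeros(5))

    def test_shannon_energy_boundary_values(self):
        e = beats.shannon_energy(np.array([0.0, 1.0, -1.0]))
        np.testing.assert_allclose(e, 0.0)

    def test_shannon_energy_maximum_at_exp_minus_half(self):
        e = beats.shannon_energy(np.array([np.exp(-0.5)]))
        assert e[0] == pytest.approx(np.exp(-1.0))
        grid = beats.shannon_energy(np.linspace(-1, 1, 2001))
        assert grid.max() <= np.exp(-1.0) + 1e-12

    def test_out_of_range_input_rejected(self):
        with pytest.raises(ValueError):
            beats.shannon_energy(np.array([1.5]))


class TestIntegration:
    def test_window_sample_counts_match_sampling_rates(self):
        # 0.15 s at 200 Hz is the canonical 30-sample window
        assert beats._window_samples(0.15, 200.0) == 30
        assert beats._window_samples(0.15, 100.0) == 15

    def test_impulse_response_is_box(self):
        e = np.zeros(50)
        e[25] = 1.0
        out = beats.window_integrate(e, 200.0, 0.15 / 10)  # 3-sample window
        assert out[24:27] == pytest.approx(1 / 3)
        assert out[:23].max() == 0

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            beats.window_integrate(np.zeros(10), 200.0, 1.0)


class TestThresholds:
    def _env_with_peaks(self, heights, fs=10.0):
        env = np.zeros(int(3 * fs) + 2)
        for k, h in enumerate(heights):
            env[3 + 4 * k] = h
        return env

    def test_single_peak_initialization(self):
        # ST = max/3 = 2, NT = mean/2 = 3 (the mean of one peak is the peak)
        st_ = beats.init_thresholds(self._env_with_peaks([6.0]), 10.0)
        assert st_.st == pytest.approx(2.0)
        assert st_.nt == pytest.approx(3.0)

    def test_two_peak_initialization(self):
        st_ = beats.init_thresholds(self._env_with_peaks([4.0, 8.0]), 10.0)
        assert st_.st == pytest.approx(8 / 3)
        assert st_.nt == pytest.approx(3.0)

    def test_equal_levels_collapse_t1_to_nt(self):
        s = beats.DetectorState(st=2.0, nt=2.0)
        assert s.t1 == pytest.approx(2.0)
        assert s.t2 == pytest.approx(1.0)

    def test_signal_update_arithmetic(self):
        s = beats.DetectorState(st=0.8, nt=0.2)
        s.update(1.6, is_signal=True)
        assert s.st == pytest.approx(0.9)

    def test_threshold_relations_from_levels(self):
        s = beats.DetectorState(st=0.8, nt=0.2)
        assert s.t1 == pytest.approx(0.35)
        assert s.t2 == pytest.approx(0.175)

    def test_update_fixed_point(self):
        s = beats.DetectorState(st=0.8, nt=0.2)
        s.update(0.8, is_signal=True)
        assert s.st == pytest.approx(0.8)

    def test_searchback_update_arithmetic(self):
        s = beats.DetectorState(st=0.8, nt=0.2)
        s.searchback_update(0.4)
        assert s.st == pytest.approx(0.7)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_relations_hold_after_any_update_sequence(self, seed):
        rng = np.random.default_rng(seed)
        s = beats.DetectorState(st=rng.uniform(0.1, 2.0), nt=rng.uniform(0.0, 1.0))
        for _ in range(30):
            s.update(rng.uniform(0.0, 3.0), is_signal=bool(rng.integers(2)))
            assert s.t1 == s.nt + (s.st - s.nt) / 4.0
            assert s.t2 == s.t1 / 2.0

    def test_geometric_convergence_to_constant_peak(self):
        s = beats.DetectorState(st=1.0, nt=0.1)
        dp = 3.0
        gaps = []
        for _ in range(10):
            gaps.append(abs(s.st - dp))
            s.update(dp, is_signal=True)
        ratios = np.array(gaps[1:]) / np.array(gaps[:-1])
        np.testing.assert_allclose(ratios, 7 / 8, atol=1e-12)


class TestDetection:
    @pytest.mark.parametrize("bpm", [40, 60, 90, 120, 180])
    def test_exact_on_clean_pulse_trains(self, clean_pulse_train, bpm):
        trace, beat_times = clean_pulse_train(bpm)
        bs = beats.detect_beats(trace, 30.0)
        tp, fp, fn, pairs = beats.match_beats(
            bs.peak_times, beat_times, tol_s=1 / 30 + 1e-9, span=(3.0, 29.6)
        )
        assert fp == 0 and fn == 0
        det = np.array([p[0] for p in pairs])
        ref = np.array([p[1] for p in pairs])
        assert mean_abs_error(np.diff(det), np.diff(ref)) <= 1 / 30

    def test_expected_beat_count_at_60bpm(self, clean_pulse_train):
        trace, beat_times = clean_pulse_train(60)
        bs = beats.detect_beats(trace, 30.0)
        # reported beats exclude the 3 s initialization segment
        assert bs.n_beats == np.sum(beat_times >= 3.0)

    def test_refractory_suppresses_close_double(self):
        # two pulses 150 ms apart are one physiological event
        cfg = syn.PulseSimConfig(fs_hz=30.0, pulse_width_s=0.3)
        singles = np.arange(0.57, 29.5, 1.0)
        trace = syn.render_pulse_waveform(singles, cfg, duration_s=30.0)
        double = syn.render_pulse_waveform(np.array([10.0, 10.15]), cfg, duration_s=30.0)
        bs = beats.detect_beats(trace + double, 30.0)
        near = bs.peak_times[(bs.peak_times > 9.8) & (bs.peak_times < 10.45)]
        assert near.size == 1

    def test_attenuated_beats_recovered(self, clean_pulse_train):
        trace, beat_times = clean_pulse_train(60)
        cfg = syn.PulseSimConfig(fs_hz=30.0, pulse_width_s=0.35)
        att = np.zeros_like(trace)
        for k, b in enumerate(beat_times):
            scale = 0.4 if k % 5 == 0 else 1.0
            att += scale * syn.render_pulse_waveform(np.array([b]), cfg, duration_s=30.0)
        bs = beats.detect_beats(att, 30.0)
        tp, fp, fn, pairs = beats.match_beats(
            bs.peak_times, beat_times, tol_s=1 / 30 + 1e-9, span=(3.0, 29.6)
        )
        assert tp / (tp + fn) == 1.0
        low = [b for k, b in enumerate(beat_times) if k % 5 == 0 and b > 3.0]
        recovered = sum(1 for b in low if any(abs(r - b) < 0.05 for _, r in pairs))
        assert recovered / len(low) >= 0.9

    def test_deeply_attenuated_beat_recovered_via_searchback(self, clean_pulse_train):
        trace, beat_times = clean_pulse_train(60)
        cfg = syn.PulseSimConfig(fs_hz=30.0, pulse_width_s=0.35)
        att = np.zeros_like(trace)
        for k, b in enumerate(beat_times):
            scale = 0.2 if k == 12 else 1.0
            att += scale * syn.render_pulse_waveform(np.array([b]), cfg, duration_s=30.0)
        bs = beats.detect_beats(att, 30.0)
        assert "searchback" in bs.provenance
        tp, fp, fn, _ = beats.match_beats(
            bs.peak_times, beat_times, tol_s=1 / 30 + 1e-9, span=(3.0, 29.6)
        )
        assert fn == 0

    def test_robust_under_noise_and_drift(self, noisy_session):
        from pulsegaze import ssa

        tps = fps_ = fns = 0
        for seed in range(5):
            trace, beat_times = noisy_session(seed)
            pulse = ssa.extract_pulse(trace, 30.0)
            bs = beats.detect_beats(pulse, 30.0)
            tp, fp, fn, _ = beats.match_beats(
                bs.peak_times, beat_times, tol_s=2 / 30, span=(3.0, 30.5)
            )
            tps += tp
            fps_ += fp
            fns += fn
        assert tps / (tps + fns) >= 0.95
        assert tps / (tps + fps_) >= 0.9

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            beats.detect_beats(np.zeros(60), 30.0)

    def test_flat_signal_has_no_normalizable_slope(self):
        with pytest.raises(ValueError):
            beats.detect_beats(np.zeros(300), 30.0)

    def test_detection_is_deterministic(self, clean_pulse_train):
        trace, _ = clean_pulse_train(75)
        a = beats.detect_beats(trace, 30.0)
        b = beats.detect_beats(trace, 30.0)
        np.testing.assert_array_equal(a.peak_times, b.peak_times)
        assert a.provenance == b.provenance


class TestMatching:
    def test_greedy_matching_counts(self):
        tp, fp, fn, pairs = beats.match_beats(
            np.array([1.0, 2.0, 3.5]), np.array([1.02, 2.01, 3.0]), tol_s=0.05
        )
        assert (tp, fp, fn) == (2, 1, 1)
        assert len(pairs) == 2

    def test_span_restricts_reference(self):
        tp, fp, fn, _ = beats.match_beats(
            np.array([5.0]), np.array([1.0, 5.0, 9.0]), tol_s=0.05, span=(4.0, 6.0)
        )
        assert (tp, fp, fn) == (1, 0, 0)
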