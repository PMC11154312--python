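import warnings

import numpy as np
import pytest

from pulsegaze import synthetic as syn


@pytest.fixture(autouse=True)
def _quiet_warnings():
    """Simulator overlap/empty-selection warnings are expected in many tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture
def clean_pulse_train():
    """Noiseless 30 s pulse train factory at a given heart rate.

    Beats are anchored at 0.57 s so none straddles the detector's 3 s
    initialization boundary within one frame at any of the tested rates.
    """

    def make(bpm: float, fs: float = 30.0, duration: float = 30.0, width: float = 0.35):
        period = 60.0 / bpm
        beat_times = np.arange(0.57, duration - 0.5 + 1e-9, period)
        cfg = syn.PulseSimConfig(fs_hz=fs, pulse_width_s=min(width, 0.8 * period))
        trace = syn.render_pulse_waveform(beat_times, cfg, duration_s=duration)
        return trace, beat_times

    return make


@pytest.fixture
def noisy_session():
    """Seeded pulse trace at ~10 dB broadband SNR with respiratory drift."""

    def make(seed: int, duration: float = 30.0, fs: float = 30.0):
        _, gt = syn.simulate_rr_series(syn.RRSimConfig(duration_s=duration, seed=seed))
        beat_times = gt.beat_times[:-1] + 0.57
        clean = syn.render_pulse_waveform(
            beat_times, syn.PulseSimConfig(fs_hz=fs, pulse_width_s=0.35), duration_s=duration + 1
        )
        noise_sd = float(np.std(clean)) / np.sqrt(10)
        cfg = syn.PulseSimConfig(
            fs_hz=fs, pulse_width_s=0.35, noise_sd=noise_sd,
            drift_amp=0.5, drift_freq_hz=0.2, seed=seed + 1000,
        )
        trace = syn.render_pulse_waveform(beat_times, cfg, duration_s=duration + 1)
        return trace, beat_times

    return make
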