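"""Ground-truthed synthetic biosignal generators.

Every downstream stage of the pipeline is testable against these
generators without any recordings:

* an RR (inter-beat interval) simulator with sinusoidal LF/HF
  modulation, so the true sympathovagal ratio lf_amp^2 / hf_amp^2 is
  known in closed form;
* a pulse-waveform renderer placing one smooth raised-cosine pulse per
  beat, plus respiratory-band drift and Gaussian noise;
* an eye/mouth state-stream simulator with exactly controlled
  closed-frame and yawn-frame counts laid out in blink/yawn-length runs;
* an ROI-frame synthesizer whose masked spatial average reproduces a
  given intensity trace exactly.

Fatigue vs. awake regimes differ in the direction physiology reports:
drowsy windows have larger interval variability (higher SD), a higher
LF/HF ratio, more eye closure and more yawning.  The magnitudes are
configurable; the defaults are chosen to be physiologically plausible
(see docs/methods.md).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RRSimConfig",
    "PulseSimConfig",
    "EyeStateSimConfig",
    "GroundTruth",
    "simulate_rr_series",
    "render_pulse_waveform",
    "simulate_eye_state_stream",
    "simulate_roi_frames",
    "AWAKE_REGIME",
    "FATIGUE_REGIME",
    "regime_configs",
    "SyntheticSession",
    "simulate_session",
]


@dataclass(frozen=True)
class RRSimConfig:
    """Beat-interval simulator settings.

    Interval i is 60/mean_hr_bpm plus LF and HF sinusoids (amplitudes in
    seconds) evaluated at the cumulative beat time, plus Gaussian jitter.
    """

    duration_s: float = 300.0
    mean_hr_bpm: float = 70.0
    lf_amp_s: float = 0.03
    hf_amp_s: float = 0.03
    lf_freq_hz: float = 0.1
    hf_freq_hz: float = 0.25
    jitter_sd_s: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not 30.0 <= self.mean_hr_bpm <= 180.0:
            raise ValueError("mean_hr_bpm must lie in [30, 180]")
        if self.lf_freq_hz >= self.hf_freq_hz:
            raise ValueError("lf_freq_hz must be below hf_freq_hz")
        if self.lf_amp_s < 0 or self.hf_amp_s < 0 or self.jitter_sd_s < 0:
            raise ValueError("amplitudes and jitter must be non-negative")
        if self.lf_amp_s + self.hf_amp_s >= 60.0 / self.mean_hr_bpm:
            raise ValueError("modulation amplitudes large enough to produce non-positive intervals")


@dataclass(frozen=True)
class PulseSimConfig:
    """Pulse-waveform renderer settings (camera-rate sampling)."""

    fs_hz: float = 30.0
    pulse_width_s: float = 0.5
    noise_sd: float = 0.0
    drift_amp: float = 0.0
    drift_freq_hz: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs_hz <= 8.0:  # Nyquist must clear the 4 Hz passband top
            raise ValueError("fs_hz must exceed 8 Hz (2 x 4 Hz passband top)")
        if self.noise_sd < 0 or self.pulse_width_s <= 0:
            raise ValueError("noise_sd must be >= 0 and pulse_width_s > 0")


@dataclass(frozen=True)
class EyeStateSimConfig:
    """Eye/mouth frame-stream simulator settings (per 60 s window)."""

    fps: float = 20.0
    window_s: float = 60.0
    closed_fraction: float = 0.1
    yawn_fraction: float = 0.0
    blink_mean_dur_s: float = 0.3
    yawn_mean_dur_s: float = 2.0
    score_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.fps * self.window_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError("fps * window_s must be an integer frame count")
        for f in (self.closed_fraction, self.yawn_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.score_noise_sd < 0:
            raise ValueError("score_noise_sd must be >= 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.window_s))


@dataclass(frozen=True)
class GroundTruth:
    """Known quantities attached to a simulated stream."""

    beat_times: np.ndarray | None = None
    true_intervals: np.ndarray | None = None
    true_lf_over_hf: float | None = None
    true_perclos: float | None = None
    true_yawn_rate: float | None = None
    labels: np.ndarray | None = None


def simulate_rr_series(cfg: RRSimConfig) -> tuple[np.ndarray, GroundTruth]:
    """Generate an LF/HF-modulated interval series with known ground truth.

    The analytic LF/HF power ratio of the interval process is
    lf_amp^2 / hf_amp^2 (equal-frequency-count sinusoids; power scales
    with amplitude squared).
    """
    rng = np.random.default_rng(cfg.seed)
    base = 60.0 / cfg.mean_hr_bpm
    times = [0.0]
    intervals = []
    t = 0.0
    while t < cfg.duration_s:
        dt = (
            base
            + cfg.lf_amp_s * np.sin(2 * np.pi * cfg.lf_freq_hz * t)
            + cfg.hf_amp_s * np.sin(2 * np.pi * cfg.hf_freq_hz * t)
            + (rng.normal(0.0, cfg.jitter_sd_s) if cfg.jitter_sd_s > 0 else 0.0)
        )
        if dt <= 0:
            raise ValueError(
                f"configuration produced a non-positive interval ({dt:.4f} s) at t={t:.2f} s; "
                "reduce modulation amplitudes or jitter"
            )
        t += dt
        times.append(t)
        intervals.append(dt)
    intervals = np.array(intervals)
    if cfg.hf_amp_s > 0:
        ratio = (cfg.lf_amp_s / cfg.hf_amp_s) ** 2
    else:
        ratio = float("inf") if cfg.lf_amp_s > 0 else float("nan")
    gt = GroundTruth(
        beat_times=np.array(times),
        true_intervals=intervals,
        true_lf_over_hf=ratio,
    )
    return intervals, gt


def render_pulse_waveform(
    beat_times: np.ndarray,
    cfg: PulseSimConfig,
    duration_s: float | None = None,
) -> np.ndarray:
    """Sampled intensity trace with one raised-cosine pulse per beat.

    pulse(t) = 0.5 * (1 + cos(2 pi (t - t_beat) / w)) on |t - t_beat| <= w/2,
    so the clean argmax of each pulse falls within half a sample of its
    beat time.  Drift and noise are additive.
    """
    bt = np.sort(np.asarray(beat_times, dtype=float))
    if duration_s is None:
        duration_s = (bt[-1] + cfg.pulse_width_s) if bt.size else 1.0
    n = int(np.ceil(duration_s * cfg.fs_hz))
    t = np.arange(n) / cfg.fs_hz
    trace = np.zeros(n)
    if bt.size > 1 and np.min(np.diff(bt)) < cfg.pulse_width_s:
        warnings.warn("beat intervals shorter than pulse width: pulses overlap", stacklevel=2)
    half = cfg.pulse_width_s / 2.0
    for b in bt:
        lo = max(0, int(np.ceil((b - half) * cfg.fs_hz)))
        hi = min(n, int(np.floor((b + half) * cfg.fs_hz)) + 1)
        if lo >= hi:
            continue
        tt = t[lo:hi] - b
        trace[lo:hi] += 0.5 * (1.0 + np.cos(2 * np.pi * tt / cfg.pulse_width_s))
    if cfg.drift_amp != 0.0:
        trace += cfg.drift_amp * np.sin(2 * np.pi * cfg.drift_freq_hz * t)
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        trace += rng.normal(0.0, cfg.noise_sd, size=n)
    return trace


def _place_runs(
    n_frames: int, n_marked: int, mean_run: int, rng: np.random.Generator
) -> np.ndarray:
    """Boolean stream with exactly n_marked True frames in ~mean_run-length runs."""
    out = np.zeros(n_frames, dtype=bool)
    if n_marked == 0:
        return out
    if n_marked > n_frames:
        raise ValueError(f"cannot mark {n_marked} of {n_frames} frames")
    k = max(1, int(round(n_marked / max(1, mean_run))))
    base, extra = divmod(n_marked, k)
    run_lens = np.full(k, base)
    run_lens[:extra] += 1
    run_lens = run_lens[run_lens > 0]
    k = run_lens.size
    gaps = rng.multinomial(n_frames - n_marked, np.full(k + 1, 1.0 / (k + 1)))
    pos = 0
    for g, rl in zip(gaps[:-1], run_lens):
        pos += int(g)
        out[pos : pos + int(rl)] = True
        pos += int(rl)
    return out


def simulate_eye_state_stream(
    cfg: EyeStateSimConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, GroundTruth]:
    """Frame streams with exact closed/yawn counts and openness scores.

    Returns (eye_closed labels, mouth_yawn labels, eye openness scores,
    mouth openness scores, ground truth).  Open frames score 1, closed
    (and yawning mouths) score at the opposite extreme, with optional
    Gaussian score noise; the realized label fractions are exact
    rationals recorded in the ground truth.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_frames
    n_closed = int(round(cfg.closed_fraction * n))
    n_yawn = int(round(cfg.yawn_fraction * n))
    closed = _place_runs(n, n_closed, max(1, int(round(cfg.blink_mean_dur_s * cfg.fps))), rng)
    yawn = _place_runs(n, n_yawn, max(1, int(round(cfg.yawn_mean_dur_s * cfg.fps))), rng)
    eye_score = np.where(closed, 0.0, 1.0)
    mouth_score = np.where(yawn, 1.0, 0.0)
    if cfg.score_noise_sd > 0:
        eye_score = eye_score + rng.normal(0.0, cfg.score_noise_sd, size=n)
        mouth_score = mouth_score + rng.normal(0.0, cfg.score_noise_sd, size=n)
    gt = GroundTruth(true_perclos=n_closed / n, true_yawn_rate=n_yawn / n)
    return closed, yawn, eye_score, mouth_score, gt


def simulate_roi_frames(
    trace: np.ndarray,
    mask_shape: tuple[int, int] = (8, 8),
    mask: np.ndarray | None = None,
    perturbation_sd: float = 0.0,
    background_sd: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame pixel arrays whose masked mean equals the trace exactly.

    In-mask pixels get the frame's trace value plus a perturbation that
    is re-centered to zero mean inside the mask, so the spatial average
    reproduces the trace to machine precision.  Out-of-mask pixels are
    arbitrary background.
    """
    x = np.asarray(trace, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("trace must be finite")
    rng = np.random.default_rng(seed)
    if mask is None:
        mask = np.zeros(mask_shape, dtype=bool)
        h, w = mask_shape
        mask[h // 4 : max(h // 4 + 1, 3 * h // 4), w // 4 : max(w // 4 + 1, 3 * w // 4)] = True
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty ROI mask")
    frames = rng.normal(0.0, background_sd, size=(x.size, *mask.shape))
    n_in = int(mask.sum())
    for i, v in enumerate(x):
        pert = rng.normal(0.0, perturbation_sd, size=n_in) if perturbation_sd > 0 else np.zeros(n_in)
        frames[i][mask] = v + pert - pert.mean()
    return frames, mask


# --- fatigue / awake regimes -------------------------------------------------

#: Regime parameter ranges (uniform draws per window).  Direction follows
#: the physiology: fatigue raises interval variability, LF/HF, eye
#: closure and yawning.  Magnitudes are package choices (docs/methods.md).
AWAKE_REGIME = {
    "mean_hr_bpm": (62.0, 78.0),
    "lf_amp_s": (0.015, 0.025),
    "hf_amp_s": (0.030, 0.045),
    "jitter_sd_s": (0.010, 0.020),
    "closed_fraction": (0.02, 0.08),
    "yawn_fraction": (0.0, 0.02),
}
FATIGUE_REGIME = {
    "mean_hr_bpm": (55.0, 70.0),
    "lf_amp_s": (0.050, 0.070),
    "hf_amp_s": (0.025, 0.035),
    "jitter_sd_s": (0.035, 0.055),
    "closed_fraction": (0.20, 0.40),
    "yawn_fraction": (0.05, 0.15),
}


def regime_configs(
    preset: str,
    seed: int,
    duration_s: float = 300.0,
    window_s: float = 60.0,
    fps: float = 20.0,
) -> tuple[RRSimConfig, EyeStateSimConfig]:
    """Draw one (RR, eye-state) configuration pair from a named regime."""
    if preset not in ("awake", "fatigue"):
        raise ValueError("preset must be 'awake' or 'fatigue'")
    regime = AWAKE_REGIME if preset == "awake" else FATIGUE_REGIME
    rng = np.random.default_rng(seed)

    def draw(key: str) -> float:
        lo, hi = regime[key]
        return float(rng.uniform(lo, hi))

    rr = RRSimConfig(
        duration_s=duration_s,
        mean_hr_bpm=draw("mean_hr_bpm"),
        lf_amp_s=draw("lf_amp_s"),
        hf_amp_s=draw("hf_amp_s"),
        jitter_sd_s=draw("jitter_sd_s"),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    eye = EyeStateSimConfig(
        fps=fps,
        window_s=window_s,
        closed_fraction=draw("closed_fraction"),
        yawn_fraction=draw("yawn_fraction"),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return rr, eye


@dataclass(frozen=True)
class SyntheticSession:
    """A full simulated recording with per-window ground truth."""

    trace: np.ndarray  # rPPG intensity at fs_hz
    fs_hz: float
    eye_scores: np.ndarray  # per-frame at fps
    mouth_scores: np.ndarray
    fps: float
    window_s: float
    labels: np.ndarray  # one {0 awake, 1 fatigued} label per window
    ground_truth: GroundTruth


def simulate_session(
    preset: str = "awake",
    seed: int = 0,
    n_windows: int = 5,
    window_s: float = 60.0,
    fs_hz: float = 30.0,
    fps: float = 20.0,
    noise_sd: float = 0.05,
    drift_amp: float = 0.3,
) -> SyntheticSession:
    """Simulate a labeled session of ``n_windows`` consecutive 60 s windows.

    ``preset='mixed'`` alternates awake and fatigue windows; otherwise
    all windows share the regime.  One root seed derives all per-stream
    seeds deterministically.
    """
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(n_windows + 1)
    duration = n_windows * window_s
    labels = np.zeros(n_windows, dtype=int)
    beat_times: list[float] = []
    eye_parts, mouth_parts = [], []
    perclos_parts, yawn_parts = [], []
    t_offset = 0.0
    for w in range(n_windows):
        if preset == "mixed":
            regime = "fatigue" if w % 2 else "awake"
        else:
            regime = preset
        labels[w] = 1 if regime == "fatigue" else 0
        wseed = int(child[w].generate_state(1)[0] % (2**31 - 1))
        rr_cfg, eye_cfg = regime_configs(regime, wseed, duration_s=window_s, window_s=window_s, fps=fps)
        _, gt = simulate_rr_series(rr_cfg)
        beat_times.extend((gt.beat_times[:-1] + t_offset).tolist())
        _, _, eye_sc, mouth_sc, egt = simulate_eye_state_stream(eye_cfg)
        eye_parts.append(eye_sc)
        mouth_parts.append(mouth_sc)
        perclos_parts.append(egt.true_perclos)
        yawn_parts.append(egt.true_yawn_rate)
        t_offset += window_s
    pulse_seed = int(child[-1].generate_state(1)[0] % (2**31 - 1))
    pcfg = PulseSimConfig(fs_hz=fs_hz, noise_sd=noise_sd, drift_amp=drift_amp, seed=pulse_seed)
    bt = np.array(beat_times)
    trace = render_pulse_waveform(bt, pcfg, duration_s=duration)
    gt = GroundTruth(
        beat_times=bt,
        true_intervals=np.diff(bt),
        true_perclos=float(np.mean(perclos_parts)),
        true_yawn_rate=float(np.mean(yawn_parts)),
        labels=labels,
    )
    return SyntheticSession(
        trace=trace,
        fs_hz=fs_hz,
        eye_scores=np.concatenate(eye_parts),
        mouth_scores=np.concatenate(mouth_parts),
        fps=fps,
        window_s=window_s,
        labels=labels,
        ground_truth=gt,
    )
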