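"""Model input vectors from windowed HRV and facial streams.

The heart-rate model consumes a 1024-sample vector built from per-second
samples of three trailing-window HRV quantities — instantaneous heart
rate, interval SD, and LF/HF — concatenated and linearly resampled to
exactly 1024 values.  The face model consumes a 600-sample vector of
per-0.1 s eye and mouth openness means over a 60 s window (300 eye
samples followed by 300 mouth samples).  Both compositions are package
conventions (the source architectures fix only the input lengths); they
are deterministic and documented in docs/methods.md.
"""

from __future__ import annotations

import numpy as np

from . import hrv

__all__ = ["build_hr_input", "build_face_input", "HR_INPUT_LEN", "FACE_INPUT_LEN"]

HR_INPUT_LEN = 1024
FACE_INPUT_LEN = 600


def _resample(x: np.ndarray, n: int) -> np.ndarray:
    if x.size == n:
        return x.astype(float)
    src = np.linspace(0.0, 1.0, x.size)
    dst = np.linspace(0.0, 1.0, n)
    return np.interp(dst, src, x)


def build_hr_input(
    beat_times: np.ndarray,
    sub_window_s: float = 60.0,
    hop_s: float = 1.0,
    spectral_cfg: hrv.SpectralConfig | None = None,
    out_len: int = HR_INPUT_LEN,
) -> np.ndarray:
    """1024-vector of [HR(t) | SD(t) | LF/HF(t)] per-second samples.

    Each quantity is evaluated on the trailing ``sub_window_s`` of beats
    at every ``hop_s`` step; two sessions differing only in heart-rate
    level differ only in the HR third of the vector.
    """
    bt = np.sort(np.asarray(beat_times, dtype=float))
    if bt.size < 4:
        raise ValueError("need at least 4 beats")
    total = bt[-1] - bt[0]
    if total < sub_window_s + hop_s:
        raise ValueError(
            f"need at least {sub_window_s + hop_s:g} s of beats, got {total:.1f} s"
        )
    cfg = spectral_cfg or hrv.SpectralConfig(segment_len=128)
    eval_times = np.arange(bt[0] + sub_window_s, bt[-1] + 1e-9, hop_s)
    hr_series, sd_series, ratio_series = [], [], []
    dd_all = np.diff(bt)
    for t in eval_times:
        m = (bt > t - sub_window_s) & (bt <= t)
        wb = bt[m]
        if wb.size < 5:
            continue
        dd = np.diff(wb)
        td = hrv.time_domain(dd)
        hr_series.append(60.0 / td.mean_s)
        sd_series.append(td.sd_s)
        try:
            spec = hrv.spectral_features(wb, dd, cfg)
            r = spec.lf_hf_ratio
        except ValueError:
            r = np.nan
        ratio_series.append(r if np.isfinite(r) else 0.0)
    if len(hr_series) < 2:
        raise ValueError("insufficient beat history for the HR feature vector")
    parts = [np.asarray(hr_series), np.asarray(sd_series), np.asarray(ratio_series)]
    per = out_len // 3
    sizes = [per, per, out_len - 2 * per]
    return np.concatenate([_resample(p, s) for p, s in zip(parts, sizes)])


def build_face_input(
    eye_scores: np.ndarray,
    mouth_scores: np.ndarray,
    fps: float = 20.0,
    window_s: float = 60.0,
    bin_s: float = 0.1,
    out_len: int = FACE_INPUT_LEN,
) -> np.ndarray:
    """600-vector: per-0.1 s eye openness means then mouth openness means."""
    eye = np.asarray(eye_scores, dtype=float)
    mouth = np.asarray(mouth_scores, dtype=float)
    if eye.shape != mouth.shape or eye.ndim != 1:
        raise ValueError("need aligned 1-D eye and mouth streams")
    n_window = int(round(window_s * fps))
    if eye.size < n_window:
        raise ValueError(f"need {n_window} frames, got {eye.size}")
    eye = eye[:n_window]
    mouth = mouth[:n_window]
    n_bins = int(round(window_s / bin_s))

    def binned(x: np.ndarray) -> np.ndarray:
        edges = np.linspace(0, n_window, n_bins + 1).astype(int)
        return np.array([x[a:b].mean() if b > a else x[min(a, n_window - 1)]
                         for a, b in zip(edges[:-1], edges[1:])])

    half = out_len // 2
    return np.concatenate([_resample(binned(eye), half), _resample(binned(mouth), out_len - half)])


def regime_hr_dataset(
    n_per_class: int,
    seed: int = 0,
    duration_s: float = 130.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Labeled HR feature vectors drawn from the awake/fatigue regimes.

    Returns (X of shape (2*n, 1024), y in {0 awake, 1 fatigued}),
    interleaved so any contiguous split stays class-balanced.
    """
    from . import synthetic as syn

    X, y = [], []
    for i in range(n_per_class):
        for label, preset in ((0, "awake"), (1, "fatigue")):
            rr, _ = syn.regime_configs(preset, seed + 100_000 * label + i, duration_s=duration_s)
            _, gt = syn.simulate_rr_series(rr)
            X.append(build_hr_input(gt.beat_times))
            y.append(label)
    return np.asarray(X), np.asarray(y)


def regime_face_dataset(
    n_per_class: int,
    seed: int = 0,
    score_noise_sd: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Labeled face feature vectors drawn from the awake/fatigue regimes."""
    from . import synthetic as syn
    from dataclasses import replace

    X, y = [], []
    for i in range(n_per_class):
        for label, preset in ((0, "awake"), (1, "fatigue")):
            _, eye = syn.regime_configs(preset, seed + 100_000 * label + i)
            eye = replace(eye, score_noise_sd=score_noise_sd)
            _, _, es, ms, _ = syn.simulate_eye_state_stream(eye)
            X.append(build_face_input(es, ms, fps=eye.fps, window_s=eye.window_s))
            y.append(label)
    return np.asarray(X), np.asarray(y)
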