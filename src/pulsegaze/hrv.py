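"""Heart-rate-variability features from inter-beat (DD) intervals.

Time domain: MEAN and SD of the DD series (SD with divisor N, the
population form).  Frequency domain: the DD series is resampled onto a
uniform 4 Hz grid (cubic interpolation) to form a tachogram, whose power
spectral density is estimated by averaged Hamming-windowed periodograms
over segments stepped by a quarter of the segment length (75% overlap),
each normalized by the window-power factor U = (1/L) * sum D(m)^2.
LF power integrates 0.04-0.15 Hz, HF 0.15-0.40 Hz; LF/HF is the fatigue
index (sympathovagal balance rises with drowsiness).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "TimeDomainFeatures",
    "SpectralConfig",
    "SpectralFeatures",
    "time_domain",
    "build_tachogram",
    "segment",
    "welch_psd",
    "band_powers",
    "spectral_features",
]


@dataclass(frozen=True)
class TimeDomainFeatures:
    mean_s: float
    sd_s: float
    n_intervals: int


@dataclass(frozen=True)
class SpectralConfig:
    """Welch estimation and band-integration parameters.

    ``step_divisor=4`` gives the quarter-length step (75% overlap);
    2 gives the conventional 50% overlap.
    """

    tachogram_fs: float = 4.0
    segment_len: int = 256
    window_fn: str = "hamming"
    step_divisor: int = 4
    lf_band: tuple[float, float] = (0.04, 0.15)
    hf_band: tuple[float, float] = (0.15, 0.40)

    def __post_init__(self) -> None:
        if self.segment_len % 4 != 0:
            raise ValueError("segment_len must be divisible by 4")
        if self.step_divisor not in (2, 4):
            raise ValueError("step_divisor must be 2 or 4")
        lf, hf = self.lf_band, self.hf_band
        if not (0 <= lf[0] < lf[1] <= hf[0] < hf[1]):
            raise ValueError("bands must be ascending and disjoint")

    @property
    def step(self) -> int:
        return self.segment_len // self.step_divisor


@dataclass(frozen=True)
class SpectralFeatures:
    freqs: np.ndarray
    psd: np.ndarray
    lf_power: float
    hf_power: float

    @property
    def lf_hf_ratio(self) -> float:
        """LF/HF; +inf when HF is zero (flag, not an exception)."""
        if self.hf_power == 0:
            return float("inf")
        return self.lf_power / self.hf_power


def time_domain(dd: Sequence[float] | np.ndarray) -> TimeDomainFeatures:
    """MEAN and population SD (divisor N) of the interval series."""
    x = np.asarray(dd, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 intervals")
    mean = float(x.mean())
    sd = float(np.sqrt(np.mean((x - mean) ** 2)))
    return TimeDomainFeatures(mean_s=mean, sd_s=sd, n_intervals=x.size)


def build_tachogram(
    beat_times: np.ndarray,
    dd: np.ndarray | None = None,
    fs_out: float = 4.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Cubic interpolation of (beat time, interval) pairs onto a uniform grid.

    Each interval is anchored at the time of its terminating beat.
    Returns (grid times, interval values).
    """
    t = np.asarray(beat_times, dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 beats to build a tachogram")
    if dd is None:
        dd = np.diff(t)
    dd = np.asarray(dd, dtype=float)
    anchors = t[1:] if dd.size == t.size - 1 else t
    if anchors.size != dd.size:
        raise ValueError("beat_times / dd length mismatch")
    spline = CubicSpline(anchors, dd)
    grid = np.arange(anchors[0], anchors[-1], 1.0 / fs_out)
    return grid, spline(grid)


def segment(y: np.ndarray, cfg: SpectralConfig) -> np.ndarray:
    """Fully contained overlapping segments, shape (J, L), step L/4."""
    x = np.asarray(y, dtype=float)
    L, step = cfg.segment_len, cfg.step
    if x.size < L:
        raise ValueError(f"series of {x.size} samples shorter than one segment ({L})")
    J = (x.size - L) // step + 1
    return np.stack([x[i * step : i * step + L] for i in range(J)])


def _window(cfg: SpectralConfig) -> np.ndarray:
    from scipy.signal import get_window

    return get_window(cfg.window_fn, cfg.segment_len, fftbins=True)


def welch_psd(y: np.ndarray, cfg: SpectralConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Averaged windowed periodograms; one-sided density (power per Hz).

    Each segment is mean-subtracted (the tachogram's ~1 s DC offset would
    otherwise leak into the LF band through the window sidelobes),
    windowed, and normalized by the window-power factor U so the estimate
    is asymptotically unbiased; interior bins are doubled so the
    integrated density matches the signal variance.
    """
    cfg = cfg or SpectralConfig()
    segs = segment(y, cfg)
    D = _window(cfg)
    L = cfg.segment_len
    fs = cfg.tachogram_fs
    U = float(np.sum(D**2)) / L
    segs = segs - segs.mean(axis=1, keepdims=True)
    spec = np.abs(np.fft.rfft(segs * D, axis=1)) ** 2 / (L * U * fs)
    psd = spec.mean(axis=0)
    if L % 2 == 0:
        psd[1:-1] *= 2.0
    else:
        psd[1:] *= 2.0
    freqs = np.fft.rfftfreq(L, d=1.0 / fs)
    return freqs, psd


def band_powers(
    freqs: np.ndarray, psd: np.ndarray, cfg: SpectralConfig | None = None
) -> SpectralFeatures:
    """Trapezoidal band integrals of the PSD and the LF/HF ratio."""
    cfg = cfg or SpectralConfig()
    if freqs[-1] < cfg.hf_band[1]:
        raise ValueError("PSD grid does not cover the HF band")

    def integrate(band: tuple[float, float]) -> float:
        lo, hi = band
        m = (freqs >= lo) & (freqs <= hi)
        if m.sum() < 2:
            return 0.0
        return float(np.trapezoid(psd[m], freqs[m]))

    return SpectralFeatures(
        freqs=freqs,
        psd=psd,
        lf_power=integrate(cfg.lf_band),
        hf_power=integrate(cfg.hf_band),
    )


def spectral_features(
    beat_times: np.ndarray,
    dd: np.ndarray | None = None,
    cfg: SpectralConfig | None = None,
) -> SpectralFeatures:
    """Tachogram -> Welch PSD -> band powers, with the segment length
    shrunk (to a multiple of 4) when the tachogram is short."""
    cfg = cfg or SpectralConfig()
    _, tach = build_tachogram(beat_times, dd, cfg.tachogram_fs)
    if tach.size < cfg.segment_len:
        L = max(16, (tach.size // 4) * 4)
        if L < 16 or L > tach.size:
            raise ValueError("tachogram too short for spectral estimation")
        cfg = SpectralConfig(
            tachogram_fs=cfg.tachogram_fs,
            segment_len=L,
            window_fn=cfg.window_fn,
            step_divisor=cfg.step_divisor,
            lf_band=cfg.lf_band,
            hf_band=cfg.hf_band,
        )
    freqs, psd = welch_psd(tach, cfg)
    return band_powers(freqs, psd, cfg)
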