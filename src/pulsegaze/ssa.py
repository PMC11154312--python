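"""Singular spectrum analysis (SSA) pulse separation and filtering.

SSA embeds the raw rPPG series into a Hankel trajectory matrix, factors it
by SVD, and reconstructs additive components by anti-diagonal averaging.
Components whose dominant frequency lies in the cardiac passband
(0.8-4 Hz, i.e. 48-240 bpm) are kept as the pulse estimate; the rest
(respiratory drift, trends, broadband noise) are discarded.  The kept
signal is then detrended with a moving-average baseline and bandpassed
with a zero-phase Hamming-window FIR filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

__all__ = [
    "FilterConfig",
    "SSADecomposition",
    "embed",
    "decompose",
    "reconstruct_component",
    "select_pulse_components",
    "moving_average",
    "moving_average_detrend",
    "bandpass",
    "extract_pulse",
]


@dataclass(frozen=True)
class FilterConfig:
    """Post-SSA filtering parameters.

    ma_window_s
        Moving-average window, seconds.  In the default ``'lowpass'``
        mode the MA is applied as a short centered smoother that knocks
        down in-band high-frequency noise before the FIR (whose 0.8 Hz
        edge already removes respiratory drift); ``'detrend'`` instead
        subtracts a slow MA baseline from the signal.
    band_hz
        FIR passband covering the physiological pulse range.
    fir_taps_s
        FIR length in seconds of taps (forced to an odd tap count).
    """

    ma_window_s: float = 0.167
    band_hz: tuple[float, float] = (0.8, 4.0)
    fir_taps_s: float = 3.0
    window_fn: str = "hamming"
    ma_mode: str = "lowpass"  # 'lowpass' (centered smoother) or 'detrend'

    def __post_init__(self) -> None:
        low, high = self.band_hz
        if not 0.0 < low < high:
            raise ValueError("passband must satisfy 0 < low < high")
        if self.ma_window_s <= 0 or self.fir_taps_s <= 0:
            raise ValueError("window lengths must be positive")
        if self.ma_mode not in ("detrend", "lowpass"):
            raise ValueError("ma_mode must be 'detrend' or 'lowpass'")


def embed(series: np.ndarray, M: int) -> np.ndarray:
    """Hankel trajectory matrix of shape (M, K), K = N - M + 1.

    Row i is the series delayed by i samples; entry (i, j) = series[i + j].
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if not 2 <= M <= n - 1:
        raise ValueError(f"embedding window M={M} outside [2, {n - 1}]")
    # sliding_window_view gives K windows of length M; transpose to M x K
    return np.lib.stride_tricks.sliding_window_view(x, M).T.copy()


@dataclass(frozen=True)
class SSADecomposition:
    """SVD factors of a trajectory matrix with a fixed sign convention."""

    U: np.ndarray  # (M, r) left singular vectors
    sigma: np.ndarray  # (r,) singular values, descending
    V: np.ndarray  # (K, r) right singular vectors

    @property
    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues of A @ A.T (squared singular values)."""
        return self.sigma**2

    @property
    def rank(self) -> int:
        return self.sigma.size

    def component_matrix(self, i: int) -> np.ndarray:
        """Rank-1 component R_i = U_i (sigma_i V_i)^T."""
        return self.sigma[i] * np.outer(self.U[:, i], self.V[:, i])

    def reconstruct(self, indices: Sequence[int] | None, n: int) -> np.ndarray:
        """Series reconstructed from the given components (all if None)."""
        if indices is None:
            indices = range(self.rank)
        indices = list(indices)
        if not indices:
            return np.zeros(n)
        R = sum(self.component_matrix(i) for i in indices)
        return reconstruct_component(R, n)


def decompose(A: np.ndarray) -> SSADecomposition:
    """SVD of the trajectory matrix, sigma descending.

    Sign convention: the largest-magnitude entry of each left vector is
    made positive so the factorization is deterministic.
    """
    A = np.asarray(A, dtype=float)
    if not np.isfinite(A).all():
        raise ValueError("trajectory matrix has non-finite entries")
    try:
        U, s, Vt = np.linalg.svd(A, full_matrices=False)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - numpy rarely fails here
        raise RuntimeError(f"SVD of {A.shape} trajectory matrix failed") from exc
    V = Vt.T
    flip = np.sign(U[np.abs(U).argmax(axis=0), np.arange(U.shape[1])])
    flip[flip == 0] = 1.0
    return SSADecomposition(U=U * flip, sigma=s, V=V * flip)


def reconstruct_component(R: np.ndarray, n: int) -> np.ndarray:
    """Anti-diagonal (Hankelization) averaging of a trajectory-shaped matrix.

    output[t] is the mean of all entries (i, j) with i + j = t; with
    R of shape (M, K) this yields a series of length M + K - 1 = n.
    """
    R = np.asarray(R, dtype=float)
    M, K = R.shape
    if M + K - 1 != n:
        raise ValueError(f"shape {R.shape} cannot reconstruct length {n}")
    idx = np.add.outer(np.arange(M), np.arange(K)).ravel()
    sums = np.bincount(idx, weights=R.ravel(), minlength=n)
    counts = np.bincount(idx, minlength=n)
    return sums / counts


def dominant_frequency(series: np.ndarray, fs: float) -> float:
    """Frequency (Hz) of the largest-magnitude DFT bin, DC included."""
    x = np.asarray(series, dtype=float)
    spec = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    return float(freqs[int(np.argmax(spec))])


def select_pulse_components(
    dec: SSADecomposition,
    n: int,
    fs: float,
    passband: tuple[float, float] = (0.8, 4.0),
    energy_floor: float = 0.01,
) -> list[int]:
    """Indices of components whose dominant frequency lies in the passband.

    Components carrying less than ``energy_floor`` of the total squared
    singular value are skipped: with a generous embedding window the
    pulse concentrates into a few strong components while broadband
    noise spreads thinly over many, so the floor is where SSA actually
    denoises.  An empty selection is valid and flagged with a warning
    (nothing pulse-like in the signal).
    """
    low, high = passband
    total = float(np.sum(dec.sigma**2))
    selected: list[int] = []
    for i in range(dec.rank):
        if total > 0 and dec.sigma[i] ** 2 < energy_floor * total:
            continue
        g = reconstruct_component(dec.component_matrix(i), n)
        if low <= dominant_frequency(g, fs) <= high:
            selected.append(i)
    if not selected:
        warnings.warn("no SSA component in the cardiac passband", stacklevel=2)
    return selected


def moving_average(series: np.ndarray, L: int) -> np.ndarray:
    """Sliding-window mean; output[i] = mean(series[i .. i+L-1]), length N-L+1."""
    x = np.asarray(series, dtype=float)
    if not 1 <= L <= x.size:
        raise ValueError(f"window L={L} outside [1, {x.size}]")
    c = np.cumsum(np.concatenate(([0.0], x)))
    return (c[L:] - c[:-L]) / L


def moving_average_detrend(series: np.ndarray, L: int) -> np.ndarray:
    """Subtract a centered moving-average baseline (same length as input)."""
    x = np.asarray(series, dtype=float)
    if not 1 <= L <= x.size:
        raise ValueError(f"window L={L} outside [1, {x.size}]")
    baseline = uniform_filter1d(x, size=L, mode="nearest")
    return x - baseline


def bandpass(series: np.ndarray, fs: float, cfg: FilterConfig | None = None) -> np.ndarray:
    """Zero-phase Hamming-window FIR bandpass (default 0.8-4 Hz)."""
    cfg = cfg or FilterConfig()
    low, high = cfg.band_hz
    if high >= fs / 2:
        raise ValueError(f"passband top {high} Hz >= Nyquist {fs / 2} Hz")
    numtaps = int(round(cfg.fir_taps_s * fs)) | 1  # odd
    taps = sps.firwin(numtaps, [low, high], pass_zero=False, window=cfg.window_fn, fs=fs)
    x = np.asarray(series, dtype=float)
    padlen = min(3 * numtaps, x.size - 1)
    return sps.filtfilt(taps, [1.0], x, padlen=padlen)


def extract_pulse(
    series: np.ndarray,
    fs: float,
    M: int | None = None,
    cfg: FilterConfig | None = None,
) -> np.ndarray:
    """Full pulse-separation chain: SSA -> component selection -> MA -> bandpass.

    M defaults to two seconds of samples (covering a full cardiac cycle
    down to 30 bpm, which concentrates the pulse into few components).
    If no SSA component falls in the passband the raw series is passed
    to the filters unchanged, so downstream stages still see data.
    """
    x = np.asarray(series, dtype=float)
    cfg = cfg or FilterConfig()
    if M is None:
        M = max(2, min(int(round(2 * fs)), x.size - 1))
    A = embed(x, M)
    dec = decompose(A)
    idx = select_pulse_components(dec, x.size, fs, cfg.band_hz)
    pulse = dec.reconstruct(idx, x.size) if idx else x.copy()
    L = max(1, int(round(cfg.ma_window_s * fs)))
    L = min(L, pulse.size)
    if cfg.ma_mode == "detrend":
        pulse = moving_average_detrend(pulse, L)
    else:
        # centered zero-phase application of the Eq-style sliding mean
        pulse = uniform_filter1d(pulse, size=L, mode="nearest")
    return bandpass(pulse, fs, cfg)
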