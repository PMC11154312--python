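"""Raw rPPG trace assembly from per-frame ROI pixels.

The camera signal is the spatial average of the skin pixels inside a
region of interest (ROI), one scalar per frame, collected into a sampled
intensity series at the camera frame rate.  ROI masks come from a
pluggable provider (a face detector + skin segmenter in deployment, the
synthetic fixture generator in tests); this module only consumes them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

__all__ = ["ROIMask", "RawTrace", "spatial_average", "assemble_trace", "select_roi"]


@dataclass(frozen=True)
class ROIMask:
    """Boolean pixel-inclusion grid for one frame.

    ``source`` records whether the mask came from a detector adapter or
    from the synthetic fixture generator.
    """

    mask: np.ndarray
    frame_index: int = 0
    source: str = "fixture"

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", m)
        if not m.any():
            raise ValueError("ROI mask includes no pixels")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class RawTrace:
    """ROI-average intensity series sampled at the camera frame rate.

    ``tau`` (the frame interval) is the reciprocal of ``fs``.
    """

    values: np.ndarray
    fs: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("trace needs at least 2 samples")
        if not np.isfinite(v).all():
            raise ValueError("trace contains non-finite values")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def tau(self) -> float:
        return 1.0 / self.fs

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n) / self.fs

    def sliding_windows(
        self, window_s: float = 30.0, hop_s: float = 1.0
    ) -> Iterator["RawTrace"]:
        """Yield windows of ``window_s`` seconds advanced by ``hop_s`` hops."""
        w = int(round(window_s * self.fs))
        h = int(round(hop_s * self.fs))
        if w < 2 or h < 1:
            raise ValueError("window/hop too short for the frame rate")
        if self.n < w:
            raise ValueError(
                f"trace has {self.n} frames but one {window_s:g} s window "
                f"needs {w}; short by {w - self.n} frames"
            )
        for start in range(0, self.n - w + 1, h):
            yield RawTrace(
                self.values[start : start + w],
                fs=self.fs,
                start_time=self.start_time + start / self.fs,
            )

    def n_windows(self, window_s: float = 30.0, hop_s: float = 1.0) -> int:
        w = int(round(window_s * self.fs))
        h = int(round(hop_s * self.fs))
        if self.n < w:
            return 0
        return (self.n - w) // h + 1


def spatial_average(frame_pixels: np.ndarray, mask: ROIMask) -> float:
    """Arithmetic mean of the in-mask pixel values of one frame."""
    px = np.asarray(frame_pixels, dtype=float)
    if px.shape != mask.mask.shape:
        raise ValueError(f"frame shape {px.shape} != mask shape {mask.mask.shape}")
    vals = px[mask.mask]
    if not np.isfinite(vals).all():
        raise ValueError("non-finite pixel inside ROI")
    return float(vals.mean())


def assemble_trace(
    per_frame_means: Sequence[float] | np.ndarray,
    t: float = 0.0,
    fs: float = 30.0,
) -> RawTrace:
    """Assemble per-frame ROI means into a :class:`RawTrace` starting at ``t``."""
    values = np.asarray(per_frame_means, dtype=float)
    if values.size == 0:
        raise ValueError("no frame means provided")
    return RawTrace(values, fs=fs, start_time=t)


def select_roi(candidate_masks: Sequence[ROIMask], scores: Sequence[float]) -> ROIMask:
    """Pick the highest-scoring candidate ROI; ties go to the lowest index.

    Scores are provider-defined (e.g. achromaticity of a skin superpixel).
    """
    if len(candidate_masks) == 0:
        raise ValueError("no ROI candidates")
    if len(candidate_masks) != len(scores):
        raise ValueError("one score per candidate required")
    s = np.asarray(scores, dtype=float)
    if not np.isfinite(s).any():
        raise ValueError("no candidate has a finite score")
    s = np.where(np.isfinite(s), s, -np.inf)
    return candidate_masks[int(np.argmax(s))]
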