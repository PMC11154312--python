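"""Facial drowsiness features from 5-point landmarks.

From the five landmarks (eye centers, nose tip, lip corners) the module
builds rotated eye and mouth region boxes, classifies per-frame eye and
mouth states from openness scores (the classifier is pluggable — the
face CNN can stand in), and reduces a 60 s window of states to two
rates: PERCLOS (fraction of closed-eye frames) and the yawn-frame
fraction.  Coordinates are 0-based pixels, origin top-left.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "LandmarkSet",
    "RegionBox",
    "FrameStates",
    "FaceWindowRates",
    "eye_boxes",
    "mouth_box",
    "classify_states",
    "window_rates",
    "load_landmarks_csv",
    "boxes_to_frame",
]


@dataclass(frozen=True)
class LandmarkSet:
    """The 5 facial key points: eyes, nose tip, lip corners (x, y) pixels."""

    left_eye: tuple[float, float]
    right_eye: tuple[float, float]
    nose: tuple[float, float]
    mouth_left: tuple[float, float]
    mouth_right: tuple[float, float]

    def __post_init__(self) -> None:
        for p in (self.left_eye, self.right_eye, self.nose, self.mouth_left, self.mouth_right):
            if not np.isfinite(p).all():
                raise ValueError("landmarks must be finite")


@dataclass(frozen=True)
class RegionBox:
    """Rotated rectangle: center, width, height, rotation (radians)."""

    center: tuple[float, float]
    width: float
    height: float
    rotation: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("box dimensions must be positive")


@dataclass(frozen=True)
class FrameStates:
    """Per-frame binary eye (closed) and mouth (yawn) states."""

    eye_closed: np.ndarray
    mouth_yawn: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.eye_closed, dtype=bool)
        m = np.asarray(self.mouth_yawn, dtype=bool)
        object.__setattr__(self, "eye_closed", e)
        object.__setattr__(self, "mouth_yawn", m)
        if e.shape != m.shape:
            raise ValueError("eye and mouth state streams must align")

    @property
    def n_frames(self) -> int:
        return self.eye_closed.size


@dataclass(frozen=True)
class FaceWindowRates:
    """PERCLOS P and yawn rate L over one detection window."""

    perclos: float
    yawn_rate: float
    window_frames: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.perclos <= 1.0 and 0.0 <= self.yawn_rate <= 1.0):
            raise ValueError("rates must lie in [0, 1]")


def _angle(p: tuple[float, float], q: tuple[float, float]) -> float:
    return float(np.arctan2(q[1] - p[1], q[0] - p[0]))


def eye_boxes(lm: LandmarkSet, scale: float = 0.6) -> tuple[RegionBox, RegionBox]:
    """One box per eye, rotated to the interocular line.

    Width = ``scale`` x interocular distance, height = width / 2.
    """
    le, re = np.asarray(lm.left_eye), np.asarray(lm.right_eye)
    dist = float(np.linalg.norm(re - le))
    if dist == 0:
        raise ValueError("eye landmarks coincide")
    alpha = _angle(lm.left_eye, lm.right_eye)
    w = scale * dist
    return (
        RegionBox(center=tuple(le), width=w, height=w / 2.0, rotation=alpha),
        RegionBox(center=tuple(re), width=w, height=w / 2.0, rotation=alpha),
    )


def mouth_box(lm: LandmarkSet) -> RegionBox:
    """Mouth region from the lip-corner line and the nose offset.

    With d the perpendicular distance from the nose tip to the lip-corner
    line, the box spans from d/2 on the nose side of the line to 5d/3 on
    the far side (total height 13d/6), with width the lip-corner distance
    and rotation following the lip-corner line.
    """
    ml, mr = np.asarray(lm.mouth_left, dtype=float), np.asarray(lm.mouth_right, dtype=float)
    nose = np.asarray(lm.nose, dtype=float)
    along = mr - ml
    width = float(np.linalg.norm(along))
    if width == 0:
        raise ValueError("lip-corner landmarks coincide")
    u = along / width
    normal = np.array([-u[1], u[0]])  # unit normal of the lip line
    d_signed = float(np.dot(nose - ml, normal))
    if d_signed == 0:
        raise ValueError("nose lies on the lip-corner line (degenerate geometry)")
    toward_nose = normal if d_signed > 0 else -normal
    d = abs(d_signed)
    mid = (ml + mr) / 2.0
    # edges at +d/2 (nose side) and -5d/3 along toward_nose; center midway
    center = mid + toward_nose * (d / 2.0 - 5.0 * d / 3.0) / 2.0
    return RegionBox(
        center=(float(center[0]), float(center[1])),
        width=width,
        height=13.0 * d / 6.0,
        rotation=_angle(tuple(ml), tuple(mr)),
    )


def classify_states(
    eye_openness: np.ndarray,
    mouth_openness: np.ndarray,
    eye_threshold: float = 0.5,
    mouth_threshold: float = 0.5,
    min_yawn_run: int = 3,
    classifier: Callable[[np.ndarray, np.ndarray], FrameStates] | None = None,
) -> FrameStates:
    """Threshold openness scores into per-frame states.

    Eyes: closed iff openness < ``eye_threshold``.  Mouth: yawn iff
    openness > ``mouth_threshold`` sustained for at least
    ``min_yawn_run`` frames (brief mouth openings are speech, not
    yawns).  A ``classifier`` callable (e.g. the face CNN adapter)
    replaces the rule entirely when given.
    """
    eye = np.asarray(eye_openness, dtype=float)
    mouth = np.asarray(mouth_openness, dtype=float)
    if eye.shape != mouth.shape or eye.ndim != 1:
        raise ValueError("need aligned 1-D eye and mouth score streams")
    if not (np.isfinite(eye).all() and np.isfinite(mouth).all()):
        bad = np.flatnonzero(~(np.isfinite(eye) & np.isfinite(mouth)))
        raise ValueError(f"missing/non-finite scores at frames {bad[:10].tolist()}")
    if classifier is not None:
        return classifier(eye, mouth)
    closed = eye < eye_threshold
    raw_yawn = mouth > mouth_threshold
    yawn = np.zeros_like(raw_yawn)
    i = 0
    n = raw_yawn.size
    while i < n:
        if raw_yawn[i]:
            j = i
            while j < n and raw_yawn[j]:
                j += 1
            if j - i >= min_yawn_run:
                yawn[i:j] = True
            i = j
        else:
            i += 1
    return FrameStates(eye_closed=closed, mouth_yawn=yawn)


def load_landmarks_csv(path) -> list[LandmarkSet]:
    """Read a per-frame 5-point landmark stream.

    Expected columns: frame, lx, ly, rx, ry, nx, ny, mlx, mly, mrx, mry
    (left eye, right eye, nose, mouth corners), sorted by frame.
    """
    import pandas as pd

    df = pd.read_csv(path).sort_values("frame")
    return [
        LandmarkSet(
            left_eye=(r.lx, r.ly),
            right_eye=(r.rx, r.ry),
            nose=(r.nx, r.ny),
            mouth_left=(r.mlx, r.mly),
            mouth_right=(r.mrx, r.mry),
        )
        for r in df.itertuples()
    ]


def boxes_to_frame(landmarks: list[LandmarkSet], scale: float = 0.6):
    """Rotated-rectangle parameters for every frame's three region boxes."""
    import pandas as pd

    rows = []
    for i, lm in enumerate(landmarks):
        left, right = eye_boxes(lm, scale)
        mouth = mouth_box(lm)
        for name, box in (("left_eye", left), ("right_eye", right), ("mouth", mouth)):
            rows.append(
                {
                    "frame": i, "region": name,
                    "cx": box.center[0], "cy": box.center[1],
                    "width": box.width, "height": box.height,
                    "rotation_rad": box.rotation,
                }
            )
    return pd.DataFrame(rows)


def window_rates(states: FrameStates, window_frames: int = 1200) -> FaceWindowRates:
    """Exact count ratios P and L over one fully populated window."""
    if states.n_frames < window_frames:
        raise ValueError(
            f"window needs {window_frames} frames, got {states.n_frames}"
        )
    e = states.eye_closed[:window_frames]
    m = states.mouth_yawn[:window_frames]
    return FaceWindowRates(
        perclos=int(e.sum()) / window_frames,
        yawn_rate=int(m.sum()) / window_frames,
        window_frames=window_frames,
    )
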