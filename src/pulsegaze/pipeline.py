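"""End-to-end orchestration: raw trace + landmark streams -> per-window
fatigue decisions and evaluation reports.

A :class:`PipelineConfig` gathers every stage's parameters, validates
them jointly, round-trips losslessly through YAML, and hashes
canonically so every output file can state exactly which configuration
produced it.  :func:`run_pipeline` is deterministic given the seed: the
same inputs and config yield byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import beats, face, features, fusion, hrv, ssa

__all__ = ["PipelineConfig", "SessionReport", "validate_config", "run_pipeline", "train_models"]


def _from_dict(cls, data: dict, path: str = "") -> Any:
    """Strict dataclass construction: unknown keys are errors."""
    known = {f.name: f for f in fields(cls)}
    kwargs = {}
    for key, val in data.items():
        where = f"{path}.{key}" if path else key
        if key not in known:
            raise ValueError(f"unknown configuration key: {where!r}")
        ftype = known[key].type
        sub = _SUBCONFIGS.get((cls, key))
        if sub is not None:
            if not isinstance(val, dict):
                raise ValueError(f"{where!r} must be a mapping")
            kwargs[key] = _from_dict(sub, val, where)
        elif isinstance(val, list):
            kwargs[key] = tuple(val)
        else:
            kwargs[key] = val
    return cls(**kwargs)


@dataclass(frozen=True)
class DecisionConfig:
    """Rule-based fallback decision thresholds (used when no trained
    models are configured): fatigued iff PERCLOS or LF/HF exceeds its
    threshold."""

    perclos_threshold: float = 0.15
    lf_hf_threshold: float = 1.5
    fused_threshold: float = 0.5


@dataclass(frozen=True)
class ModelPaths:
    hr_checkpoint: str | None = None
    face_checkpoint: str | None = None
    fusion_checkpoint: str | None = None


@dataclass(frozen=True)
class FacialConfig:
    eye_threshold: float = 0.5
    mouth_threshold: float = 0.5
    min_yawn_run: int = 3
    window_frames: int = 1200


@dataclass(frozen=True)
class SSAStageConfig:
    embedding_s: float = 2.0
    energy_floor: float = 0.01


# the PipelineConfig field names shadow the module names in the class body
_FilterConfig = ssa.FilterConfig
_DetectorConfig = beats.DetectorConfig
_SpectralConfig = hrv.SpectralConfig


@dataclass(frozen=True)
class PipelineConfig:
    fs_hz: float = 30.0
    fps: float = 20.0
    window_s: float = 60.0
    seed: int = 0
    ssa: SSAStageConfig = field(default_factory=SSAStageConfig)
    filter: _FilterConfig = field(default_factory=_FilterConfig)
    detector: _DetectorConfig = field(default_factory=_DetectorConfig)
    spectral: _SpectralConfig = field(default_factory=_SpectralConfig)
    facial: FacialConfig = field(default_factory=FacialConfig)
    models: ModelPaths = field(default_factory=ModelPaths)
    decision: DecisionConfig = field(default_factory=DecisionConfig)

    def __post_init__(self) -> None:
        if self.fs_hz <= 0 or self.fps <= 0 or self.window_s <= 0:
            raise ValueError("rates and window duration must be positive")
        if self.filter.band_hz[1] >= self.fs_hz / 2:
            raise ValueError(
                f"filter.band_hz top {self.filter.band_hz[1]} Hz >= Nyquist {self.fs_hz / 2} Hz"
            )
        if self.window_s < self.detector.init_s + 2.0:
            raise ValueError("window_s too short for detector initialization")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return [clean(v) for v in obj]
            return obj

        return yaml.safe_dump(clean(self.to_dict()), sort_keys=True)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


_SUBCONFIGS = {
    (PipelineConfig, "ssa"): SSAStageConfig,
    (PipelineConfig, "filter"): _FilterConfig,
    (PipelineConfig, "detector"): _DetectorConfig,
    (PipelineConfig, "spectral"): _SpectralConfig,
    (PipelineConfig, "facial"): FacialConfig,
    (PipelineConfig, "models"): ModelPaths,
    (PipelineConfig, "decision"): DecisionConfig,
}


def validate_config(raw_text: str) -> PipelineConfig:
    """Parse YAML text into a fully defaulted, validated PipelineConfig."""
    data = yaml.safe_load(raw_text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("configuration must be a YAML mapping")
    return _from_dict(PipelineConfig, data)


@dataclass
class WindowRecord:
    index: int
    t0_s: float
    n_beats: int
    mean_s: float | None
    sd_s: float | None
    lf: float | None
    hf: float | None
    lf_hf: float | None
    perclos: float
    yawn_rate: float
    hr_prob: float | None
    face_prob: float | None
    fused_prob: float | None
    decision: str


@dataclass
class SessionReport:
    config_hash: str
    seed: int
    version: str
    decision_mode: str
    windows: list[WindowRecord]

    def to_json(self) -> str:
        payload = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "decision_mode": self.decision_mode,
            "windows": [dataclasses.asdict(w) for w in self.windows],
        }
        return json.dumps(payload, sort_keys=True, indent=2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(w) for w in self.windows])

    @property
    def decisions(self) -> np.ndarray:
        return np.array([1 if w.decision == "fatigued" else 0 for w in self.windows])


def _load_models(cfg: PipelineConfig):
    m = cfg.models
    if not (m.hr_checkpoint and m.face_checkpoint and m.fusion_checkpoint):
        return None
    return (
        fusion.CNNClassifier.load(m.hr_checkpoint),
        fusion.CNNClassifier.load(m.face_checkpoint),
        fusion.BiLSTMFusion.load(m.fusion_checkpoint),
    )


def run_pipeline(
    cfg: PipelineConfig,
    trace: np.ndarray,
    eye_scores: np.ndarray,
    mouth_scores: np.ndarray,
) -> SessionReport:
    """Run every stage on one session and assemble the per-window report.

    Stage errors are re-raised with the stage name and window index so a
    long batch run points at the offending segment.
    """
    from . import __version__

    trace = np.asarray(trace, dtype=float)
    n_windows = int(trace.size // round(cfg.window_s * cfg.fs_hz))
    n_face_windows = int(eye_scores.size // round(cfg.window_s * cfg.fps))
    n_windows = min(n_windows, n_face_windows)
    if n_windows == 0:
        raise ValueError("inputs shorter than one analysis window")

    try:
        pulse = ssa.extract_pulse(
            trace,
            cfg.fs_hz,
            M=max(2, int(round(cfg.ssa.embedding_s * cfg.fs_hz))),
            cfg=cfg.filter,
        )
        detector_cfg = dataclasses.replace(cfg.detector, include_init_beats=True)
        beat_series = beats.detect_beats(pulse, cfg.fs_hz, detector_cfg)
    except Exception as exc:
        raise RuntimeError(f"stage 'pulse-extraction/beat-detection' failed: {exc}") from exc

    models = _load_models(cfg)
    wf = int(round(cfg.window_s * cfg.fps))
    records: list[WindowRecord] = []
    hr_probs, face_probs = [], []
    for w in range(n_windows):
        t0, t1 = w * cfg.window_s, (w + 1) * cfg.window_s
        wb = beat_series.peak_times[(beat_series.peak_times >= t0) & (beat_series.peak_times < t1)]
        mean_s = sd_s = lf = hf = ratio = None
        try:
            if wb.size >= 3:
                td = hrv.time_domain(np.diff(wb))
                mean_s, sd_s = td.mean_s, td.sd_s
            if wb.size >= 8:
                spec = hrv.spectral_features(wb, cfg=cfg.spectral)
                lf, hf = spec.lf_power, spec.hf_power
                ratio = spec.lf_hf_ratio if np.isfinite(spec.lf_hf_ratio) else None
            states = face.classify_states(
                eye_scores[w * wf : (w + 1) * wf],
                mouth_scores[w * wf : (w + 1) * wf],
                eye_threshold=cfg.facial.eye_threshold,
                mouth_threshold=cfg.facial.mouth_threshold,
                min_yawn_run=cfg.facial.min_yawn_run,
            )
            rates = face.window_rates(states, wf)
        except Exception as exc:
            raise RuntimeError(f"stage 'window-features' failed at window {w}: {exc}") from exc

        hr_p = face_p = None
        if models is not None:
            hr_model, face_model, _ = models
            try:
                vec = features.build_hr_input(wb, sub_window_s=cfg.window_s / 2.0, hop_s=1.0)
                hr_p = float(hr_model.predict_proba(vec)[0, 1])
            except ValueError:
                hr_p = 0.5  # not enough beats in the window: uninformative
            fvec = features.build_face_input(
                eye_scores[w * wf : (w + 1) * wf],
                mouth_scores[w * wf : (w + 1) * wf],
                fps=cfg.fps,
                window_s=cfg.window_s,
            )
            face_p = float(face_model.predict_proba(fvec)[0, 1])
            hr_probs.append(hr_p)
            face_probs.append(face_p)

        records.append(
            WindowRecord(
                index=w, t0_s=t0, n_beats=int(wb.size),
                mean_s=mean_s, sd_s=sd_s, lf=lf, hf=hf, lf_hf=ratio,
                perclos=rates.perclos, yawn_rate=rates.yawn_rate,
                hr_prob=hr_p, face_prob=face_p, fused_prob=None, decision="awake",
            )
        )

    if models is not None:
        _, _, bilstm = models
        seq = np.stack(
            [
                np.array([1 - h, h, 1 - f, f])
                for h, f in zip(hr_probs, face_probs)
            ]
        )[None]
        fused = bilstm.predict_proba(seq)[0, :, 1]
        for rec, p in zip(records, fused):
            rec.fused_prob = float(p)
            rec.decision = "fatigued" if p >= cfg.decision.fused_threshold else "awake"
        mode = "bilstm-fusion"
    else:
        for rec in records:
            fatigued = rec.perclos > cfg.decision.perclos_threshold or (
                rec.lf_hf is not None and rec.lf_hf > cfg.decision.lf_hf_threshold
            )
            rec.decision = "fatigued" if fatigued else "awake"
        mode = "threshold-rule"

    return SessionReport(
        config_hash=cfg.config_hash,
        seed=cfg.seed,
        version=__version__,
        decision_mode=mode,
        windows=records,
    )


def train_models(
    out_dir: str | Path,
    seed: int = 0,
    n_per_class: int = 60,
    epochs: int = 50,
    sequence_len: int = 8,
) -> dict:
    """Train both CNNs and the BiLSTM head on regime-labeled synthetic
    data and write checkpoints; returns held-out accuracies.

    A quarter of each dataset is held out; fusion sequences are built by
    pairing the two models' held-in probabilities window-wise.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    Xh, yh = features.regime_hr_dataset(n_per_class, seed=seed)
    Xf, yf = features.regime_face_dataset(n_per_class, seed=seed + 1)
    n = len(yh)
    split = n - n // 4

    hr_model = fusion.CNNClassifier(fusion.HRModelConfig(), seed=seed)
    hr_res = hr_model.fit(Xh[:split], yh[:split], epochs=epochs, seed=seed)
    face_model = fusion.CNNClassifier(fusion.FaceModelConfig(), seed=seed + 1)
    face_res = face_model.fit(Xf[:split], yf[:split], epochs=epochs, seed=seed + 1)

    hr_acc = float(np.mean(hr_model.predict(Xh[split:]) == yh[split:]))
    face_acc = float(np.mean(face_model.predict(Xf[split:]) == yf[split:]))

    # Fusion training inputs are out-of-fold probabilities (stacking):
    # the final CNNs' held-in outputs are near-perfect one-hots and would
    # never show the fusion head which channel errs; fold-wise models
    # reproduce each channel's real error pattern on unseen windows.
    ph_oof = np.empty((split, 2))
    pf_oof = np.empty((split, 2))
    half = split // 2
    folds = [(np.arange(half), np.arange(half, split)), (np.arange(half, split), np.arange(half))]
    for k, (tr, te) in enumerate(folds):
        m_h = fusion.CNNClassifier(fusion.HRModelConfig(), seed=seed + 10 + k)
        m_h.fit(Xh[tr], yh[tr], epochs=epochs, seed=seed + 10 + k)
        ph_oof[te] = m_h.predict_proba(Xh[te])
        m_f = fusion.CNNClassifier(fusion.FaceModelConfig(), seed=seed + 20 + k)
        m_f.fit(Xf[tr], yf[tr], epochs=epochs, seed=seed + 20 + k)
        pf_oof[te] = m_f.predict_proba(Xf[te])

    ph = hr_model.predict_proba(Xh)
    pf = face_model.predict_proba(Xf)

    # Window labels follow a sticky Markov chain: drowsiness is an episode,
    # not an i.i.d. coin flip, and the temporal persistence is what the
    # BiLSTM exploits to overrule an isolated wrong channel.  Training
    # additionally flips one channel of occasional windows so the head
    # sees single-channel disagreements and learns to resolve them from
    # the other channel plus context.
    def make_seqs(idx_pool, n_seq, ph_src, pf_src, corrupt_p=0.0, p_stay=0.85):
        pool0 = idx_pool[yh[idx_pool] == 0]
        pool1 = idx_pool[yh[idx_pool] == 1]
        seqs, labs = [], []
        for _ in range(n_seq):
            lab = np.empty(sequence_len, dtype=int)
            lab[0] = rng.integers(2)
            for t in range(1, sequence_len):
                lab[t] = lab[t - 1] if rng.random() < p_stay else 1 - lab[t - 1]
            idx = np.array([rng.choice(pool1 if l else pool0) for l in lab])
            block = np.concatenate([ph_src[idx], pf_src[idx]], axis=1)
            if corrupt_p > 0:
                for t in range(sequence_len):
                    if rng.random() < corrupt_p:
                        lo = 0 if rng.random() < 0.5 else 2
                        u = rng.uniform(0.6, 1.0)
                        wrong = 1 - lab[t]
                        block[t, lo + wrong] = u
                        block[t, lo + 1 - wrong] = 1.0 - u
            seqs.append(block)
            labs.append(lab)
        return np.asarray(seqs), np.asarray(labs)

    train_seqs, train_labs = make_seqs(np.arange(split), 48, ph_oof, pf_oof, corrupt_p=0.12)
    test_seqs, test_labs = make_seqs(np.arange(split, n), 8, ph, pf)
    bilstm = fusion.BiLSTMFusion(input_dim=4, hidden=8, seed=seed)
    fus_res = bilstm.fit(train_seqs, train_labs, epochs=200, lr=0.05, seed=seed)
    fusion_acc = float(np.mean(bilstm.predict(test_seqs) == test_labs))

    hr_model.save(str(out / "hr_cnn.npz"))
    face_model.save(str(out / "face_cnn.npz"))
    bilstm.save(str(out / "fusion_bilstm.npz"))
    summary = {
        "hr_accuracy": hr_acc,
        "face_accuracy": face_acc,
        "fusion_accuracy": fusion_acc,
        "hr_epochs": hr_res.epochs_run,
        "face_epochs": face_res.epochs_run,
        "fusion_epochs": fus_res.epochs_run,
        "seed": seed,
    }
    (out / "training_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
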