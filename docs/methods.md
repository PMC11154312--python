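# Methods

This note describes the models and procedures implemented in
`pulsegaze`, the parameters that matter, and the choices made where the
underlying method left the design open.

## Signal model and scope

The package assumes two synchronized per-frame streams from a face
camera:

* a scalar **rPPG intensity** per frame — the spatial mean of the skin
  pixels inside a region of interest (ROI), sampled at the camera rate
  (default 30 frames/s). Face detection, skin segmentation and landmark
  regression are *not* implemented; they enter through a provider
  interface (`trace.ROIMask`, landmark CSV streams), with the synthetic
  generator as the default provider.
* per-frame **eye and mouth openness scores** derived from 5-point
  landmarks (eye centers, nose tip, lip corners), at a nominal 20
  frames/s with 60 s analysis windows of 1200 frames.

Fatigue is decided per 60 s window from two modalities: heart-rate
variability (HRV) computed from camera-detected beats, and
PERCLOS/yawn-rate facial statistics, fused by a bidirectional LSTM over
the window sequence.

## Pulse separation (SSA)

The raw trace is embedded into a Hankel trajectory matrix (window `M`,
default 2 s of samples), factored by SVD, and additive components are
recovered by anti-diagonal averaging. A component is kept as pulse if

1. its dominant DFT frequency lies in the cardiac band 0.8–4 Hz
   (48–240 bpm), and
2. it carries at least 1% of the total squared singular value.

The energy floor is where SSA actually denoises: with a 2 s embedding
window the quasi-periodic pulse concentrates into a handful of strong
components while broadband sensor noise spreads thinly over the rest.
A 1 s window (one cardiac cycle) proved too short to achieve that
concentration, which is why the default is 2 s. An empty selection is a
valid, warned outcome (no pulse-like structure) and falls back to the
raw series so downstream stages still run.

The kept signal is then smoothed by a short centered moving average
(default 0.167 s ≈ 5 samples at 30 Hz) and bandpassed by a zero-phase
Hamming-window FIR (0.8–4 Hz, 3 s of taps). Two remarks:

* The moving average is applied as a *low-pass*, exactly what a sliding
  mean is. It cannot remove respiratory wander — the FIR's 0.8 Hz low
  edge does that (≈80 dB at 0.2 Hz) — but it is essential against
  in-band 2.5–4 Hz noise, which the detector's five-point derivative
  amplifies roughly threefold relative to the ~1.2 Hz pulse
  fundamental. A `ma_mode='detrend'` option instead subtracts a slow MA
  baseline, for users who want an explicit detrending stage.
* All filtering is zero-phase (centered MA, forward-backward FIR), so
  beat times read off the filtered waveform are not lag-shifted.

## Beat detection (improved Pan–Tompkins)

Chain: five-point numerical differentiation (edge samples by
replication) → normalization to unit maximum magnitude → Shannon energy
`−x²·ln x²` (0 at x=0) → centered moving-window integration (default
0.15 s; 0.18 s available) → adaptive dual-threshold decision.

Thresholds: a signal level ST and noise level NT are seeded from the
candidate envelope peaks of the first 3 s (ST = max/3, NT = mean/2) and
updated exponentially: `new/8 + 7·old/8` for the matching class, with
decision thresholds always `T1 = NT + (ST − NT)/4` and `T2 = T1/2`.
Beats are barred within a 200 ms refractory period. A gap exceeding
1.66× the mean of the last eight inter-beat (DD) intervals triggers a
search-back over the gap's rejected candidates with the lowered
threshold `T2`; a recovered peak pulls ST harder (`DP/4 + 3·ST/4`) and
is marked `provenance='searchback'`.

Two design points matter at camera rates, where the pulse is a smooth
~0.35 s wave rather than a narrow QRS complex:

* **Waveform-referenced peaks with inline redundancy removal.** The
  Shannon envelope of a wide smooth pulse has several lobes per beat
  (the energy is zero both at zero slope *and* at the maximum slope, so
  each flank splits in two). Every accepted envelope peak is therefore
  mapped to the largest waveform sample within ±0.75 of a refractory
  period (±0.15 s), and a detection landing within the refractory
  period of the previous beat replaces it only if its envelope value is
  larger. The mapping radius is deliberately *below* the refractory
  period so that lobes of one pulse always merge while two legitimate
  beats never can. Reported beat times index the waveform, not the
  envelope.
* **DD bookkeeping on refined beats.** The last-eight-DD buffer that
  gates search-back is derived from the final beat list. Feeding it raw
  envelope acceptances (which include sub-refractory duplicate lobes)
  collapses the reference interval and makes search-back recover noise
  in every ordinary gap.

The 3 s initialization segment is excluded from reported beats by
default (`include_init_beats` restores it), since its thresholds are
retrospective.

## HRV features

Time domain: MEAN and SD of the DD intervals with divisor `N` (the
population form, as the method defines it).

Frequency domain: the (unevenly spaced) DD series is anchored at each
interval's terminating beat time, cubic-spline interpolated onto a
uniform 4 Hz tachogram, and its PSD estimated by averaged
Hamming-windowed periodograms over `L = 256`-sample segments (64 s)
stepped by `L/4` (75% overlap; a conventional 50% mode is available).
Each periodogram is normalized by the window-power factor
`U = (1/L)·ΣD(m)²` and converted to a one-sided density so the
integrated PSD matches the signal variance. Segments are mean-subtracted
first: the tachogram rides on a ~1 s DC offset whose sidelobe leakage
would otherwise contaminate the LF band. When a window's tachogram is
shorter than `L`, the segment length shrinks to the largest fitting
multiple of 4 (never below 16 samples).

Band edges follow the HRV standard: LF 0.04–0.15 Hz, HF 0.15–0.40 Hz;
LF/HF is reported as `+inf` (a flag, not an exception) when HF is zero.
The implementation is cross-checked in the tests against
`scipy.signal.welch` at identical settings.

## Facial features

From the 5 landmarks: the eye boxes are centered on each eye, rotated to
the interocular line, with width = 0.6 × interocular distance and
height = width/2 (the 0.6 scale makes the height rule operational; the
method ties neither to a measurable quantity). The mouth box takes `d`
as the perpendicular distance from the nose tip to the lip-corner line
and spans from `d/2` on the nose side to `5d/3` beyond it (height
`13d/6`), rotated with the lip line. Both constructions are equivariant
under translation and rotation of the landmark set.

Per-frame states come from a pluggable classifier; the default rule is
closed iff eye openness < 0.5, and yawn iff mouth openness > 0.5
sustained ≥ 3 frames (brief openings are speech). PERCLOS `P` and yawn
rate `L` are exact count ratios over 1200-frame windows.

## Classifiers and fusion

Both CNNs are stride-1, valid-padding 1-D networks with no pooling (the
conv stack is flattened directly, as specified): the HR model takes a
1024-vector through three 32-filter convolutions (kernels 16, 8, 4) and
fully connected layers of 256 and 128; the face model takes a 600-vector
through three 24-filter convolutions (kernels 10, 5, 3) and layers of
128 and 64; each ends in dropout (0.5) and a 2-way softmax. Training is
Adam (lr 10⁻³), cross-entropy, batch 32, ≤ 50 epochs with early stop
once the epoch loss falls below 10⁻³; inference is deterministic
(dropout off). The networks, backpropagation and Adam are implemented
directly in numpy; the tests check the convolution forward pass against
a direct-loop reference and the gradients against finite differences.

**Input compositions** (the architectures fix only the lengths; these
are package conventions):

* HR 1024-vector: per-second samples of instantaneous HR, interval SD,
  and LF/HF over a trailing 60 s sub-window, concatenated as three
  thirds and linearly resampled to 1024.
* Face 600-vector: per-0.1 s means of eye openness (300 values) then
  mouth openness (300 values) over the 60 s window.

**LSTM cell**: gates `Γ = σ(W[h,x]+b)`, candidate `C̃ = tanh(W_c[h,x]+b_c)`,
state `C_t = Γ_u·C̃ + Γ_f·C_{t−1}`, and output `h_t = Γ_o·C_t` — the
cell state leaves through the output gate *without* a tanh, following
the method as printed. `standard_lstm=True` restores the conventional
`h_t = Γ_o·tanh(C_t)`. The **BiLSTM head** runs one cell forward and one
backward over the per-window `[p_hr, p_face]` probability sequence and
feeds the concatenated hidden states to a learned softmax — this learned
layer realizes the "weighted" combination of the two modalities.
Swapping the directions (and the head's weight blocks) while reversing
time reproduces the predictions exactly.

**Fusion training** uses stacking: the head is trained on *out-of-fold*
CNN probabilities (2 folds), on sequences whose window labels follow a
sticky Markov chain (stay probability 0.85) — drowsiness is an episode,
not an i.i.d. coin flip, and this temporal persistence is what lets the
BiLSTM overrule an isolated wrong channel. Because well-separated
synthetic regimes yield almost no natural disagreements, training
sequences additionally have one channel of ~12% of windows flipped to a
confident wrong probability, so the head sees single-channel conflicts
and learns to resolve them from the other channel plus context.

**Metrics**: Se = TP/(TP+FN), +P = TP/(TP+FP), and a detection-style
Acc = TP/(TP+FP+FN) with no TN term, exactly as the method defines it;
the conventional (TP+TN)/total accuracy is reported separately to avoid
confusion. Beat-level matching is greedy one-to-one within a tolerance
(one frame on clean signals, two under noise).

## Synthetic data: what it emulates, and what it does not

The generator defines the conditions every claim in the test suite is
measured under.

* **RR series**: interval `i` = 60/HR + LF and HF sinusoids (defaults
  0.1 and 0.25 Hz) evaluated at the cumulative beat time, plus Gaussian
  jitter. The analytic LF/HF power ratio is `(a_LF/a_HF)²`. A
  configuration that produces a non-positive interval is rejected.
* **Pulse waveform**: one raised-cosine pulse per beat, default width
  0.35 s — the steep systolic-wave-like feature of a real PPG cycle —
  plus a respiratory-band drift sinusoid and white Gaussian noise. SNR
  statements refer to broadband noise at the camera rate. The clean
  argmax of each pulse falls within half a sample of its beat time.
* **Eye/mouth streams**: exactly `round(fraction × frames)` marked
  frames laid out in blink-length (0.3 s) and yawn-length (2 s) runs
  placed uniformly at random; ground-truth fractions are exact
  rationals.
* **Regimes**: per-window parameters are drawn uniformly from ranges
  whose direction follows the physiology — fatigue raises interval SD
  (jitter 0.035–0.055 s vs 0.010–0.020 s), LF/HF (amplitude ratios
  giving ≈2–8 vs ≈0.1–0.7), eye closure (0.20–0.40 vs 0.02–0.08) and
  yawning (0.05–0.15 vs 0–0.02). The magnitudes are package choices;
  the source material reports only the direction of change.

What the generator does **not** emulate: real PPG morphology (dicrotic
notch, amplitude modulation), motion artifacts, illumination changes,
skin-tone optics, missing frames, or landmark jitter. Passing tests
therefore demonstrate the *algorithmic* correctness and noise behavior
of the chain under controlled conditions, not field performance on
driver video.

## Numerical choices and degenerate inputs

* SVD sign convention: the largest-magnitude entry of each left singular
  vector is made positive, so decompositions are deterministic.
* Envelope candidate peaks are strict local maxima; plateaus take the
  leftmost sample.
* Integration windows round half up (0.15 s × 200 Hz = 30 samples).
* All-zero signals fail fast in `normalize` (no slope to detect);
  empty ROI masks, coincident landmarks, and a nose on the lip line are
  errors; an all-drift trace yields an empty SSA selection with a
  warning, not an error.
* Window counts use the closed form `floor((N − W)/H) + 1`; only fully
  contained Welch segments are used.
* One root seed derives all per-stream seeds (`numpy.random.SeedSequence`);
  reports carry the config hash and seed, contain no timestamps, and are
  byte-identical across reruns.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run on 30 s detector traces
(40–180 bpm), 20 noisy seeded runs, 50 LF/HF configurations of 300 s
each, 100 fatigue/awake pairs of 120 s each, and classifier datasets of
60 windows per class with a 25% held-out split; these sizes were chosen
so the statistics stabilize while the whole suite stays interactive.

## Known limitations

* At 40 bpm the pulse fundamental (0.67 Hz) lies below the 0.8 Hz band
  edge; detection then rides on the harmonics. It works on clean
  signals but is the least robust corner under noise.
* The tachogram spectrum assumes enough beats per window; windows with
  fewer than 8 detected beats report time-domain features only.
* `Acc` without a TN term rewards detectors that call everything
  positive less than conventional accuracy does, but it is kept as the
  method's primary accuracy definition.
* The pipeline's rule-based fallback decision (PERCLOS > 0.15 or
  LF/HF > 1.5) is a transparent default for unlabeled operation, not a
  validated clinical threshold.
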