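# Methods

`cecgpose` classifies sleep posture (supine, left lateral, right lateral)
from two channels of capacitive ECG (cECG) recorded by mattress-embedded
electrodes. Because the electrodes are fixed in the mattress while the body
turns, posture changes the projection of the cardiac electrical vector onto
the electrode axes — the same heart produces visibly different ECG
morphology in each posture. The package covers the full experimental loop:
a synthetic-data generator that emulates this physics, signal conditioning,
R-peak detection, per-beat and 30-s segmentation, a bidirectional-LSTM
classifier, and leave-one-subject-out cross-validation (LOSOCV) scored with
per-class sensitivity (SEN), overall accuracy (ACC) and Cohen's kappa.

## Synthetic cECG model

No public dataset pairs mattress cECG with posture labels, so the generator
is a first-class, tested component rather than a fixture.

**Cardiac source.** Each beat is a sum of five Gaussian waves (P, Q, R, S, T)
on the cardiac phase circle, in the spirit of the classic
Gaussian-wave/dipole ECG simulators. Unlike a scalar template, every wave
carries its own projection axis in the frontal plane, so the instantaneous
dipole traces a 2-D loop. Channel *k* (lead angle φ_k) of a subject in
posture *p* (rotation θ_p about the body's longitudinal axis) sees wave *w*
with amplitude

    a_w · gain_k · cos(α_w + θ_p − φ_k)

which is exactly the "rotate the loop, project onto a fixed lead" physics
that makes posture classification from cECG possible. Defaults:
θ = {supine 0°, left −60°, right +60°}, φ = {0°, 75°}. These values are a
fixed convention chosen to give distinct, non-degenerate projections for
all three postures on at least one channel; they claim no anatomical
fidelity and are overridable.

**Inter-subject variability.** `make_subject(seed)` jitters wave amplitudes
(±25%), timings (±4%), widths (±15%) and projection axes (±12°), draws a
sleeping heart rate from N(62, 7²) bpm clipped to [45, 90] (sleep HR sits
well below resting wake values), per-channel coupling gains in [0.8, 1.2]
(clothing/contact), and nuisance amplitudes: baseline wander 0.1–0.3 mV
(≤ 0.4 Hz), 50 Hz powerline 0.02–0.08 mV, white noise SD 0.03–0.08 mV.
The R wave is drawn in 1.2–2.0 mV and is always the largest wave, so the
5 mV artifact rule can never clip physiology at default gains.

**Rhythm.** RR intervals are i.i.d. truncated-Normal around 60/HR with SD
derived from a per-subject HR SD of 2–6 bpm, plus a 3% sinusoidal modulation
at 0.25 Hz emulating respiratory sinus arrhythmia.

**Protocols.** `short_term_protocol` renders one record per subject with the
three postures in randomized order (default 5 min each, 500 Hz), with
transition segments assumed trimmed (no artifacts). `overnight_protocol`
renders one long record (default 366 min) with random 5–60 min posture
dwells; every posture change injects a 2–5 s motion-artifact burst whose
peak (7–11 mV, renormalized to ≥ 6 mV per channel) always violates the 5 mV
excision bound. Injected bursts are logged on the record so tests can verify
the cleaner removes exactly them.

**Determinism.** Each record's RNG stream is derived from
(seed, CRC32(subject id)); identical inputs give bit-identical records.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: the capacitive coupling transfer function and its
motion-dependent drift, electrode repositioning, clothing effects,
arrhythmias and ectopy, muscle-noise bursts below 5 mV, and any overlap of
posture effect with respiration. The separation between postures is a free
knob of the simulator (set by θ and the wave axes), so synthetic-recovery
accuracies validate the pipeline's mechanics, not clinical performance.

## Preprocessing

* **Band-pass** 0.5–40 Hz, 4th-order Butterworth applied forward-backward
  (`sosfiltfilt`) so morphology is not phase-shifted.
* **Artifact excision** flags any sample whose raw amplitude exceeds
  ±5 mV on either channel, pads 0.5 s on each side, and merges runs. The
  rule is applied to raw amplitudes (the threshold is physical); sample
  values are never altered, only a validity mask, so indices stay aligned.
* **R-peak detection** uses the multiscale morphological derivative (MMD):
  for a flat structuring element of length *s*,
  `MMD_s(n) = dilation_s(n) + erosion_s(n) − 2·f(n)` (moving max + moving
  min − twice the signal, centered windows, truncated at the edges), and the
  detector response is the mean of |MMD_s| over scales {21, 31, 41} samples
  at 500 Hz (~40–80 ms, bracketing QRS width). |MMD| is invariant to signal
  polarity, which matters because cECG lead polarity can invert with
  posture. The per-channel responses are **summed into one fused response**:
  posture rotation can null the QRS projection on one lead entirely, and a
  single-channel detector measurably loses beats in whole posture blocks
  (recall ≈ 0.978 on clean synthetic records versus ≥ 0.999 fused).
  Candidates are local maxima of the fused response above an adaptive
  threshold (0.4 × a rolling 98th percentile over 10 s, evaluated on 2.5-s
  hops and interpolated), a 250 ms refractory keeps the larger response, and
  each peak is re-centered on the extremum of max(|ch1|, |ch2|) within
  ±50 ms. Peaks inside excised intervals are dropped.

## Segmentation

A beat spans `[R_i, R_{i+1})` (half-open). Each channel is linearly
resampled to 250 points and then z-scored per segment — resampling first
keeps the advertised invariant that every emitted channel has exactly mean 0
and SD 1; z-scoring before a linear resample would not. Beats that touch
excised samples, cross a posture boundary, or are flat (SD < 1e-9 mV) are
dropped. Windows are disjoint 30-s epochs tiling each posture block
(trailing remainder dropped); a beat belongs to the window containing its
R wave. For the short-term protocol one 5-min excerpt is cut per posture
interval from the start of its first fully valid stretch; for overnight
evaluation each labelled interval is windowed over its whole extent.

## Classifier

Three stacked bidirectional LSTM layers (200/100/50 hidden units per
direction by default; "layer size" is read as per-direction width, so
concatenated outputs are 400/200/100) over the 250-step, 2-feature beat
sequence, followed by a dense softmax over the three postures reading the
concatenated last forward and last backward states of the top layer. The
cell is the peephole-gated LSTM with tanh state activations and logistic
gate activations; all three gate peepholes read the *previous* cell state
c_{t−1} (including the output gate, where the more common convention is
c_t — the c_{t−1} form is implemented deliberately and verified by
gradient checking). Training minimizes mean cross-entropy with Adam
(lr 1e-3, batch 128 — unspecified upstream, standard defaults) for a fixed
150 epochs, no early stopping, no class weighting (short-term classes are
balanced by construction).

No deep-learning framework is used: the network, BPTT and Adam are
implemented in NumPy (`cecgpose.nn`). Analytic gradients are verified
against central-difference numerical gradients in float64 to ~1e-5 relative
error. Engineering choices that matter on one CPU: time-major float32
buffers so every per-step slice is contiguous, the sigmoid-gate block
[i, f, o] stored separately from the tanh candidate, one big GEMM for all
input projections per layer/direction, and a persistent workspace pool so
large buffers are allocated once per shape (repeated page faults otherwise
dominate the arithmetic). With these, one scaled-down LOSOCV fold trains in
roughly 2–3 minutes.

**Scaled configuration.** Full-size training (≈ 600k parameters, 150
epochs) is hours of CPU time, so the package ships a documented desk-scale
configuration used by its own test suite and acceptance run: layers
[64, 32, 16], 30 epochs, same depth, loss, optimizer and everything else.
It preserves every structural property being tested (bidirectionality,
stacking, voting, determinism) at ~20× less compute.

**Window vote.** A window's label is the plurality of its beats' argmax
predictions; ties break to the larger summed probability mass over the
window, then to the fixed class order (S, L, R). Windows with no surviving
beats are excluded from window-level scoring and logged.

## Evaluation

SEN per class is TP/(TP+FN)×100 from the one-vs-rest collapse of the 3×3
confusion matrix; ACC is trace/total×100 (the standard multiclass collapse
of the two-class accuracy formula); kappa = (p_o − p_e)/(1 − p_e) with
p_o = trace/total and p_e = Σ row_i·col_i/total². A truth-empty class has
undefined SEN: it is reported as None, excluded from averages, and logged —
never imputed as 0. Aggregation across subjects is a weighted arithmetic
mean (default weight 1 per subject); rounding (one decimal for percentages,
three for kappa) happens only in rendered tables.

LOSOCV holds out each subject once, re-initializing and re-training the
model per fold with fixed seeds. Every pipeline stage ahead of the model is
stateless (the filter, excision rule, detector and segmentation fit nothing
on data), so train/test leakage is impossible by construction; the fold
loop still asserts the held-out subject contributes no training beats.
Overnight evaluation trains on all short-term records and scores the
artifact-excised overnight record at beat and window level; which training
set the original overnight experiment used is not stated upstream, so
"all short-term subjects" is this package's documented choice.

## Numerical and degenerate-input policy

* Filter cutoffs must satisfy 0 < low < high < fs/2; violations raise.
* MMD scales must be odd and ≥ 3; shrinking windows at sequence edges avoid
  fabricated extrema.
* Records shorter than 2 s refuse peak detection; fewer than 2 peaks refuse
  beat/RR construction; single-class training sets refuse training.
* kappa of an empty or all-agreeing degenerate margin (p_e = 1) is defined
  as 1 when p_o = 1, else 0.
* float32 sigmoid overflow is left to IEEE semantics (exp → inf → sigmoid
  exactly 0); no clipping bias is introduced.
* EDF export uses 16-bit samples over a symmetric per-channel physical
  range (quantization ≤ range/65534), 1-s records, integer rates only.

## Problem sizes used by the shipped runs

The test suite and `scripts/acceptance.py` exercise the pipeline at sizes a
single CPU handles comfortably while keeping every contract intact: cohorts
of 3–15 subjects at 0.5–5 min per posture for arithmetic and detector
checks; the LOSOCV recovery run uses 6 subjects × 3 postures × 60 s with the
[64, 32, 16] model and 30 epochs (the acceptance script uses 4 subjects
under the same conditions); the determinism check uses 3 subjects × 30 s
with an [8, 6, 4] model and 2 epochs, which is sufficient because bitwise
reproducibility does not depend on convergence.

## Known limitations

* Synthetic separability between postures is a simulator knob, not a
  calibrated quantity; accuracy numbers on synthetic cohorts do not
  transfer to real mattresses.
* The 30-s "window mode" is implemented as per-beat classification plus
  majority vote; feeding one resampled 30-s trace to the network is exposed
  only through the segmentation API, not as a first-class trained mode.
* Only S/L/R are modelled; prone is out of scope.
* The EDF reader accepts only the two-channel files this package writes;
  it is not a general EDF implementation.
* CSV records store 6 decimal places (1 nV resolution) — lossy only below
  the simulated noise floor.
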