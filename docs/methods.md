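# Methods

`seizcos` implements a patient-specific seizure detector for multichannel
scalp EEG built around cosine-parameterized convolutions: a multiscale
cosine-convolution (MCC) front end, heterogeneous two-stream cosine
convolution (HTSCC) feature blocks, a calibrated post-processing chain,
segment/event/AUROC evaluation, and branch-wise Grad-CAM. This note
records the model, its assumptions, the defaults, and the design choices
made where the design was genuinely open.

## The cosine kernel

A temporal convolution kernel of length `k` is generated from two scalars,
amplitude `A` and angular frequency `ω` (radians/sample):

    K[m] = A · cos(ω · (m − (k−1)/2)),  m = 0 … k−1.

Properties the implementation relies on (and tests assert): the kernel is
symmetric about its center, so convolution and cross-correlation coincide;
it is linear in `A`; a kernel of length 1 degenerates to `[A]` with `ω`
inert. Each kernel slot costs 2 learnable parameters instead of `k`, a
per-kernel reduction of `(k−2)/k` (77.8 % at k=9). Both `A` and `ω` are
initialized from N(0, 1). `ω` is left unconstrained: values outside
[0, π] alias, and training may exploit that; no wrapping is applied.
Cosine layers carry no bias term by default so the per-kernel count is
exactly 2; bias is configurable.

## Architecture

Input is an 18 × 1024 segment (4 s at 256 Hz, microvolts after filtering;
no z-scoring — batch normalization inside the network handles scale).

* **MCC module.** Three parallel branches with temporal cosine kernels of
  length 9, 5, 1 (32 filters each). Per branch: temporal conv (shared
  across electrodes) → standard spatial conv spanning all 18 electrodes
  (this layer is always a free-weight convolution, never cosine) → batch
  normalization → dropout (0.5) → max pooling (12/12). Branch outputs are
  concatenated along the pooled time axis ("width-wise"); at the defaults
  the branch widths are 84/85/85 bins. Channel-axis concatenation is
  available for experimentation.
* **HTSCC module** (×2). Shallow stream: one cosine conv (k=3), no
  normalization or regularization. Deep stream: two cosine convs (k=3),
  each followed by layer normalization and spatial dropout (0.25, whole
  feature channels). Streams merge by channel concatenation (default) or
  addition. Stream convs use zero-padded "same" convolution so the two
  stream widths always match for merging; the standalone cosine-conv
  operator defaults to "valid" padding.
* **Classifier.** Flatten → dense hidden layer (64, ReLU) → dense →
  softmax over {interictal, ictal}.

Hidden-layer widths, pooling and fc sizes are defaults chosen to match the
architecture's published feature-map shapes (32 filters per branch, ~85
pooled bins per branch); the original model's total parameter counts are
not reconstruction targets. The only pointwise activation is the ReLU on
the hidden dense layer — the convolutional trunk is described without
activation functions in its source description, and max pooling already
provides nonlinearity; this choice is ours and is configurable only by
editing the head.

The layer stack is written directly in numpy (forward caches + manual
backward passes, verified against finite differences); no deep-learning
framework is used. Default compute dtype is float32 (float64 available
via `ModelConfig.dtype`). The first-layer temporal convolutions skip the
gradient with respect to their input — it is never consumed (Grad-CAM
attaches *after* the MCC module) and materializing it is the single
largest memory cost of the backward pass.

## Preprocessing and the patient split

* **Filtering.** Each channel is decomposed by a 5-level Daubechies-4 DWT
  (symmetric padding); only detail bands d3–d5 (4–32 Hz at 256 Hz) are
  kept before reconstruction. The filter runs on the continuous recording
  before segmentation so window edges see no transform transients.
* **Labels.** 4 s windows cut synchronously across channels; a window is
  ictal iff it overlaps any annotated interval (any-overlap, half-open
  `[onset, offset)`, sample index `floor(t·fs)`).
* **Ictal oversampling.** Selected training seizures are concatenated into
  one stream and windowed with step `Δ = ⌊T/n_over⌋` (204 samples at
  n_over = 5, ≈80 % overlap).
* **Interictal training.** `2·n_over` seizure-free chunks of length
  `L_sz/2` each (`L_sz` = total training-seizure duration), placed at
  uniformly spaced positions over the seizure-free sample range excluding
  the calibration span (deterministic stratified placement, shifted right
  on collision), then windowed without overlap. Interictal training
  duration ≈ `n_over · L_sz`, so segment counts are roughly class-balanced
  and no class weighting is used.
* **Calibration.** The earliest contiguous seizure-free span of 20 min
  (default), disjoint from training chunks and the test material; it never
  touches network weights.
* **Test.** Everything else in chronological order. The spans consumed by
  training events, training chunks and calibration are excised and the
  remainder concatenated into one test recording with re-referenced
  annotations. Splice boundaries are a known artifact of this
  representation; they are seizure-free on both sides by construction.

No guard margin is placed around seizures beyond non-overlap, and no
artifact-rejection stage exists beyond the DWT filter.

## Training

Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8), cross-entropy, batch 128,
shuffled each epoch, no early stopping. Learning rate starts at 2e-4 and
decays by 0.89125 every 20 epochs, clamped at 2e-5 (0.89125²⁰ ≈ 0.1, so
the floor is reached at epoch 400; the clamp reconciles the stated decay
count with the stated final rate). Full-scale runs use 500 epochs;
desk-scale synthetic benchmarks use 10–15 (the synthetic task separates
within ~5). Training is deterministic for a fixed seed on one device:
shuffling and dropout draw from one seeded generator. Per-batch validation
is not performed (it has no effect on weights); per-epoch loss/accuracy
are logged instead.

## Post-processing

Scores `x_t` (per 4 s segment) pass through:

1. **MAF** — `y_t = (2N+1)⁻¹ Σ_{n=−N}^{N} x_{t+n}`; boundary points use the
   mean over the in-range part of the window (length-preserving).
2. **Threshold** — label 1 iff `y_t > Thr` (strict).
3. **Collar** — every positive run grows by `K` segments on each side
   (K counts 4 s segments; the unit is a design choice).
4. Maximal positive runs become events `[i·d, (j+1)·d)`.

`(N, Thr, K)` is calibrated per patient: among grid points
(N ∈ 0–6, Thr ∈ 0.1–0.9 step 0.1, K ∈ 0–6) whose pipeline detects every
*training* seizure event (any overlap) when applied to the training-event
score stream, choose the one minimizing false-alarm events on the
seizure-free calibration stream; ties break by smaller K, smaller N, then
Thr nearest 0.5. If no point detects all training events the calibrator
warns and returns the best-detection point. The objective itself is a
design choice — only the calibration data it may use was prescribed.

## Evaluation

Segment metrics are the usual confusion-matrix rates (percentages; a
missing class makes the corresponding rate undefined and it is reported
as n/a). Event scoring uses any overlap on half-open intervals: a marked
seizure is detected iff ≥1 predicted event overlaps it; a predicted event
is false iff it overlaps no marked seizure; multiple hits on one seizure
count once and are not false; FDR = false events / test hours. The
fixed-post-processing AUROC smooths scores with a 24 s window — six 4 s
segments, implemented as an asymmetric 6-tap mean (3 past, current,
2 future) because a centered odd window cannot span exactly 24 s — and
dilates the *reference labels* by 6 segments (the collar applied to truth,
since scores are continuous); both are interpretations and are flagged as
such. Across-patient summaries report mean ± population SD
(the convention that reproduces printed across-patient spreads such as
97.98 ± 4.60); the pooled event sensitivity `100·Σdetected/Σmarked` is
also provided, since the two aggregators differ.

## Grad-CAM

Computed against the concatenated MCC output with the ictal logit
(pre-softmax) as target, in evaluation mode: channel weights are the
global average of the gradient over a feature block; the map is the
rectified weighted channel sum. The concatenated width W splits into
three sequential blocks of `⌊W/3⌋` bins with the remainder on the last
block (the published 256-vs-3×86 width inconsistency is inherited; the
split rule is a repair). Block maps are resized to the input sample axis
by linear interpolation; the fused map is their pointwise mean. Maps are
max-normalized (zero maps stay zero) — only relative attention is
meaningful, and normalized maps are invariant to positive rescaling of
the logits.

## Synthetic data

The generator emulates fixed-rate multichannel recordings: per-channel
1/f-shaped Gaussian background (β = 1, ~20 µV RMS) plus a deterministic
10 Hz rhythm and white sensor noise, with injected seizure episodes from
three morphologies (spike-wave composites at ~3 Hz, amplitude-ramped
~6 Hz rhythmic bursts, sparse asymmetric sharp waves), 50 µV at unit
gain. Two features matter for realism and were deliberate choices:

* the per-channel ictal gain (uniform in [0.5, 1.5]) is drawn **once per
  channel**, not per event, emulating a patient-stable spatial
  distribution of seizure activity — without this a classifier can key on
  each event's random scalp pattern and patient-specific training cannot
  generalize across events;
* spike-wave events **wax and wane** (~2.5 s discharge bursts separated by
  ~1 s lulls), as electrographic seizures are discontinuous — this is what
  makes windows straddling a seizure boundary carry a learnable partial
  signature at all.

One global seed spawns a counter-based substream per channel, so adding
channels never reshuffles existing ones; recordings are bit-reproducible
from (config, seed). The generator does **not** model artifacts
(EMG/EOG), inter-channel propagation delays, nonstationary background, or
any physiologically validated dynamics, so passing synthetic benchmarks
demonstrates that the pipeline's machinery is correct and can recover
injected events — not clinical performance. The standard synthetic
patient used by the benchmarks is a 2 h, 18-channel record with two
training seizures (30 s) and six held-out seizures (30–40 s) at gain 6,
leaving a >20 min seizure-free stretch for calibration.

## Problem sizes of the shipped benchmarks

The test-suite and acceptance-script runs use the standard 2 h synthetic
patient, 15 training epochs, and a 1 h event-free record for the
chance-level control; these sizes were chosen so a complete run finishes
comfortably on a single CPU core while leaving the detection task
non-trivial. The full 500-epoch schedule and multi-day recordings are
supported by the same code paths but are not exercised by the shipped
benchmarks.

## Known limitations

* The numpy training loop is single-device and unbatched across workers;
  it is meant for desk-scale experiments, not for training on ~1000 h
  archives.
* Concatenating surviving spans into one test recording introduces splice
  boundaries; post-processing smoothing can mix scores across a splice.
* EDF support is limited to plain EDF (16-bit) reading via mne and a
  minimal fixture writer; EDF+ embedded annotations and BDF are out of
  scope. Seizure annotations travel in a sidecar CSV/JSON
  (`onset_s,offset_s`), with a thin converter for CHB-MIT-style summary
  text files.
* Calibration assumes the calibration stream is seizure-free; it is not
  validated against hidden seizures.
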