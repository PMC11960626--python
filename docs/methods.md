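# Methods

This package implements a complete desk-scale pipeline for detecting and
analyzing broiler chicken vocalizations: a signal front end, a
convolutional detector with transfer-learning machinery, the
tagger-driven sample-extraction rule, acoustic call-feature analysis, a
class-balanced evaluation protocol, and a seeded synthetic-call
generator that stands in for the unreleased field-recording database.
This note records the models, the parameters that matter, and the design
choices made where the procedure left room.

## Signal front end

Audio is resampled to 16 kHz (band-limited polyphase) and transformed to
a 64-band log-mel spectrogram: 512-point STFT, Hann window, 160-sample
(10 ms) hop, triangular area-normalized mel filters spanning 50 Hz to
8 kHz. Frames are centred on multiples of the hop with reflection
padding, so a clip of N samples yields exactly `floor(N / 160)` frames
and 1.94 s of audio maps to 194 frames — the detector's receptive field.
Mel powers are converted to dB relative to the per-recording spectrogram
maximum, floored at −80 dB, and mapped linearly onto (−1, 1); silence
therefore sits at −1. The dB reference and dynamic range are not fixed
by the procedure being reproduced; per-recording max-referencing with an
80 dB range is this package's choice and is config-exposed
(`FrontendConfig`). A consequence worth knowing: per-recording scaling
removes absolute loudness as a detector cue; class discrimination rests
on spectro-temporal shape.

Denoising is spectral gating: per-band thresholds at the (rolling) mean
plus 1.5 SD of the band's dB magnitude, a sigmoid soft mask 3 dB wide,
mask smoothing over 3 bands × 5 frames, inversion via overlap-add. With
a supplied noise clip the statistics are stationary; without one they
are estimated from the clip itself with a ~1 s rolling window
(non-stationary mode). Output length and rate always equal the input;
sub-window clips pass through unchanged with a warning.

## Detector architecture

The detector is fully convolutional: eleven valid (unpadded) 2-D
convolutions with ELU activations and batch normalization, then a 1-D
convolutional head (kernel 1) over the 128 remaining channels. The
declared stack (`netspec.table1()`) reproduces the published per-layer
output shapes for a 194 × 64 input, a 194-frame time receptive field, a
24-frame (240 ms) effective stride, and 1,161,094 trainable parameters
(1.2 M; batch-norm scale and shift are counted as trainable, running
statistics are not). Three heads exist: 5 softmax classes + 1 linear
age neuron (`finetune6`), 6 softmax classes + age (`finetune7`, adds a
background class), and 527 sigmoid outputs for multi-label pre-training
(`pretrain527`). Heads can be swapped without touching body weights.

The engine is written on numpy with BLAS GEMM kernels (per-kernel-offset
accumulation, batch-chunked to stay cache-resident) and reverse-mode
gradients, verified against finite differences. Numerical choices:
He-style truncated-normal initialization for conv weights,
small-variance (0.01) truncated-normal head weights, zero biases;
batch-norm eps 1e-3, running-statistic momentum 0.9; Adam with
eps 1e-7. A frozen layer keeps its weights bit-identical through
training and runs its batch normalization in inference mode.

## Transfer learning

Pre-training optimizes MSE between the sigmoid head and per-clip binary
tag targets (Adam, lr 0.001, batch 32), monitoring macro mean average
precision on a 3 % held-out split and restoring the best snapshot.
Fine-tuning is two-phase: phase 1 trains only the head with the body
frozen; phase 2 clones the model into a five-branch meta-model in which
branch k freezes its first k conv blocks, and trains all branches
jointly (50 epochs, batch 16, Adam lr 0.001 by default). Branch class
probabilities and age outputs are aggregated by arithmetic mean — the
combination rule is not textually fixed in the source; the mean
preserves the probability simplex and reduces variance. The loss is
cross-entropy plus 0.5 × MSE on normalized age (age / 36 days, clamped
to [0, 1]); the age term is masked for background samples and for all
pre-training data. Training data are class-balanced by seeded
oversampling; the checkpoint criterion in both phases is balanced
accuracy on a validation set of 25 recordings per class.

Implementation notes: because the frozen prefixes of all branches hold
identical weights forever, the forward pass computes that prefix once
per input and feeds each branch from the cached activation — an exact
reformulation, not an approximation. In phase 1 the frozen body's
embeddings are likewise computed once per sample on deterministic
center crops and the head is trained on the cache; random 194-frame
crops (with reflection padding for short clips) are used in phase 2 and
pre-training, where body weights move. The optimizer is re-initialized
at the start of phase 2. The background-extended recognizer is trained
by the same two-phase recipe with the 7-output head and background
samples included.

## Sample extraction

An external tagger scores each second of audio for the label subset
{Fowl; Chicken, rooster; Bird; Bird vocalization, bird call, bird song}.
Seconds whose maximum likelihood over those labels strictly exceeds 0.2
are marked ("exceeded" read as strict), marked runs are padded by 1 s on
each side, overlapping or touching padded intervals are consolidated
(equivalently: connected components of the union of padded
neighbourhoods), and a consolidated segment is retained iff its peak
likelihood is at least 0.3 (non-strict). Per-second aggregation across
labels is the maximum — any-label exceedance. The observed 45 s upper
segment length is treated as a property of real data, not a rule; an
optional cap is available but off by default. The tagger itself is
pluggable; tests drive the rule with synthetic likelihood series.

## Call features

Calls are cut with a 10 ms RMS power envelope (dB re full scale,
smoothed over 5 frames) and a dynamic threshold: noise floor = 20th
percentile of the envelope, onset threshold at floor + 0.25 × (peak −
floor), offset 3 dB lower (hysteresis), minimum call 30 ms, merge gap
20 ms, and a 12 dB minimum dynamic range below which a clip is treated
as silence. Because the threshold is level-relative, segmentation is
invariant to amplitude scaling.

Four features per call: length (s); maximum envelope power (dB re full
scale — the absolute reference makes the generator's drawn peak powers
recoverable, whereas the front end's per-recording reference would not
be); fundamental frequency at the frame of maximal energy; and f0 trend
in Hz per 10 ms. The f0 tracker is a YIN-family estimator on 10 ms
frames: cumulative mean normalized difference function, computed after
4× band-limited upsampling of each frame (a 3 kHz fundamental spans
only ~5.3 samples of period at 16 kHz, too coarse for integer lags),
trough candidates filtered by YIN's first-below-threshold rule (0.2) to
suppress octave-down errors, a Viterbi pass that penalizes log-pitch
jumps across frames, sub-sample refinement by maximizing the exact
spectral autocorrelation, and a voicing decision from the selected
trough's aperiodicity (threshold 0.4) over a 400-6000 Hz search range.
The trend is the least-squares slope of voiced f0 against time × 10 ms
(an endpoint-difference estimator is selectable in `FeatureConfig`);
regression was chosen for robustness to frame-level estimator jitter.
Calls with fewer than 3 voiced frames are skipped and logged.
Summaries report the arithmetic mean and sample SD (n − 1) per
(class, week) cell; single-record cells report SD 0, empty cells are
omitted.

## Synthetic bioacoustics

The generator realizes the published per-class, per-week call
statistics (duration, peak power, f0, f0 trend, each mean ± SD for
distress calls, pleasure notes, short peeps and warbles over weeks 1-5;
pleasure notes are undefined after week 3 and the generator refuses
those cells). Feature values are drawn from truncated normals (mean ±
2.5 SD intersected with physical bounds: duration 0.05-2 s, f0
400-6000 Hz, trend ±300 Hz/10 ms, power −90..−3 dBFS). A call is a
harmonic stack (fundamental + 2 harmonics, −8 dB/harmonic, harmonics
above 0.48 × rate dropped) following the drawn contour — linear for
distress/pleasure/short peeps; for warbles, repetitive bow-shaped
elements — arched f0 excursions (depth ~12 % of f0) repeated every
80-150 ms across the call — superposed on the drawn net slope,
matching the described repetitive bow structure of that call type — under an attack-decay
envelope peaking at 25 % of the duration. The waveform is rescaled so
its measured 10 ms peak RMS equals the drawn power in dB re full scale,
closing the loop with the feature extractor. Distress calls come in
bouts of 2-5 repetitions with 80-200 ms gaps and small per-repetition
jitter. Two non-call classes complete the taxonomy: "other" (an
inharmonic 1.5-3.5 kHz noise burst with invented, week-constant
statistics — no published acoustics exist for that class) and
"background" (ventilation-like low-frequency-weighted noise with slow
level modulation, and/or a 50 Hz-harmonic hum; no concentrated
harmonic energy in the 1-6 kHz call band). `make_dataset` embeds one
call (or bout) per clip in background at a configurable SNR (drawn call
peak RMS over background RMS; default 15 dB, 20 dB in the end-to-end
experiment), draws age uniformly within the sample's week (week 5
covers days 29-36), and returns ground truth for every drawn value.

What the generator does not emulate: reverberation and microphone
coloration, overlapping simultaneous calls, flock chorus babble,
realistic "other sounds" diversity, and the heavy-tailed variability of
real vocalizations. Passing tests therefore demonstrate that the
pipeline's machinery is correct and that the training recipe can learn
calls with the published statistics — not field performance on real
recordings.

A deliberate consequence of the published statistics: duration, f0 and
trend alone do **not** separate distress calls from short peeps (their
distributions overlap almost completely; a depth-2 tree ensemble on
those three features reaches only ~0.5 balanced accuracy over the four
call types). The structural cues the generator also realizes — bout
repetition for distress, bow excursion for warbles — are what make the
classes discriminable (~0.9 with them included), and the separability
property test is therefore defined over the full drawn descriptor set.
This mirrors the source data's own observation that the four simple
features overlap strongly across call types.

## Evaluation protocol

Metrics: per-class precision, recall, F1 and class-wise accuracy from
the pooled confusion matrix; global accuracy; balanced accuracy (mean
of per-class recalls — equal to global accuracy on a balanced test
set); and age MAE in days over non-background samples. The protocol
trains the detector n times (10 by default), each time excluding a
different random class-balanced test set (25/class by default) from
training and validation, and pools the union of test predictions. A
clip-level label is the majority vote over step argmaxes with ties
broken by mean probability. Stream inference
(resample → denoise → log-mel → detector) emits one prediction per
240 ms for any clip of at least 1.94 s.

## Reduced-scale end-to-end experiment

The full-scale study conditions (a 2559-recording database, 100 AudioSet
pre-training epochs, 10 × 50-epoch fine-tuning runs) are not
reproducible at desk scale, so the end-to-end acceptance experiment runs
the identical pipeline at reduced size: 34 samples per class-week cell
over weeks 1-3 (102 per class across the six classes — the weeks in
which all four vocalization types are defined), SNR 20 dB, two-phase
fine-tuning with 50 phase-1 epochs (cached-embedding head training) and
3 phase-2 epochs of the five-branch meta-model, evaluated by a single
class-balanced holdout of 10 test samples per class. These sizes are
the package's chosen desk-scale conditions; the protocol, architecture,
losses, oversampling and checkpoint rules are exactly the full-scale
ones.

Known shortfall: three meta-model epochs are roughly 6 % of the
full-scale fine-tuning schedule, and ~100 distinct samples per class
sit far below the ~500 per class the full protocol assumes. At this
scale the detector separates background, "other" sounds and distress
bouts reliably but remains undertrained on the pleasure / short-peep /
warble contour distinctions, and the age head stays coarse; the
end-to-end test computes and reports the resulting pooled balanced
accuracy and age MAE, which fall short of the full-scale targets. The
shortfall is a training-budget effect, not a pipeline defect: longer
probe runs improve monotonically with the schedule (and plateau only
when the small sample count begins to overfit), and every component of
the recipe — freezing, branching, checkpointing, losses, evaluation —
is verified by its own oracle tests.

## Known limitations

* The CNN engine is single-threaded BLAS; it is adequate for the
  reduced experiment but not for full-scale training.
* The spectral-gating denoiser implements the algorithm class with a
  documented contract, not any specific package's numerics.
* The f0 tracker is a light-weight YIN-family implementation; extreme
  SNR or strongly inharmonic calls degrade its voicing decisions.
* Absolute SPL calibration is out of scope; all powers are dB re
  digital full scale.
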