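# broilervoc

Acoustic monitoring of broiler chickens: detect and classify the four
described broiler vocalization types — **distress calls**, **pleasure
notes**, **short peeps** and **warbles** — plus "other" sounds and
vocalization-free background, from farm audio recordings. The package
is aimed at bioacoustics and precision-livestock-farming researchers
who need a tested, self-contained reference implementation of the full
pipeline: signal front end, convolutional detector, transfer-learning
recipe, call acoustics, and evaluation protocol.

## What's inside

* **Front end** (`audio`, `frontend`, `denoise`) — WAV I/O, polyphase
  resampling to 16 kHz, spectral-gating noise suppression, and the
  64-band log-mel representation (512-point STFT, Hann window, 10 ms
  hop, 50 Hz-8 kHz, dB scaled into (−1, 1)).
* **Detector** (`netspec`, `nn`) — a declarative description of the
  12-layer fully convolutional architecture (11 × Conv2D with ELU +
  batch norm, one Conv1D head) with analytic shape / receptive-field /
  stride / parameter calculators, plus a numpy/BLAS training engine
  supporting head swapping, per-layer freezing and the five-branch
  graduated-freezing meta-model. For a 194 × 64 input the stack has a
  receptive field of 194 frames (1.94 s — the minimum input for one
  prediction), an effective stride of 24 frames (240 ms), and 1.2 M
  trainable parameters.
* **Training** (`training`) — multi-label sigmoid pre-training
  (MSE, best-mAP checkpointing), two-phase fine-tuning (head-only, then
  the five-branch meta-model), oversampling to class balance, and the
  multi-task loss: cross-entropy + 0.5 × MSE on the normalized broiler
  age, masked for background samples.
* **Sample extraction** (`extraction`) — turn any tagger's per-second
  likelihoods into retained candidate segments (mark > 0.2, pad ± 1 s,
  consolidate, keep peak ≥ 0.3).
* **Call features** (`features`) — power-envelope call segmentation
  with dynamic thresholding, a YIN-family f0 tracker, and the
  four-feature call description (length, max power, f0 at maximal
  energy, f0 trend in Hz per 10 ms) with per-class/week mean ± SD
  summaries.
* **Synthetic bioacoustics** (`synth`) — a seeded generator of harmonic
  calls following the published per-class, per-week feature statistics
  (plus background noise and bouts), with full ground truth, so the
  whole pipeline is testable without the unreleased recording database.
* **Evaluation + CLI** (`evaluation`, `cli`) — precision / recall / F1 /
  class-wise accuracy / balanced accuracy / age MAE, the repeated
  class-balanced holdout protocol, sliding-window stream inference, and
  `broilervoc` subcommands `synth`, `extract`, `features`, `train`,
  `detect`, `eval`.

## Worked example

Generate a small labeled synthetic dataset, measure call features, and
inspect the detector architecture:

```python
>>> from broilervoc import (table1, layer_output_shape, receptive_field,
...                         effective_stride, count_parameters)
>>> spec = table1()
>>> receptive_field(spec), effective_stride(spec)
(194, 24)
>>> count_parameters(spec, "finetune6")
1161094
>>> layer_output_shape(spec)[:3]
[(192, 62), (190, 60), (94, 29)]
```

The receptive field says one prediction needs 194 spectrogram frames
(1.94 s of audio); the stride says predictions then repeat every 240 ms;
the parameter count rounds to the advertised 1.2 million.

```python
>>> from broilervoc import SynthCallParams, synth_call, segment_calls, extract_features
>>> params = SynthCallParams.from_table("distress", 1)   # week-1 distress calls
>>> clip, truth = synth_call(params, rng_seed=9, pad_s=0.3)
>>> seg = segment_calls(clip)[0]
>>> rec = extract_features(clip, seg)
>>> round(truth.drawn["f0_hz"]), round(rec.f0_hz)
(3097, 3056)
>>> round(truth.drawn["trend_hz_per_10ms"], 1), round(rec.f0_trend_hz_per_10ms, 1)
(-27.8, -25.6)
```

The generator drew a week-1 distress call with a ~3.1 kHz fundamental
descending at ~28 Hz per 10 ms; segmentation plus the YIN-family
tracker recover the pitch within ~1 % and the trend within ~10 % —
the loop-back the test suite checks across all classes and weeks.

From the shell, the same machinery:

```sh
broilervoc synth --n 20 --weeks 1,2,3 --seed 1 --out dataset/
broilervoc features --manifest dataset/manifest.csv --out calls.csv --summary table.csv
broilervoc eval --manifest dataset/manifest.csv --repeats 2 --test-per-class 10 --out report.json
```

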