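"""Evaluation protocol: metrics, repeated holdout, stream inference.

Classification quality is reported as per-class precision, recall, F1
and class-wise accuracy, plus global and balanced accuracy (BACC, the
mean of per-class recalls; on a class-balanced test set it equals
global accuracy). Age estimation quality is the mean absolute error in
days over non-background samples.

The evaluation protocol trains the detector ``n_repeats`` times, each
time holding out a different random class-balanced test set (25 per
class by default); per-repeat reports are aggregated into one pooled
report over the union of test predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .audio import AudioClip, resample
from .denoise import DEFAULT_DENOISE, DenoiseConfig, denoise_spectral_gating
from .frontend import DEFAULT_FRONTEND, FrontendConfig, compute_logmel
from .training import (
    AGE_SPAN_DAYS,
    CLASSES_5,
    CLASSES_6,
    LabeledSample,
    TrainConfig,
    crop_frames,
    finetune_two_phase,
    prepare_spectrograms,
)
from .nn import build_detector
from .netspec import table1

__all__ = [
    "EvalReport",
    "PredictionTimeline",
    "evaluate_classification",
    "repeated_holdout",
    "detect_stream",
    "make_cnn_train_fn",
]


@dataclass
class EvalReport:
    """Classification + age-estimation metrics over one test set."""

    classes: tuple[str, ...]
    confusion: np.ndarray                 # rows = truth, cols = prediction
    per_class: pd.DataFrame               # precision/recall/f1/accuracy
    accuracy: float
    balanced_accuracy: float
    age_mae_days: float | None
    n_test: int
    per_week_confusions: dict | None = None

    def summary(self) -> str:
        lines = [
            f"n_test={self.n_test}  accuracy={self.accuracy:.3f}  "
            f"balanced_accuracy={self.balanced_accuracy:.3f}"
            + (
                f"  age_mae={self.age_mae_days:.2f} days"
                if self.age_mae_days is not None
                else ""
            ),
            self.per_class.round(3).to_string(),
        ]
        return "\n".join(lines)


def evaluate_classification(
    predictions,
    truths,
    ages_pred_days=None,
    ages_true_days=None,
    classes=CLASSES_6,
    weeks=None,
) -> EvalReport:
    """Score predicted labels (and optionally ages) against truth.

    ``ages_*_days`` may contain NaN/None for background samples; the
    MAE is computed over samples whose true class is not background.
    ``weeks`` (optional, per sample) adds per-week confusion matrices.
    """
    classes = tuple(classes)
    predictions = list(predictions)
    truths = list(truths)
    if len(predictions) != len(truths):
        raise ValueError("predictions and truths differ in length")
    for t in truths:
        if t not in classes:
            raise ValueError(f"truth class {t!r} not in the configured class set")
    for p in predictions:
        if p not in classes:
            raise ValueError(f"predicted class {p!r} not in the configured class set")

    k = len(classes)
    index = {c: i for i, c in enumerate(classes)}
    conf = np.zeros((k, k), dtype=int)
    for t, p in zip(truths, predictions):
        conf[index[t], index[p]] += 1

    n = conf.sum()
    rows = []
    recalls = []
    for i, c in enumerate(classes):
        tp = conf[i, i]
        fp = conf[:, i].sum() - tp
        fn = conf[i, :].sum() - tp
        tn = n - tp - fp - fn
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        rows.append(
            {
                "class": c,
                "precision": prec,
                "recall": rec,
                "f1": f1,
                "accuracy": (tp + tn) / n if n else 0.0,
                "support": int(tp + fn),
            }
        )
        if tp + fn:
            recalls.append(rec)
    per_class = pd.DataFrame(rows).set_index("class")
    accuracy = float(np.trace(conf) / n) if n else 0.0
    bacc = float(np.mean(recalls)) if recalls else 0.0

    mae = None
    if ages_pred_days is not None and ages_true_days is not None:
        ap = np.asarray(ages_pred_days, dtype=float)
        at = np.asarray(ages_true_days, dtype=float)
        mask = np.array([t != "background" for t in truths]) & ~np.isnan(at)
        if mask.any():
            mae = float(np.mean(np.abs(ap[mask] - at[mask])))

    per_week = None
    if weeks is not None:
        per_week = {}
        warr = np.asarray(weeks)
        for w in sorted(set(warr[~pd.isna(warr)])):
            sel = warr == w
            sub = np.zeros((k, k), dtype=int)
            for t, p, s in zip(truths, predictions, sel):
                if s:
                    sub[index[t], index[p]] += 1
            per_week[int(w)] = sub

    return EvalReport(
        classes=classes,
        confusion=conf,
        per_class=per_class,
        accuracy=accuracy,
        balanced_accuracy=bacc,
        age_mae_days=mae,
        n_test=int(n),
        per_week_confusions=per_week,
    )


def repeated_holdout(
    dataset: list[LabeledSample],
    n_repeats: int = 10,
    test_per_class: int = 25,
    train_fn=None,
    rng_seed: int = 0,
    classes=None,
) -> tuple[EvalReport, list[EvalReport]]:
    """Repeated class-balanced holdout evaluation.

    Each repeat draws ``test_per_class`` samples per class as a test
    set, excluded from everything ``train_fn`` sees. ``train_fn(train,
    rng)`` must return a predictor ``predict(samples) -> (labels,
    ages_days | None)``. Returns the pooled report over all repeats'
    test predictions plus the per-repeat reports.
    """
    if train_fn is None:
        raise ValueError("train_fn is required")
    if classes is None:
        labels_present = {s.label for s in dataset}
        classes = tuple(c for c in CLASSES_6 if c in labels_present)
    by_class: dict[str, list[int]] = {c: [] for c in classes}
    for i, s in enumerate(dataset):
        if s.label in by_class:
            by_class[s.label].append(i)
    for c in classes:
        if len(by_class[c]) <= test_per_class:
            raise ValueError(
                f"class {c!r} has {len(by_class[c])} samples; "
                f"need more than test_per_class={test_per_class}"
            )

    rng = np.random.default_rng(rng_seed)
    reports = []
    pooled_pred, pooled_true, pooled_ap, pooled_at = [], [], [], []
    for rep in range(n_repeats):
        test_idx = []
        for c in classes:
            test_idx.extend(
                rng.choice(by_class[c], size=test_per_class, replace=False)
            )
        test_set = set(int(i) for i in test_idx)
        train = [s for i, s in enumerate(dataset) if i not in test_set]
        test = [dataset[i] for i in sorted(test_set)]
        predict = train_fn(train, np.random.default_rng(rng.integers(2**31)))
        labels, ages = predict(test)
        true_ages = [
            np.nan if s.age_days is None else s.age_days for s in test
        ]
        rep_report = evaluate_classification(
            labels,
            [s.label for s in test],
            ages_pred_days=ages,
            ages_true_days=true_ages,
            classes=classes,
        )
        reports.append(rep_report)
        pooled_pred.extend(labels)
        pooled_true.extend(s.label for s in test)
        if ages is not None:
            pooled_ap.extend(ages)
            pooled_at.extend(true_ages)
    pooled = evaluate_classification(
        pooled_pred,
        pooled_true,
        ages_pred_days=pooled_ap if pooled_ap else None,
        ages_true_days=pooled_at if pooled_at else None,
        classes=classes,
    )
    return pooled, reports


# ---------------------------------------------------------------------------
# stream inference
# ---------------------------------------------------------------------------


@dataclass
class PredictionTimeline:
    """Per-step detector outputs over a long clip (240 ms spacing)."""

    times_s: np.ndarray            # centre time of each prediction step
    probs: np.ndarray              # (steps, n_classes)
    ages_norm: np.ndarray          # (steps,)
    classes: tuple[str, ...]
    step_seconds: float

    @property
    def n_steps(self) -> int:
        return self.probs.shape[0]

    def step_labels(self) -> list[str]:
        return [self.classes[i] for i in np.argmax(self.probs, axis=1)]

    def majority_label(self) -> str:
        """Dominant class over the timeline: majority vote over step
        argmaxes, ties broken by mean probability."""
        labels = self.step_labels()
        counts = pd.Series(labels).value_counts()
        top = counts[counts == counts.max()].index
        if len(top) == 1:
            return top[0]
        mean_p = self.probs.mean(axis=0)
        return max(top, key=lambda c: mean_p[self.classes.index(c)])

    def age_days(self) -> float:
        return float(np.clip(self.ages_norm.mean(), 0, 1) * AGE_SPAN_DAYS)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probs, columns=list(self.classes))
        df.insert(0, "time_s", self.times_s)
        df["age_norm"] = self.ages_norm
        return df


def detect_stream(
    clip: AudioClip,
    model,
    denoise: bool = True,
    frontend: FrontendConfig = DEFAULT_FRONTEND,
    denoise_config: DenoiseConfig = DEFAULT_DENOISE,
    classes=None,
) -> PredictionTimeline:
    """Run the full inference pipeline over a clip of any length.

    resample -> (spectral-gating denoise) -> log-mel -> detector. The
    clip must cover at least the receptive field (1.94 s) after
    resampling; shorter input raises with the stated minimum.
    """
    clip16 = resample(clip, frontend.sample_rate)
    n_frames = len(clip16) // frontend.hop
    if n_frames < model.min_frames:
        raise ValueError(
            f"clip of {clip.duration:.2f} s yields {n_frames} frames; "
            f"the detector needs at least {model.min_frames} frames "
            f"({model.min_frames * frontend.hop / frontend.sample_rate:.2f} s)"
        )
    if denoise:
        clip16 = denoise_spectral_gating(clip16, config=denoise_config)
    spec = compute_logmel(clip16, frontend)
    x = spec.values.astype(np.float32)[None, ..., None]
    out = model.predict(x)
    probs, age = out["probs"][0], out["age"][0]
    if classes is None:
        classes = CLASSES_5 if probs.shape[1] == 5 else CLASSES_6
    step_s = model.step_frames * spec.hop_seconds
    rf_s = model.min_frames * spec.hop_seconds
    times = rf_s / 2 + step_s * np.arange(probs.shape[0])
    return PredictionTimeline(
        times_s=times,
        probs=probs,
        ages_norm=age,
        classes=tuple(classes),
        step_seconds=step_s,
    )


def make_cnn_train_fn(
    config: TrainConfig,
    frontend: FrontendConfig = DEFAULT_FRONTEND,
    base_model=None,
    val_per_class: int | None = None,
):
    """Build a ``train_fn`` for :func:`repeated_holdout` that runs the
    full two-phase fine-tuning pipeline.

    ``base_model`` supplies pre-trained body weights (it is copied per
    repeat); when absent a fresh detector is initialized per repeat.
    A class-balanced validation split is carved from the training
    samples for checkpoint monitoring.
    """
    vpc = val_per_class if val_per_class is not None else config.val_per_class

    def train_fn(train_samples, rng):
        classes = tuple(
            c for c in CLASSES_6 if any(s.label == c for s in train_samples)
        )
        head = "finetune7" if "background" in classes else "finetune6"
        if base_model is not None:
            model = base_model.copy()
            if model.head_kind != head:
                from .nn import swap_head

                model = swap_head(model, head, rng=int(rng.integers(2**31)))
        else:
            model = build_detector(table1(), head, rng=int(rng.integers(2**31)))
        by_class: dict[str, list[int]] = {c: [] for c in classes}
        for i, s in enumerate(train_samples):
            by_class[s.label].append(i)
        val_idx = set()
        for c in classes:
            take = min(vpc, max(1, len(by_class[c]) // 4))
            val_idx.update(
                int(i) for i in rng.choice(by_class[c], size=take, replace=False)
            )
        val = [train_samples[i] for i in sorted(val_idx)]
        train = [s for i, s in enumerate(train_samples) if i not in val_idx]
        cfg = TrainConfig(
            **{**config.__dict__, "seed": int(rng.integers(2**31)),
               "val_per_class": 1}
        )
        branched, _ = finetune_two_phase(model, train, val, cfg, frontend)

        def predict(samples):
            specs = prepare_spectrograms(samples, frontend)
            labels, ages = [], []
            for i in range(0, len(specs), 32):
                xb = np.stack(
                    [crop_frames(s, cfg.crop_frames) for s in specs[i : i + 32]]
                )[..., None]
                out = branched.predict(xb)
                p = out["probs"].mean(axis=1)
                labels.extend(classes[j] for j in np.argmax(p, axis=1))
                ages.extend(
                    float(np.clip(a, 0, 1) * AGE_SPAN_DAYS)
                    for a in out["age"].mean(axis=1)
                )
            return labels, ages

        return predict

    return train_fn
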