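"""Training procedures for the vocalization detector.

The detector is trained in two stages, mirroring a transfer-learning
recipe: multi-label pre-training with a 527-way sigmoid head (Adam,
lr 0.001, MSE loss, batches of 32, best-mAP checkpointing), then
two-phase fine-tuning on labeled broiler samples — phase 1 trains only
the output head with the conv stack frozen; phase 2 trains the
five-branch meta-model with graduated layer freezing (50 epochs, batch
16, Adam lr 0.001 by default). Training data is class-balanced by
oversampling, and the monitored checkpoint metric is balanced accuracy
on a held-out validation set of 25 recordings per class.

The loss is a weighted multi-task objective: cross-entropy on the class
output plus 0.5 x mean squared error on the normalized-age output; the
age term is masked out for background samples. Age is normalized by the
36-day study span (``age_norm = age_days / 36``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, balanced_accuracy_score

from .audio import AudioClip, read_wav, resample
from .frontend import DEFAULT_FRONTEND, FrontendConfig, compute_logmel
from .nn import Adam, BranchedDetector, DetectorModel, make_branched, softmax

__all__ = [
    "VOCALIZATION_CLASSES",
    "CLASSES_5",
    "CLASSES_6",
    "AGE_SPAN_DAYS",
    "LabeledSample",
    "PretrainSample",
    "TrainConfig",
    "oversample_balance",
    "combined_loss",
    "pretrain",
    "finetune_two_phase",
    "read_manifest",
    "write_manifest",
    "prepare_spectrograms",
]

VOCALIZATION_CLASSES = ("distress", "pleasure", "short_peep", "warble")
CLASSES_5 = VOCALIZATION_CLASSES + ("other",)
CLASSES_6 = CLASSES_5 + ("background",)
AGE_SPAN_DAYS = 36


@dataclass
class LabeledSample:
    """A labeled clip: audio + vocalization class + broiler age in days.

    ``age_days`` is present for every class except ``background``.
    """

    clip: AudioClip
    label: str
    age_days: int | None = None

    def __post_init__(self):
        if self.label not in CLASSES_6:
            raise ValueError(f"unknown class {self.label!r}")
        if self.label == "background":
            if self.age_days is not None:
                raise ValueError("background samples carry no age")
        else:
            if self.age_days is None:
                raise ValueError(f"{self.label!r} sample needs age_days")
            if not 1 <= self.age_days <= AGE_SPAN_DAYS:
                raise ValueError(f"age_days {self.age_days} outside 1..36")

    @property
    def age_norm(self) -> float:
        if self.age_days is None:
            return 0.0
        return min(max(self.age_days / AGE_SPAN_DAYS, 0.0), 1.0)


@dataclass
class PretrainSample:
    """A clip with a 527-dimensional binary tag target for pre-training."""

    clip: AudioClip
    targets: np.ndarray

    def __post_init__(self):
        self.targets = np.asarray(self.targets, dtype=np.float32).reshape(-1)


@dataclass
class TrainConfig:
    pretrain_epochs: int = 100
    phase1_epochs: int = 50
    phase2_epochs: int = 50
    batch_size: int = 16
    pretrain_batch_size: int = 32
    learning_rate: float = 0.001
    age_weight: float = 0.5
    val_per_class: int = 25
    val_fraction_pretrain: float = 0.03
    n_branches: int = 5
    crop_frames: int = 194
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1 or self.pretrain_batch_size < 1:
            raise ValueError("batch sizes must be positive")
        if self.age_weight < 0:
            raise ValueError("age weight must be >= 0")
        if self.val_per_class < 1:
            raise ValueError("validation count must be positive")


# ---------------------------------------------------------------------------
# dataset utilities
# ---------------------------------------------------------------------------


def oversample_balance(dataset: list, rng_seed: int = 0, key=None) -> list:
    """Balance class counts by duplicating under-represented classes.

    Every original sample is retained; each minority class is topped up
    to the majority count with duplicates drawn uniformly (with
    replacement) using ``rng_seed``. ``key`` extracts the class label
    (defaults to the ``label`` attribute).
    """
    if not dataset:
        raise ValueError("cannot balance an empty dataset")
    key = key or (lambda s: s.label)
    rng = np.random.default_rng(rng_seed)
    groups: dict = {}
    for s in dataset:
        groups.setdefault(key(s), []).append(s)
    target = max(len(g) for g in groups.values())
    out = list(dataset)
    for label in sorted(groups):
        g = groups[label]
        deficit = target - len(g)
        if deficit > 0:
            out.extend(g[i] for i in rng.integers(0, len(g), size=deficit))
    return out


def read_manifest(path) -> pd.DataFrame:
    """Read a sample manifest CSV with columns path,label,age_days."""
    df = pd.read_csv(path)
    missing = {"path", "label", "age_days"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


def write_manifest(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def load_manifest_samples(path, root=None) -> list[LabeledSample]:
    """Materialize :class:`LabeledSample` objects from a manifest CSV."""
    import os

    df = read_manifest(path)
    root = root if root is not None else os.path.dirname(str(path))
    out = []
    for row in df.itertuples():
        age = None if pd.isna(row.age_days) else int(row.age_days)
        out.append(
            LabeledSample(read_wav(os.path.join(root, row.path)), row.label, age)
        )
    return out


def prepare_spectrograms(
    samples, frontend: FrontendConfig = DEFAULT_FRONTEND
) -> list[np.ndarray]:
    """Resample + log-mel for a list of samples (front-end run once)."""
    out = []
    for s in samples:
        clip = s.clip if isinstance(s, (LabeledSample, PretrainSample)) else s
        clip = resample(clip, frontend.sample_rate)
        out.append(compute_logmel(clip, frontend).values.astype(np.float32))
    return out


def _pad_frames(values: np.ndarray, frames: int) -> np.ndarray:
    """Reflection-pad a (frames, bands) spectrogram on the time axis."""
    while values.shape[0] < frames:
        pad = min(frames - values.shape[0], values.shape[0] - 1)
        if pad < 1:
            pad = frames - values.shape[0]
            values = np.pad(values, ((0, pad), (0, 0)), mode="edge")
        else:
            values = np.pad(values, ((0, pad), (0, 0)), mode="reflect")
    return values


def crop_frames(values: np.ndarray, frames: int, rng=None) -> np.ndarray:
    """Random (or centered, when ``rng`` is None) fixed-length crop."""
    values = _pad_frames(values, frames)
    slack = values.shape[0] - frames
    if slack == 0:
        return values
    start = (slack // 2) if rng is None else int(rng.integers(0, slack + 1))
    return values[start : start + frames]


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def combined_loss(
    class_probs,
    class_target,
    age_pred,
    age_target_norm,
    age_weight: float = 0.5,
    age_mask=None,
) -> float:
    """Cross-entropy + ``age_weight`` x MSE multi-task loss.

    ``class_probs`` must be a probability distribution (rows summing to
    one); ``class_target`` holds integer class indices. ``age_mask``
    marks samples whose age term counts (False for background); masked
    samples contribute zero to the age loss.
    """
    p = np.atleast_2d(np.asarray(class_probs, dtype=np.float64))
    if not np.allclose(p.sum(axis=-1), 1.0, atol=1e-5) or (p < -1e-9).any():
        raise ValueError("class_probs is not a probability distribution")
    y = np.atleast_1d(np.asarray(class_target, dtype=int))
    ce = float(-np.mean(np.log(np.maximum(p[np.arange(y.size), y], 1e-12))))
    age_pred = np.atleast_1d(np.asarray(age_pred, dtype=np.float64))
    age_t = np.atleast_1d(np.asarray(age_target_norm, dtype=np.float64))
    mask = (
        np.ones_like(age_pred, dtype=bool)
        if age_mask is None
        else np.atleast_1d(np.asarray(age_mask, dtype=bool))
    )
    if mask.any():
        mse = float(np.mean((age_pred[mask] - age_t[mask]) ** 2))
    else:
        mse = 0.0
    return ce + age_weight * mse


def _ce_age_grad(logits, y, age_t, age_mask, age_weight, n_classes):
    """Loss and head-output gradient for a single detector.

    ``logits``: (B, S, n_classes + 1); the clip label applies to every
    prediction step.
    """
    B, S, _ = logits.shape
    probs = softmax(logits[..., :n_classes])
    idx = np.broadcast_to(y[:, None], (B, S))
    picked = np.take_along_axis(probs, idx[..., None], axis=2)[..., 0]
    ce = float(-np.mean(np.log(np.maximum(picked, 1e-12))))
    age = logits[..., n_classes]
    mask = np.broadcast_to(age_mask[:, None], (B, S))
    count = max(int(mask.sum()), 1)
    diff = (age - age_t[:, None]) * mask
    mse = float((diff**2).sum() / count)

    dlogits = np.empty_like(logits)
    dp = probs.copy()
    np.put_along_axis(
        dp, idx[..., None], np.take_along_axis(dp, idx[..., None], axis=2) - 1.0, axis=2
    )
    dlogits[..., :n_classes] = dp / (B * S)
    dlogits[..., n_classes] = age_weight * 2.0 * diff / count
    return ce + age_weight * mse, dlogits.astype(np.float32)


def _branched_ce_age_grad(logits_list, y, age_t, age_mask, age_weight, n_classes):
    """Loss on the branch-mean output and per-branch head gradients."""
    n = len(logits_list)
    probs = [softmax(l[..., :n_classes]) for l in logits_list]
    ages = [l[..., n_classes] for l in logits_list]
    pbar = np.mean(probs, axis=0)
    abar = np.mean(ages, axis=0)
    B, S, _ = pbar.shape
    idx = np.broadcast_to(y[:, None], (B, S))
    picked = np.take_along_axis(pbar, idx[..., None], axis=2)[..., 0]
    ce = float(-np.mean(np.log(np.maximum(picked, 1e-12))))
    mask = np.broadcast_to(age_mask[:, None], (B, S))
    count = max(int(mask.sum()), 1)
    diff = (abar - age_t[:, None]) * mask
    mse = float((diff**2).sum() / count)

    dpbar = np.zeros_like(pbar)
    np.put_along_axis(
        dpbar, idx[..., None], -1.0 / np.maximum(picked, 1e-12)[..., None], axis=2
    )
    dpbar /= B * S
    dabar = age_weight * 2.0 * diff / count
    dlogits_list = []
    for p in probs:
        dp = dpbar / n
        dz = p * (dp - (dp * p).sum(axis=-1, keepdims=True))
        dl = np.empty(p.shape[:2] + (n_classes + 1,), dtype=np.float32)
        dl[..., :n_classes] = dz
        dl[..., n_classes] = dabar / n
        dlogits_list.append(dl)
    return ce + age_weight * mse, dlogits_list


def _sigmoid_mse_grad(logits, targets):
    """MSE between sigmoid outputs and binary targets, with gradient."""
    p = 1.0 / (1.0 + np.exp(-logits))
    t = targets[:, None, :]  # clip-level targets at every step
    diff = p - t
    loss = float(np.mean(diff**2))
    dlogits = (2.0 * diff * p * (1 - p) / diff.size).astype(np.float32)
    return loss, dlogits


# ---------------------------------------------------------------------------
# pre-training
# ---------------------------------------------------------------------------


def pretrain(
    model: DetectorModel,
    dataset: list[PretrainSample],
    config: TrainConfig = TrainConfig(),
    frontend: FrontendConfig = DEFAULT_FRONTEND,
) -> tuple[DetectorModel, pd.DataFrame]:
    """Multi-label pre-training with best-mAP checkpointing.

    Optimizes MSE between the sigmoid head outputs and the per-clip
    binary targets; a small validation split (3% by default) is scored
    each epoch with mean average precision and the best snapshot is
    restored at the end. Returns the (mutated) model and the epoch log.
    """
    if model.head_kind != "pretrain527":
        raise ValueError("pretrain requires the pretrain527 head")
    if len(dataset) < config.pretrain_batch_size:
        raise ValueError(
            f"dataset of {len(dataset)} clips is smaller than one batch "
            f"({config.pretrain_batch_size})"
        )
    log_rows = []
    if config.pretrain_epochs == 0:
        return model, pd.DataFrame(log_rows)

    rng = np.random.default_rng(config.seed)
    specs = prepare_spectrograms(dataset, frontend)
    targets = np.stack([s.targets for s in dataset])
    n_val = max(1, int(round(config.val_fraction_pretrain * len(dataset))))
    order = rng.permutation(len(dataset))
    val_idx, train_idx = order[:n_val], order[n_val:]

    opt = Adam(lr=config.learning_rate)
    best = (-np.inf, None)
    for epoch in range(config.pretrain_epochs):
        perm = rng.permutation(train_idx)
        losses = []
        for i in range(0, len(perm), config.pretrain_batch_size):
            idx = perm[i : i + config.pretrain_batch_size]
            xb = np.stack(
                [crop_frames(specs[j], config.crop_frames, rng) for j in idx]
            )[..., None]
            logits = model.forward_logits(xb, training=True)
            loss, dlogits = _sigmoid_mse_grad(logits, targets[idx])
            model.backward(dlogits)
            opt.step(model.trainable_layers())
            losses.append(loss)
        xv = np.stack(
            [crop_frames(specs[j], config.crop_frames) for j in val_idx]
        )[..., None]
        scores = model.predict(xv)["scores"].mean(axis=1)
        mAP = _mean_average_precision(targets[val_idx], scores)
        log_rows.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_map": mAP}
        )
        if mAP > best[0]:
            best = (mAP, {k: v.copy() for k, v in model.state_arrays().items()})
    if best[1] is not None:
        model.load_state_arrays(best[1])
    return model, pd.DataFrame(log_rows)


#: pseudo tag-vocabulary indices used when pre-training on synthetic
#: clips: each class maps to its own tag plus, for vocalizations, a
#: shared bird/fowl parent tag — the desk-scale analog of multi-label
#: AudioSet targets.
_PSEUDO_TAG_PARENT = 0
_PSEUDO_TAGS = {c: i + 1 for i, c in enumerate(CLASSES_6)}


def pseudo_tag_targets(label: str, n_tags: int = 527) -> np.ndarray:
    """527-dim binary target vector for a labeled synthetic clip."""
    t = np.zeros(n_tags, dtype=np.float32)
    t[_PSEUDO_TAGS[label]] = 1.0
    if label not in ("background", "other"):
        t[_PSEUDO_TAG_PARENT] = 1.0
    return t


def as_pretrain_samples(samples: list) -> list[PretrainSample]:
    """Wrap labeled samples as multi-label pre-training samples."""
    return [PretrainSample(s.clip, pseudo_tag_targets(s.label)) for s in samples]


def _mean_average_precision(y_true, y_score) -> float:
    present = y_true.sum(axis=0) > 0
    if not present.any():
        return 0.0
    return float(
        average_precision_score(y_true[:, present], y_score[:, present], average="macro")
    )


# ---------------------------------------------------------------------------
# two-phase fine-tuning
# ---------------------------------------------------------------------------


def _class_set(model: DetectorModel) -> tuple[str, ...]:
    return CLASSES_5 if model.n_classes == 5 else CLASSES_6


def _encode(samples, classes):
    y = np.array([classes.index(s.label) for s in samples])
    age = np.array([s.age_norm for s in samples], dtype=np.float32)
    mask = np.array([s.label != "background" for s in samples])
    return y, age, mask


def _val_bacc(predict, specs, y, crop, batch=32):
    preds = []
    for i in range(0, len(specs), batch):
        xb = np.stack([crop_frames(s, crop) for s in specs[i : i + batch]])[..., None]
        p = predict(xb)["probs"].mean(axis=1)
        preds.extend(np.argmax(p, axis=1))
    return float(balanced_accuracy_score(y, preds))


def finetune_two_phase(
    model: DetectorModel,
    train: list[LabeledSample],
    val: list[LabeledSample],
    config: TrainConfig = TrainConfig(),
    frontend: FrontendConfig = DEFAULT_FRONTEND,
) -> tuple[BranchedDetector, pd.DataFrame]:
    """Two-phase fine-tuning with BACC-monitored checkpointing.

    Phase 1 trains only the output head (every conv block frozen, so the
    2-D convolution weights stay bit-identical); because the body is
    fixed, its per-sample embeddings are computed once on deterministic
    center crops and the head is trained on the cached features. Phase 2
    builds the graduated-freezing meta-model and trains it end to end
    with random crops and a fresh optimizer. Both phases use the
    oversampled (class-balanced) training set and snapshot the weights
    with the best validation balanced accuracy.
    """
    classes = _class_set(model)
    val_labels = {s.label for s in val}
    for c in classes:
        if c not in val_labels:
            raise ValueError(f"validation set is missing class {c!r}")
    rng = np.random.default_rng(config.seed)

    balanced = oversample_balance(train, rng_seed=config.seed)
    tr_specs = prepare_spectrograms(balanced, frontend)
    va_specs = prepare_spectrograms(val, frontend)
    y_tr, age_tr, mask_tr = _encode(balanced, classes)
    y_va, _, _ = _encode(val, classes)
    C = model.n_classes
    log_rows = []

    # ---- phase 1: head only, cached body features --------------------
    model.freeze_blocks(model.n_blocks)
    if config.phase1_epochs > 0:
        emb = []
        for i in range(0, len(tr_specs), 32):
            xb = np.stack(
                [crop_frames(s, config.crop_frames) for s in tr_specs[i : i + 32]]
            )[..., None]
            emb.append(model.forward_blocks(xb.astype(np.float32), training=False))
        emb = np.concatenate(emb)  # (N, 1, 1, 128)
        emb_va = []
        for i in range(0, len(va_specs), 32):
            xb = np.stack(
                [crop_frames(s, config.crop_frames) for s in va_specs[i : i + 32]]
            )[..., None]
            emb_va.append(model.forward_blocks(xb.astype(np.float32), training=False))
        emb_va = np.concatenate(emb_va)

        opt = Adam(lr=config.learning_rate)
        best = (-np.inf, None)
        for epoch in range(config.phase1_epochs):
            perm = rng.permutation(len(balanced))
            losses = []
            for i in range(0, len(perm), config.batch_size):
                idx = perm[i : i + config.batch_size]
                logits = model.head.forward(emb[idx], training=True)
                loss, dlogits = _ce_age_grad(
                    logits, y_tr[idx], age_tr[idx], mask_tr[idx], config.age_weight, C
                )
                model.head.backward(dlogits, need_dx=False)
                opt.step([model.head])
                losses.append(loss)
            logits_va = model.head.forward(emb_va)
            preds = np.argmax(softmax(logits_va[..., :C]).mean(axis=1), axis=1)
            bacc = float(balanced_accuracy_score(y_va, preds))
            log_rows.append(
                {
                    "phase": 1,
                    "epoch": epoch,
                    "train_loss": float(np.mean(losses)),
                    "val_bacc": bacc,
                }
            )
            if bacc > best[0]:
                best = (bacc, (model.head.W.copy(), model.head.b.copy()))
        if best[1] is not None:
            model.head.W, model.head.b = best[1][0].copy(), best[1][1].copy()

    # ---- phase 2: five-branch meta-model ------------------------------
    model.freeze_blocks(0)
    branched = make_branched(model, config.n_branches)
    if config.phase2_epochs > 0:
        opt = Adam(lr=config.learning_rate)  # optimizer state starts fresh
        best = (-np.inf, None)
        for epoch in range(config.phase2_epochs):
            perm = rng.permutation(len(balanced))
            losses = []
            for i in range(0, len(perm), config.batch_size):
                idx = perm[i : i + config.batch_size]
                xb = np.stack(
                    [crop_frames(tr_specs[j], config.crop_frames, rng) for j in idx]
                )[..., None]
                outs = branched.forward_logits_per_branch(xb, training=True)
                loss, dlist = _branched_ce_age_grad(
                    outs, y_tr[idx], age_tr[idx], mask_tr[idx], config.age_weight, C
                )
                branched.backward_per_branch(dlist)
                opt.step(branched.trainable_layers())
                losses.append(loss)
            bacc = _val_bacc(branched.predict, va_specs, y_va, config.crop_frames)
            log_rows.append(
                {
                    "phase": 2,
                    "epoch": epoch,
                    "train_loss": float(np.mean(losses)),
                    "val_bacc": bacc,
                }
            )
            if bacc > best[0]:
                best = (bacc, branched.snapshot())
        if best[1] is not None:
            branched.load_state_arrays(best[1])
    return branched, pd.DataFrame(log_rows)
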