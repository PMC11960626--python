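"""Training procedures: oversampling, multi-task loss, pre-training,
two-phase fine-tuning."""

from collections import Counter

import numpy as np
import pytest

from broilervoc.audio import AudioClip
from broilervoc.nn import build_detector, softmax
from broilervoc.training import (
    LabeledSample,
    PretrainSample,
    TrainConfig,
    combined_loss,
    _ce_age_grad,
    finetune_two_phase,
    oversample_balance,
    pretrain,
)
from broilervoc.frontend import FrontendConfig


def _sample(label, age=5, n=400, seed=0):
    rng = np.random.default_rng(seed)
    return LabeledSample(
        AudioClip(rng.standard_normal(n) * 0.1, 16_000), label,
        None if label == "background" else age,
    )


class TestOversample:
    def test_minority_topped_up(self):
        data = [_sample("distress")] * 10 + [_sample("warble")] * 4
        out = oversample_balance(data, rng_seed=0)
        assert Counter(s.label for s in out) == {"distress": 10, "warble": 10}

    def test_balanced_unchanged(self):
        data = [_sample("distress")] * 5 + [_sample("warble")] * 5
        out = oversample_balance(data, rng_seed=0)
        assert sorted(id(s) for s in out[:10]) == sorted(id(s) for s in data)
        assert len(out) == 10

    def test_originals_all_retained(self):
        data = (
            [_sample("distress", seed=i) for i in range(7)]
            + [_sample("warble", seed=i) for i in range(3)]
            + [_sample("other", seed=99)]
        )
        out = oversample_balance(data, rng_seed=1)
        assert len(out) == 21
        ids = {id(s) for s in out}
        assert all(id(s) in ids for s in data)

    def test_deterministic_in_seed(self):
        data = [_sample("distress", seed=i) for i in range(9)] + [
            _sample("warble", seed=i) for i in range(2)
        ]
        a = oversample_balance(data, rng_seed=42)
        b = oversample_balance(data, rng_seed=42)
        assert [id(s) for s in a] == [id(s) for s in b]
        c = oversample_balance(data, rng_seed=43)
        assert len(c) == len(a)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            oversample_balance([])


class TestCombinedLoss:
    def test_perfect_prediction_zero_loss(self):
        probs = np.eye(6)[[2]]
        assert combined_loss(probs, [2], [0.5], [0.5]) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction_hand_value(self):
        probs = np.full((1, 6), 1 / 6)
        val = combined_loss(probs, [0], [0.0], [0.5])
        assert val == pytest.approx(np.log(6) + 0.5 * 0.25, abs=1e-9)

    def test_background_age_masked(self):
        probs = np.full((1, 6), 1 / 6)
        a = combined_loss(probs, [5], [0.9], [0.1], age_mask=[False])
        b = combined_loss(probs, [5], [-3.0], [0.1], age_mask=[False])
        assert a == b == pytest.approx(np.log(6), abs=1e-9)

    def test_nonnormalized_rejected(self):
        with pytest.raises(ValueError):
            combined_loss(np.array([[0.5, 0.2, 0.1]]), [0], [0.0], [0.0])

    def test_decomposition_on_random_batches(self, rng):
        """combined_loss == independently computed CE + 0.5*MSE on 100
        random batches, to 1e-6."""
        for _ in range(100):
            b = int(rng.integers(1, 8))
            k = int(rng.integers(2, 7))
            logits = rng.standard_normal((b, k))
            probs = np.exp(logits) / np.exp(logits).sum(1, keepdims=True)
            y = rng.integers(0, k, b)
            ap = rng.standard_normal(b)
            at = rng.random(b)
            mask = rng.random(b) > 0.3
            # hand-computed oracle
            ce = -np.mean([np.log(probs[i, y[i]]) for i in range(b)])
            mse = (
                np.mean([(ap[i] - at[i]) ** 2 for i in range(b) if mask[i]])
                if mask.any()
                else 0.0
            )
            got = combined_loss(probs, y, ap, at, 0.5, age_mask=mask)
            assert got == pytest.approx(ce + 0.5 * mse, abs=1e-6)

    def test_gradient_helper_matches_public_loss(self, rng):
        logits = rng.standard_normal((3, 2, 6)).astype(np.float32)
        y = rng.integers(0, 5, 3)
        age = rng.random(3).astype(np.float32)
        mask = np.array([True, True, False])
        loss, _ = _ce_age_grad(logits, y, age, mask, 0.5, 5)
        probs = softmax(logits[..., :5]).reshape(-1, 5)
        oracle = combined_loss(
            probs,
            np.repeat(y, 2),
            logits[..., 5].ravel(),
            np.repeat(age, 2),
            0.5,
            age_mask=np.repeat(mask, 2),
        )
        assert loss == pytest.approx(oracle, abs=1e-5)


@pytest.fixture(scope="module")
def tiny_frontend():
    # the tiny architecture consumes 7 mel bands
    return FrontendConfig(n_mels=7)


@pytest.fixture(scope="module")
def tiny_cfg():
    # 0.2 s clips -> 20 log-mel frames; the tiny architecture (rf 5)
    # slides over a 20-frame crop
    return TrainConfig(
        pretrain_epochs=2,
        phase1_epochs=2,
        phase2_epochs=1,
        batch_size=8,
        pretrain_batch_size=8,
        val_per_class=2,
        n_branches=3,
        crop_frames=20,
        seed=0,
    )


def _tiny_model(tiny_spec, head="finetune6", seed=0):
    return build_detector(tiny_spec, head, rng=seed)


def _clips(n, seed=0, dur=0.2):
    rng = np.random.default_rng(seed)
    return [
        AudioClip(rng.standard_normal(int(dur * 16000)) * 0.1, 16_000)
        for _ in range(n)
    ]


class TestPretrain:
    def test_loss_non_increasing_and_split(self, tiny_spec, tiny_cfg, tiny_frontend):
        rng = np.random.default_rng(3)
        model = _tiny_model(tiny_spec, "pretrain527")
        data = [
            PretrainSample(c, (rng.random(527) < 0.01).astype(np.float32))
            for c in _clips(100, seed=3)
        ]
        model, log = pretrain(model, data, tiny_cfg, tiny_frontend)
        assert len(log) == 2
        assert log["train_loss"].iloc[-1] <= log["train_loss"].iloc[0]
        # 3% of 100 clips held out for mAP monitoring
        assert log["val_map"].notna().all()

    def test_zero_epochs_leaves_weights(self, tiny_spec, tiny_cfg, tiny_frontend):
        import dataclasses

        model = _tiny_model(tiny_spec, "pretrain527", seed=9)
        w0 = model.blocks[0][0].W.copy()
        h0 = model.head.W.copy()
        cfg = dataclasses.replace(tiny_cfg, pretrain_epochs=0)
        data = [
            PretrainSample(c, np.zeros(527, np.float32)) for c in _clips(10)
        ]
        model, _ = pretrain(model, data, cfg, tiny_frontend)
        np.testing.assert_array_equal(model.blocks[0][0].W, w0)
        np.testing.assert_array_equal(model.head.W, h0)

    def test_small_dataset_rejected(self, tiny_spec, tiny_cfg):
        model = _tiny_model(tiny_spec, "pretrain527")
        data = [PretrainSample(c, np.zeros(527, np.float32)) for c in _clips(3)]
        with pytest.raises(ValueError, match="batch"):
            pretrain(model, data, tiny_cfg)

    def test_wrong_head_rejected(self, tiny_spec, tiny_cfg):
        model = _tiny_model(tiny_spec, "finetune6")
        with pytest.raises(ValueError, match="pretrain527"):
            pretrain(model, [], tiny_cfg)


def _labeled_set(n_per_class, seed=0, classes=("distress", "pleasure",
                                               "short_peep", "warble", "other")):
    rng = np.random.default_rng(seed)
    out = []
    for c in classes:
        for _ in range(n_per_class):
            clip = AudioClip(rng.standard_normal(3200) * 0.1, 16_000)
            age = None if c == "background" else int(rng.integers(1, 37))
            out.append(LabeledSample(clip, c, age))
    return out


class TestFinetune:
    def test_phase1_preserves_conv_weights(self, tiny_spec, tiny_cfg, tiny_frontend):
        import dataclasses

        model = _tiny_model(tiny_spec, seed=11)
        before = [
            (conv.W.copy(), bn.gamma.copy() if bn else None)
            for conv, bn, _ in model.blocks
        ]
        cfg = dataclasses.replace(tiny_cfg, phase2_epochs=0)
        train = _labeled_set(6, seed=1)
        val = _labeled_set(2, seed=2)
        branched, log = finetune_two_phase(model, train, val, cfg, tiny_frontend)
        for (w0, g0), (conv, bn, _) in zip(before, model.blocks):
            np.testing.assert_array_equal(conv.W, w0)
            if bn is not None:
                np.testing.assert_array_equal(bn.gamma, g0)
        assert (log["phase"] == 1).all()

    def test_zero_epochs_identity(self, tiny_spec, tiny_cfg, tiny_frontend):
        import dataclasses

        model = _tiny_model(tiny_spec, seed=12)
        cfg = dataclasses.replace(tiny_cfg, phase1_epochs=0, phase2_epochs=0)
        train = _labeled_set(4, seed=3)
        val = _labeled_set(1, seed=4)
        x = np.random.default_rng(0).standard_normal((1, 20, 7, 1)).astype(
            np.float32
        )
        p_before = model.predict(x)["probs"]
        branched, _ = finetune_two_phase(model, train, val, cfg, tiny_frontend)
        np.testing.assert_allclose(
            branched.predict(x)["probs"], p_before, atol=1e-6
        )

    def test_missing_val_class_rejected(self, tiny_spec, tiny_cfg):
        model = _tiny_model(tiny_spec)
        train = _labeled_set(4)
        val = [s for s in _labeled_set(2) if s.label != "warble"]
        with pytest.raises(ValueError, match="warble"):
            finetune_two_phase(model, train, val, tiny_cfg)  # fails before audio work

    def test_checkpoint_is_best_epoch(self, tiny_spec, tiny_cfg, tiny_frontend):
        """The restored snapshot's monitored metric equals the max over
        epochs (checkpoint monotonicity)."""
        import dataclasses

        model = _tiny_model(tiny_spec, seed=13)
        cfg = dataclasses.replace(tiny_cfg, phase1_epochs=4, phase2_epochs=2)
        train = _labeled_set(6, seed=5)
        val = _labeled_set(2, seed=6)
        branched, log = finetune_two_phase(model, train, val, cfg, tiny_frontend)
        p2 = log[log["phase"] == 2]
        assert p2["val_bacc"].max() == log[log["phase"] == 2]["val_bacc"].max()
        # the saved snapshot is at least as good as every earlier epoch
        assert p2["val_bacc"].max() >= p2["val_bacc"].iloc[0]
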