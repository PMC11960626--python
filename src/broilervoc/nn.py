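"""Trainable convolutional detector built from an :class:`ArchitectureSpec`.

A compact CNN engine on numpy + BLAS: valid 2-D convolutions (evaluated
as per-kernel-offset GEMMs with beta-accumulation, which keeps working
memory small on long inputs), ELU activations, batch normalization, a
dense 1-D head, and reverse-mode gradients for all of it. The engine
exists so the exact detector architecture — including per-layer weight
freezing and the five-branch meta-model used during fine-tuning — is
fully controllable and inspectable from Python.

Layer freezing semantics: a frozen block keeps its convolution weights
and batch-norm parameters bit-identical through any number of training
steps, and its batch normalization runs in inference mode (running
statistics, no updates).
"""

from __future__ import annotations

import copy
import json

import numpy as np
from scipy.linalg.blas import sgemm

from .netspec import (
    HEAD_WIDTHS,
    ArchitectureSpec,
    receptive_field,
    effective_stride,
)

__all__ = [
    "DetectorModel",
    "BranchedDetector",
    "build_detector",
    "swap_head",
    "make_branched",
    "Adam",
    "softmax",
]


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _truncated_normal(rng: np.random.Generator, shape, std: float) -> np.ndarray:
    x = rng.standard_normal(shape)
    # redraw beyond 2 SD (bounded tails keep early activations tame)
    bad = np.abs(x) > 2.0
    while bad.any():
        x[bad] = rng.standard_normal(int(bad.sum()))
        bad = np.abs(x) > 2.0
    return (x * std).astype(np.float32)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class Conv2D:
    """Valid 2-D convolution over (batch, time, freq, channels)."""

    def __init__(self, c_in, c_out, kernel, strides, rng):
        kt, kf = kernel
        fan_in = kt * kf * c_in
        self.W = _truncated_normal(rng, (kt, kf, c_in, c_out), np.sqrt(2.0 / fan_in))
        self.b = np.zeros(c_out, dtype=np.float32)
        self.kernel, self.strides = (kt, kf), tuple(strides)
        self.frozen = False
        self._x = None
        self.dW = None
        self.db = None

    def out_shape(self, t, f):
        (kt, kf), (st, sf) = self.kernel, self.strides
        return (t - kt) // st + 1, (f - kf) // sf + 1

    # batch-chunked evaluation keeps per-offset buffers cache-resident
    _CHUNK_FLOATS = 2_000_000

    def _chunk(self, ot, of, C, B):
        per = max(ot * of * C, 1)
        return max(1, min(B, self._CHUNK_FLOATS // per))

    def forward(self, x, training=False):
        B, T, F, C = x.shape
        (kt, kf), (st, sf) = self.kernel, self.strides
        if T < kt or F < kf:
            raise ValueError(
                f"input {(T, F)} smaller than kernel {(kt, kf)}: shape infeasible"
            )
        ot, of = self.out_shape(T, F)
        c_out = self.W.shape[3]
        out = np.empty((B, ot, of, c_out), dtype=np.float32)
        step = self._chunk(ot, of, C, B)
        for lo in range(0, B, step):
            hi = min(lo + step, B)
            n = (hi - lo) * ot * of
            acc = np.zeros((c_out, n), dtype=np.float32, order="F")
            buf = np.empty((hi - lo, ot, of, C), dtype=np.float32)
            for a in range(kt):
                for b_ in range(kf):
                    np.copyto(
                        buf,
                        x[lo:hi, a : a + ot * st : st, b_ : b_ + of * sf : sf, :],
                    )
                    acc = sgemm(
                        1.0,
                        self.W[a, b_],
                        buf.reshape(n, C).T,
                        beta=1.0,
                        c=acc,
                        trans_a=1,
                        overwrite_c=1,
                    )
            out[lo:hi] = acc.T.reshape(hi - lo, ot, of, c_out)
        out += self.b
        self._x = x if training else None
        return out

    def backward(self, dy, need_dx=True):
        x = self._x
        B, T, F, C = x.shape
        (kt, kf), (st, sf) = self.kernel, self.strides
        ot, of = self.out_shape(T, F)
        dy = np.ascontiguousarray(dy, dtype=np.float32)
        if not self.frozen:
            self.db = dy.reshape(-1, dy.shape[-1]).sum(axis=0)
            self.dW = np.zeros_like(self.W)
        dx = np.zeros_like(x, dtype=np.float32) if need_dx else None
        step = self._chunk(ot, of, C, B)
        for lo in range(0, B, step):
            hi = min(lo + step, B)
            n = (hi - lo) * ot * of
            dy2 = dy[lo:hi].reshape(n, -1)
            buf = np.empty((hi - lo, ot, of, C), dtype=np.float32)
            for a in range(kt):
                for b_ in range(kf):
                    if not self.frozen:
                        np.copyto(
                            buf,
                            x[lo:hi, a : a + ot * st : st,
                              b_ : b_ + of * sf : sf, :],
                        )
                        self.dW[a, b_] += buf.reshape(n, C).T @ dy2
                    if need_dx:
                        dx[lo:hi, a : a + ot * st : st,
                           b_ : b_ + of * sf : sf, :] += (
                            dy2 @ self.W[a, b_].T
                        ).reshape(hi - lo, ot, of, C)
        self._x = None
        return dx

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}


class BatchNorm:
    """Per-channel batch normalization over (batch, time, freq)."""

    eps = 1e-3
    momentum = 0.9

    def __init__(self, c):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.frozen = False
        self._cache = None
        self.dgamma = None
        self.dbeta = None

    def forward(self, x, training=False):
        if training and not self.frozen:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(np.float32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        # in-place affine on the conv output; xhat is recovered in
        # backward from the stored output, avoiding an extra full array
        scale = self.gamma * inv
        shift = self.beta - mean.astype(np.float32) * scale
        x *= scale
        x += shift
        if training:
            self._cache = (x, inv)
        return x

    def backward(self, dy, need_dx=True):
        y, inv = self._cache
        self._cache = None
        if self.frozen:
            if not need_dx:
                return None
            dy *= self.gamma * inv
            return dy
        gamma_safe = np.where(np.abs(self.gamma) < 1e-12, 1e-12, self.gamma)
        xhat = (y - self.beta) / gamma_safe
        self.dgamma = (dy * xhat).sum(axis=(0, 1, 2))
        self.dbeta = dy.sum(axis=(0, 1, 2))
        if not need_dx:
            return None
        dxhat = dy
        dxhat *= self.gamma
        mean_d = dxhat.mean(axis=(0, 1, 2))
        mean_dx = (dxhat * xhat).mean(axis=(0, 1, 2))
        dxhat -= mean_d
        xhat *= mean_dx
        dxhat -= xhat
        dxhat *= inv
        return dxhat

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}


class ELU:
    def __init__(self):
        self._out = None

    def forward(self, x, training=False):
        out = np.maximum(x, np.float32(0.0))
        out += np.expm1(np.minimum(x, np.float32(0.0)))
        if training:
            self._out = out
        return out

    def backward(self, dy, need_dx=True):
        # d/dx ELU = 1 for x > 0, exp(x) = out + 1 for x <= 0,
        # i.e. min(out + 1, 1); the cached output is consumed in place
        out = self._out
        self._out = None
        out += np.float32(1.0)
        np.minimum(out, np.float32(1.0), out=out)
        dy *= out
        return dy


class Head:
    """1-D convolutional output layer (kernel 1): dense over channels."""

    def __init__(self, c_in, kind, rng):
        if kind not in HEAD_WIDTHS:
            raise ValueError(f"unknown head kind {kind!r}")
        self.kind = kind
        self.W = _truncated_normal(rng, (c_in, HEAD_WIDTHS[kind]), 0.01)
        self.b = np.zeros(HEAD_WIDTHS[kind], dtype=np.float32)
        self.frozen = False
        self._h = None
        self.dW = None
        self.db = None

    def forward(self, x, training=False):
        # x: (B, t, 1, C) after the conv stack
        B, t, f, C = x.shape
        if f != 1:
            raise ValueError(f"head expects frequency extent 1, got {f}")
        h = x.reshape(B, t, C)
        logits = h @ self.W + self.b
        self._h = h if training else None
        return logits  # (B, steps, width)

    def backward(self, dlogits, need_dx=True):
        h = self._h
        self._h = None
        B, t, C = h.shape
        d2 = dlogits.reshape(B * t, -1).astype(np.float32)
        if not self.frozen:
            self.dW = h.reshape(B * t, C).T @ d2
            self.db = d2.sum(axis=0)
        if not need_dx:
            return None
        return (d2 @ self.W.T).reshape(B, t, 1, C)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


class DetectorModel:
    """The convolutional detector: conv blocks + output head.

    ``blocks[k]`` is the k-th conv2d block ``(Conv2D, BatchNorm, ELU)``.
    ``head_kind`` selects the output layer: ``finetune6`` (5 softmax class
    neurons + linear age), ``finetune7`` (6 + age) or ``pretrain527``
    (multi-label sigmoid).
    """

    def __init__(self, spec: ArchitectureSpec, head_kind: str, rng=None):
        rng = np.random.default_rng(rng)
        self.spec = spec
        self.head_kind = head_kind
        self.blocks = []
        c_in = 1
        conv2d = [l for l in spec.layers if l.kind == "conv2d"]
        for l in conv2d:
            conv = Conv2D(c_in, l.filters, l.kernel, l.strides, rng)
            bn = BatchNorm(l.filters) if l.batch_norm else None
            self.blocks.append((conv, bn, ELU()))
            c_in = l.filters
        self.head = Head(c_in, head_kind, rng)
        self.min_frames = receptive_field(spec)
        self.step_frames = effective_stride(spec)

    # -- structure -----------------------------------------------------

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def n_classes(self) -> int:
        if self.head_kind == "pretrain527":
            raise ValueError("pre-training head has no class outputs")
        return HEAD_WIDTHS[self.head_kind] - 1

    def frozen_block_count(self) -> int:
        return sum(1 for conv, _, _ in self.blocks if conv.frozen)

    def freeze_blocks(self, k: int) -> None:
        """Freeze the first ``k`` conv2d blocks (weights and BN stats)."""
        for i, (conv, bn, _) in enumerate(self.blocks):
            frozen = i < k
            conv.frozen = frozen
            if bn is not None:
                bn.frozen = frozen

    def n_parameters(self) -> int:
        return sum(
            p.size for layer in self._layers() for p in layer.params().values()
        )

    def _layers(self):
        for conv, bn, _ in self.blocks:
            yield conv
            if bn is not None:
                yield bn
        yield self.head

    def trainable_layers(self):
        return [l for l in self._layers() if not l.frozen]

    # -- forward / backward --------------------------------------------

    def n_steps(self, n_frames: int) -> int:
        if n_frames < self.min_frames:
            raise ValueError(
                f"input of {n_frames} frames is below the minimum of "
                f"{self.min_frames} frames ({self.min_frames / 100:.2f} s)"
            )
        return (n_frames - self.min_frames) // self.step_frames + 1

    def forward_blocks(self, x, start=0, stop=None, training=False):
        for conv, bn, act in self.blocks[start:stop]:
            x = conv.forward(x, training)
            if bn is not None:
                x = bn.forward(x, training)
            x = act.forward(x, training)
        return x

    def forward_logits(self, x, training=False, start_block=0):
        """Raw head outputs of shape (batch, steps, head_width)."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        if start_block == 0:
            self.n_steps(x.shape[1])  # validates minimum length
        h = self.forward_blocks(x, start=start_block, training=training)
        return self.head.forward(h, training)

    def predict(self, x) -> dict:
        """Inference outputs: class probabilities and age (or sigmoid scores)."""
        logits = self.forward_logits(x, training=False)
        if self.head_kind == "pretrain527":
            return {"scores": 1.0 / (1.0 + np.exp(-logits))}
        C = self.n_classes
        return {"probs": softmax(logits[..., :C]), "age": logits[..., C]}

    def backward(self, dlogits, stop_block=0):
        """Backpropagate head-output gradients down to ``stop_block``."""
        dy = self.head.backward(dlogits, need_dx=self.n_blocks > stop_block)
        for i in range(self.n_blocks - 1, stop_block - 1, -1):
            conv, bn, act = self.blocks[i]
            need_dx = i > stop_block
            dy = act.backward(dy)
            if bn is not None:
                dy = bn.backward(dy, need_dx=True)
            dy = conv.backward(dy, need_dx=need_dx)
        return dy

    # -- persistence / copying -----------------------------------------

    def copy(self) -> "DetectorModel":
        return copy.deepcopy(self)

    def state_arrays(self) -> dict:
        state = {}
        for i, layer in enumerate(self._layers()):
            for name, arr in layer.params().items():
                state[f"layer{i}.{name}"] = arr
            if isinstance(layer, BatchNorm):
                for name, arr in layer.buffers().items():
                    state[f"layer{i}.{name}"] = arr
        return state

    def load_state_arrays(self, state: dict) -> None:
        for i, layer in enumerate(self._layers()):
            for name in layer.params():
                layer.__dict__[_attr_for(name)] = state[f"layer{i}.{name}"].copy()
            if isinstance(layer, BatchNorm):
                for name in layer.buffers():
                    layer.__dict__[name] = state[f"layer{i}.{name}"].copy()

    def save(self, path) -> None:
        meta = {
            "spec": self.spec.to_dict(),
            "head_kind": self.head_kind,
            "frozen_blocks": self.frozen_block_count(),
        }
        np.savez(
            path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            **self.state_arrays(),
        )

    @classmethod
    def load(cls, path) -> "DetectorModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            model = cls(
                ArchitectureSpec.from_dict(meta["spec"]), meta["head_kind"], rng=0
            )
            model.load_state_arrays({k: v for k, v in data.items() if k != "__meta__"})
        model.freeze_blocks(meta["frozen_blocks"])
        return model


def _attr_for(name: str) -> str:
    return name


def build_detector(
    spec: ArchitectureSpec, head_kind: str = "finetune6", rng=None
) -> DetectorModel:
    """Initialize a detector (He-style truncated-normal conv weights,
    small-variance head, zero biases)."""
    return DetectorModel(spec, head_kind, rng=rng)


def swap_head(model: DetectorModel, new_head_kind: str, rng=None) -> DetectorModel:
    """Return a copy with a freshly initialized head of ``new_head_kind``.

    Every conv block (weights, batch-norm parameters and statistics) is
    preserved bit-identically; only the output layer is replaced.
    """
    rng = np.random.default_rng(rng)
    out = model.copy()
    c_in = out.head.W.shape[0]
    out.head = Head(c_in, new_head_kind, rng)
    out.head_kind = new_head_kind
    return out


# ---------------------------------------------------------------------------
# five-branch meta-model
# ---------------------------------------------------------------------------


class BranchedDetector:
    """Meta-model of ``n`` detector copies with graduated layer freezing.

    Branch ``k`` has its first ``k`` conv blocks frozen (branch 0 trains
    everything). Class probabilities and age outputs are aggregated by
    arithmetic mean over branches, which keeps the class output on the
    probability simplex.

    Because the frozen prefixes of all branches hold identical (never
    updated) weights, the forward pass evaluates that shared prefix once
    per input and feeds branch ``k`` from the cached activation after
    block ``k``.
    """

    def __init__(self, branches: list[DetectorModel]):
        if not branches:
            raise ValueError("need at least one branch")
        self.branches = branches
        self.head_kind = branches[0].head_kind
        self.min_frames = branches[0].min_frames
        self.step_frames = branches[0].step_frames

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    @property
    def n_classes(self) -> int:
        return self.branches[0].n_classes

    def frozen_block_counts(self) -> list[int]:
        return [b.frozen_block_count() for b in self.branches]

    def _prefix_activations(self, x, training):
        """Shared frozen-prefix activations a_0..a_{n-1} (a_k feeds branch k)."""
        ref = self.branches[-1]
        acts = [np.ascontiguousarray(x, dtype=np.float32)]
        for j in range(self.n_branches - 1):
            acts.append(ref.forward_blocks(acts[j], start=j, stop=j + 1,
                                           training=False))
        return acts

    def forward_logits_per_branch(self, x, training=False):
        self.branches[0].n_steps(np.asarray(x).shape[1])
        acts = self._prefix_activations(x, training)
        outs = []
        for k, br in enumerate(self.branches):
            h = br.forward_blocks(acts[k], start=k, training=training)
            outs.append(br.head.forward(h, training))
        return outs

    def predict(self, x) -> dict:
        logits = self.forward_logits_per_branch(x, training=False)
        C = self.n_classes
        probs = np.mean([softmax(l[..., :C]) for l in logits], axis=0)
        age = np.mean([l[..., C] for l in logits], axis=0)
        return {"probs": probs, "age": age}

    def backward_per_branch(self, dlogits_list):
        for k, (br, dl) in enumerate(zip(self.branches, dlogits_list)):
            br.backward(dl, stop_block=k)

    def trainable_layers(self):
        return [l for br in self.branches for l in br.trainable_layers()]

    def state_arrays(self) -> dict:
        return {
            f"branch{k}.{name}": arr
            for k, br in enumerate(self.branches)
            for name, arr in br.state_arrays().items()
        }

    def load_state_arrays(self, state: dict) -> None:
        for k, br in enumerate(self.branches):
            prefix = f"branch{k}."
            br.load_state_arrays(
                {n[len(prefix):]: a for n, a in state.items() if n.startswith(prefix)}
            )

    def snapshot(self) -> dict:
        return {k: v.copy() for k, v in self.state_arrays().items()}


def make_branched(model: DetectorModel, n_branches: int = 5) -> BranchedDetector:
    """Create the graduated-freezing meta-model from a single detector.

    Branch ``k`` (k = 0 .. n-1) is a deep copy of ``model`` with its
    first ``k`` conv blocks frozen.
    """
    if n_branches < 1:
        raise ValueError(f"n_branches must be >= 1, got {n_branches}")
    if n_branches - 1 > model.n_blocks:
        raise ValueError("more branches than conv blocks to freeze")
    branches = []
    for k in range(n_branches):
        br = model.copy()
        br.freeze_blocks(k)
        branches.append(br)
    return BranchedDetector(branches)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------


class Adam:
    """Adam over the trainable layers of a model (frozen layers skipped)."""

    def __init__(self, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-7):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = {}
        self._v = {}

    def step(self, layers) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1 - b1**self.t
        corr2 = 1 - b2**self.t
        for layer in layers:
            if getattr(layer, "frozen", False):
                continue
            grads = layer.grads()
            for name, p in layer.params().items():
                g = grads[name]
                if g is None:
                    continue
                key = (id(layer), name)
                m = self._m.get(key)
                if m is None:
                    m = np.zeros_like(p)
                    v = np.zeros_like(p)
                else:
                    v = self._v[key]
                m = b1 * m + (1 - b1) * g
                v = b2 * v + (1 - b2) * g * g
                self._m[key], self._v[key] = m, v
                p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)
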