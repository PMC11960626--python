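"""Declarative architecture of the vocalization detector.

The detector is a fully convolutional network: eleven 2-D convolutional
layers (ELU + batch normalization, valid padding) followed by a single
1-D convolutional head over the 128 channels that remain once the
frequency axis has collapsed to one bin. Three head variants exist:

* ``finetune6`` — 5 softmax class neurons + 1 linear age neuron;
* ``finetune7`` — 6 softmax class neurons (adds a background class) + age;
* ``pretrain527`` — 527 sigmoid neurons for multi-label pre-training.

This module is purely analytic: it declares layer shapes and computes
output shapes, the time-axis receptive field, the effective stride and
trainable-parameter counts without building any weights. The builders in
:mod:`broilervoc.nn` consume these specs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import yaml

__all__ = [
    "LayerSpec",
    "ArchitectureSpec",
    "HEAD_WIDTHS",
    "table1",
    "layer_output_shape",
    "receptive_field",
    "effective_stride",
    "count_parameters",
]

# softmax classes + 1 linear age neuron, or sigmoid width for pre-training
HEAD_WIDTHS = {"finetune6": 6, "finetune7": 7, "pretrain527": 527}


@dataclass(frozen=True)
class LayerSpec:
    """One convolutional layer: kind, filters, kernel and stride extents."""

    kind: str                   # 'conv2d' | 'conv1d'
    filters: int
    kernel: tuple[int, int]     # (time, freq) extents; conv1d uses (k, 1)
    strides: tuple[int, int]
    activation: str = "elu"     # 'elu' | 'head'
    batch_norm: bool = True

    def __post_init__(self):
        if self.kind not in ("conv2d", "conv1d"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if min(self.kernel) < 1 or min(self.strides) < 1:
            raise ValueError("kernel and stride extents must be >= 1")
        if self.filters < 1:
            raise ValueError("filter count must be >= 1")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Ordered stack of layers plus the nominal input shape."""

    layers: tuple[LayerSpec, ...]
    input_shape: tuple[int, int] = (194, 64)

    @property
    def conv2d_layers(self) -> tuple[LayerSpec, ...]:
        return tuple(l for l in self.layers if l.kind == "conv2d")

    def to_dict(self) -> dict:
        return {
            "input_shape": list(self.input_shape),
            "layers": [asdict(l) for l in self.layers],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        layers = tuple(
            LayerSpec(
                kind=l["kind"],
                filters=l["filters"],
                kernel=tuple(l["kernel"]),
                strides=tuple(l["strides"]),
                activation=l.get("activation", "elu"),
                batch_norm=l.get("batch_norm", True),
            )
            for l in d["layers"]
        )
        return cls(layers=layers, input_shape=tuple(d["input_shape"]))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ArchitectureSpec":
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "ArchitectureSpec":
        return cls.from_dict(json.loads(text))


def table1() -> ArchitectureSpec:
    """The canonical 12-layer detector architecture.

    Eleven valid 2-D convolutions whose kernels/strides reduce a
    (194, 64) log-mel input to a single (1, 1) position with 128
    channels, plus the 1-D output head (kernel 1, stride 1, no batch
    norm). With this stack the time-axis receptive field is 194 frames
    (1.94 s, the minimum input for one prediction) and the effective
    stride is 24 frames (240 ms).
    """
    c2 = lambda f, k, s: LayerSpec("conv2d", f, k, s)
    return ArchitectureSpec(
        layers=(
            c2(64, (3, 3), (1, 1)),
            c2(64, (3, 3), (1, 1)),
            c2(96, (4, 4), (2, 2)),
            c2(96, (3, 3), (1, 1)),
            c2(128, (5, 3), (3, 2)),
            c2(128, (3, 3), (1, 1)),
            c2(128, (4, 3), (2, 2)),
            c2(128, (3, 3), (1, 1)),
            c2(128, (3, 3), (1, 1)),
            c2(128, (3, 1), (2, 1)),
            c2(128, (4, 1), (1, 1)),
            LayerSpec("conv1d", 6, (1, 1), (1, 1), activation="head",
                      batch_norm=False),
        )
    )


def _out_extent(n: int, k: int, s: int) -> int:
    return (n - k) // s + 1


def layer_output_shape(
    spec: ArchitectureSpec, input_shape: tuple[int, int] | None = None
) -> list[tuple[int, int]]:
    """(time, freq) output shape after each 2-D convolution.

    Valid (unpadded) convolution semantics: ``out = floor((in - k)/s) + 1``
    on each axis. The 1-D head (kernel 1) leaves spatial extents unchanged
    and is not listed. Raises ``ValueError`` naming the first layer whose
    kernel no longer fits.
    """
    t, f = input_shape if input_shape is not None else spec.input_shape
    shapes = []
    for i, layer in enumerate(spec.conv2d_layers):
        (kt, kf), (st, sf) = layer.kernel, layer.strides
        if t < kt or f < kf:
            raise ValueError(
                f"input {(t, f)} smaller than kernel {(kt, kf)} of conv2d "
                f"layer {i + 1}: shape infeasible"
            )
        t, f = _out_extent(t, kt, st), _out_extent(f, kf, sf)
        shapes.append((t, f))
    return shapes


def receptive_field(spec: ArchitectureSpec) -> int:
    """Time-axis receptive field in input frames of one output step.

    Accumulates ``rf += (kernel_t - 1) * jump`` with ``jump`` multiplied
    by each layer's time stride, over all layers in order.
    """
    rf, jump = 1, 1
    for layer in spec.layers:
        rf += (layer.kernel[0] - 1) * jump
        jump *= layer.strides[0]
    return rf


def effective_stride(spec: ArchitectureSpec) -> int:
    """Input-frame offset between consecutive output steps."""
    jump = 1
    for layer in spec.layers:
        jump *= layer.strides[0]
    return jump


def count_parameters(spec: ArchitectureSpec, head_kind: str = "finetune6") -> int:
    """Total trainable parameter count for a given head variant.

    Each convolution contributes ``kt*kf*c_in*c_out + c_out`` (weights +
    bias); batch-normalized layers add ``2*c_out`` (trainable scale and
    shift; the running statistics are buffers, not parameters). The head
    layer's width is set by ``head_kind`` regardless of the declared
    filter count of the final conv1d layer.
    """
    if head_kind not in HEAD_WIDTHS:
        raise ValueError(f"unknown head kind {head_kind!r}")
    total = 0
    c_in = 1
    for layer in spec.layers:
        c_out = HEAD_WIDTHS[head_kind] if layer.activation == "head" else layer.filters
        kt, kf = layer.kernel
        total += kt * kf * c_in * c_out + c_out
        if layer.batch_norm:
            total += 2 * c_out
        c_in = c_out
    return total
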