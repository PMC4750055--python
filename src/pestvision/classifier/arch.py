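"""Declarative network architectures and the ablation presets.

The reference ("overall") architecture is an 8-layer AlexNet-family
network tuned for 12-class pest recognition: Conv1 has 128 local
receptive fields of 11x11 applied with stride 3 (the swept optima),
Conv2-5 use the usual 5x5/3x3 geometry with 256/384/384/256 filters, and
two 4096-wide fully-connected layers precede the classification layer.
ReLU follows every conv/FC hidden layer; overlapping 3x3 stride-2 max
pooling sits after Conv1, Conv2 and the deepest conv layer; inverted
dropout (default ratio 0.7) follows each hidden FC layer.

Presets 1-10 reproduce the ablation table: Types 2-7 successively remove
FC7, FC6, Conv5, Conv4, Conv3, Conv2; Types 8-10 shrink the Conv2-5
widths in steps of 64 filters.  When conv layers are ablated the
terminal pooling stage is retained (the new deepest conv layer is
followed by the final pool in addition to its own), so the classifier
input stays compact and parameter counts decrease monotonically along
the removal sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .layers import Conv2D, Dense, Dropout, Flatten, MaxPool, ReLU

__all__ = ["ConvSpec", "ArchitectureSpec", "Network", "preset", "count_parameters", "build_network", "reduced"]

LOSSES = ("softmax", "hinge_ova")


@dataclass(frozen=True)
class ConvSpec:
    n_filters: int
    kernel_size: int
    stride: int = 1
    padding: int = 0
    n_pools: int = 0  # number of 3x3/2 max-pool stages after this layer


@dataclass(frozen=True)
class ArchitectureSpec:
    conv_layers: tuple[ConvSpec, ...]
    fc_layers: tuple[int, ...] = (4096, 4096)
    dropout_ratio: float = 0.7
    n_classes: int = 12
    loss: str = "softmax"
    input_size: int = 227

    def __post_init__(self) -> None:
        if len(self.conv_layers) < 1:
            raise ValueError("at least one conv layer is required")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not (0.0 <= self.dropout_ratio < 1.0):
            raise ValueError("dropout ratio must lie in [0, 1); 1 would deactivate every unit")
        if self.loss not in LOSSES:
            raise ValueError(f"loss must be one of {LOSSES}")


def _full_convs(widths=(256, 384, 384, 256)) -> tuple[ConvSpec, ...]:
    w2, w3, w4, w5 = widths
    return (
        ConvSpec(128, 11, stride=3, padding=0, n_pools=1),
        ConvSpec(w2, 5, stride=1, padding=2, n_pools=1),
        ConvSpec(w3, 3, stride=1, padding=1, n_pools=0),
        ConvSpec(w4, 3, stride=1, padding=1, n_pools=0),
        ConvSpec(w5, 3, stride=1, padding=1, n_pools=1),
    )


def preset(type_index: int) -> ArchitectureSpec:
    """Ablation-table preset architectures (Types 1-10)."""
    if not (1 <= type_index <= 10):
        raise ValueError("type_index must lie in 1..10")
    if type_index == 1:
        return ArchitectureSpec(conv_layers=_full_convs())
    if type_index == 2:  # removed FC7
        return ArchitectureSpec(conv_layers=_full_convs(), fc_layers=(4096,))
    if type_index == 3:  # removed FC6, 7
        return ArchitectureSpec(conv_layers=_full_convs(), fc_layers=())
    if type_index in (4, 5, 6, 7):  # additionally remove Conv5, 4, 3, 2
        keep = 8 - type_index  # 4, 3, 2, 1 conv layers
        convs = list(_full_convs()[:keep])
        last = convs[-1]
        if last.n_pools == 0:
            convs[-1] = replace(last, n_pools=1)
        else:  # the retained terminal pool stacks on the layer's own pool
            convs[-1] = replace(last, n_pools=last.n_pools + 1)
        return ArchitectureSpec(conv_layers=tuple(convs), fc_layers=())
    widths = {
        8: (192, 320, 320, 192),
        9: (128, 256, 256, 128),
        10: (64, 192, 192, 64),
    }[type_index]
    return ArchitectureSpec(conv_layers=_full_convs(widths))


def reduced(
    spec: ArchitectureSpec,
    input_size: int = 64,
    width_divisor: int = 4,
    fc_width: int = 256,
    n_classes: int | None = None,
) -> ArchitectureSpec:
    """Desk-scale profile of an architecture.

    Shrinks the input, divides all conv widths by ``width_divisor`` and
    caps FC widths at ``fc_width`` so training fits a workstation budget
    while preserving the layer topology.
    """
    convs = tuple(
        replace(c, n_filters=max(c.n_filters // width_divisor, 8)) for c in spec.conv_layers
    )
    fcs = tuple(min(w, fc_width) for w in spec.fc_layers)
    return replace(
        spec,
        conv_layers=convs,
        fc_layers=fcs,
        input_size=input_size,
        n_classes=spec.n_classes if n_classes is None else n_classes,
    )


def _feature_geometry(spec: ArchitectureSpec) -> tuple[int, int]:
    """(spatial side, channels) of the conv stack output; raises on underflow."""
    side = spec.input_size
    channels = 3
    for i, conv in enumerate(spec.conv_layers):
        padded = side + 2 * conv.padding
        if padded < conv.kernel_size:
            raise ValueError(f"conv layer {i + 1}: kernel {conv.kernel_size} exceeds feature map {padded}")
        side = (padded - conv.kernel_size) // conv.stride + 1
        channels = conv.n_filters
        for _ in range(conv.n_pools):
            if side < 3:
                raise ValueError(f"conv layer {i + 1}: feature map {side} too small to pool")
            side = (side - 3) // 2 + 1
    return side, channels


def count_parameters(spec: ArchitectureSpec) -> int:
    """Exact number of weights and biases of the built network."""
    side, channels = _feature_geometry(spec)
    total = 0
    in_ch = 3
    for conv in spec.conv_layers:
        total += conv.n_filters * (in_ch * conv.kernel_size**2) + conv.n_filters
        in_ch = conv.n_filters
    n_in = side * side * channels
    for width in spec.fc_layers:
        total += n_in * width + width
        n_in = width
    total += n_in * spec.n_classes + spec.n_classes
    return total


class Network:
    """A built network: ordered layers plus the loss identifier."""

    def __init__(self, layers, spec: ArchitectureSpec):
        self.layers = layers
        self.spec = spec

    def forward(self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        """Scores for a batch ``(N, H, W, 3)`` (uint8 or float) -> ``(N, K)``."""
        x = np.asarray(x)
        if x.ndim == 3:
            x = x[None]
        x = x.astype(np.float32)
        if x.max() > 1.5:
            x = x / 255.0
        x = x.transpose(0, 3, 1, 2) - 0.5
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dscores: np.ndarray) -> None:
        g = dscores.astype(np.float32)
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def parameters(self):
        for layer in self.layers:
            yield from zip(layer.params, layer.grads, layer.decay)

    def n_parameters(self) -> int:
        return sum(p.size for p, _, _ in self.parameters())

    def predict(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Eval-mode scores for a stack of images."""
        out = []
        for i in range(0, len(images), batch_size):
            out.append(self.forward(images[i : i + batch_size], train=False))
        return np.concatenate(out, axis=0)


def build_network(spec: ArchitectureSpec, seed: int = 0, init_std: float = 0.01) -> Network:
    """Materialize an :class:`ArchitectureSpec` with Gaussian N(0, std^2)
    weights and zero biases."""
    _feature_geometry(spec)  # validate before allocating anything
    rng = np.random.default_rng(seed)
    layers = []
    in_ch = 3
    for conv in spec.conv_layers:
        layers.append(
            Conv2D(in_ch, conv.n_filters, conv.kernel_size, conv.stride, conv.padding, rng=rng, init_std=init_std)
        )
        layers.append(ReLU())
        for _ in range(conv.n_pools):
            layers.append(MaxPool(3, 2))
        in_ch = conv.n_filters
    layers.append(Flatten())
    side, channels = _feature_geometry(spec)
    n_in = side * side * channels
    for width in spec.fc_layers:
        layers.append(Dense(n_in, width, rng=rng, init_std=init_std))
        layers.append(ReLU())
        layers.append(Dropout(spec.dropout_ratio))
        n_in = width
    layers.append(Dense(n_in, spec.n_classes, rng=rng, init_std=init_std))
    return Network(layers, spec)
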