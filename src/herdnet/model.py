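"""The S-ResNet single-frame classifier architecture and its MAC accounting.

S-ResNet is a small 1-D residual CNN over a single 10-feature frame treated
as a length-10, one-channel sequence: an initial 1->32 convolution, two
residual blocks widening to 64 and 128 channels (kernel 3 main path, kernel
1 shortcut, batch norm everywhere), global average pooling over the length
axis, and a two-layer dense head (128 -> 64 -> num_classes).

:class:`ModelSpec` carries the per-layer channel widths so that pruning can
rewrite them; :func:`count_macs` prices a spec in multiply-accumulate
operations under a fixed, documented convention.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .nn import BatchNorm1d, Conv1d, Linear, Module, Tensor

#: Order of the weighted layers in the network (GAP carries no weights).
LAYER_ORDER = [
    "conv1",
    "b1_conv_a",
    "b1_conv_b",
    "b1_shortcut",
    "b2_conv_a",
    "b2_conv_b",
    "b2_shortcut",
    "fc1",
    "fc2",
]

MAC_CONVENTION = (
    "kernel multiplies plus bias accumulations for conv and fc layers only; "
    "stride 1, length-preserving padding (L_out = input_length); "
    "BN, activations and GAP excluded"
)


@dataclass(frozen=True)
class LayerSpec:
    name: str
    kind: str  # 'conv1d' | 'fc'
    in_channels: int
    out_channels: int
    kernel: int = 1
    stride: int = 1
    has_bias: bool = True
    has_bn: bool = True
    activation: str = "relu"

    def __post_init__(self):
        if self.kind not in ("conv1d", "fc"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError(f"layer {self.name}: channels must be >= 1")
        if self.kind == "conv1d" and self.kernel not in (1, 3):
            raise ValueError(f"layer {self.name}: conv kernel must be 1 or 3")
        if self.stride < 1:
            raise ValueError(f"layer {self.name}: stride must be >= 1")


@dataclass(frozen=True)
class ModelSpec:
    """Per-layer widths plus input length and class count."""

    layers: tuple[LayerSpec, ...]
    input_length: int = 10
    num_classes: int = 4

    def __post_init__(self):
        names = [l.name for l in self.layers]
        if names != LAYER_ORDER:
            raise ValueError(f"layers must be {LAYER_ORDER}, got {names}")
        l = self.layer
        pairs = [
            ("b1_conv_b", "b1_shortcut", "out_channels"),
            ("b2_conv_b", "b2_shortcut", "out_channels"),
            ("b1_conv_a", "b1_shortcut", "in_channels"),
            ("b2_conv_a", "b2_shortcut", "in_channels"),
        ]
        for a, b, attr in pairs:
            if getattr(l(a), attr) != getattr(l(b), attr):
                raise ValueError(
                    f"residual width mismatch: {a}.{attr}={getattr(l(a), attr)} "
                    f"vs {b}.{attr}={getattr(l(b), attr)}"
                )
        chain = [
            ("conv1", "b1_conv_a"), ("b1_conv_a", "b1_conv_b"),
            ("b1_conv_b", "b2_conv_a"), ("b2_conv_a", "b2_conv_b"),
            ("b2_conv_b", "fc1"), ("fc1", "fc2"),
        ]
        for up, down in chain:
            if l(up).out_channels != l(down).in_channels:
                raise ValueError(
                    f"width mismatch: {up}.out={l(up).out_channels} vs "
                    f"{down}.in={l(down).in_channels}"
                )
        if l("fc2").out_channels != self.num_classes:
            raise ValueError("fc2.out must equal num_classes")

    def layer(self, name: str) -> LayerSpec:
        for l in self.layers:
            if l.name == name:
                return l
        raise KeyError(name)

    def widths(self) -> dict[str, int]:
        return {l.name: l.out_channels for l in self.layers}

    def with_widths(self, **widths: int) -> "ModelSpec":
        """Rebuild the spec with new widths (keys: conv1, block1_mid,
        block1_out, block2_mid, block2_out, fc1); the wiring and tied
        shortcut widths follow automatically."""
        cur = {
            "conv1": self.layer("conv1").out_channels,
            "block1_mid": self.layer("b1_conv_a").out_channels,
            "block1_out": self.layer("b1_conv_b").out_channels,
            "block2_mid": self.layer("b2_conv_a").out_channels,
            "block2_out": self.layer("b2_conv_b").out_channels,
            "fc1": self.layer("fc1").out_channels,
        }
        unknown = set(widths) - set(cur)
        if unknown:
            raise ValueError(f"unknown width keys: {sorted(unknown)}")
        cur.update(widths)
        return build_sresnet(
            **cur, input_length=self.input_length, num_classes=self.num_classes
        )

    # -- serialization -------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "layers": [asdict(l) for l in self.layers],
                "input_length": self.input_length,
                "num_classes": self.num_classes,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        obj = json.loads(text)
        return cls(
            layers=tuple(LayerSpec(**l) for l in obj["layers"]),
            input_length=obj["input_length"],
            num_classes=obj["num_classes"],
        )


def build_sresnet(
    conv1: int = 32,
    block1_mid: int = 64,
    block1_out: int = 64,
    block2_mid: int = 128,
    block2_out: int = 128,
    fc1: int = 64,
    input_length: int = 10,
    num_classes: int = 4,
) -> ModelSpec:
    """The default S-ResNet family: widths 32/(64,64;64)/(128,128;128)/64."""
    conv = lambda name, i, o, k: LayerSpec(name, "conv1d", i, o, kernel=k)
    return ModelSpec(
        layers=(
            conv("conv1", 1, conv1, 3),
            conv("b1_conv_a", conv1, block1_mid, 3),
            conv("b1_conv_b", block1_mid, block1_out, 3),
            conv("b1_shortcut", conv1, block1_out, 1),
            conv("b2_conv_a", block1_out, block2_mid, 3),
            conv("b2_conv_b", block2_mid, block2_out, 3),
            conv("b2_shortcut", block1_out, block2_out, 1),
            LayerSpec("fc1", "fc", block2_out, fc1, has_bn=False, activation="none"),
            LayerSpec("fc2", "fc", fc1, num_classes, has_bn=False, activation="none"),
        ),
        input_length=input_length,
        num_classes=num_classes,
    )


@dataclass
class MacReport:
    per_layer: dict[str, int]
    total: int
    convention: str = MAC_CONVENTION

    @property
    def total_millions(self) -> float:
        return round(self.total / 1e6, 3)

    def to_json(self) -> str:
        return json.dumps(
            {
                "per_layer": self.per_layer,
                "total": self.total,
                "total_millions": self.total_millions,
                "convention": self.convention,
            },
            indent=2,
        )


def layer_macs(layer: LayerSpec, input_length: int) -> int:
    """MACs of one weighted layer under the package convention."""
    if layer.kind == "conv1d":
        l_out = input_length  # stride 1, same padding
        macs = layer.out_channels * layer.in_channels * layer.kernel * l_out
        if layer.has_bias:
            macs += layer.out_channels * l_out
        return macs
    macs = layer.out_channels * layer.in_channels
    if layer.has_bias:
        macs += layer.out_channels
    return macs


def count_macs(spec: ModelSpec) -> MacReport:
    per_layer = {l.name: layer_macs(l, spec.input_length) for l in spec.layers}
    return MacReport(per_layer=per_layer, total=int(sum(per_layer.values())))


class SResNet(Module):
    """Executable S-ResNet network for a :class:`ModelSpec`."""

    def __init__(self, spec: ModelSpec, rng: np.random.Generator | None = None,
                 head_relu: bool = False, dtype=np.float64):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.spec = spec
        self.head_relu = head_relu
        self.dtype = np.dtype(dtype)
        for l in spec.layers:
            if l.kind == "conv1d":
                setattr(self, l.name, Conv1d(l.in_channels, l.out_channels,
                                             l.kernel, rng, bias=l.has_bias,
                                             dtype=dtype))
            else:
                setattr(self, l.name, Linear(l.in_channels, l.out_channels,
                                             rng, bias=l.has_bias, dtype=dtype))
            if l.has_bn:
                setattr(self, l.name + "_bn", BatchNorm1d(l.out_channels,
                                                          dtype=dtype))

    def conv_bn(self, name: str, x: Tensor) -> Tensor:
        y = getattr(self, name)(x)
        bn = getattr(self, name + "_bn", None)
        return bn(y) if bn is not None else y

    def __call__(self, x) -> Tensor:
        """Class scores (pre-softmax logits) for frames x of shape (N, L)."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=self.dtype))
        if x.ndim != 2 or x.shape[1] != self.spec.input_length:
            raise ValueError(
                f"expected input of shape (N, {self.spec.input_length}), "
                f"got {x.shape}"
            )
        h = x.reshape(x.shape[0], 1, self.spec.input_length)
        h = self.conv_bn("conv1", h).relu()
        for blk in ("b1", "b2"):
            main = self.conv_bn(f"{blk}_conv_a", h).relu()
            main = self.conv_bn(f"{blk}_conv_b", main)
            short = self.conv_bn(f"{blk}_shortcut", h)
            h = (main + short).relu()
        pooled = h.mean(axis=2)  # GAP over the length axis
        z = self.fc1(pooled)
        if self.head_relu:
            z = z.relu()
        return self.fc2(z)

    def predict_logits(self, X: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Eval-mode logits computed without building an autodiff tape."""
        was_training = self.training
        self.eval()
        X = np.asarray(X, dtype=self.dtype)
        try:
            outs = [self(X[i: i + batch_size]).data
                    for i in range(0, len(X), batch_size)]
        finally:
            self.train(was_training)
        return np.concatenate(outs) if outs else np.empty((0, self.spec.num_classes))
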