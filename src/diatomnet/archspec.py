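"""Declarative architecture specs, analytic shape propagation, and parameter counting.

DiatomNet is a small inception-style CNN for diatom micrograph crops.  This
module is the single source of truth for its architecture: the same
:class:`ArchitectureSpec` that builds the trainable network (module
:mod:`diatomnet.network`) also drives closed-form shape tracing and
learnable-parameter accounting, so the engineering claims about the model
(output sizes per stage, depth 10, 1.85 M parameters) can be checked without
ever allocating a weight tensor.

Conventions
-----------
* Spatial sizes are written ``height x width`` where *height* is the long
  (432-pixel) axis of the canonical input, matching how the architecture
  table is printed.  Image arrays elsewhere in the package use the usual
  ``(rows, cols)`` = (128, 432) raster order; :mod:`diatomnet.network`
  transposes at the boundary.
* ``same`` padded convolutions pad ``floor(k/2)`` on each side:
  ``d -> floor((d + 2*floor(k/2) - k)/s) + 1``.
* ``valid_ceil`` pooling uses ceiling division with no padding:
  ``d -> ceil((d - k)/s) + 1`` (edge windows may be clipped).
* Inception modules preserve spatial size and concatenate their four branch
  outputs along channels.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import yaml

__all__ = [
    "InceptionConfig",
    "LayerSpec",
    "ArchitectureSpec",
    "ShapeTrace",
    "ParamReport",
    "Discrepancy",
    "ShapeUnderflowError",
    "default_diatomnet_spec",
    "reduced_diatomnet_spec",
    "trace_shapes",
    "count_parameters",
    "validate_against_table",
    "spec_to_yaml",
    "spec_from_yaml",
]

LAYER_KINDS = frozenset(
    {
        "convolution",
        "max_pool",
        "avg_pool",
        "cross_channel_norm",
        "inception",
        "dropout",
        "linear",
        "softmax",
    }
)

PADDING_MODES = frozenset({"same", "valid_ceil", "valid_floor", "explicit"})


class ShapeUnderflowError(ValueError):
    """A layer would produce a non-positive spatial dimension."""


@dataclass(frozen=True)
class InceptionConfig:
    """Channel budgets of one dimension-reduced inception module.

    The four parallel branches are: a 1x1 convolution; a 1x1 reduction
    followed by a 3x3 convolution; a 1x1 reduction followed by a 5x5
    convolution; and a 3x3 stride-1 max pool followed by a 1x1 projection.
    """

    one_by_one: int
    three_reduce: int
    three_by_three: int
    five_reduce: int
    five_by_five: int
    pool_proj: int

    def __post_init__(self) -> None:
        for name in (
            "one_by_one",
            "three_reduce",
            "three_by_three",
            "five_reduce",
            "five_by_five",
            "pool_proj",
        ):
            v = getattr(self, name)
            if not isinstance(v, int) or v <= 0:
                raise ValueError(f"InceptionConfig.{name} must be a positive integer, got {v!r}")

    @property
    def concat_channels(self) -> int:
        """Output channels: the four terminal branch widths concatenated."""
        return self.one_by_one + self.three_by_three + self.five_by_five + self.pool_proj

    def as_tuple(self) -> tuple[int, int, int, int, int, int]:
        return (
            self.one_by_one,
            self.three_reduce,
            self.three_by_three,
            self.five_reduce,
            self.five_by_five,
            self.pool_proj,
        )


@dataclass(frozen=True)
class LayerSpec:
    """One layer in the architecture dialect.

    ``depth_contribution`` follows the printed-depth convention: one per
    sequential learnable stage (an inception module counts 2 because its
    longest path stacks two convolutions; pooling, normalization, dropout
    and softmax count 0).
    """

    kind: str
    label: str
    patch: Optional[tuple[int, int]] = None  # (k_h, k_w)
    stride: int = 1
    padding_mode: str = "valid_floor"
    padding: Optional[tuple[int, int]] = None  # explicit (p_h, p_w)
    out_channels: Optional[int] = None
    inception: Optional[InceptionConfig] = None
    rate: Optional[float] = None
    norm_params: Optional[tuple[int, float, float, float]] = None  # (window, k, alpha, beta)
    depth_contribution: int = 0

    def __post_init__(self) -> None:
        if self.kind not in LAYER_KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.stride < 1:
            raise ValueError(f"layer {self.label!r}: stride must be >= 1")
        if self.patch is not None and (self.patch[0] < 1 or self.patch[1] < 1):
            raise ValueError(f"layer {self.label!r}: patch dims must be >= 1")
        if self.padding_mode not in PADDING_MODES:
            raise ValueError(f"layer {self.label!r}: bad padding_mode {self.padding_mode!r}")
        if self.kind == "convolution" and (self.patch is None or self.out_channels is None):
            raise ValueError(f"convolution {self.label!r} needs patch and out_channels")
        if self.kind in ("max_pool", "avg_pool") and self.patch is None:
            raise ValueError(f"pooling layer {self.label!r} needs a patch size")
        if self.kind == "inception" and self.inception is None:
            raise ValueError(f"inception layer {self.label!r} needs an InceptionConfig")
        if self.kind == "dropout":
            if self.rate is None or not (0.0 <= self.rate <= 1.0):
                raise ValueError(f"dropout {self.label!r} needs rate in [0, 1]")
        if self.kind == "linear" and self.out_channels is None:
            raise ValueError(f"linear {self.label!r} needs out_channels")
        if self.depth_contribution < 0:
            raise ValueError(f"layer {self.label!r}: depth_contribution must be >= 0")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Ordered layer description plus the input/output contract."""

    input_height: int
    input_width: int
    input_channels: int
    num_classes: int
    layers: tuple[LayerSpec, ...]

    def __post_init__(self) -> None:
        if min(self.input_height, self.input_width, self.input_channels) < 1:
            raise ValueError("input dimensions must be positive")
        if self.num_classes < 2:
            raise ValueError("need at least two classes")
        labels = [l.label for l in self.layers]
        if len(set(labels)) != len(labels):
            raise ValueError("layer labels must be unique")
        if len(self.layers) < 2 or self.layers[-1].kind != "softmax" or self.layers[-2].kind != "linear":
            raise ValueError("spec must end with linear(num_classes) then softmax")
        if self.layers[-2].out_channels != self.num_classes:
            raise ValueError("final linear layer width must equal num_classes")

    @property
    def depth(self) -> int:
        """Total depth under the printed-depth convention."""
        return sum(l.depth_contribution for l in self.layers)


@dataclass(frozen=True)
class ShapeTrace:
    """Per-layer analytic output sizes, in spec order."""

    entries: tuple[tuple[str, int, int, int], ...]  # (label, h, w, c)

    def by_label(self) -> dict[str, tuple[int, int, int]]:
        return {lab: (h, w, c) for lab, h, w, c in self.entries}


@dataclass(frozen=True)
class ParamReport:
    """Closed-form learnable-parameter accounting."""

    per_layer: tuple[tuple[str, int, int], ...]  # (label, weights, biases)
    total: int
    total_millions_2dp: float
    input_channels: int


@dataclass(frozen=True)
class Discrepancy:
    label: str
    expected: tuple[int, int, int]
    actual: Optional[tuple[int, int, int]]


# ---------------------------------------------------------------------------
# canonical specs


def _conv(label, k, stride, c_out, depth=1):
    return LayerSpec(
        kind="convolution",
        label=label,
        patch=(k, k),
        stride=stride,
        padding_mode="same",
        out_channels=c_out,
        depth_contribution=depth,
    )


def _maxpool(label, k=3, stride=2):
    return LayerSpec(
        kind="max_pool", label=label, patch=(k, k), stride=stride, padding_mode="valid_ceil"
    )


def _inception(label, cfg):
    return LayerSpec(kind="inception", label=label, inception=cfg, depth_contribution=2)


def default_diatomnet_spec(
    num_classes: int = 68, input_channels: int = 3
) -> ArchitectureSpec:
    """The canonical DiatomNet: 432x128 color input, three inception modules.

    The stem is conv7x7/2 -> maxpool3x3/2 -> cross-channel norm ->
    conv1x1 -> conv3x3, followed by three dimension-reduced inception modules
    each chased by a 3x3/2 max pool (the pool after the third module brings
    the 13x4 map to the 6x2 consumed by the global average pool), then
    dropout 0.40, a linear head, and softmax.  Every convolution carries a
    bias and is followed by ReLU; there is no batch normalization.
    """
    layers = (
        _conv("conv1", 7, 2, 64),
        _maxpool("pool1"),
        LayerSpec(
            kind="cross_channel_norm",
            label="norm1",
            norm_params=(5, 2.0, 1e-4, 0.75),
        ),
        _conv("conv2_reduce", 1, 1, 64),
        _conv("conv2", 3, 1, 192),
        _maxpool("pool2"),
        _inception("inception1", InceptionConfig(64, 96, 128, 16, 32, 32)),
        _maxpool("pool3"),
        _inception("inception2", InceptionConfig(192, 96, 208, 16, 48, 64)),
        _maxpool("pool4"),
        _inception("inception3", InceptionConfig(384, 192, 384, 48, 128, 128)),
        _maxpool("pool5"),  # reconciliation pool: 13x4 -> 6x2 ahead of the global avg pool
        LayerSpec(
            kind="avg_pool",
            label="avgpool",
            patch=(6, 2),
            stride=1,
            padding_mode="valid_floor",
        ),
        LayerSpec(kind="dropout", label="dropout", rate=0.40),
        LayerSpec(kind="linear", label="fc", out_channels=num_classes, depth_contribution=1),
        LayerSpec(kind="softmax", label="softmax"),
    )
    return ArchitectureSpec(
        input_height=432,
        input_width=128,
        input_channels=input_channels,
        num_classes=num_classes,
        layers=layers,
    )


def reduced_diatomnet_spec(num_classes: int = 5, input_channels: int = 3) -> ArchitectureSpec:
    """A depth-reduced DiatomNet: the stem plus the first inception module only.

    Keeps the canonical 432x128 input and all stem/inception widths but drops
    the second and third inception modules, ending with a global average pool
    over the 27x8 map, dropout, and a small linear head.  This is the
    desk-scale network used for synthetic-benchmark training runs.
    """
    layers = (
        _conv("conv1", 7, 2, 64),
        _maxpool("pool1"),
        LayerSpec(kind="cross_channel_norm", label="norm1", norm_params=(5, 2.0, 1e-4, 0.75)),
        _conv("conv2_reduce", 1, 1, 64),
        _conv("conv2", 3, 1, 192),
        _maxpool("pool2"),
        _inception("inception1", InceptionConfig(64, 96, 128, 16, 32, 32)),
        _maxpool("pool3"),
        LayerSpec(
            kind="avg_pool",
            label="avgpool",
            patch=(27, 8),
            stride=1,
            padding_mode="valid_floor",
        ),
        LayerSpec(kind="dropout", label="dropout", rate=0.40),
        LayerSpec(kind="linear", label="fc", out_channels=num_classes, depth_contribution=1),
        LayerSpec(kind="softmax", label="softmax"),
    )
    return ArchitectureSpec(
        input_height=432,
        input_width=128,
        input_channels=input_channels,
        num_classes=num_classes,
        layers=layers,
    )


# ---------------------------------------------------------------------------
# shape propagation


def _conv_dim(d: int, k: int, s: int, pad: int) -> int:
    return (d + 2 * pad - k) // s + 1


def _pool_dim(d: int, k: int, s: int, mode: str, pad: int = 0) -> int:
    if mode == "valid_ceil":
        return math.ceil((d - k) / s) + 1
    return (d + 2 * pad - k) // s + 1


def _same_pad(k: int) -> int:
    return k // 2


def trace_shapes(spec: ArchitectureSpec) -> ShapeTrace:
    """Propagate the input size through every layer analytically.

    Raises :class:`ShapeUnderflowError` naming the first layer whose output
    would have a non-positive spatial dimension.
    """
    h, w, c = spec.input_height, spec.input_width, spec.input_channels
    entries: list[tuple[str, int, int, int]] = []
    for layer in spec.layers:
        if layer.kind == "convolution":
            kh, kw = layer.patch
            if layer.padding_mode == "same":
                ph, pw = _same_pad(kh), _same_pad(kw)
            elif layer.padding_mode == "explicit":
                ph, pw = layer.padding
            else:
                ph, pw = 0, 0
            h = _conv_dim(h, kh, layer.stride, ph)
            w = _conv_dim(w, kw, layer.stride, pw)
            c = layer.out_channels
        elif layer.kind in ("max_pool", "avg_pool"):
            kh, kw = layer.patch
            if layer.padding_mode == "same":
                # stride-1 size-preserving pool (inception pool branch)
                ph, pw = _same_pad(kh), _same_pad(kw)
                h = _pool_dim(h, kh, layer.stride, "valid_floor", ph)
                w = _pool_dim(w, kw, layer.stride, "valid_floor", pw)
            else:
                h = _pool_dim(h, kh, layer.stride, layer.padding_mode)
                w = _pool_dim(w, kw, layer.stride, layer.padding_mode)
        elif layer.kind == "cross_channel_norm":
            pass
        elif layer.kind == "inception":
            c = layer.inception.concat_channels
        elif layer.kind == "dropout":
            pass
        elif layer.kind == "linear":
            h, w, c = 1, 1, layer.out_channels
        elif layer.kind == "softmax":
            pass
        if h < 1 or w < 1 or c < 1:
            raise ShapeUnderflowError(
                f"layer {layer.label!r} produces non-positive output size {h}x{w}x{c}"
            )
        entries.append((layer.label, h, w, c))
    return ShapeTrace(entries=tuple(entries))


# ---------------------------------------------------------------------------
# parameter accounting


def _conv_params(kh: int, kw: int, c_in: int, c_out: int) -> tuple[int, int]:
    return kh * kw * c_in * c_out, c_out


def _inception_params(cfg: InceptionConfig, c_in: int) -> tuple[int, int]:
    weights = biases = 0
    for kh, kw, ci, co in (
        (1, 1, c_in, cfg.one_by_one),
        (1, 1, c_in, cfg.three_reduce),
        (3, 3, cfg.three_reduce, cfg.three_by_three),
        (1, 1, c_in, cfg.five_reduce),
        (5, 5, cfg.five_reduce, cfg.five_by_five),
        (1, 1, c_in, cfg.pool_proj),
    ):
        w, b = _conv_params(kh, kw, ci, co)
        weights += w
        biases += b
    return weights, biases


def count_parameters(spec: ArchitectureSpec) -> ParamReport:
    """Closed-form learnable-parameter count, layer by layer.

    Convolutions contribute ``k_h*k_w*c_in*c_out + c_out``; the linear head
    contributes ``c_in*c_out + c_out`` where ``c_in`` is its flattened input;
    pooling, normalization, dropout and softmax contribute nothing.  Padding
    and stride never change the count.
    """
    trace = trace_shapes(spec)
    per_layer: list[tuple[str, int, int]] = []
    h, w, c = spec.input_height, spec.input_width, spec.input_channels
    for layer, (_, oh, ow, oc) in zip(spec.layers, trace.entries):
        if layer.kind == "convolution":
            kh, kw = layer.patch
            wts, bs = _conv_params(kh, kw, c, layer.out_channels)
        elif layer.kind == "inception":
            wts, bs = _inception_params(layer.inception, c)
        elif layer.kind == "linear":
            wts, bs = h * w * c * layer.out_channels, layer.out_channels
        else:
            wts, bs = 0, 0
        per_layer.append((layer.label, wts, bs))
        h, w, c = oh, ow, oc
    total = sum(w + b for _, w, b in per_layer)
    return ParamReport(
        per_layer=tuple(per_layer),
        total=total,
        total_millions_2dp=round(total / 1e6, 2),
        input_channels=spec.input_channels,
    )


# ---------------------------------------------------------------------------
# regression guard against the printed layer table

# Expected output sizes of the canonical architecture, row by row as printed.
# Each expectation names the trace labels it may bind to, first match wins:
# the third inception's printed 6x2x1024 row is realized by the
# reconciliation pool when present, by the module itself otherwise.
_TABLE_EXPECTATIONS: tuple[tuple[tuple[str, ...], tuple[int, int, int]], ...] = (
    (("conv1",), (216, 64, 64)),
    (("pool1",), (108, 32, 64)),
    (("conv2",), (108, 32, 192)),
    (("pool2",), (54, 16, 192)),
    (("inception1",), (54, 16, 256)),
    (("pool3",), (27, 8, 256)),
    (("inception2",), (27, 8, 512)),
    (("pool4",), (13, 4, 512)),
    (("pool5", "inception3"), (6, 2, 1024)),
    (("avgpool",), (1, 1, 1024)),
    (("dropout",), (1, 1, 1024)),
    (("fc",), (1, 1, 68)),
    (("softmax",), (1, 1, 68)),
)


def validate_against_table(trace: ShapeTrace) -> list[Discrepancy]:
    """Compare a trace of the canonical spec against the published output sizes.

    Returns one :class:`Discrepancy` per mismatching (or missing) row; an
    empty list means the trace reproduces every printed size.
    """
    by_label = trace.by_label()
    issues: list[Discrepancy] = []
    for labels, expected in _TABLE_EXPECTATIONS:
        bound = next((lab for lab in labels if lab in by_label), None)
        if bound is None:
            issues.append(Discrepancy(label=labels[0], expected=expected, actual=None))
            continue
        actual = by_label[bound]
        if actual != expected:
            issues.append(Discrepancy(label=bound, expected=expected, actual=actual))
    return issues


# ---------------------------------------------------------------------------
# serialization


def _layer_to_dict(layer: LayerSpec) -> dict:
    d: dict = {"kind": layer.kind, "label": layer.label}
    if layer.patch is not None:
        d["patch"] = list(layer.patch)
    if layer.kind in ("convolution", "max_pool", "avg_pool"):
        d["stride"] = layer.stride
        d["padding_mode"] = layer.padding_mode
        if layer.padding is not None:
            d["padding"] = list(layer.padding)
    if layer.out_channels is not None:
        d["out_channels"] = layer.out_channels
    if layer.inception is not None:
        d["inception"] = list(layer.inception.as_tuple())
    if layer.rate is not None:
        d["rate"] = layer.rate
    if layer.norm_params is not None:
        d["norm_params"] = list(layer.norm_params)
    if layer.depth_contribution:
        d["depth"] = layer.depth_contribution
    return d


def _layer_from_dict(d: dict) -> LayerSpec:
    inception = None
    if "inception" in d:
        inception = InceptionConfig(*[int(v) for v in d["inception"]])
    norm = tuple(d["norm_params"]) if "norm_params" in d else None
    if norm is not None:
        norm = (int(norm[0]), float(norm[1]), float(norm[2]), float(norm[3]))
    return LayerSpec(
        kind=d["kind"],
        label=d["label"],
        patch=tuple(d["patch"]) if "patch" in d else None,
        stride=int(d.get("stride", 1)),
        padding_mode=d.get("padding_mode", "valid_floor"),
        padding=tuple(d["padding"]) if "padding" in d else None,
        out_channels=d.get("out_channels"),
        inception=inception,
        rate=d.get("rate"),
        norm_params=norm,
        depth_contribution=int(d.get("depth", 0)),
    )


def spec_to_yaml(spec: ArchitectureSpec) -> str:
    doc = {
        "input": {
            "height": spec.input_height,
            "width": spec.input_width,
            "channels": spec.input_channels,
        },
        "num_classes": spec.num_classes,
        "layers": [_layer_to_dict(l) for l in spec.layers],
    }
    buf = io.StringIO()
    yaml.safe_dump(doc, buf, sort_keys=False)
    return buf.getvalue()


def spec_from_yaml(text: str) -> ArchitectureSpec:
    doc = yaml.safe_load(text)
    return ArchitectureSpec(
        input_height=int(doc["input"]["height"]),
        input_width=int(doc["input"]["width"]),
        input_channels=int(doc["input"]["channels"]),
        num_classes=int(doc["num_classes"]),
        layers=tuple(_layer_from_dict(d) for d in doc["layers"]),
    )
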