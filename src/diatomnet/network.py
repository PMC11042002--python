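"""Trainable network construction and inference.

A :class:`NetworkInstance` binds an :class:`~diatomnet.archspec.ArchitectureSpec`
to concrete weight tensors built by the numpy engine.  Weights are drawn with
the Glorot (Xavier) normal initializer — zero-mean Gaussians with variance
``2 / (fan_in + fan_out)`` — and biases start at zero; construction is
deterministic given the seed.

Image convention: crops enter as ``(rows, cols[, 3])`` rasters in ``[0, 1]``
with rows = ``spec.input_width`` (128) and cols = ``spec.input_height`` (432);
the long axis of the crop corresponds to the "height" of the printed
architecture table.  :func:`forward` transposes at this boundary so callers
never deal with the internal ``(C, H, W)`` layout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import archspec as A
from . import engine as E

__all__ = ["NetworkInstance", "Prediction", "build_network", "forward", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class Prediction:
    """Class probabilities for one crop, with deterministic tie-breaking."""

    probabilities: np.ndarray
    predicted_class: int
    confidence: float


class NetworkInstance:
    """A spec plus its parameter store, assembled from engine layers."""

    def __init__(self, spec: A.ArchitectureSpec, seed: int, dtype=np.float32):
        spec_trace = A.trace_shapes(spec)  # validates shapes before any allocation
        self.spec = spec
        self.seed = int(seed)
        self.dtype = dtype
        self.layers: list[tuple[str, E.Layer]] = []
        self._build(spec_trace)
        self._init_glorot(np.random.default_rng(self.seed))
        self.reseed_dropout(self.seed)

    # -- construction -----------------------------------------------------

    def _build(self, trace: A.ShapeTrace) -> None:
        h, w, c = self.spec.input_height, self.spec.input_width, self.spec.input_channels
        for layer, (_, oh, ow, oc) in zip(self.spec.layers, trace.entries):
            if layer.kind == "convolution":
                kh, kw = layer.patch
                if layer.padding_mode == "same":
                    pad = (kh // 2, kw // 2)
                elif layer.padding_mode == "explicit":
                    pad = layer.padding
                else:
                    pad = (0, 0)
                obj = E.Conv2d(c, layer.out_channels, kh, kw, layer.stride, pad, relu=True, dtype=self.dtype)
            elif layer.kind == "max_pool":
                obj = E.MaxPool2d(
                    layer.patch[0],
                    layer.stride,
                    ceil_mode=(layer.padding_mode == "valid_ceil"),
                    same=(layer.padding_mode == "same"),
                )
            elif layer.kind == "avg_pool":
                obj = E.AvgPool2d(layer.patch[0], layer.patch[1], layer.stride)
            elif layer.kind == "cross_channel_norm":
                n_, k_, al, be = layer.norm_params
                obj = E.CrossChannelNorm(n_, k_, al, be)
            elif layer.kind == "inception":
                obj = E.InceptionModule(c, layer.inception, dtype=self.dtype)
            elif layer.kind == "dropout":
                obj = E.Dropout(layer.rate)
            elif layer.kind == "linear":
                obj = E.Linear(h * w * c, layer.out_channels, dtype=self.dtype)
            elif layer.kind == "softmax":
                obj = E.Softmax()
            else:  # pragma: no cover - guarded by LayerSpec validation
                raise AssertionError(layer.kind)
            self.layers.append((layer.label, obj))
            h, w, c = oh, ow, oc
        first = self.layers[0][1]
        if isinstance(first, E.Conv2d):
            first.compute_dx = False  # nothing upstream consumes the input gradient

    def _init_glorot(self, rng: np.random.Generator) -> None:
        for _, obj in self.layers:
            for name in sorted(obj.params):
                if not name.endswith("W"):
                    continue
                wt = obj.params[name]
                if wt.ndim == 4:  # conv: (kh, kw, c_in, c_out)
                    kh, kw, c_in, c_out = wt.shape
                    fan_in, fan_out = kh * kw * c_in, kh * kw * c_out
                else:  # linear: (c_out, c_in)
                    fan_in, fan_out = wt.shape[1], wt.shape[0]
                std = np.sqrt(2.0 / (fan_in + fan_out))
                wt[...] = rng.normal(0.0, std, size=wt.shape).astype(wt.dtype)

    def reseed_dropout(self, seed: int) -> None:
        """Give every dropout layer a fresh deterministic stream."""
        streams = np.random.SeedSequence(seed).spawn(
            sum(1 for _, o in self.layers if isinstance(o, E.Dropout))
        )
        i = 0
        for _, obj in self.layers:
            if isinstance(obj, E.Dropout):
                obj.rng = np.random.default_rng(streams[i])
                i += 1

    # -- parameter access -------------------------------------------------

    def parameter_store(self) -> dict[str, np.ndarray]:
        """Flat ``"layer/param" -> array`` view of all learnable tensors."""
        return {
            f"{label}/{name}": arr
            for label, obj in self.layers
            for name, arr in obj.params.items()
        }

    def num_parameters(self) -> int:
        return sum(arr.size for arr in self.parameter_store().values())

    def copy_parameters(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.parameter_store().items()}

    def load_parameters(self, store: dict[str, np.ndarray]) -> None:
        own = self.parameter_store()
        if set(own) != set(store):
            raise ValueError("parameter store keys do not match this architecture")
        for k, arr in own.items():
            arr[...] = store[k]

    def zero_grads(self) -> None:
        for _, obj in self.layers:
            obj.zero_grads()

    # -- execution --------------------------------------------------------

    def _to_input_batch(self, images: np.ndarray) -> np.ndarray:
        """Map ``(N, rows, cols[, C])`` crops to the internal (N, H, W, C)."""
        spec = self.spec
        if images.ndim == 3:
            images = images[..., None]
        n, r, c_, ch = images.shape
        if ch == 1 and spec.input_channels == 3:
            images = np.repeat(images, 3, axis=3)
            ch = 3
        if (r, c_, ch) != (spec.input_width, spec.input_height, spec.input_channels):
            raise ValueError(
                f"input crops must be {spec.input_width}x{spec.input_height}"
                f"x{spec.input_channels} (rows x cols x channels), got {r}x{c_}x{ch}"
            )
        # rows=short axis, cols=long axis -> (N, H=long, W=short, C)
        return np.ascontiguousarray(images.transpose(0, 2, 1, 3), dtype=self.dtype)

    def forward_batch(
        self, images: np.ndarray, training: bool = False, capture: tuple[str, ...] = ()
    ) -> np.ndarray | tuple[np.ndarray, dict[str, np.ndarray]]:
        """Run crops through the network; returns ``(N, num_classes)`` probabilities.

        ``capture`` names layer labels whose activations are returned alongside.
        """
        x = self._to_input_batch(np.asarray(images))
        captured: dict[str, np.ndarray] = {}
        for label, obj in self.layers:
            x = obj.forward(x, training=training)
            if label in capture:
                captured[label] = x
        return (x, captured) if capture else x

    def forward_logits(self, x_internal: np.ndarray, training: bool) -> np.ndarray:
        """Internal-layout forward stopping before the softmax (training path)."""
        x = x_internal
        for label, obj in self.layers:
            if isinstance(obj, E.Softmax):
                break
            x = obj.forward(x, training=training)
        return x

    def backward_logits(self, dlogits: np.ndarray) -> np.ndarray:
        dy = dlogits
        for label, obj in reversed(self.layers):
            if isinstance(obj, E.Softmax):
                continue
            dy = obj.backward(dy)
        return dy


def build_network(spec: A.ArchitectureSpec, seed: int, dtype=np.float32) -> NetworkInstance:
    """Assemble a trainable network; deterministic given ``seed``."""
    return NetworkInstance(spec, seed, dtype=dtype)


def forward(net: NetworkInstance, image: np.ndarray, training_mode: bool = False) -> Prediction:
    """Classify one crop.  Argmax ties break to the lowest class index."""
    probs = net.forward_batch(np.asarray(image)[None, ...], training=training_mode)[0]
    cls = int(np.argmax(probs))  # np.argmax returns the first (lowest) maximal index
    return Prediction(probabilities=probs, predicted_class=cls, confidence=float(probs[cls]))


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(net: NetworkInstance, path, metadata: dict | None = None) -> None:
    """Single-archive checkpoint: spec + seed + parameters + metadata.

    Round-trips bit-exactly (arrays are stored unmodified).
    """
    meta = {
        "spec_yaml": A.spec_to_yaml(net.spec),
        "seed": net.seed,
        "dtype": np.dtype(net.dtype).name,
        "metadata": metadata or {},
    }
    arrays = {k.replace("/", "__"): v for k, v in net.parameter_store().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[NetworkInstance, dict]:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        arrays = {k: z[k] for k in z.files if k != "__meta__"}
    spec = A.spec_from_yaml(meta["spec_yaml"])
    net = NetworkInstance(spec, meta["seed"], dtype=np.dtype(meta["dtype"]).type)
    net.load_parameters({k.replace("__", "/"): v for k, v in arrays.items()})
    return net, meta["metadata"]
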