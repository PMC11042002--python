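"""Layer activation maps and input-resolution heat maps.

For a chosen depth (early / intermediate / deep) the channel with the
largest activation is selected — by spatial sum by default, by single
largest pixel optionally — and its spatial response returned at the layer's
native resolution.  The deep-layer map, bilinearly upsampled to the input
crop's resolution and min-max normalized, is the heat map used to localize
the image regions driving the classification.

Layer anchors: *early* is the first stem convolution, *intermediate* the
second inception module, *deep* the last inception module.  On
architectures with a single inception module, intermediate and deep both
resolve to it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage.transform import resize as sk_resize

from .network import NetworkInstance
from .preprocess import DiatomCrop

__all__ = ["ActivationMap", "HeatMap", "SELECTORS", "activation_map", "heat_map"]

SELECTORS = ("early", "intermediate", "deep")


@dataclass(frozen=True)
class ActivationMap:
    """One channel's spatial response at a layer's native resolution.

    ``map`` is in the architecture-table layout (first axis = the long image
    axis), nonnegative because every anchored layer is ReLU-terminated.
    """

    layer_label: str
    channel_index: int
    map: np.ndarray
    source_crop_id: str


@dataclass(frozen=True)
class HeatMap:
    """Deep-layer response upsampled to crop resolution, in [0, 1].

    ``map`` is in image convention ``(rows, cols)`` matching the crop.
    Constant activations yield an all-zero map with ``constant=True``.
    """

    map: np.ndarray
    overlay_ready: bool = True
    constant: bool = False


def _anchor_labels(net: NetworkInstance) -> dict[str, str]:
    convs = [l.label for l in net.spec.layers if l.kind == "convolution"]
    incs = [l.label for l in net.spec.layers if l.kind == "inception"]
    if not convs:
        raise ValueError("architecture has no convolution layer to anchor 'early'")
    deep = incs[-1] if incs else convs[-1]
    if len(incs) >= 2:
        intermediate = incs[1]
    elif incs:
        intermediate = incs[0]
    else:
        intermediate = convs[min(1, len(convs) - 1)]
    return {"early": convs[0], "intermediate": intermediate, "deep": deep}


def activation_map(
    net: NetworkInstance,
    crop: DiatomCrop | np.ndarray,
    layer_selector: str,
    mode: str = "sum",
) -> ActivationMap:
    """Spatial map of the maximally activated channel at the selected depth.

    ``mode='sum'`` ranks channels by summed activation (default);
    ``mode='peak'`` by their single largest value.  Ties break to the lowest
    channel index.
    """
    if layer_selector not in SELECTORS:
        raise ValueError(
            f"invalid layer selector {layer_selector!r}; expected one of {SELECTORS}"
        )
    if mode not in ("sum", "peak"):
        raise ValueError(f"invalid mode {mode!r}; expected 'sum' or 'peak'")
    pixels = crop.pixels if isinstance(crop, DiatomCrop) else np.asarray(crop)
    crop_id = crop.crop_id if isinstance(crop, DiatomCrop) else "<array>"
    label = _anchor_labels(net)[layer_selector]
    _, captured = net.forward_batch(pixels[None, ...], training=False, capture=(label,))
    act = captured[label][0]  # (H, W, C) channels-last
    scores = act.sum(axis=(0, 1)) if mode == "sum" else act.max(axis=(0, 1))
    channel = int(np.argmax(scores))  # first maximal index on ties
    return ActivationMap(
        layer_label=label,
        channel_index=channel,
        map=np.ascontiguousarray(act[..., channel]),
        source_crop_id=crop_id,
    )


def heat_map(net: NetworkInstance, crop: DiatomCrop | np.ndarray, mode: str = "sum") -> HeatMap:
    """Deep-layer activation upsampled to the crop's resolution, normalized."""
    pixels = crop.pixels if isinstance(crop, DiatomCrop) else np.asarray(crop)
    rows, cols = pixels.shape[:2]
    amap = activation_map(net, crop, "deep", mode=mode)
    # native layout is (long axis, short axis); image convention is the transpose
    up = sk_resize(amap.map.astype(np.float64).T, (rows, cols), order=1, mode="reflect")
    lo, hi = float(up.min()), float(up.max())
    if hi - lo <= 1e-12:
        return HeatMap(map=np.zeros((rows, cols)), overlay_ready=True, constant=True)
    return HeatMap(map=(up - lo) / (hi - lo), overlay_ready=True, constant=False)
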