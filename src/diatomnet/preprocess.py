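"""Annotated micrographs to model-ready crops.

Each diatom is cut out of its micrograph by the annotated boundary polygon,
rotated so the principal axis of the polygon is horizontal ("horizontal
normalization"), cropped to the rotated polygon's bounding box with the
outside filled by a local background estimate, resized to the canonical
432x128 (width x height) input, and expanded into the four flip variants.

Coordinate conventions (used throughout the package):
* rasters are ``(rows, cols[, channels])`` with 0-based indices;
* polygons are ordered ``(x, y)`` pixel-coordinate vertex lists, ``x`` along
  columns and ``y`` along rows (y increases downward);
* bounding boxes are half-open;
* the principal-axis angle of a vertex set is
  ``0.5 * atan2(2*mu11, mu20 - mu02)`` of the centered vertex coordinates,
  in degrees, measured from the +x axis toward +y.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from skimage.draw import polygon as draw_polygon
from skimage.morphology import dilation, disk
from skimage.transform import resize as sk_resize
from skimage.transform import rotate as sk_rotate

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotatedImage",
    "DiatomCrop",
    "TARGET_HEIGHT",
    "TARGET_WIDTH",
    "AUGMENTATIONS",
    "principal_axis_angle",
    "extract_and_normalize",
    "resize_crop",
    "augment_flips",
    "read_annotation",
    "write_annotation",
]

TARGET_HEIGHT = 128  # rows: the average post-crop height of the source imagery
TARGET_WIDTH = 432  # cols: the average post-crop width

AUGMENTATIONS = ("original", "vflip", "hflip", "vhflip")


@dataclass(frozen=True)
class AnnotatedImage:
    """A micrograph with per-diatom polygon annotations and species labels."""

    image_id: str
    pixels: np.ndarray  # (rows, cols) or (rows, cols, 3), float in [0, 1]
    objects: tuple[tuple[np.ndarray, str], ...]  # ((V, 2) xy polygon, species)

    def validate(self, label_set: Optional[set[str]] = None) -> None:
        h, w = self.pixels.shape[:2]
        for i, (poly, species) in enumerate(self.objects):
            if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
                raise ValueError(f"{self.image_id} object {i}: polygon needs >=3 (x, y) vertices")
            if poly[:, 0].min() < 0 or poly[:, 1].min() < 0 or poly[:, 0].max() > w - 1 or poly[:, 1].max() > h - 1:
                raise ValueError(f"{self.image_id} object {i}: polygon outside image bounds")
            if label_set is not None and species not in label_set:
                raise ValueError(f"{self.image_id} object {i}: unknown species {species!r}")


@dataclass(frozen=True)
class DiatomCrop:
    """One extracted, horizontally normalized diatom image."""

    crop_id: str
    pixels: np.ndarray  # (rows, cols[, 3]) float in [0, 1]
    species: str
    source: tuple[str, int]  # (image_id, object index)
    augmentation: str = "original"
    rotation_applied: float = 0.0  # degrees
    mask: Optional[np.ndarray] = None  # ground-truth object mask, where known


def principal_axis_angle(polygon_xy: np.ndarray) -> float:
    """Major-axis angle (degrees) of the vertex-coordinate second-moment matrix."""
    p = np.asarray(polygon_xy, dtype=float)
    x = p[:, 0] - p[:, 0].mean()
    y = p[:, 1] - p[:, 1].mean()
    mu20, mu02, mu11 = (x * x).mean(), (y * y).mean(), (x * y).mean()
    return float(np.degrees(0.5 * np.arctan2(2.0 * mu11, mu20 - mu02)))


def _polygon_area(polygon_xy: np.ndarray) -> float:
    x, y = polygon_xy[:, 0], polygon_xy[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def _mask_from_polygon(polygon_xy: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    rr, cc = draw_polygon(polygon_xy[:, 1], polygon_xy[:, 0], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def _background_fill(patch: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Median intensity of a 2-pixel dilated annulus around the mask."""
    annulus = dilation(mask, disk(2)) & ~mask
    if not annulus.any():
        annulus = ~mask
    if not annulus.any():  # mask fills the whole patch: fall back to its median
        annulus = np.ones_like(mask)
    if patch.ndim == 3:
        return np.median(patch[annulus], axis=0)
    return np.median(patch[annulus])


def extract_and_normalize(annotated: AnnotatedImage) -> list[DiatomCrop]:
    """Extract one horizontally normalized crop per annotated object.

    The object patch is rotated (bilinear, reflective boundary) by the
    polygon's principal-axis angle so the major axis lies horizontal, then
    cropped to the rotated polygon's bounding box; pixels outside the polygon
    are replaced with the local background fill.  Degenerate (zero-area)
    polygons are skipped with a logged warning.  The 180-degree ambiguity of
    the axis is left unresolved; the flip augmentations cover both senses.
    """
    annotated.validate()
    img = annotated.pixels
    h, w = img.shape[:2]
    crops: list[DiatomCrop] = []
    for idx, (poly, species) in enumerate(annotated.objects):
        poly = np.asarray(poly, dtype=float)
        if _polygon_area(poly) <= 1.0:
            logger.warning(
                "skipping degenerate polygon: image %s object %d (area ~ 0)",
                annotated.image_id,
                idx,
            )
            continue
        theta = principal_axis_angle(poly)

        # sub-image with margin covering any rotation of the polygon
        x0, x1 = poly[:, 0].min(), poly[:, 0].max()
        y0, y1 = poly[:, 1].min(), poly[:, 1].max()
        cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
        half = 0.5 * float(np.hypot(x1 - x0, y1 - y0)) + 3.0
        r0, r1 = int(np.floor(cy - half)), int(np.ceil(cy + half)) + 1
        c0, c1 = int(np.floor(cx - half)), int(np.ceil(cx + half)) + 1
        pad = ((max(0, -r0), max(0, r1 - h)), (max(0, -c0), max(0, c1 - w)))
        if img.ndim == 3:
            pad = pad + ((0, 0),)
        patch = np.pad(
            img[max(0, r0) : min(h, r1), max(0, c0) : min(w, c1)], pad, mode="reflect"
        )
        local = poly - np.array([c0, r0])  # polygon in patch (x, y) coords

        # rotate patch by +theta about its center; this maps a +theta axis to
        # horizontal.  Matching point map: p' = [[c, s], [-s, c]] (p - ctr) + ctr.
        rotated = sk_rotate(
            patch.astype(np.float64), theta, resize=False, order=1, mode="reflect"
        )
        ctr = (np.array(patch.shape[:2][::-1], dtype=float) - 1.0) / 2.0  # (x, y)
        rad = np.deg2rad(theta)
        rot = np.array([[np.cos(rad), np.sin(rad)], [-np.sin(rad), np.cos(rad)]])
        rpoly = (local - ctr) @ rot.T + ctr

        # half-open bounding box of the rotated polygon, clipped to the patch
        bx0 = max(0, int(np.floor(rpoly[:, 0].min())))
        bx1 = min(rotated.shape[1], int(np.ceil(rpoly[:, 0].max())) + 1)
        by0 = max(0, int(np.floor(rpoly[:, 1].min())))
        by1 = min(rotated.shape[0], int(np.ceil(rpoly[:, 1].max())) + 1)
        box = rotated[by0:by1, bx0:bx1]
        bpoly = rpoly - np.array([bx0, by0])
        mask = _mask_from_polygon(bpoly, box.shape[:2])
        fill = _background_fill(box, mask)
        out = np.where(mask[..., None] if box.ndim == 3 else mask, box, fill)
        crops.append(
            DiatomCrop(
                crop_id=f"{annotated.image_id}_obj{idx}",
                pixels=out.astype(np.float32),
                species=species,
                source=(annotated.image_id, idx),
                augmentation="original",
                rotation_applied=theta,
                mask=mask,
            )
        )
    return crops


def resize_crop(
    crop: DiatomCrop, target_height: int = TARGET_HEIGHT, target_width: int = TARGET_WIDTH
) -> DiatomCrop:
    """Direct bilinear rescale to the fixed input size (aspect not preserved)."""
    if target_height < 1 or target_width < 1:
        raise ValueError("target size must be positive")
    if crop.pixels.size == 0:
        raise ValueError(f"crop {crop.crop_id} is empty")
    if crop.pixels.shape[:2] == (target_height, target_width):
        return crop
    out = sk_resize(
        crop.pixels.astype(np.float64),
        (target_height, target_width) + crop.pixels.shape[2:],
        order=1,
        mode="reflect",
        anti_aliasing=crop.pixels.shape[0] > target_height or crop.pixels.shape[1] > target_width,
    ).astype(np.float32)
    mask = None
    if crop.mask is not None:
        mask = (
            sk_resize(crop.mask.astype(float), (target_height, target_width), order=0) > 0.5
        )
    return replace(crop, pixels=out, mask=mask)


def _flip(pixels: np.ndarray, how: str) -> np.ndarray:
    if how == "vflip":
        return pixels[::-1].copy()
    if how == "hflip":
        return pixels[:, ::-1].copy()
    if how == "vhflip":
        return pixels[::-1, ::-1].copy()
    return pixels


def augment_flips(crop: DiatomCrop) -> list[DiatomCrop]:
    """The original plus its vertical, horizontal, and double flips.

    Only un-augmented crops may be expanded; augmenting an augmented crop is
    an error (it would silently double-count variants downstream).
    """
    if crop.augmentation != "original":
        raise ValueError(f"crop {crop.crop_id} is already augmented ({crop.augmentation})")
    out = [crop]
    for how in AUGMENTATIONS[1:]:
        out.append(
            replace(
                crop,
                crop_id=f"{crop.crop_id}_{how}",
                pixels=_flip(crop.pixels, how),
                mask=None if crop.mask is None else _flip(crop.mask, how),
                augmentation=how,
            )
        )
    return out


# ---------------------------------------------------------------------------
# annotation I/O: one JSON document per micrograph


def read_annotation(path, pixels: Optional[np.ndarray] = None) -> AnnotatedImage:
    """Read ``{image_id, width, height, objects: [{species, polygon}]}`` JSON.

    ``pixels`` may be supplied directly; otherwise a sibling image file named
    ``<image_id>.png`` next to the annotation is loaded.
    """
    path = Path(path)
    doc = json.loads(path.read_text())
    for key in ("image_id", "width", "height", "objects"):
        if key not in doc:
            raise ValueError(f"{path}: missing annotation field {key!r}")
    if pixels is None:
        import imageio.v3 as iio

        img_path = path.parent / f"{doc['image_id']}.png"
        pixels = np.asarray(iio.imread(img_path), dtype=np.float32) / 255.0
    if pixels.shape[0] != doc["height"] or pixels.shape[1] != doc["width"]:
        raise ValueError(f"{path}: raster size does not match declared width/height")
    objects = tuple(
        (np.asarray(o["polygon"], dtype=float), str(o["species"])) for o in doc["objects"]
    )
    ann = AnnotatedImage(image_id=str(doc["image_id"]), pixels=pixels, objects=objects)
    ann.validate()
    return ann


def write_annotation(annotated: AnnotatedImage, directory, write_image: bool = True) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    doc = {
        "image_id": annotated.image_id,
        "width": int(annotated.pixels.shape[1]),
        "height": int(annotated.pixels.shape[0]),
        "objects": [
            {"species": species, "polygon": np.asarray(poly, dtype=float).tolist()}
            for poly, species in annotated.objects
        ],
    }
    out = directory / f"{annotated.image_id}.json"
    out.write_text(json.dumps(doc))
    if write_image:
        import imageio.v3 as iio

        arr = np.clip(annotated.pixels * 255.0, 0, 255).astype(np.uint8)
        iio.imwrite(directory / f"{annotated.image_id}.png", arr)
    return out
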