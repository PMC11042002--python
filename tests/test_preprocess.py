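"""Crop extraction, horizontal normalization, resizing, and flip augmentation."""

import dataclasses
import json

import numpy as np
import pytest

from diatomnet import preprocess as P
from diatomnet import synthetic_data as S


def _mask_angle_deg(mask: np.ndarray) -> float:
    """Moment-based principal-axis angle of a binary mask (independent oracle)."""
    ys, xs = np.nonzero(mask)
    x = xs - xs.mean()
    y = ys - ys.mean()
    mu20, mu02, mu11 = (x * x).mean(), (y * y).mean(), (x * y).mean()
    return float(np.degrees(0.5 * np.arctan2(2 * mu11, mu20 - mu02)))


def _angle_dist(a: float, b: float) -> float:
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def _capsule_annotation(angle_deg: float, canvas=(240, 240), length=150.0, width=40.0):
    spec = S.SyntheticSpec(
        class_params=(S.ClassShape(length=length, aspect=length / width, stria_freq=0.08),),
        per_class_counts=(1,),
        canvas=canvas,
        objects_per_image=(1, 1),
        orientation_range=(angle_deg, angle_deg),
        seed=3,
    )
    images, truth = S.generate(spec)
    return images[0], truth[0]


class TestExtractAndNormalize:
    @pytest.mark.parametrize("angle", [0.0, 23.0, 37.0, 81.0, 122.0, 160.0])
    def test_object_is_horizontal_after_normalization(self, angle):
        ann, _ = _capsule_annotation(angle)
        crops = P.extract_and_normalize(ann)
        assert len(crops) == 1
        residual = _angle_dist(_mask_angle_deg(crops[0].mask), 0.0)
        assert residual <= 1.0

    def test_already_horizontal_rectangle_rotates_by_nearly_zero(self):
        img = np.full((60, 120), 0.2, dtype=np.float32)
        img[20:40, 10:110] = 0.8
        poly = np.array([[10, 20], [109, 20], [109, 39], [10, 39]], dtype=float)
        ann = P.AnnotatedImage("rect", img, ((poly, "sp"),))
        crops = P.extract_and_normalize(ann)
        assert abs(crops[0].rotation_applied) < 1e-6

    def test_one_crop_per_object_with_labels_in_annotation_order(self):
        img = np.full((80, 200), 0.1, dtype=np.float32)
        polys = []
        for i, x0 in enumerate((10, 80, 150)):
            img[30:50, x0 : x0 + 40] = 0.9
            polys.append(
                (
                    np.array(
                        [[x0, 30], [x0 + 39, 30], [x0 + 39, 49], [x0, 49]], dtype=float
                    ),
                    f"species_{i}",
                )
            )
        ann = P.AnnotatedImage("multi", img, tuple(polys))
        crops = P.extract_and_normalize(ann)
        assert [c.species for c in crops] == ["species_0", "species_1", "species_2"]
        assert [c.source for c in crops] == [("multi", 0), ("multi", 1), ("multi", 2)]

    def test_degenerate_polygon_is_skipped_with_warning(self, caplog):
        img = np.full((40, 40), 0.5, dtype=np.float32)
        line = np.array([[5, 5], [30, 5], [5, 5]], dtype=float)  # zero area
        box = np.array([[5, 10], [30, 10], [30, 30], [5, 30]], dtype=float)
        ann = P.AnnotatedImage("deg", img, ((line, "a"), (box, "b")))
        with caplog.at_level("WARNING"):
            crops = P.extract_and_normalize(ann)
        assert len(crops) == 1 and crops[0].species == "b"
        assert any("degenerate" in r.message for r in caplog.records)

    def test_annotation_bounds_validation(self):
        img = np.zeros((20, 20), dtype=np.float32)
        poly = np.array([[5, 5], [25, 5], [25, 15]], dtype=float)  # exceeds width
        with pytest.raises(ValueError, match="bounds"):
            P.AnnotatedImage("oob", img, ((poly, "a"),)).validate()


class TestResize:
    def test_resize_to_canonical_input_size(self):
        crop = P.DiatomCrop(
            "c", np.random.default_rng(0).random((260, 860)).astype(np.float32), "sp", ("i", 0)
        )
        out = P.resize_crop(crop)
        assert out.pixels.shape == (128, 432)

    def test_identity_resize_returns_unchanged_pixels(self):
        px = np.random.default_rng(1).random((128, 432)).astype(np.float32)
        crop = P.DiatomCrop("c", px, "sp", ("i", 0))
        out = P.resize_crop(crop)
        assert out.pixels is px

    def test_constant_crop_stays_constant(self):
        crop = P.DiatomCrop("c", np.full((50, 300), 0.37, dtype=np.float32), "sp", ("i", 0))
        out = P.resize_crop(crop)
        np.testing.assert_allclose(out.pixels, 0.37, atol=1e-5)

    def test_nonpositive_target_rejected(self):
        crop = P.DiatomCrop("c", np.zeros((10, 10), dtype=np.float32), "sp", ("i", 0))
        with pytest.raises(ValueError):
            P.resize_crop(crop, target_height=0, target_width=100)


class TestFlips:
    @pytest.fixture()
    def crop(self):
        px = np.random.default_rng(2).random((16, 32)).astype(np.float32)
        return P.DiatomCrop("c", px, "sp", ("i", 0))

    def test_four_variants_with_provenance(self, crop):
        out = P.augment_flips(crop)
        assert [c.augmentation for c in out] == ["original", "vflip", "hflip", "vhflip"]
        assert all(c.species == "sp" and c.source == ("i", 0) for c in out)

    def test_flip_group_laws(self, crop):
        out = {c.augmentation: c.pixels for c in P.augment_flips(crop)}
        np.testing.assert_array_equal(out["vflip"][::-1], out["original"])  # involution
        np.testing.assert_array_equal(out["hflip"][:, ::-1], out["original"])
        np.testing.assert_array_equal(out["vhflip"], out["vflip"][:, ::-1])  # composition

    def test_hflip_differs_exactly_at_mirrored_coordinates(self, crop):
        out = {c.augmentation: c.pixels for c in P.augment_flips(crop)}
        np.testing.assert_array_equal(out["hflip"], crop.pixels[:, ::-1])

    def test_augmenting_an_augmented_crop_is_an_error(self, crop):
        vflip = P.augment_flips(crop)[1]
        with pytest.raises(ValueError, match="already augmented"):
            P.augment_flips(vflip)

    def test_per_class_counts_exactly_quadruple(self):
        crops = [
            P.DiatomCrop(f"c{i}", np.zeros((4, 8), dtype=np.float32), f"sp{i % 2}", (f"i{i}", 0))
            for i in range(6)
        ]
        augmented = [v for c in crops for v in P.augment_flips(c)]
        assert len(augmented) == 24
        for lab in ("sp0", "sp1"):
            assert sum(c.species == lab for c in augmented) == 12


class TestAnnotationIO:
    def test_json_round_trip(self, tmp_path):
        ann, _ = _capsule_annotation(30.0, canvas=(200, 200))
        P.write_annotation(ann, tmp_path)
        restored = P.read_annotation(tmp_path / f"{ann.image_id}.json")
        assert restored.image_id == ann.image_id
        assert len(restored.objects) == len(ann.objects)
        np.testing.assert_allclose(restored.objects[0][0], ann.objects[0][0], atol=1e-9)

    def test_missing_field_rejected(self, tmp_path):
        (tmp_path / "bad.json").write_text(json.dumps({"image_id": "x", "objects": []}))
        with pytest.raises(ValueError, match="width"):
            P.read_annotation(tmp_path / "bad.json", pixels=np.zeros((4, 4)))
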