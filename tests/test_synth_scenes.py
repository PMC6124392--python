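"""Scene-generator tests: determinism, class balance, augmentation geometry."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from refinebank import benchmark_data as bd
from refinebank.core_io import Box, GroundTruthBox, read_voc_annotations
from refinebank.evaluation import iou
from refinebank.synth_scenes import (
    ClassAppearance,
    SceneSpec,
    augment,
    default_appearances,
    generate_dataset,
    generate_index,
    generate_scene,
)


class TestGenerateScene:
    def test_single_class_frequency_vector(self):
        spec = SceneSpec(image_size=128, boxes_per_image=4.0, max_box_side=64,
                         class_frequencies={"canker": 1.0}, seed=5)
        _, boxes = generate_scene(spec, seed=5)
        assert boxes and all(b.class_label == "canker" for b in boxes)

    def test_fixed_seed_is_deterministic(self):
        spec = SceneSpec(image_size=128, max_box_side=64, seed=9)
        img1, boxes1 = generate_scene(spec, seed=9)
        img2, boxes2 = generate_scene(spec, seed=9)
        np.testing.assert_array_equal(img1, img2)
        assert boxes1 == boxes2

    def test_boxes_lie_within_image_and_satisfy_invariants(self):
        spec = SceneSpec(image_size=128, boxes_per_image=8.0, max_box_side=64, seed=1)
        for s in range(5):
            _, boxes = generate_scene(spec, seed=s)
            for gt in boxes:
                assert 0 <= gt.box.x_min < gt.box.x_max <= 128
                assert 0 <= gt.box.y_min < gt.box.y_max <= 128

    def test_mutual_overlap_constraint_respected(self):
        spec = SceneSpec(image_size=192, boxes_per_image=10.0, max_box_side=96, seed=2)
        _, boxes = generate_scene(spec, seed=2)
        for i, a in enumerate(boxes):
            for b in boxes[i + 1 :]:
                inter = a.box.intersection_area(b.box)
                assert inter / min(a.box.area, b.box.area) <= 0.5 + 1e-9

    def test_class_shares_match_configured_frequencies(self):
        # many draws; leaf mold share within 3 multinomial sd of its frequency
        freqs = bd.disease_class_frequencies()
        spec = SceneSpec(image_size=256, boxes_per_image=12.0, max_box_side=64,
                         seed=31)
        labels = []
        for s in range(120):
            _, boxes = generate_scene(spec, seed=s)
            labels += [b.class_label for b in boxes]
        n = len(labels)
        assert n > 1000
        p = freqs["leaf_mold"]
        share = labels.count("leaf_mold") / n
        assert abs(share - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_confusable_pair_appearances_are_close(self):
        apps = default_appearances()
        for a, b in (("gray_mold", "canker"), ("canker", "plague")):
            dist = np.linalg.norm(
                np.array(apps[a].base_color) - np.array(apps[b].base_color)
            )
            assert dist < 0.1


class TestGenerateDataset:
    def test_zero_images_gives_empty_index(self, tmp_path):
        index = generate_dataset(SceneSpec(image_size=96, max_box_side=48, seed=0),
                                 0, tmp_path)
        assert len(index) == 0

    def test_files_written_and_readable(self, tmp_path):
        spec = SceneSpec(image_size=96, max_box_side=48, seed=4)
        generate_dataset(spec, 5, tmp_path)
        assert len(list((tmp_path / "images").glob("*.png"))) == 5
        assert len(list((tmp_path / "annotations").glob("*.xml"))) == 5
        assert (tmp_path / "splits.json").exists()
        back = read_voc_annotations(tmp_path / "annotations")
        assert len(back) == 5
        for rec in back:
            assert rec.path is not None and rec.path.exists()

    def test_round_trip_preserves_boxes_exactly(self, tmp_path):
        spec = SceneSpec(image_size=96, max_box_side=48, seed=4)
        index = generate_dataset(spec, 3, tmp_path)
        back = read_voc_annotations(tmp_path / "annotations")
        for image_id in index.image_ids:
            assert [g.box for g in back[image_id].boxes] == [
                g.box for g in index[image_id].boxes
            ]

    def test_same_seed_gives_identical_directory_digest(self, tmp_path):
        def digest(root: Path) -> str:
            h = hashlib.sha256()
            for p in sorted(root.rglob("*")):
                if p.is_file():
                    h.update(p.name.encode())
                    h.update(p.read_bytes())
            return h.hexdigest()

        spec = SceneSpec(image_size=96, max_box_side=48, seed=12)
        generate_dataset(spec, 4, tmp_path / "a")
        generate_dataset(spec, 4, tmp_path / "b")
        assert digest(tmp_path / "a") == digest(tmp_path / "b")


class TestAugment:
    def _image(self, rng, h=100, w=100):
        return (rng.random((h, w, 3)) * 255).astype(np.uint8)

    def test_identity_config_changes_nothing(self, rng):
        img = self._image(rng)
        boxes = [GroundTruthBox("i", Box(10, 0, 20, 10), "canker")]
        out_img, out_boxes = augment(img, boxes, {}, seed=0)
        np.testing.assert_array_equal(out_img, img)
        assert out_boxes == boxes

    def test_horizontal_flip_reflects_boxes(self, rng):
        img = self._image(rng)
        boxes = [GroundTruthBox("i", Box(10, 0, 20, 10), "canker")]
        _, out = augment(img, boxes, {"hflip": True}, seed=0)
        assert out[0].box == Box(80, 0, 90, 10)

    def test_flip_moves_pixels_with_boxes(self, rng):
        img = self._image(rng)
        boxes = [GroundTruthBox("i", Box(10, 0, 20, 10), "canker")]
        flipped, out = augment(img, boxes, {"hflip": True}, seed=0)
        b = out[0].box
        np.testing.assert_array_equal(
            flipped[0:10, int(b.x_min) : int(b.x_max)],
            img[0:10, 10:20][:, ::-1],
        )

    def test_rotation_90_maps_square_box_exactly(self, rng):
        img = self._image(rng, 100, 100)
        boxes = [GroundTruthBox("i", Box(10, 20, 30, 40), "canker")]
        _, out = augment(img, boxes, {"rotation": 90.0}, seed=0)
        # analytic: (x, y) -> (y, S - x) for a 90-degree CCW rotation (y down)
        expected = Box(20, 100 - 30, 40, 100 - 10)
        assert iou(out[0].box, expected) == pytest.approx(1.0, abs=1e-9)

    def test_rotation_90_moves_pixels_consistently(self, rng):
        img = self._image(rng, 64, 64)
        rot, _ = augment(img, [], {"rotation": 90.0}, seed=0)
        np.testing.assert_allclose(
            rot.astype(float), np.rot90(img, k=1).astype(float), atol=1.0
        )

    def test_crop_drops_boxes_below_quarter_area(self, rng):
        img = self._image(rng)
        boxes = [
            GroundTruthBox("i", Box(0, 0, 20, 20), "canker"),   # fully inside crop
            GroundTruthBox("i", Box(45, 45, 95, 95), "plague"),  # 5x5 of 50x50 kept
        ]
        _, out = augment(img, boxes, {"crop": (0, 0, 50, 50)}, seed=0)
        assert [g.class_label for g in out] == ["canker"]

    def test_crop_larger_than_image_errors(self, rng):
        with pytest.raises(ValueError, match="crop"):
            augment(self._image(rng), [], {"crop": (0, 0, 200, 200)}, seed=0)

    def test_resize_scales_boxes(self, rng):
        img = self._image(rng)
        boxes = [GroundTruthBox("i", Box(10, 20, 30, 40), "canker")]
        out_img, out = augment(img, boxes, {"resize": 0.5}, seed=0)
        assert out_img.shape[:2] == (50, 50)
        assert out[0].box == Box(5, 10, 15, 20)

    def test_intensity_ops_leave_boxes_untouched(self, rng):
        img = self._image(rng)
        boxes = [GroundTruthBox("i", Box(10, 20, 30, 40), "canker")]
        cfg = {"contrast": 1.3, "brightness": 0.1, "color": (1.1, 0.9, 1.0),
               "noise": 0.02}
        out_img, out = augment(img, boxes, cfg, seed=0)
        assert out == boxes
        assert out_img.shape == img.shape

    def test_unknown_op_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown"):
            augment(self._image(rng), [], {"warp": 1}, seed=0)

    def test_noise_is_deterministic_given_seed(self, rng):
        img = self._image(rng)
        a, _ = augment(img, [], {"noise": 0.05}, seed=3)
        b, _ = augment(img, [], {"noise": 0.05}, seed=3)
        np.testing.assert_array_equal(a, b)
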