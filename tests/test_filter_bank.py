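"""Filter-bank tests: scale adaptation, training-set construction, verifiers."""

import numpy as np
import pytest

from refinebank.core_io import Box, Detection, GroundTruthBox, Patch, extract_patch
from refinebank.evaluation import match_detections
from refinebank.filter_bank import (
    FilterBankModel,
    LabeledPatchSet,
    OracleFilterBank,
    ScalePolicy,
    VerifierSpec,
    build_training_set,
    sample_background_boxes,
    scale_adapt,
    train_verifier,
    verify,
)

POLICY = ScalePolicy(small_size=32, large_size=48, side_cutoff=150.0)


def color_patch_set(class_label, n, size, rng, sd=0.01, pos_color=0.7, neg_color=0.3):
    """Linearly separable fixture: positives and negatives differ in mean color."""
    patches, labels, prov = [], [], []
    for i in range(n):
        pos = i % 2 == 0
        mean = pos_color if pos else neg_color
        pixels = np.clip(mean + rng.normal(0, sd, (size, size, 3)), 0, 1).astype(np.float32)
        patches.append(Patch(pixels, scale_tag="small"))
        labels.append(1 if pos else 0)
        prov.append("tp" if pos else "background")
    return LabeledPatchSet(class_label, patches, np.array(labels), prov)


class TestScaleAdapt:
    def test_small_box_routes_to_small_scale(self):
        policy = ScalePolicy(300, 500, 150.0)
        src = Detection("i", Box(0, 0, 80, 60), "canker", 0.9)
        patch = Patch(np.zeros((60, 80, 3), np.float32), source=src)
        out = scale_adapt(patch, policy)
        assert out.pixels.shape == (300, 300, 3)
        assert out.scale_tag == "small"

    def test_large_box_routes_to_large_scale(self):
        policy = ScalePolicy(300, 500, 150.0)
        src = Detection("i", Box(0, 0, 400, 200), "canker", 0.9)
        patch = Patch(np.zeros((200, 400, 3), np.float32), source=src)
        out = scale_adapt(patch, policy)
        assert out.pixels.shape == (500, 500, 3)
        assert out.scale_tag == "large"

    def test_already_adapted_patch_is_pixel_identical(self, rng):
        pixels = rng.random((300, 300, 3)).astype(np.float32)
        src = Detection("i", Box(0, 0, 100, 100), "canker", 0.9)
        patch = Patch(pixels, source=src, scale_tag="small")
        out = scale_adapt(patch, ScalePolicy(300, 500, 150.0))
        assert out.pixels is pixels

    def test_policy_invariants(self):
        with pytest.raises(ValueError):
            ScalePolicy(500, 300, 150.0)
        with pytest.raises(ValueError):
            ScalePolicy(300, 500, 0.0)


class TestBuildTrainingSet:
    def _fixture(self, small_index, n_fp_keep=3):
        classes = small_index.class_labels()
        label = max(
            classes,
            key=lambda c: sum(g.class_label == c for g in small_index.ground_truths()),
        )
        gts = small_index.ground_truths()
        dets = []
        # one aligned TP candidate per GT of the class, plus shifted FPs
        for k, g in enumerate(g for g in gts if g.class_label == label):
            dets.append(Detection(g.image_id, g.box, label, 0.9))
        for k, g in enumerate(g for g in gts if g.class_label == label):
            if k >= n_fp_keep:
                break
            b = g.box
            shift = b.width  # disjoint from the GT -> guaranteed FP
            x1 = min(b.x_max + shift, 192.0)
            x0 = x1 - b.width
            dets.append(Detection(g.image_id, Box(x0, b.y_min, x1, b.y_max), label, 0.4))
        match = match_detections(dets, gts, 0.5)
        return label, dets, match

    def test_balancing_and_stratified_split_arithmetic(self, small_index):
        label, dets, match = self._fixture(small_index)
        n_pos = sum(
            1 for d, s in zip(match.detections, match.statuses)
            if s and d.class_label == label
        )
        backgrounds = sample_background_boxes(small_index, 40, seed=0, max_side=96)
        train, test = build_training_set(
            label, dets, match, small_index, backgrounds,
            split_fraction=0.8, seed=1, scale_policy=POLICY,
        )
        assert train.n_pos + test.n_pos == n_pos
        assert train.n_neg + test.n_neg == n_pos  # balanced up to 1:1
        assert train.n_pos == int(round(0.8 * n_pos))
        assert set(train.provenance) <= {"tp", "fp", "background"}

    def test_zero_true_positives_is_an_error(self, small_index):
        label = small_index.class_labels()[0]
        gts = small_index.ground_truths()
        dets = [Detection("scene_00000", Box(0, 0, 10, 10), label, 0.9)]
        match = match_detections([], gts, 0.5)
        with pytest.raises(ValueError, match="no true positives"):
            build_training_set(label, dets, match, small_index, [])

    def test_no_fp_fallback_uses_background_negatives(self, small_index):
        label, dets, match = self._fixture(small_index, n_fp_keep=0)
        backgrounds = sample_background_boxes(small_index, 40, seed=0, max_side=96)
        train, test = build_training_set(
            label, dets, match, small_index, backgrounds,
            split_fraction=0.5, seed=1, scale_policy=POLICY,
        )
        negs = [p for p in train.provenance + test.provenance if p != "tp"]
        assert negs and all(p == "background" for p in negs)

    def test_background_boxes_avoid_ground_truth(self, small_index):
        from refinebank.evaluation import iou

        boxes = sample_background_boxes(small_index, 30, seed=4, max_side=96)
        for bg in boxes:
            for gt in small_index[bg.image_id].boxes:
                assert iou(bg.box, gt.box) <= 0.2


class TestTrainVerifier:
    def test_separable_colors_reach_high_heldout_accuracy(self, rng):
        train = color_patch_set("canker", 200, 32, rng)
        test = color_patch_set("canker", 60, 32, rng)
        spec = VerifierSpec(class_label="canker", conv_depth=5, input_size=32,
                            epochs=10, seed=0)
        verifier = train_verifier(spec, train, test, POLICY)
        assert verifier.history.val_accuracy[-1] >= 0.95

    def test_shuffled_labels_stay_at_chance(self, rng):
        train = color_patch_set("canker", 200, 32, rng, sd=0.3,
                                pos_color=0.5, neg_color=0.5)
        test = color_patch_set("canker", 80, 32, rng, sd=0.3,
                               pos_color=0.5, neg_color=0.5)
        spec = VerifierSpec(class_label="canker", conv_depth=2, input_size=32,
                            epochs=4, seed=0)
        verifier = train_verifier(spec, train, test, POLICY)
        assert abs(verifier.history.val_accuracy[-1] - 0.5) <= 0.15

    def test_single_label_set_rejected(self, rng):
        train = color_patch_set("canker", 10, 32, rng)
        train.labels[:] = 1
        spec = VerifierSpec(class_label="canker", input_size=32)
        with pytest.raises(ValueError, match="both labels"):
            train_verifier(spec, train, None, POLICY)

    def test_training_is_deterministic_given_seed(self, rng):
        spec = VerifierSpec(class_label="c", conv_depth=1, input_size=32,
                            epochs=2, seed=3)
        out = []
        for _ in range(2):
            train = color_patch_set("c", 40, 32, np.random.default_rng(8))
            v = train_verifier(spec, train, None, POLICY)
            out.append(v.net.state_dict())
        for key in out[0]:
            np.testing.assert_array_equal(out[0][key], out[1][key])


class TestBankAndVerify:
    def _trained_bank(self, rng):
        train = color_patch_set("canker", 120, 32, rng)
        spec = VerifierSpec(class_label="canker", conv_depth=2, input_size=32,
                            epochs=8, seed=0)
        bank = FilterBankModel()
        bank.add(train_verifier(spec, train, None, POLICY))
        return bank

    def test_verify_decision_respects_threshold_rule(self, rng):
        bank = self._trained_bank(rng)
        image = np.full((64, 64, 3), 0.7, dtype=np.float32)
        det = Detection("i", Box(0, 0, 64, 64), "canker", 0.9)
        decision = verify(bank, det, image)
        assert decision.verdict == (decision.probability >= 0.5)
        assert decision.verdict  # bright patch is the positive color

    def test_missing_class_raises_with_name(self, rng):
        bank = self._trained_bank(rng)
        det = Detection("i", Box(0, 0, 10, 10), "plague", 0.9)
        with pytest.raises(KeyError, match="plague"):
            verify(bank, det, np.zeros((32, 32, 3), np.float32))

    def test_verify_is_deterministic(self, rng):
        bank = self._trained_bank(rng)
        image = rng.random((64, 64, 3)).astype(np.float32)
        det = Detection("i", Box(0, 0, 64, 64), "canker", 0.9)
        p1 = verify(bank, det, image).probability
        p2 = verify(bank, det, image).probability
        assert p1 == p2

    def test_one_verifier_per_class(self, rng):
        bank = self._trained_bank(rng)
        assert len(bank) == 1
        train = color_patch_set("plague", 40, 32, rng)
        spec = VerifierSpec(class_label="plague", conv_depth=1, input_size=32,
                            epochs=1, seed=0)
        bank.add(train_verifier(spec, train, None, POLICY))
        assert len(bank) == 2 and bank.class_labels == ["canker", "plague"]

    def test_save_load_round_trip_preserves_probabilities(self, rng, tmp_path):
        bank = self._trained_bank(rng)
        bank.save(tmp_path / "bank")
        loaded = FilterBankModel.load(tmp_path / "bank")
        image = rng.random((64, 64, 3)).astype(np.float32)
        det = Detection("i", Box(0, 0, 64, 64), "canker", 0.9)
        assert verify(loaded, det, image).probability == pytest.approx(
            verify(bank, det, image).probability, abs=1e-6
        )

    def test_oracle_bank_accepts_exactly_the_tps(self, single_image_index):
        dets = [
            Detection("img0", Box(10, 10, 40, 40), "canker", 0.9),   # TP
            Detection("img0", Box(12, 12, 42, 42), "canker", 0.8),   # duplicate FP
            Detection("img0", Box(60, 60, 90, 90), "canker", 0.7),   # wrong class FP
        ]
        matches = {
            "canker": match_detections(dets, single_image_index.ground_truths(), 0.5)
        }
        oracle = OracleFilterBank.from_matches(matches)
        img = single_image_index["img0"].array
        verdicts = [oracle.decide(d, img).verdict for d in dets]
        assert verdicts == [True, False, False]
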