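"""Rough rule, augmentation bookkeeping, CNN training and serialization."""

import dataclasses

import numpy as np
import pytest

from sampdetect import measure
from sampdetect.classify import (CLASS_ORDER, ClassifierModel,
                                 build_training_set, classify, classify_batch,
                                 extract_crop, normalize_crop, rough_classify,
                                 train_classifier)
from sampdetect.nn import SmallCNN


def stats_with(aspect, circ):
    return measure.ShapeStats(
        area_px=50, perimeter_px=30.0, feret_h_px=10, feret_v_px=5,
        feret_max_px=10, feret_min_px=10 / aspect, circularity=circ,
        aspect_ratio=aspect, size_px=10, size_um=180.0, size_category="large")


class TestRoughClassify:
    def test_disk_is_grain(self):
        assert rough_classify(stats_with(1.0, 0.95)) == "grain"

    def test_bar_is_fiber(self):
        assert rough_classify(stats_with(15.0, 0.19)) == "fiber"

    def test_natural_sediment_mean_shape_is_grain(self):
        # natural grains are elongated (aspect 3.16, circ 0.42): the fiber
        # gate must sit above them
        assert rough_classify(stats_with(3.16, 0.42)) == "grain"

    def test_elongated_very_noncircular_is_fiber(self):
        assert rough_classify(stats_with(3.5, 0.15)) == "fiber"


class TestCrops:
    def test_extract_crop_is_centred(self):
        frame = np.zeros((200, 300), dtype=np.uint8)
        frame[95:106, 145:156] = 200
        crop = extract_crop(frame, (150.0, 100.0), feret_max_px=11)
        assert crop.shape == (100, 100)
        yy, xx = np.nonzero(crop > 100)
        assert abs(yy.mean() - 49.5) < 2 and abs(xx.mean() - 49.5) < 2

    def test_oversized_particle_downscaled(self):
        frame = np.zeros((400, 400), dtype=np.uint8)
        frame[100:300, 150:250] = 180
        crop = extract_crop(frame, (200.0, 200.0), feret_max_px=220)
        assert crop.shape == (100, 100)
        assert (crop > 90).any()
        assert not (crop[:2] > 90).any()   # fits with padding

    def test_normalize_to_unit_range(self):
        crop = np.array([[10, 110], [210, 10]], dtype=np.uint8)
        norm = normalize_crop(crop)
        assert norm.min() == 0.0 and norm.max() == 1.0


class TestBuildTrainingSet:
    def test_augmentation_multiplicity(self, small_crop_dataset):
        crops, labels = small_crop_dataset
        x, y = build_training_set(crops, labels, n_per_class=50, seed=0)
        # 50 per class x 2 mirror states x 4 rotations
        assert len(x) == 50 * 8 * 2
        assert (np.bincount(y) == 50 * 8).all()

    def test_deterministic_under_seed(self, small_crop_dataset):
        crops, labels = small_crop_dataset
        x1, y1 = build_training_set(crops, labels, n_per_class=20, seed=4)
        x2, y2 = build_training_set(crops, labels, n_per_class=20, seed=4)
        assert np.array_equal(x1, x2) and np.array_equal(y1, y2)

    def test_deficient_class_named_in_error(self, small_crop_dataset):
        crops, labels = small_crop_dataset
        keep = np.r_[0:60, 60:100]    # 60 grains, only 40 fibers
        with pytest.raises(ValueError, match="fiber"):
            build_training_set(crops[keep], labels[keep], n_per_class=50)

    def test_no_augmentation_keeps_count(self, small_crop_dataset):
        crops, labels = small_crop_dataset
        x, _ = build_training_set(crops, labels, n_per_class=10, augment=(),
                                  seed=0)
        assert len(x) == 20


def tiny_model(small_crop_dataset, seed=0, shuffle_labels=False):
    crops, labels = small_crop_dataset
    labels = np.asarray(labels).copy()
    if shuffle_labels:
        labels = np.random.default_rng(99).permutation(labels)
    ts = build_training_set(crops, labels, n_per_class=40, augment=("mirror",),
                            seed=seed)
    return train_classifier(ts, max_epochs=12, seed=seed, input_size=32)


class TestTrainClassifier:
    def test_learns_separable_classes(self, small_crop_dataset):
        crops, labels = small_crop_dataset
        model = tiny_model(small_crop_dataset)
        preds = classify_batch(model, crops[40:60])   # held-out grains
        acc = np.mean([p.label == "grain" for p in preds])
        preds_f = classify_batch(model, crops[100:120])  # held-out fibers
        acc_f = np.mean([p.label == "fiber" for p in preds_f])
        assert acc >= 0.8 and acc_f >= 0.8

    def test_shuffled_labels_learn_nothing(self, small_crop_dataset):
        crops, labels = small_crop_dataset
        model = tiny_model(small_crop_dataset, shuffle_labels=True)
        preds = classify_batch(model, crops)
        acc = np.mean([p.label == t for p, t in zip(preds, labels)])
        assert 0.25 <= acc <= 0.75

    def test_training_is_deterministic(self, small_crop_dataset):
        crops, labels = small_crop_dataset
        ts = build_training_set(crops, labels, n_per_class=10, seed=1)
        m1 = train_classifier(ts, max_epochs=2, seed=5, input_size=32)
        m2 = train_classifier(ts, max_epochs=2, seed=5, input_size=32)
        for a, b in zip(m1.net.state_arrays().values(),
                        m2.net.state_arrays().values()):
            assert np.array_equal(a, b)

    def test_confidence_at_least_half(self, small_crop_dataset):
        crops, _ = small_crop_dataset
        model = tiny_model(small_crop_dataset)
        for pred in classify_batch(model, crops[:10]):
            assert 50.0 <= pred.confidence_pct <= 100.0
            assert pred.label in CLASS_ORDER

    def test_unbalanced_training_set_rejected(self, small_crop_dataset):
        crops, labels = small_crop_dataset
        x, y = build_training_set(crops, labels, n_per_class=10, seed=0)
        with pytest.raises(ValueError):
            train_classifier((x[y == 0], y[y == 0]))


class TestModelSerialization:
    def test_save_load_bit_identical_predictions(self, small_crop_dataset,
                                                 tmp_path):
        crops, _ = small_crop_dataset
        model = tiny_model(small_crop_dataset)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = ClassifierModel.load(path)
        assert loaded.class_order == CLASS_ORDER
        x = crops[:8]
        a = classify_batch(model, x)
        b = classify_batch(loaded, x)
        assert [(p.label, p.confidence_pct) for p in a] == \
               [(p.label, p.confidence_pct) for p in b]

    def test_metadata_round_trip(self, small_crop_dataset, tmp_path):
        model = tiny_model(small_crop_dataset)
        model.save(tmp_path / "m.npz")
        meta = ClassifierModel.load(tmp_path / "m.npz").metadata
        assert meta["epochs"] == model.metadata["epochs"]
        assert meta["seed"] == model.metadata["seed"]


class TestGradients:
    def test_backprop_matches_numerical_gradient(self):
        net = SmallCNN(input_size=8, n_classes=2, channels=(2, 3, 4),
                       hidden=5, seed=0)
        x = np.random.default_rng(1).random((3, 8, 8))
        y = np.array([0, 1, 0])
        net.loss_and_grads(x, y)
        params = [p for l in net.layers for p in l.params]
        grads = [g.copy() for l in net.layers for g in l.grads]
        eps = 1e-6
        rng = np.random.default_rng(2)
        for p, g in zip(params, grads):
            flat = rng.integers(0, p.size, size=min(3, p.size))
            for k in flat:
                idx = np.unravel_index(k, p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                lp = net.loss_and_grads(x, y)
                p[idx] = orig - eps
                lm = net.loss_and_grads(x, y)
                p[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(g[idx], rel=1e-4, abs=1e-8)


class TestAugmentationInvariance:
    def test_mirror_agreement_on_clean_crops(self, small_crop_dataset):
        crops, _ = small_crop_dataset
        model = tiny_model(small_crop_dataset)
        preds = classify_batch(model, crops)
        preds_m = classify_batch(model, np.flip(crops, axis=2))
        agree = np.mean([a.label == b.label for a, b in zip(preds, preds_m)])
        assert agree >= 0.95
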