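import numpy as np
import pytest

from biofilmquant._util import stream_rng
from biofilmquant.features import FeatureConfig, compute_feature_stack
from biofilmquant.imgio import BinaryMask, RoiSample, TrainingSet
from biofilmquant.preprocess import PreprocessConfig, apply_preset
from biofilmquant.segment import (RemovalResult, apply_classifier,
                                  extract_training_samples, load_classifier,
                                  quantify, remove_small_objects, save_classifier,
                                  train_classifier)
from biofilmquant.synthgen import SyntheticSpec, render_pair
from biofilmquant.validate import sample_rois_from_mask


def _mask(arr):
    return BinaryMask(np.asarray(arr, dtype=np.uint8))


class TestTrainingExtraction:
    def test_ten_rois_give_1440_rows(self, sla_stack):
        samples = [RoiSample(x=14 * i, y=0, label="biofilm") for i in range(5)]
        samples += [RoiSample(x=14 * i, y=40, label="surface") for i in range(5)]
        X, y = extract_training_samples(sla_stack, TrainingSet(samples))
        assert X.shape == (1440, sla_stack.n_features)
        assert y.shape == (1440,)
        assert set(np.unique(y)) == {0, 1}

    def test_truth_mode_labels_follow_mask(self, sla_stack, sla_pair):
        ts = TrainingSet([RoiSample(x=30, y=30, label="biofilm"),
                          RoiSample(x=80, y=80, label="surface")])
        _, y = extract_training_samples(sla_stack, ts, truth=sla_pair.before_mask)
        expected = np.concatenate([
            sla_pair.before_mask.pixels[30:42, 30:42].ravel(),
            sla_pair.before_mask.pixels[80:92, 80:92].ravel()]).astype(np.int64)
        assert np.array_equal(y, expected)

    def test_out_of_bounds_roi_rejected(self, sla_stack):
        ts = TrainingSet([RoiSample(x=250, y=0, label="biofilm"),
                          RoiSample(x=0, y=0, label="surface")])
        with pytest.raises(ValueError, match="bounds"):
            extract_training_samples(sla_stack, ts)


class TestClassifier:
    def test_separable_samples_reach_perfect_training_accuracy(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (200, 5)), rng.normal(3, 0.1, (200, 5))])
        y = np.repeat([0, 1], 200)
        clf = train_classifier(X, y, feature_fingerprint="test")
        assert clf.model.score(X, y) == 1.0

    def test_single_class_rejected(self):
        X = np.zeros((10, 3))
        with pytest.raises(ValueError):
            train_classifier(X, np.zeros(10, dtype=int), feature_fingerprint="t")

    def test_seeded_training_is_deterministic(self, sla_stack, sla_pair):
        ts = sample_rois_from_mask(sla_pair.before_mask, 12, stream_rng(5, 1))
        X, y = extract_training_samples(sla_stack, ts, truth=sla_pair.before_mask)
        masks = []
        for _ in range(2):
            clf = train_classifier(X, y, feature_fingerprint=sla_stack.fingerprint, seed=9)
            masks.append(apply_classifier(clf, sla_stack).mask.pixels)
        assert np.array_equal(masks[0], masks[1])

    def test_probability_map_definition(self, sla_stack, sla_pair):
        ts = sample_rois_from_mask(sla_pair.before_mask, 10, stream_rng(6, 1))
        X, y = extract_training_samples(sla_stack, ts, truth=sla_pair.before_mask)
        clf = train_classifier(X, y, feature_fingerprint=sla_stack.fingerprint)
        res = apply_classifier(clf, sla_stack)
        assert res.probability_map.min() >= 0.0 and res.probability_map.max() <= 1.0
        assert np.array_equal(res.mask.pixels, (res.probability_map > 0.5).astype(np.uint8))
        assert res.biofilm_area_px == res.mask.area_px

    def test_fingerprint_mismatch_rejected(self, sla_stack, sla_pair):
        ts = sample_rois_from_mask(sla_pair.before_mask, 10, stream_rng(7, 1))
        X, y = extract_training_samples(sla_stack, ts)
        clf = train_classifier(X, y, feature_fingerprint="something-else")
        with pytest.raises(ValueError, match="fingerprint"):
            apply_classifier(clf, sla_stack)

    def test_held_out_accuracy_on_sla_fixture(self, sla_stack, sla_pair):
        """20 truth-guided ROIs suffice to segment the rest of the image."""
        ts = sample_rois_from_mask(sla_pair.before_mask, 20, stream_rng(0, 1))
        X, y = extract_training_samples(sla_stack, ts, truth=sla_pair.before_mask)
        clf = train_classifier(X, y, feature_fingerprint=sla_stack.fingerprint, seed=0)
        mask = remove_small_objects(apply_classifier(clf, sla_stack).mask)
        trained = np.zeros(sla_pair.before_mask.shape, dtype=bool)
        for s in ts.samples:
            ys, xs = s.slices()
            trained[ys, xs] = True
        held_out = ~trained
        agree = mask.as_bool() == sla_pair.before_mask.as_bool()
        assert agree[held_out].mean() >= 0.9

    def test_roi_self_consistency(self, sla_stack, sla_pair):
        ts = sample_rois_from_mask(sla_pair.before_mask, 16, stream_rng(3, 1))
        X, y = extract_training_samples(sla_stack, ts, truth=sla_pair.before_mask)
        clf = train_classifier(X, y, feature_fingerprint=sla_stack.fingerprint)
        res = apply_classifier(clf, sla_stack)
        pred = res.mask.pixels
        correct = 0
        for s in ts.samples:
            ys, xs = s.slices()
            correct += (pred[ys, xs] == sla_pair.before_mask.pixels[ys, xs]).sum()
        assert correct / len(y) >= 0.95

    def test_save_load_roundtrip(self, tmp_path, sla_stack, sla_pair):
        ts = sample_rois_from_mask(sla_pair.before_mask, 10, stream_rng(8, 1))
        X, y = extract_training_samples(sla_stack, ts)
        clf = train_classifier(X, y, feature_fingerprint=sla_stack.fingerprint, seed=2)
        save_classifier(clf, tmp_path / "clf.joblib")
        back = load_classifier(tmp_path / "clf.joblib")
        assert back.feature_fingerprint == clf.feature_fingerprint
        a = apply_classifier(clf, sla_stack).mask.pixels
        b = apply_classifier(back, sla_stack).mask.pixels
        assert np.array_equal(a, b)


class TestBatchStratification:
    def test_coverage_matched_classifier_wins(self):
        """Classifiers trained on biofilm-rich vs biofilm-poor images each
        segment their own coverage stratum at least as well as the swap."""
        stacks, truths, clfs = {}, {}, {}
        for name, cov, sd in (("rich", 0.55, 21), ("poor", 0.08, 22)):
            spec = SyntheticSpec(surface_type="sla", width=192, height=192,
                                 target_coverage=cov, seed=sd)
            pair = render_pair(spec)
            img = apply_preset(pair.before_img, PreprocessConfig.for_surface("sla"))
            st = compute_feature_stack(img, FeatureConfig.default())
            ts = sample_rois_from_mask(pair.before_mask, 20, stream_rng(sd, 1))
            X, y = extract_training_samples(st, ts, truth=pair.before_mask)
            clfs[name] = train_classifier(X, y, feature_fingerprint=st.fingerprint, seed=sd)
            stacks[name], truths[name] = st, pair.before_mask.as_bool()

        def acc(clf_name, img_name):
            m = remove_small_objects(apply_classifier(clfs[clf_name], stacks[img_name]).mask)
            return (m.as_bool() == truths[img_name]).mean()

        own = acc("rich", "rich") + acc("poor", "poor")
        swapped = acc("poor", "rich") + acc("rich", "poor")
        assert own > swapped


class TestPostprocessing:
    def test_strict_smaller_than_20_boundary(self):
        arr = np.zeros((64, 64), dtype=np.uint8)
        arr[2, 2:21] = 1          # 19-pixel line component
        arr[10:14, 10:15] = 1     # 20-pixel block component
        out = remove_small_objects(_mask(arr), min_size=20)
        assert out.pixels[2, 2:21].sum() == 0
        assert out.pixels[10:14, 10:15].sum() == 20

    def test_empty_mask_unchanged(self):
        out = remove_small_objects(_mask(np.zeros((40, 40))))
        assert out.area_px == 0

    def test_diagonal_connectivity_is_eight(self):
        arr = np.zeros((40, 40), dtype=np.uint8)
        for i in range(25):  # diagonal chain: one 25-px component under 8-conn
            arr[i, i] = 1
        assert remove_small_objects(_mask(arr), min_size=20).area_px == 25
        assert remove_small_objects(_mask(arr), min_size=20, connectivity=4).area_px == 0

    def test_idempotent_and_never_grows(self, rng):
        m = _mask(rng.random((80, 80)) > 0.7)
        once = remove_small_objects(m)
        twice = remove_small_objects(once)
        assert np.array_equal(once.pixels, twice.pixels)
        assert once.area_px <= m.area_px
        assert not (once.as_bool() & ~m.as_bool()).any()


class TestQuantify:
    def test_arithmetic(self):
        before = np.zeros((64, 64), dtype=np.uint8)
        before.ravel()[:2000] = 1
        after = np.zeros((64, 64), dtype=np.uint8)
        after.ravel()[:500] = 1
        res = quantify(_mask(before), _mask(after))
        assert res.percent_remaining == 25.0
        assert res.percent_removed == 75.0

    def test_identical_masks_give_100(self, rng):
        m = _mask(rng.random((40, 40)) > 0.5)
        assert quantify(m, m.copy()).percent_remaining == 100.0

    def test_area_increase_flagged(self):
        before = np.zeros((64, 64), dtype=np.uint8)
        before.ravel()[:1000] = 1
        after = np.zeros((64, 64), dtype=np.uint8)
        after.ravel()[:1100] = 1
        with pytest.warns(UserWarning, match="increased"):
            res = quantify(_mask(before), _mask(after))
        assert res.percent_remaining == pytest.approx(110.0)

    def test_empty_before_rejected(self):
        with pytest.raises(ValueError, match="no biofilm"):
            quantify(_mask(np.zeros((40, 40))), _mask(np.ones((40, 40))))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimensions"):
            quantify(_mask(np.ones((40, 40))), _mask(np.ones((40, 42))))

    def test_removal_result_requires_positive_before(self):
        with pytest.raises(ValueError):
            RemovalResult(area_before_px=0, area_after_px=5)
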