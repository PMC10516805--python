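import numpy as np
import pytest

import osteoseg as osg
from osteoseg.errors import DomainError, ModelIOError, TrainingError


def two_class_table():
    return osg.ClassTable(
        (
            osg.ClassEntry(1, "background", (0, 0, 255)),
            osg.ClassEntry(2, "cell", (255, 0, 0)),
        )
    )


@pytest.fixture
def separable_fixture(rng):
    """Pure purple blob on pure white: colours alone separate the classes."""
    pixels = np.full((48, 48, 3), 255, dtype=np.uint8)
    rr, cc = np.mgrid[0:48, 0:48]
    blob = (rr - 24) ** 2 + (cc - 24) ** 2 < 14**2
    pixels[blob] = (128, 72, 148)
    img = osg.RasterImage(pixels, calibration_um=1.0)
    labels = np.zeros((48, 48), dtype=np.uint8)
    inside = np.argwhere((rr - 24) ** 2 + (cc - 24) ** 2 < 10**2)
    outside = np.argwhere((rr - 24) ** 2 + (cc - 24) ** 2 > 20**2)
    for src, cid in ((inside, 2), (outside, 1)):
        pick = src[rng.choice(len(src), size=150, replace=False)]
        labels[pick[:, 0], pick[:, 1]] = cid
    return img, osg.AnnotationMap(labels, two_class_table()), blob


class TestTraining:
    def test_separable_fixture_reaches_full_training_accuracy(self, separable_fixture, small_config):
        img, ann, _ = separable_fixture
        model = osg.PixelClassifier(
            feature_config=small_config, n_trees=30, random_state=3,
            class_table=ann.class_table,
        ).fit([img], [ann])
        seg = model.predict(img)
        mask = ann.labels > 0
        assert (seg.labels[mask] == ann.labels[mask]).all()

    def test_held_out_pixels_get_confident_correct_probabilities(self, separable_fixture, small_config):
        img, ann, blob = separable_fixture
        model = osg.PixelClassifier(
            feature_config=small_config, n_trees=30, random_state=3,
            class_table=ann.class_table,
        ).fit([img], [ann])
        probs = model.predict_proba(img)
        # evaluate well inside each region, away from the colour boundary
        rr, cc = np.mgrid[0:48, 0:48]
        core = (rr - 24) ** 2 + (cc - 24) ** 2 < 10**2
        rim = (rr - 24) ** 2 + (cc - 24) ** 2 > 20**2
        held_out = (core | rim) & (ann.labels == 0)
        expected = np.where(core, 2, 1)[held_out]
        modal = np.asarray(ann.class_table.ids)[np.argmax(probs.probs, axis=2)][held_out]
        confident = probs.probs.max(axis=2)[held_out] > 0.9
        assert np.mean((modal == expected) & confident) >= 0.99

    def test_same_seed_gives_identical_manifest_and_predictions(self, separable_fixture, small_config):
        img, ann, _ = separable_fixture
        import json

        runs = []
        for _ in range(2):
            model = osg.PixelClassifier(
                feature_config=small_config, n_trees=20, random_state=11,
                class_table=ann.class_table,
            ).fit([img], [ann])
            runs.append(
                (json.dumps(model.manifest_, sort_keys=True), model.predict(img).labels)
            )
        assert runs[0][0] == runs[1][0]
        np.testing.assert_array_equal(runs[0][1], runs[1][1])

    def test_unannotated_class_raises_naming_the_class(self, separable_fixture, small_config):
        img, ann, _ = separable_fixture
        only_bg = osg.AnnotationMap(
            np.where(ann.labels == 1, 1, 0).astype(np.uint8), ann.class_table
        )
        with pytest.raises(TrainingError, match="cell"):
            osg.PixelClassifier(
                feature_config=small_config, class_table=ann.class_table
            ).fit([img], [only_bg])

    def test_shape_mismatch_rejected(self, separable_fixture, small_config):
        img, ann, _ = separable_fixture
        short = osg.AnnotationMap(ann.labels[:-2], ann.class_table)
        with pytest.raises(DomainError, match="shape"):
            osg.PixelClassifier(
                feature_config=small_config, class_table=ann.class_table
            ).fit([img], [short])

    def test_manifest_counts_match_annotation_totals(self, separable_fixture, small_config):
        img, ann, _ = separable_fixture
        model = osg.PixelClassifier(
            feature_config=small_config, n_trees=10, class_table=ann.class_table
        ).fit([img], [ann])
        assert model.manifest_["training_pixels_per_class"] == {
            "background": 150,
            "cell": 150,
        }


class TestPrediction:
    def test_probabilities_normalise_per_pixel(self, separable_fixture, small_config):
        img, ann, _ = separable_fixture
        model = osg.PixelClassifier(
            feature_config=small_config, n_trees=15, class_table=ann.class_table
        ).fit([img], [ann])
        probs = model.predict_proba(img).probs
        np.testing.assert_allclose(probs.sum(axis=2), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_half_turn_rotation_commutes_with_prediction(self, separable_fixture, small_config):
        img, ann, _ = separable_fixture
        model = osg.PixelClassifier(
            feature_config=small_config, n_trees=15, class_table=ann.class_table
        ).fit([img], [ann])
        direct = model.predict_proba(
            osg.RasterImage(np.ascontiguousarray(np.rot90(img.pixels, 2)), 1.0)
        ).probs
        rotated = np.rot90(model.predict_proba(img).probs, 2)
        np.testing.assert_allclose(direct, rotated, atol=1e-6)

    def test_forest_matches_analytic_threshold_rule(self, rng):
        """A 1-feature, threshold-separable problem: the forest's decision must
        agree with the analytic threshold on essentially every pixel."""
        lo = rng.integers(0, 101, size=(32, 32), dtype=np.uint8)
        hi = rng.integers(150, 256, size=(32, 32), dtype=np.uint8)
        cell = rng.random((32, 32)) < 0.5
        gray = np.where(cell, hi, lo).astype(np.uint8)
        img = osg.RasterImage(np.repeat(gray[:, :, None], 3, axis=2), 1.0)
        ann = osg.AnnotationMap(np.where(cell, 2, 1).astype(np.uint8), two_class_table())
        config = osg.FeatureConfig(scales=(0.3,), groups=("smoothed_colour",))
        model = osg.PixelClassifier(
            feature_config=config, n_trees=25, random_state=5,
            class_table=ann.class_table,
        ).fit([img], [ann])
        test_gray = np.where(
            rng.random((32, 32)) < 0.5,
            rng.integers(150, 256, size=(32, 32)),
            rng.integers(0, 101, size=(32, 32)),
        ).astype(np.uint8)
        test_img = osg.RasterImage(np.repeat(test_gray[:, :, None], 3, axis=2), 1.0)
        predicted = model.predict(test_img).labels
        analytic = np.where(test_gray > 125, 2, 1)
        assert np.mean(predicted == analytic) >= 0.999


class TestSegment:
    def _probs(self, grid):
        return osg.ProbabilityMap(
            np.asarray(grid, dtype=np.float64), osg.default_class_table(), 2.031
        )

    def test_argmax_assigns_highest_class(self):
        seg = osg.segment(self._probs([[[0.1, 0.2, 0.3, 0.4]]]))
        assert seg.labels[0, 0] == 4

    def test_ties_break_toward_lowest_class_id(self):
        seg = osg.segment(self._probs([[[0.25, 0.25, 0.25, 0.25]]]))
        assert seg.labels[0, 0] == 1

    def test_one_hot_probabilities_recover_classes(self, rng):
        labels = rng.integers(1, 5, size=(9, 7))
        one_hot = np.eye(4)[labels - 1]
        seg = osg.segment(self._probs(one_hot))
        np.testing.assert_array_equal(seg.labels, labels)
        assert seg.calibration_um == 2.031

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(DomainError):
            self._probs([[[0.5, 0.5, 0.5, 0.5]]])


class TestPersistence:
    def test_save_load_round_trip_predicts_identically(self, separable_fixture, small_config, tmp_path):
        img, ann, _ = separable_fixture
        model = osg.PixelClassifier(
            feature_config=small_config, n_trees=10, random_state=7,
            class_table=ann.class_table,
        ).fit([img], [ann])
        p = str(tmp_path / "model.osc")
        model.save(p)
        loaded = osg.load_model(p)
        np.testing.assert_array_equal(
            loaded.predict_proba(img).probs, model.predict_proba(img).probs
        )
        assert loaded.manifest_ == model.manifest_

    def test_truncated_file_raises_load_error(self, separable_fixture, small_config, tmp_path):
        img, ann, _ = separable_fixture
        model = osg.PixelClassifier(
            feature_config=small_config, n_trees=5, class_table=ann.class_table
        ).fit([img], [ann])
        p = str(tmp_path / "model.osc")
        model.save(p)
        blob = open(p, "rb").read()
        open(p, "wb").write(blob[: len(blob) // 2])
        with pytest.raises(ModelIOError):
            osg.load_model(p)

    def test_unfitted_model_cannot_save_or_predict(self, tmp_path):
        model = osg.PixelClassifier()
        with pytest.raises(DomainError):
            model.save(str(tmp_path / "m.osc"))


def test_sklearn_param_interface_round_trips():
    model = osg.PixelClassifier(n_trees=42, random_state=9)
    params = model.get_params()
    assert params["n_trees"] == 42
    clone = osg.PixelClassifier().set_params(**params)
    assert clone.get_params() == params
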