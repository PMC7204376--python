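import numpy as np
import pytest

import earasym as ea
from earasym.detector import (
    EYE_SUBSET,
    ERTModel,
    align_shape_to_box,
    apply_stage,
    augment_training_set,
    flag_incorrect_detection,
    generate_initial_samples,
    grid_search,
    nme,
    predict_landmarks,
    shape_bounding_box,
    train_cascade,
    _clip_box_to_image,
)


def _box(shape, image):
    return _clip_box_to_image(shape_bounding_box(shape, 0.2), image.shape)


class TestNME:
    def test_exact_prediction_is_zero(self, template):
        assert nme(template, template) == 0.0

    def test_single_point_offset(self, template):
        pts = template.points.copy()
        pts[0] += (2.0, 0.0)  # 2 px error, interocular distance 60
        full = nme(pts, template.points)
        assert full == pytest.approx(2.0 / 60 / 68)
        assert nme(pts, template.points, point_subset=[0]) == pytest.approx(2.0 / 60)

    def test_eye_subset_matches_hand_rolled_oracle(self, template):
        rng = np.random.default_rng(5)
        noisy = template.points + rng.normal(0, 1.5, (68, 2))
        expected = np.mean(
            [np.linalg.norm(noisy[i] - template.points[i]) for i in EYE_SUBSET]) / 60.0
        assert nme(noisy, template.points, point_subset=EYE_SUBSET) == pytest.approx(expected)

    def test_squared_variant(self, template):
        pts = template.points.copy()
        pts[0] += (2.0, 0.0)
        assert nme(pts, template.points, point_subset=[0], squared=True) == \
            pytest.approx(4.0 / 60)


class TestAugmentation:
    @pytest.fixture()
    def tiny_set(self):
        rng = np.random.default_rng(0)
        images = [rng.uniform(0, 255, (32, 32)) for _ in range(3)]
        shapes = [rng.uniform(5, 27, (68, 2)) for _ in range(3)]
        return images, shapes

    def test_factor_one_is_identity(self, tiny_set):
        images, shapes = tiny_set
        ai, ash = augment_training_set(images, shapes, factor=1, seed=0)
        assert len(ai) == 3
        for a, b in zip(ash, shapes):
            np.testing.assert_array_equal(a, b)

    def test_output_size_is_factor_times_input(self, tiny_set):
        images, shapes = tiny_set
        ai, ash = augment_training_set(images, shapes, factor=10, seed=0)
        assert len(ai) == len(ash) == 30

    def test_deterministic_given_seed(self, tiny_set):
        images, shapes = tiny_set
        _, a = augment_training_set(images, shapes, factor=4, seed=7)
        _, b = augment_training_set(images, shapes, factor=4, seed=7)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_factor_below_one_rejected(self, tiny_set):
        images, shapes = tiny_set
        with pytest.raises(ValueError):
            augment_training_set(images, shapes, factor=0, seed=0)


class TestInitialSamples:
    def test_sample_count(self, rendered_faces):
        images, shapes = rendered_faces
        samples = generate_initial_samples(images[:5], shapes[:5], n_initializations=3, seed=0)
        assert len(samples) == 15

    def test_mean_shape_initialization(self, rendered_faces):
        images, shapes = rendered_faces
        s = generate_initial_samples(images[:3], shapes[:3], n_initializations=1,
                                     seed=0, use_mean_shape=True)
        from earasym.detector import compute_mean_shape
        expected = align_shape_to_box(
            compute_mean_shape(shapes[:3]),
            _clip_box_to_image(shape_bounding_box(shapes[0], 0.2), images[0].shape))
        np.testing.assert_allclose(s[0].current_shape, expected)

    def test_residual_zero_iff_current_equals_target(self, rendered_faces):
        images, shapes = rendered_faces
        s = generate_initial_samples(images[:3], shapes[:3], n_initializations=2, seed=0)[0]
        assert np.abs(s.residual).max() > 0
        s.current_shape = s.target_shape.copy()
        assert np.abs(s.residual).max() == 0

    def test_single_shape_multiple_inits_rejected(self, rendered_faces):
        images, shapes = rendered_faces
        with pytest.raises(ValueError):
            generate_initial_samples(images[:1], shapes[:1], n_initializations=2, seed=0)


class TestCascadeTraining:
    def test_zero_learning_rate_is_a_no_op(self, rendered_faces):
        images, shapes = rendered_faces
        samples = generate_initial_samples(images[:8], shapes[:8], 1, seed=2)
        model = train_cascade(samples, stages=2, trees_per_stage=5, depth=3,
                              learning_rate=0.0, seed=2)
        image, truth = images[10], shapes[10]
        box = _box(truth, image)
        init = align_shape_to_box(model.mean_shape, box)
        pred = predict_landmarks(model, image, box)
        np.testing.assert_array_equal(pred.points, init)

    def test_training_error_non_increasing_within_each_stage(self, trained_detector):
        model, _, _ = trained_detector
        for stage_history in model.train_history:
            assert all(b <= a + 1e-12 for a, b in zip(stage_history, stage_history[1:]))

    def test_overfits_a_single_repeated_image(self, rendered_faces):
        images, shapes = rendered_faces
        samples = generate_initial_samples([images[0]] * 6, [shapes[0]] * 6,
                                           1, seed=3, use_mean_shape=True)
        model = train_cascade(samples, stages=8, trees_per_stage=30, depth=4,
                              learning_rate=0.5, seed=3)
        pred = predict_landmarks(model, images[0], _box(shapes[0], images[0]))
        assert nme(pred, shapes[0]) < 0.01

    def test_beats_mean_shape_baseline_on_held_out_faces(self, trained_detector):
        model, (test_images, test_shapes), _ = trained_detector
        model_errs, baseline_errs = [], []
        for image, truth in zip(test_images, test_shapes):
            box = _box(truth, image)
            model_errs.append(nme(predict_landmarks(model, image, box), truth))
            baseline_errs.append(nme(align_shape_to_box(model.mean_shape, box), truth))
        assert np.mean(model_errs) < np.mean(baseline_errs)

    def test_empty_and_invalid_inputs(self):
        with pytest.raises(ValueError):
            train_cascade([])


class TestPrediction:
    def test_cascade_is_the_fold_of_per_stage_updates(self, trained_detector):
        model, (test_images, test_shapes), _ = trained_detector
        image, truth = test_images[0], test_shapes[0]
        box = _box(truth, image)
        shape = align_shape_to_box(model.mean_shape, box)
        for stage in model.stages:
            shape = apply_stage(stage, image, shape, model.mean_shape)
        np.testing.assert_array_equal(shape, predict_landmarks(model, image, box).points)

    def test_deterministic(self, trained_detector):
        model, (test_images, test_shapes), _ = trained_detector
        box = _box(test_shapes[0], test_images[0])
        a = predict_landmarks(model, test_images[0], box)
        b = predict_landmarks(model, test_images[0], box)
        np.testing.assert_array_equal(a.points, b.points)

    def test_zero_stage_model_returns_aligned_mean_shape(self, trained_detector):
        model, (test_images, test_shapes), _ = trained_detector
        empty = ERTModel(mean_shape=model.mean_shape)
        box = _box(test_shapes[0], test_images[0])
        pred = predict_landmarks(empty, test_images[0], box)
        np.testing.assert_array_equal(pred.points, align_shape_to_box(model.mean_shape, box))

    def test_box_outside_image_rejected(self, trained_detector):
        model, (test_images, _), _ = trained_detector
        with pytest.raises(ValueError):
            predict_landmarks(model, test_images[0], (-5, 0, 50, 50))

    def test_serialization_round_trip_is_bit_identical(self, trained_detector, tmp_path):
        model, (test_images, test_shapes), _ = trained_detector
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = ERTModel.load(path)
        box = _box(test_shapes[0], test_images[0])
        a = predict_landmarks(model, test_images[0], box)
        b = predict_landmarks(loaded, test_images[0], box)
        np.testing.assert_array_equal(a.points, b.points)


class TestGridSearch:
    def test_single_cell_grid_returns_that_model(self, rendered_faces):
        images, shapes = rendered_faces
        samples = generate_initial_samples(images[:10], shapes[:10], 1, seed=4)
        test_set = list(zip(images[10:14], shapes[10:14]))
        model, table = grid_search(samples, test_set, depths=[3], learning_rates=[0.3],
                                   stages=2, trees_per_stage=8, seed=4)
        assert table.shape == (1, 1)
        assert model.depth == 3 and model.learning_rate == 0.3

    def test_table_covers_the_grid_and_argmin_is_minimal(self, rendered_faces):
        images, shapes = rendered_faces
        samples = generate_initial_samples(images[:10], shapes[:10], 1, seed=4)
        test_set = list(zip(images[10:14], shapes[10:14]))
        model, table = grid_search(samples, test_set, depths=[2, 3],
                                   learning_rates=[0.1, 0.5],
                                   stages=2, trees_per_stage=8, seed=4)
        assert table.shape == (2, 2)
        best = table.loc[model.depth, model.learning_rate]
        assert (table.to_numpy() >= best - 1e-15).all()

    def test_empty_grid_rejected(self, rendered_faces):
        images, shapes = rendered_faces
        samples = generate_initial_samples(images[:4], shapes[:4], 1, seed=4)
        with pytest.raises(ValueError):
            grid_search(samples, [], depths=[], learning_rates=[0.1])


class TestIncorrectDetectionFlag:
    def test_exact_prediction_never_flagged(self, template):
        for thr in (0.01, 0.08, 1.0):
            flagged, _ = flag_incorrect_detection(template, template, threshold=thr)
            assert not flagged

    def test_collapsed_eyes_flagged_against_open_truth(self, template):
        pred = template.points.copy()
        pred[36:48] = pred[36]
        flagged, reason = flag_incorrect_detection(pred, template)
        assert flagged and "NME" in reason

    def test_truth_free_sanity_checks(self, template):
        # taller-than-wide eye
        pred = template.points.copy()
        pred[37:39, 1] -= 40
        flagged, reason = flag_incorrect_detection(pred)
        assert flagged and "taller" in reason
        # healthy open face passes
        assert not flag_incorrect_detection(template)[0]

    def test_recall_on_injected_corrupt_detections(self, default_cohort):
        rng = np.random.default_rng(33)
        flags = []
        n_corrupt = 0
        for seq, _grade in default_cohort[:60]:
            truth = seq[0]
            pred = truth.points.copy()
            corrupt = rng.random() < 0.1
            if corrupt:
                n_corrupt += 1
                # eye landmarks drift far off target, as in a failed detection
                pred[36:48] += rng.normal(0, 12, (12, 2))
            else:
                pred += rng.normal(0, 0.5, (68, 2))
            flagged, _ = flag_incorrect_detection(pred, truth)
            flags.append((corrupt, flagged))
        recall = sum(f for c, f in flags if c) / max(n_corrupt, 1)
        false_flags = sum(f for c, f in flags if not c)
        assert recall >= 0.9
        assert false_flags <= 3

    def test_invalid_threshold(self, template):
        with pytest.raises(ValueError):
            flag_incorrect_detection(template, template, threshold=0.0)
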