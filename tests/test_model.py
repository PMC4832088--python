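import numpy as np
import pandas as pd
import pytest

import vbmpattern as vp
from vbmpattern.model import PatternClassificationModel, apply_to_external

from conftest import make_separable_matrix


class TestTrainLinearSvm:
    def test_symmetric_pair_boundary_at_zero(self):
        clf = vp.train_linear_svm(
            np.array([[1.0], [-1.0]]), np.array(["case", "control"])
        )
        assert clf.intercept == pytest.approx(0, abs=1e-9)
        assert clf.predict(np.array([[0.5], [-0.5]])).tolist() == ["case", "control"]

    def test_separable_data_trains_to_perfect_accuracy(self):
        rng = np.random.default_rng(0)
        x = np.r_[rng.normal(2, 0.1, (10, 3)), rng.normal(-2, 0.1, (10, 3))]
        y = np.array(["case"] * 10 + ["control"] * 10)
        clf = vp.train_linear_svm(x, y, regularization=100.0)
        assert (clf.predict(x) == y).all()

    def test_xor_layout_capped_by_linear_separability(self):
        # oracle: no linear rule classifies more than 3 of the 4 XOR points
        x = np.array([[0, 0], [1, 1], [0, 1], [1, 0]], dtype=float)
        y = np.array(["case", "case", "control", "control"])
        rng = np.random.default_rng(1)
        best = 0
        for _ in range(2000):
            w, b = rng.normal(size=2), rng.normal()
            pred = np.where(x @ w + b > 0, "case", "control")
            best = max(best, (pred == y).mean())
        assert best <= 0.75
        clf = vp.train_linear_svm(x, y)
        assert (clf.predict(x) == y).mean() <= 0.75

    def test_empty_feature_set_rejected(self):
        with pytest.raises(ValueError, match="no voxels"):
            vp.train_linear_svm(np.empty((4, 0)), np.array(["case"] * 2 + ["control"] * 2))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            vp.train_linear_svm(np.ones((3, 2)), np.array(["case"] * 3))


@pytest.fixture(scope="module")
def matrix():
    return make_separable_matrix(n_cases=6, n_controls=8, gap=0.5, seed=3)


@pytest.fixture(scope="module")
def separable_model():
    mat = make_separable_matrix(n_cases=6, n_controls=8, gap=0.5, seed=3)
    return PatternClassificationModel(
        mat, vp.CVConfig(selection=vp.SelectionConfig(z_threshold=1.5), seed=5)
    )


class TestRepeatedCV:
    def cfg(self, **kw):
        kw.setdefault("selection", vp.SelectionConfig(z_threshold=1.5))
        kw.setdefault("seed", 5)
        return vp.CVConfig(**kw)

    def test_single_iteration_records_two_predictions(self, matrix):
        res = PatternClassificationModel(matrix, self.cfg(n_iterations=1)).fit()
        valid = res.iteration_records[~res.iteration_records["skipped"]]
        assert len(valid) == 2
        assert set(valid["true_label"]) == {"case", "control"}

    def test_test_rows_disjoint_from_train(self, matrix):
        model = PatternClassificationModel(matrix, self.cfg())
        for it in range(20):
            rng = model._iteration_rng(it)
            train, test = model.draw_split(rng)
            assert len(np.intersect1d(train, test)) == 0
            assert matrix.labels[test].tolist() == ["case", "control"]

    def test_reproducible_from_seed(self, matrix):
        r1 = PatternClassificationModel(matrix, self.cfg(n_iterations=25)).fit()
        r2 = PatternClassificationModel(matrix, self.cfg(n_iterations=25)).fit()
        pd.testing.assert_frame_equal(r1.iteration_records, r2.iteration_records)

    def test_strong_signal_classifies_well(self, matrix):
        res = PatternClassificationModel(matrix, self.cfg(n_iterations=100)).fit()
        assert res.prediction_accuracy > 0.75
        assert res.n_skipped == 0

    def test_summary_invariants(self, matrix):
        res = PatternClassificationModel(matrix, self.cfg(n_iterations=100)).fit()
        s = res.tested
        assert (s["severity_score"] >= 0).all() and (s["severity_score"] <= 1).all()
        assert (s["mca"] >= 0.5).all()
        assert (s["n_predicted_case"] <= s["n_tested"]).all()
        assert s["n_tested"].sum() == 200

    def test_all_subjects_eventually_tested(self, matrix):
        res = PatternClassificationModel(matrix, self.cfg(n_iterations=200)).fit()
        assert (res.subject_summaries["n_tested"] > 0).all()

    def test_empty_selection_iterations_skipped_and_logged(self, matrix):
        cfg = self.cfg(n_iterations=10, selection=vp.SelectionConfig(z_threshold=50.0))
        res = PatternClassificationModel(matrix, cfg).fit()
        assert res.n_skipped == 10
        assert np.isnan(res.majority_accuracy)

    def test_default_train_count_is_min_group_minus_one(self, matrix):
        model = PatternClassificationModel(matrix, self.cfg())
        assert model.n_train_per_group == 5

    def test_oversized_train_count_rejected(self, matrix):
        with pytest.raises(ValueError, match="n_train_per_group"):
            PatternClassificationModel(matrix, self.cfg(n_train_per_group=6))

    def test_mca_definition_matches_majority_agreement(self, matrix):
        res = PatternClassificationModel(matrix, self.cfg(n_iterations=60)).fit()
        s = res.tested
        expected = np.maximum(s["prop_correct"], 1 - s["prop_correct"])
        assert np.allclose(s["mca"], expected)


class TestFinalClassifierAndExternal:
    @pytest.fixture()
    def model(self, separable_model):
        return separable_model

    def test_selection_is_definitional_full_sample(self, model):
        clf = model.train_final_classifier()
        zmap = vp.difference_zmap(model.matrix)
        expected = vp.select_voxels(zmap, model.config.selection)
        assert np.array_equal(clf.selected_columns, expected)

    def test_deterministic_weights(self, model):
        a = model.train_final_classifier()
        b = model.train_final_classifier()
        assert np.array_equal(a.weights, b.weights)
        assert a.intercept == b.intercept

    def test_external_equal_training_reproduces_training_predictions(self, model):
        clf = model.train_final_classifier()
        preds = apply_to_external(clf, model, model.matrix)
        assert np.array_equal(preds, clf.predict(model.matrix.values))
        # training-set optimism: separable data reclassifies perfectly
        assert (preds == model.matrix.labels).all()

    def test_single_subject_external(self, model):
        clf = model.train_final_classifier()
        external = vp.VoxelMatrix(
            values=model.matrix.values[:1],
            voxel_index=model.matrix.voxel_index,
            labels=model.matrix.labels[:1],
            affine=model.matrix.affine,
            grid_shape=model.matrix.grid_shape,
        )
        assert apply_to_external(clf, model, external).shape == (1,)

    def test_grid_mismatch_names_shapes(self, model):
        external = vp.VoxelMatrix(
            values=np.ones((2, 4)),
            voxel_index=np.array([[i, 0, 0] for i in range(4)]),
            labels=np.array(["case", "control"]),
            affine=np.eye(4),
            grid_shape=(4, 1, 1),
        )
        clf = model.train_final_classifier()
        with pytest.raises(ValueError, match=r"\(4, 1, 1\)"):
            apply_to_external(clf, model, external)

    def test_empty_selection_blocks_final_training(self):
        matrix = make_separable_matrix(gap=0.0, seed=0)
        model = PatternClassificationModel(
            matrix, vp.CVConfig(selection=vp.SelectionConfig(z_threshold=50.0))
        )
        with pytest.raises(ValueError, match="empty voxel selection"):
            model.train_final_classifier()

    def test_control_only_external_matches_false_alarm_rate(self, strong_matrix, strong_results):
        # external cohort drawn from the control generator: the fraction
        # predicted case should behave like 1 - specificity
        # same seed as the training cohort -> same template texture;
        # different group sizes -> fresh subject noise draws
        cfg = vp.CohortConfig(clusters=vp.default_clusters(), seed=7,
                              n_cases=2, n_controls=40)
        volumes, phenotypes = vp.generate_cohort(cfg)
        keep = [i for i, p in enumerate(phenotypes) if p.label == "control"]
        mask3d = np.zeros(strong_matrix.grid_shape, bool)
        mask3d[tuple(strong_matrix.voxel_index.T)] = True
        external = vp.assemble_matrix(
            [volumes[i] for i in keep], ["control"] * len(keep), mask3d
        )
        preds = strong_results.predict_external(external)
        predicted_case_fraction = (preds == "case").mean()
        spec = strong_results.performance().specificity
        assert abs(predicted_case_fraction - (1 - spec)) < 0.35
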