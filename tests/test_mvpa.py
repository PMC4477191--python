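"""MVPA: feature extraction, kernel, SVM (against analytic and primal-QP
oracles), leave-one-pair-out CV, permutation testing, weight maps, and ROC."""

import numpy as np
import pandas as pd
import pytest

import reho_mvpa as rm
from reho_mvpa.mvpa import (
    FeatureMatrix, _pairs_from_labels, decision_values,
)
from conftest import primal_svm_decisions, make_dataset


def _toy_dataset(X, labels, mask_shape=(3, 3, 2)):
    """Wrap a feature matrix into a CohortDataset with a trivial mask."""
    n_vox = X.shape[1]
    mask_arr = np.zeros(mask_shape, bool)
    mask_arr.ravel()[:n_vox] = True
    mask = rm.GreyMask(mask_arr, (3.0, 3.0, 3.0))
    maps = []
    for i in range(X.shape[0]):
        data = np.full(mask_shape, np.nan)
        data.ravel()[:n_vox] = X[i]
        maps.append(rm.ReHoMap(data=data, mask=mask, cluster_size=27))
    ids = [f"s{i:02d}" for i in range(X.shape[0])]
    return rm.CohortDataset(subject_ids=ids, maps=maps,
                            labels=np.asarray(labels), mask=mask)


class TestFeatureExtraction:
    def test_shape_and_order(self):
        X = np.arange(40, dtype=float).reshape(4, 10)
        ds = _toy_dataset(X, [1, 1, -1, -1], mask_shape=(10, 1, 1))
        feats = rm.extract_features(ds)
        np.testing.assert_array_equal(feats.X, X)
        assert feats.n_dropped == 0

    def test_missing_voxel_dropped_cohort_wide(self):
        X = np.arange(40, dtype=float).reshape(4, 10)
        ds = _toy_dataset(X, [1, 1, -1, -1], mask_shape=(10, 1, 1))
        ds.maps[1].data.ravel()[3] = np.nan
        ds.maps[2].data.ravel()[7] = np.nan
        feats = rm.extract_features(ds)
        assert feats.X.shape == (4, 8)
        assert feats.n_dropped == 2

    def test_scatter_round_trip(self):
        X = np.random.default_rng(0).random((3, 6))
        ds = _toy_dataset(X, [1, -1, 1])
        feats = rm.extract_features(ds)
        w = np.arange(6, dtype=float)
        out = feats.scatter(w)
        assert out.shape == ds.mask.data.shape
        np.testing.assert_array_equal(out.ravel()[feats.index_map], w)
        off = np.ones(out.size, bool)
        off[feats.index_map] = False
        assert np.all(out.ravel()[off] == 0)


class TestLinearKernel:
    def test_orthonormal_rows_give_identity(self):
        X = np.eye(2, 5)
        np.testing.assert_allclose(rm.linear_kernel(X), np.eye(2))

    def test_symmetric_psd(self, rng):
        X = rng.standard_normal((7, 12))
        K = rm.linear_kernel(X)
        np.testing.assert_array_equal(K, K.T)
        assert np.linalg.eigvalsh(K).min() >= -1e-8

    def test_matches_explicit_double_loop(self, rng):
        X = rng.standard_normal((5, 20))
        K = rm.linear_kernel(X)
        for i in range(5):
            for j in range(5):
                assert K[i, j] == pytest.approx(float(np.dot(X[i], X[j])),
                                                abs=1e-12)

    def test_nonfinite_features_name_subjects(self):
        X = np.ones((3, 4))
        X[1, 2] = np.inf
        with pytest.raises(ValueError, match=r"\[1\]"):
            rm.linear_kernel(X)


class TestTrainSvm:
    def test_symmetric_two_point_problem_analytic(self):
        X = np.array([[1.0, 0.0], [-1.0, 0.0]])
        y = np.array([1, -1])
        model = rm.train_svm(rm.linear_kernel(X), y)
        w = model.dual_coefficients @ X
        np.testing.assert_allclose(w, [1.0, 0.0], atol=1e-6)
        assert model.bias == pytest.approx(0.0, abs=1e-6)
        assert set(model.support_indices) == {0, 1}
        f = decision_values(model, rm.linear_kernel(X))
        np.testing.assert_allclose(f, [1.0, -1.0], atol=1e-6)

    def test_separable_cloud_perfect_training_accuracy(self, rng):
        X = rng.standard_normal((20, 5))
        X[:10, 0] += 50.0
        X[10:, 0] -= 50.0
        y = np.array([1] * 10 + [-1] * 10)
        model = rm.train_svm(rm.linear_kernel(X), y)
        f = decision_values(model, rm.linear_kernel(X))
        assert np.all(np.sign(f) == y)

    def test_box_constraint_and_kkt(self, rng):
        X = rng.standard_normal((12, 8))
        y = np.array([1] * 6 + [-1] * 6)
        C = 1.0
        K = rm.linear_kernel(X)
        model = rm.train_svm(K, y, cost=C)
        a = model.dual_coefficients
        assert np.all(np.abs(a) <= C + 1e-9)
        f = decision_values(model, K)
        unbounded = (np.abs(a) > 1e-7) & (np.abs(a) < C - 1e-7)
        np.testing.assert_allclose(f[unbounded], y[unbounded], atol=1e-6)

    @pytest.mark.parametrize("trial", range(5))
    def test_dual_matches_primal_oracle(self, trial):
        r = np.random.default_rng(77 + trial)
        n = int(r.integers(8, 41))
        d = int(r.integers(5, 501))
        X = r.standard_normal((n, d))
        y = np.ones(n, dtype=int)
        y[: n // 2] = -1
        y = r.permutation(y)
        K = rm.linear_kernel(X)
        model = rm.train_svm(K, y)
        f_dual = decision_values(model, K)
        f_primal = primal_svm_decisions(X, y, C=1.0)
        np.testing.assert_allclose(f_dual, f_primal, atol=1e-4)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).standard_normal((4, 3))
        with pytest.raises(ValueError):
            rm.train_svm(rm.linear_kernel(X), np.ones(4, dtype=int))


class TestWeightMap:
    def test_two_point_problem_map(self):
        X = np.array([[1.0, 0.0], [-1.0, 0.0]])
        ds = _toy_dataset(X, [1, -1])
        feats = rm.extract_features(ds)
        model = rm.train_svm(rm.linear_kernel(feats), ds.labels)
        wmap = rm.dual_to_weight_map(model, feats, ds.mask)
        flat = wmap.data.ravel()[feats.index_map]
        np.testing.assert_allclose(flat, [1.0, 0.0], atol=1e-6)

    def test_representer_identity(self, rng):
        X = rng.standard_normal((10, 30))
        y = np.array([1] * 5 + [-1] * 5)
        ds = _toy_dataset(X, y, mask_shape=(5, 3, 2))
        feats = rm.extract_features(ds)
        K = rm.linear_kernel(feats)
        model = rm.train_svm(K, y)
        wmap = rm.dual_to_weight_map(model, feats, ds.mask)
        w = wmap.data.ravel()[feats.index_map]
        f_primal = X @ w + model.bias
        f_dual = decision_values(model, K)
        np.testing.assert_allclose(f_primal, f_dual, atol=1e-6)

    def test_label_flip_negates_map(self, rng):
        X = rng.standard_normal((10, 30))
        y = np.array([1] * 5 + [-1] * 5)
        ds = _toy_dataset(X, y, mask_shape=(5, 3, 2))
        feats = rm.extract_features(ds)
        K = rm.linear_kernel(feats)
        m1 = rm.dual_to_weight_map(rm.train_svm(K, y), feats, ds.mask)
        m2 = rm.dual_to_weight_map(rm.train_svm(K, -y), feats, ds.mask)
        np.testing.assert_allclose(m1.data, -m2.data, atol=1e-8)


class TestLeaveOnePairOut:
    def test_single_pair_enumerates(self, rng):
        # with one pair held out the fold count is 1 and only the two
        # held-out subjects are predicted... but a 1-pair cohort has an
        # empty training set, so use 2 pairs and check the fold structure
        X = rng.standard_normal((4, 6))
        ds = _toy_dataset(X, [1, 1, -1, -1])
        cv = rm.leave_one_pair_out_cv(ds)
        assert len(cv.fold_models) == 2
        assert len(cv.per_subject) == 4
        assert cv.accuracy == pytest.approx(
            (cv.sensitivity * 2 + cv.specificity * 2) / 4)

    def test_strong_effect_perfect_accuracy(self, strong_effect_config):
        ds, _ = make_dataset(strong_effect_config)
        cv = rm.leave_one_pair_out_cv(ds)
        assert cv.accuracy == 1.0

    def test_margin_sign_matches_prediction(self, rng):
        X = rng.standard_normal((8, 10))
        X[:4] += 3.0
        ds = _toy_dataset(X, [1, 1, 1, 1, -1, -1, -1, -1], mask_shape=(10, 1, 1))
        cv = rm.leave_one_pair_out_cv(ds)
        per = cv.per_subject
        nonzero = per["test_margin"] != 0
        assert np.all(np.sign(per.loc[nonzero, "test_margin"]) ==
                      per.loc[nonzero, "predicted_label"])

    def test_unequal_groups_rejected(self, rng):
        X = rng.standard_normal((5, 6))
        ds = _toy_dataset(X, [1, 1, 1, -1, -1])
        with pytest.raises(ValueError, match="equal group sizes"):
            rm.leave_one_pair_out_cv(ds)

    def test_pair_id_column_controls_pairing(self):
        labels = np.array([1, 1, -1, -1])
        pair_ids = np.array(["a", "b", "b", "a"])
        pairs = _pairs_from_labels(labels, pair_ids)
        assert pairs == [(0, 3), (1, 2)]

    def test_exchangeability_under_subject_reordering(self, rng):
        X = rng.standard_normal((8, 12))
        X[:4] += 1.0
        labels = np.array([1, 1, 1, 1, -1, -1, -1, -1])
        ds = _toy_dataset(X, labels, mask_shape=(12, 1, 1))
        cv = rm.leave_one_pair_out_cv(ds)
        # reorder within groups, preserving the patient-k/control-k pairing
        order = [1, 0, 3, 2, 5, 4, 7, 6]
        ds2 = _toy_dataset(X[order], labels[order], mask_shape=(12, 1, 1))
        ds2.subject_ids = [ds.subject_ids[i] for i in order]
        cv2 = rm.leave_one_pair_out_cv(ds2)
        assert cv2.accuracy == cv.accuracy
        m1 = dict(zip(cv.per_subject["subject_id"], cv.per_subject["test_margin"]))
        m2 = dict(zip(cv2.per_subject["subject_id"], cv2.per_subject["test_margin"]))
        for sid in m1:
            assert m1[sid] == pytest.approx(m2[sid], abs=1e-9)


class TestPermutation:
    def test_forced_bound_with_perfect_observed(self, strong_effect_config):
        ds, _ = make_dataset(strong_effect_config)
        perm = rm.permutation_test(ds, n_permutations=99, seed=1)
        # no null permutation can beat 100% accuracy
        assert perm.p_values["accuracy"] <= 0.01 + 1e-12

    def test_same_seed_reproduces_null(self, small_null_config):
        ds, _ = make_dataset(small_null_config)
        p1 = rm.permutation_test(ds, n_permutations=20, seed=5)
        p2 = rm.permutation_test(ds, n_permutations=20, seed=5)
        pd.testing.assert_frame_equal(p1.null_statistics, p2.null_statistics)
        assert p1.p_values == p2.p_values

    def test_p_value_floor(self, small_null_config):
        ds, _ = make_dataset(small_null_config)
        perm = rm.permutation_test(ds, n_permutations=19, seed=2)
        for p in perm.p_values.values():
            assert 1.0 / 20 <= p <= 1.0

    def test_invalid_permutation_count(self, small_null_config):
        ds, _ = make_dataset(small_null_config)
        with pytest.raises(ValueError):
            rm.permutation_test(ds, n_permutations=0, seed=1)


class TestConsensusWeightMap:
    def test_single_fold_equals_unit_normalized_fold(self, rng):
        X = rng.standard_normal((6, 8))
        X[:3] += 2.0
        ds = _toy_dataset(X, [1, 1, 1, -1, -1, -1], mask_shape=(8, 1, 1))
        feats = rm.extract_features(ds)
        cv = rm.leave_one_pair_out_cv(ds, features=feats)
        single = rm.consensus_weight_map(cv.fold_models[:1], feats, ds.mask)
        model = cv.fold_models[0]
        w = model.dual_coefficients @ feats.X[model.training_indices]
        np.testing.assert_allclose(
            single.data.ravel()[feats.index_map], w / np.linalg.norm(w),
            atol=1e-12)

    def test_identical_folds_average_to_any_fold(self, rng):
        X = rng.standard_normal((6, 8))
        ds = _toy_dataset(X, [1, 1, 1, -1, -1, -1], mask_shape=(8, 1, 1))
        feats = rm.extract_features(ds)
        cv = rm.leave_one_pair_out_cv(ds, features=feats)
        rep = rm.consensus_weight_map([cv.fold_models[0]] * 3, feats, ds.mask)
        one = rm.consensus_weight_map([cv.fold_models[0]], feats, ds.mask)
        np.testing.assert_allclose(rep.data, one.data, atol=1e-12)

    def test_injected_voxels_carry_top_weights(self, strong_effect_config):
        ds, truth = make_dataset(strong_effect_config)
        feats = rm.extract_features(ds)
        cv = rm.leave_one_pair_out_cv(ds, features=feats)
        wmap = rm.consensus_weight_map(cv.fold_models, feats, ds.mask)
        w = np.abs(wmap.data)
        inj = truth.astype(bool) & ds.mask.data
        noninj = ~truth.astype(bool) & ds.mask.data
        cutoff = np.percentile(w[noninj], 90)
        assert np.mean(w[inj] > cutoff) >= 0.8


class TestThreshold:
    def _map_from_values(self, values):
        # one value every third voxel so each survivor is its own cluster
        shape = (3 * len(values), 1, 3)
        data = np.zeros(shape)
        for i, v in enumerate(values):
            data[3 * i, 0, 1] = v
        mask = rm.GreyMask(np.ones(shape, bool), (3.0, 3.0, 3.0))
        return rm.WeightMap(data=data, mask=mask)

    def test_stated_rule_on_toy_values(self):
        wmap = self._map_from_values([20.0, -18.0, 6.0, 5.9, 0.0])
        table = rm.threshold_weight_map(wmap, fraction=0.30)
        kept = sorted(table["peak_weight"])
        assert kept == [-18.0, 6.0, 20.0]  # 5.9 < 6.0 dropped; 6.0 kept (>=)

    def test_fraction_one_keeps_only_max(self):
        wmap = self._map_from_values([20.0, -18.0, 6.0])
        table = rm.threshold_weight_map(wmap, fraction=1.0)
        assert list(table["peak_weight"]) == [20.0]

    def test_sign_interpretation(self):
        wmap = self._map_from_values([20.0, -18.0])
        table = rm.threshold_weight_map(wmap, fraction=0.30)
        by_w = dict(zip(table["peak_weight"], table["class"]))
        assert by_w[20.0] == "patient" and by_w[-18.0] == "control"

    def test_all_zero_map_warns_empty(self):
        wmap = self._map_from_values([0.0, 0.0])
        with pytest.warns(UserWarning):
            table = rm.threshold_weight_map(wmap, fraction=0.30)
        assert table.empty

    def test_peak_mm_coordinates_via_affine(self):
        wmap = self._map_from_values([10.0])
        table = rm.threshold_weight_map(wmap, fraction=0.5)
        assert (table.loc[0, ["peak_x_mm", "peak_y_mm", "peak_z_mm"]].tolist()
                == [0.0, 0.0, 3.0])

    def test_cluster_peaks_recover_injected_region(self, strong_effect_config):
        ds, truth = make_dataset(strong_effect_config)
        feats = rm.extract_features(ds)
        cv = rm.leave_one_pair_out_cv(ds, features=feats)
        wmap = rm.consensus_weight_map(cv.fold_models, feats, ds.mask)
        table = rm.threshold_weight_map(wmap, fraction=0.30)
        from scipy.ndimage import binary_dilation
        near_truth = binary_dilation(truth.astype(bool), np.ones((3, 3, 3)))
        for _, row in table.iterrows():
            assert near_truth[row["peak_i"], row["peak_j"], row["peak_k"]]

    def test_invalid_fraction_rejected(self):
        wmap = self._map_from_values([1.0])
        with pytest.raises(ValueError):
            rm.threshold_weight_map(wmap, fraction=0.0)


class TestROC:
    def _cv(self, labels, margins):
        per = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(len(labels))],
            "true_label": labels,
            "predicted_label": np.where(np.asarray(margins) > 0, 1, -1),
            "test_margin": margins,
        })
        return rm.CVResult(per_subject=per, accuracy=0, sensitivity=0,
                           specificity=0)

    def test_perfectly_ordered_margins_auc_one(self):
        cv = self._cv([1, 1, -1, -1], [2.0, 1.0, -1.0, -2.0])
        assert rm.roc_from_margins(cv).auc == pytest.approx(1.0)

    def test_sign_flip_complements_auc(self, rng):
        labels = np.array([1] * 10 + [-1] * 10)
        margins = rng.standard_normal(20)
        a = rm.roc_from_margins(self._cv(labels, margins)).auc
        b = rm.roc_from_margins(self._cv(labels, -margins)).auc
        assert a + b == pytest.approx(1.0)

    def test_identical_margins_degenerate(self):
        cv = self._cv([1, 1, -1, -1], [0.5] * 4)
        with pytest.warns(UserWarning):
            roc = rm.roc_from_margins(cv)
        assert roc.auc == 0.5
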