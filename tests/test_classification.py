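"""Nested leave-one-pair-out CV, permutation nulls, importance, learning curve."""

import warnings

import numpy as np
import pandas as pd
import pytest

from ptemark import classification as cls
from ptemark import synthetic_cohort as sc


def make_table(rng, n_per_group=8, separation=0.0, informative=None):
    """Synthetic 135-column feature table with optional planted mean shift."""
    les_cols, conn_cols, alff_cols = cls.feature_columns(sc.ROI_NAMES)
    cols = les_cols + conn_cols + alff_cols
    n = 2 * n_per_group
    x = rng.standard_normal((n, len(cols)))
    y = np.array(["PTE"] * n_per_group + ["nonPTE"] * n_per_group)
    idx = informative if informative is not None else list(range(10))
    x[: n_per_group, idx] += separation
    ids = [f"s{i:02d}" for i in range(n)]
    data = pd.DataFrame(x, index=ids, columns=cols)
    labels = pd.Series(y, index=ids)
    return cls.assemble_features(
        data[les_cols], data[conn_cols], data[alff_cols], labels,
        roi_names=sc.ROI_NAMES,
    )


class TestAssemble:
    def test_block_sizes_sum_to_135(self):
        les, conn, alff = cls.feature_columns(sc.ROI_NAMES)
        assert (len(les), len(conn), len(alff)) == (15, 105, 15)
        table = make_table(np.random.default_rng(0))
        assert table.data.shape[1] == 135
        assert table.feature_group.value_counts().to_dict() == {
            "connectivity": 105, "lesion": 15, "alff": 15,
        }

    def test_alignment_is_order_independent(self, rng):
        table = make_table(rng)
        les = table.subset_block("lesion").data.sample(frac=1.0, random_state=1)
        conn = table.subset_block("connectivity").data.sample(frac=1.0, random_state=2)
        alff = table.subset_block("alff").data.sample(frac=1.0, random_state=3)
        shuffled = cls.assemble_features(les, conn, alff, table.labels,
                                         roi_names=sc.ROI_NAMES)
        pd.testing.assert_frame_equal(shuffled.data, table.data)

    def test_subject_missing_from_block_rejected(self, rng):
        table = make_table(rng)
        les = table.subset_block("lesion").data.drop(index="s03")
        with pytest.raises(ValueError, match="s03"):
            cls.assemble_features(les, table.subset_block("connectivity").data,
                                  table.subset_block("alff").data, table.labels)


class TestNestedCV:
    def test_fold_contract_one_pair_held_out(self, rng):
        table = make_table(rng, n_per_group=5)
        x, y = table.x, table.y
        gen = np.random.default_rng(0)
        pte = np.flatnonzero(y == 1)
        non = np.flatnonzero(y == 0)
        pairs = list(zip(gen.permutation(pte), gen.permutation(non)))
        seen = np.zeros(y.size, dtype=int)
        for ip, inn in pairs:
            assert y[ip] == 1 and y[inn] == 0
            seen[ip] += 1
            seen[inn] += 1
        assert (seen == 1).all()  # every subject tested exactly once

    def test_unbalanced_labels_rejected(self, rng):
        table = make_table(rng, n_per_group=5)
        bad = cls.FeatureTable(table.data.iloc[1:], table.labels.iloc[1:],
                               table.feature_group)
        with pytest.raises(ValueError, match="balanced"):
            cls.nested_cv_auc(bad, cls.fast_config(n_repeats=1))

    def test_hyperparameter_choice_ignores_test_pair(self, rng):
        """Held-out rows play no role in standardization, PCA or tuning:
        replacing them with wild values leaves the fitted fold unchanged."""
        table = make_table(rng, n_per_group=6, separation=1.0)
        x, y = table.x, table.y
        train = np.arange(2, x.shape[0])
        cfg = cls.fast_config(n_repeats=1, pca_components_grid=(3, 6))
        r1 = np.random.default_rng(7)
        r2 = np.random.default_rng(7)
        _, sel1 = cls._fit_fold(x[train], y[train], x[:2], cfg, r1)
        wild = x[:2] * 1e6 + 123.0
        scores2, sel2 = cls._fit_fold(x[train], y[train], wild, cfg, r2)
        assert sel1 == sel2
        assert np.isfinite(scores2).all()

    def test_separable_features_reach_perfect_auc(self, rng):
        table = make_table(rng, n_per_group=6, separation=12.0)
        res = cls.nested_cv_auc(table, cls.fast_config(n_repeats=3, method="ksvm"))
        assert res.mean == pytest.approx(1.0)
        assert res.auc_samples.shape == (3,)
        assert np.isfinite(res.oof_scores).all()

    def test_randomized_labels_score_at_chance(self, rng):
        """AUC on label-free noise concentrates near 0.5."""
        table = make_table(rng, n_per_group=8, separation=0.0)
        cfg = cls.fast_config(n_repeats=1, seed=0)
        null = cls.permutation_auc_null(table, cfg, n_null=40)
        assert abs(null.null_auc_samples.mean() - 0.5) <= 0.05

    def test_seeded_determinism(self, rng):
        table = make_table(rng, n_per_group=5, separation=0.8)
        cfg = cls.fast_config(n_repeats=2, seed=11)
        r1 = cls.nested_cv_auc(table, cfg)
        r2 = cls.nested_cv_auc(table, cfg)
        assert np.array_equal(r1.auc_samples, r2.auc_samples)

    @pytest.mark.parametrize("method", ["svm", "rf", "nn"])
    def test_other_methods_run(self, method, rng):
        table = make_table(rng, n_per_group=4, separation=5.0)
        cfg = cls.fast_config(n_repeats=1, method=method, seed=1)
        res = cls.nested_cv_auc(table, cfg)
        assert 0.0 <= res.mean <= 1.0


class TestPermutationNull:
    def test_null_distribution_and_ranksum(self, rng):
        table = make_table(rng, n_per_group=6, separation=8.0)
        cfg = cls.fast_config(n_repeats=3, seed=2)
        obs = cls.nested_cv_auc(table, cfg)
        null = cls.permutation_auc_null(table, cfg, n_null=15, observed=obs)
        assert null.ranksum_p < 0.01  # separable signal beats its null
        assert null.kde_grid.shape == null.kde_density.shape

    def test_small_n_null_warns(self, rng):
        table = make_table(rng, n_per_group=4)
        with pytest.warns(UserWarning, match="unstable"):
            cls.permutation_auc_null(table, cls.fast_config(n_repeats=1), n_null=3)

    def test_null_seeded_determinism(self, rng):
        table = make_table(rng, n_per_group=4)
        cfg = cls.fast_config(n_repeats=1, seed=5)
        n1 = cls.permutation_auc_null(table, cfg, n_null=5)
        n2 = cls.permutation_auc_null(table, cfg, n_null=5)
        assert np.array_equal(n1.null_auc_samples, n2.null_auc_samples)


class TestImportance:
    def test_planted_feature_dominates(self, rng):
        table = make_table(rng, n_per_group=10, separation=4.0, informative=[20])
        cfg = cls.fast_config(method="svm")
        imp, roi_imp = cls.svm_feature_importance(table, cfg)
        assert imp.shape == (135,) and roi_imp.shape == (15,)
        assert imp.idxmax() == table.data.columns[20]

    def test_tree_and_network_methods_rejected(self, rng):
        table = make_table(rng)
        with pytest.raises(ValueError):
            cls.svm_feature_importance(table, cls.fast_config(method="rf"))

    def test_roi_aggregation_matches_hand_rule(self, rng):
        """ROI importances equal the hand-computed aggregation: lesion and
        ALFF features go to their ROI, connectivity features split equally
        between their two ROIs."""
        table = make_table(rng, n_per_group=16, separation=10.0, informative=[15])
        imp, roi_imp = cls.svm_feature_importance(table, cls.fast_config(method="svm"))
        # feature 15 is the first connectivity column and dominates
        assert imp.idxmax() == "conn_L_Frontal_R_Frontal"
        iu = np.triu_indices(15, k=1)
        pairs = list(zip(*iu))
        expected = pd.Series(0.0, index=list(sc.ROI_NAMES))
        for k, name in enumerate(sc.ROI_NAMES):
            expected[name] += imp.iloc[k] + imp.iloc[120 + k]  # lesion + alff
        for j, (a, b) in enumerate(pairs):
            expected[sc.ROI_NAMES[a]] += imp.iloc[15 + j] / 2
            expected[sc.ROI_NAMES[b]] += imp.iloc[15 + j] / 2
        assert np.allclose(roi_imp.to_numpy(), expected.to_numpy())

    def test_noise_features_yield_flat_roi_profile(self):
        """Without planted signal no ROI dominates the importance profile."""
        hits = 0
        for seed in range(10):
            table = make_table(np.random.default_rng(200 + seed), n_per_group=10)
            _, roi_imp = cls.svm_feature_importance(table,
                                                    cls.fast_config(method="svm"))
            hits += roi_imp.max() <= 3.0 * np.median(roi_imp)
        assert hits >= 8


class TestLearningCurve:
    @pytest.fixture(scope="class")
    def planted_table(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from ptemark.pipeline import cohort_feature_table

            cfg = sc.strong_config(n_per_group=10, grid_shape=(32, 32, 12),
                                   n_volumes=64, seed=21)
            return cohort_feature_table(cfg)

    def test_auc_does_not_degrade_with_more_subjects(self, planted_table):
        cfg = cls.fast_config(n_repeats=2, seed=3)
        curve = cls.learning_curve(planted_table, cfg, (8, 12, 16), subset_draws=2)
        assert curve.n_values.tolist() == [8, 12, 16]
        assert curve.mean_auc[-1] >= curve.mean_auc[0] - 0.05

    def test_full_cohort_subset_matches_direct_cv(self, planted_table):
        cfg = cls.fast_config(n_repeats=3, seed=4)
        curve = cls.learning_curve(planted_table, cfg, (20,), subset_draws=1)
        direct = cls.nested_cv_auc(planted_table, cfg)
        assert abs(curve.mean_auc[0] - direct.mean) <= 0.15  # Monte-Carlo slack

    def test_too_small_subsets_skipped_with_warning(self, planted_table):
        cfg = cls.fast_config(n_repeats=1, seed=5)
        with pytest.warns(UserWarning, match="skipped"):
            curve = cls.learning_curve(planted_table, cfg, (4, 8), subset_draws=1)
        assert curve.n_values.tolist() == [8]

    def test_odd_or_oversized_subset_rejected(self, planted_table):
        cfg = cls.fast_config(n_repeats=1)
        with pytest.raises(ValueError):
            cls.learning_curve(planted_table, cfg, (7,))
        with pytest.raises(ValueError):
            cls.learning_curve(planted_table, cfg, (999,))


class TestExtrapolation:
    def test_three_points_interpolated_exactly(self):
        curve = cls.LearningCurve(
            n_values=np.array([10, 20, 30]),
            mean_auc=np.array([0.6, 0.7, 0.75]),
            sd_auc=np.zeros(3),
        )
        ext = cls.extrapolate_auc(curve, fit_last_k=3, target_n=20)
        assert ext.predicted_auc == pytest.approx(0.7, abs=1e-9)

    def test_quadratic_coefficients_recovered(self):
        n = np.arange(10, 80, 6, dtype=float)
        coeffs_true = np.array([-2e-5, 0.004, 0.5])
        curve = cls.LearningCurve(
            n_values=n, mean_auc=np.polyval(coeffs_true, n), sd_auc=np.zeros(n.size)
        )
        ext = cls.extrapolate_auc(curve, fit_last_k=6, target_n=100)
        assert np.abs(ext.coefficients - coeffs_true).max() < 1e-9
        assert ext.predicted_auc == pytest.approx(np.polyval(coeffs_true, 100),
                                                  abs=1e-9)

    def test_out_of_range_prediction_clipped_with_warning(self):
        curve = cls.LearningCurve(
            n_values=np.array([10.0, 20, 30]),
            mean_auc=np.array([0.5, 0.7, 1.0]),
            sd_auc=np.zeros(3),
        )
        with pytest.warns(UserWarning, match="clipped"):
            ext = cls.extrapolate_auc(curve, fit_last_k=3, target_n=60)
        assert ext.predicted_auc == 1.0

    def test_insufficient_points_rejected(self):
        curve = cls.LearningCurve(
            n_values=np.array([10.0, 20]),
            mean_auc=np.array([0.5, 0.6]),
            sd_auc=np.zeros(2),
        )
        with pytest.raises(ValueError):
            cls.extrapolate_auc(curve, fit_last_k=3, target_n=50)
        curve3 = cls.LearningCurve(
            n_values=np.array([10.0, 20, 30]),
            mean_auc=np.array([0.5, 0.6, 0.65]),
            sd_auc=np.zeros(3),
        )
        with pytest.raises(ValueError):
            cls.extrapolate_auc(curve3, fit_last_k=4, target_n=50)
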