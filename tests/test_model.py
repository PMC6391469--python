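"""Model evaluation protocol: metrics, forests, cross-validation, sweeps."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from knockin import model as mdl
from knockin.dataset import labels_array
from knockin.model import (
    HdrEfficiencyModel,
    confusion_accuracy,
    cross_validate,
    distance_regression,
    improvement_statistic,
    make_folds,
    region_sweep_run,
    roc_auc,
    run_model_family,
    train_forest,
)


class TestRocAuc:
    def test_perfect_and_inverted(self):
        labels = np.array([0, 0, 1, 1])
        assert roc_auc([0.1, 0.2, 0.8, 0.9], labels) == 1.0
        assert roc_auc([0.9, 0.8, 0.2, 0.1], labels) == 0.0

    def test_random_scores_near_half(self, rng):
        labels = rng.integers(0, 2, size=1000)
        while len(np.unique(labels)) < 2:
            labels = rng.integers(0, 2, size=1000)
        scores = rng.random(1000)
        assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.05)

    def test_equals_mann_whitney(self, rng):
        labels = rng.integers(0, 2, size=60)
        labels[:5], labels[-5:] = 0, 1
        scores = rng.random(60)
        u = sps.mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
        expected = u / ((labels == 1).sum() * (labels == 0).sum())
        assert roc_auc(scores, labels) == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestConfusion:
    def test_holdout_style_matrix(self):
        # 6 actual-low (4 predicted low), 9 actual-high (7 predicted high)
        truth = np.array([0] * 6 + [1] * 9)
        pred = np.array([0] * 4 + [1] * 2 + [0] * 2 + [1] * 7)
        matrix, acc = confusion_accuracy(pred, truth)
        np.testing.assert_array_equal(matrix, [[4, 2], [2, 7]])
        assert acc == pytest.approx(11 / 15)
        assert round(acc, 3) == 0.733

    def test_all_correct(self):
        _, acc = confusion_accuracy([0, 1, 1], [0, 1, 1])
        assert acc == 1.0

    def test_matches_tally_oracle(self, rng):
        truth = rng.integers(0, 2, size=100)
        pred = rng.integers(0, 2, size=100)
        matrix, acc = confusion_accuracy(pred, truth)
        for a in (0, 1):
            for p in (0, 1):
                assert matrix[a, p] == np.sum((truth == a) & (pred == p))
        assert acc == pytest.approx(np.mean(truth == pred))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_accuracy([0, 1], [0, 1, 1])


class TestImprovement:
    def test_quoted_means_give_83_percent(self):
        # selected targets average 0.528 against an overall mean of 0.288
        effs = np.array([0.528, 0.528, 0.048, 0.048])  # mean 0.288
        mask = np.array([True, True, False, False])
        assert improvement_statistic(effs, mask) == pytest.approx(
            100 * (0.528 - 0.288) / 0.288
        )
        assert round(improvement_statistic(effs, mask)) == 83

    def test_select_all_is_zero(self, rng):
        effs = rng.random(20)
        assert improvement_statistic(effs, np.ones(20, bool)) == pytest.approx(0.0)

    def test_two_sample_toy(self):
        assert improvement_statistic([0.2, 0.6], [False, True]) == pytest.approx(50.0)

    def test_top_m_selection_never_negative(self, rng):
        effs = rng.random(30)
        for m in (1, 5, 15, 30):
            mask = np.zeros(30, bool)
            mask[np.argsort(effs)[-m:]] = True
            assert improvement_statistic(effs, mask) >= 0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            improvement_statistic([0.2, 0.4], [False, False])


class TestDistanceRegression:
    def _samples(self, d, eff):
        from knockin.dataset import Sample

        return [
            Sample(f"T{i}", "A" * 20, "ACGTA", int(di), 100, int(round(e * 100)), 0)
            for i, (di, e) in enumerate(zip(d, eff))
        ]

    def test_collinear_r2_one(self):
        s = self._samples([1, 2, 3, 4], [0.8, 0.6, 0.4, 0.2])
        slope, intercept, r2 = distance_regression(s)
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(-0.2)

    def test_constant_efficiency_r2_zero(self):
        s = self._samples([1, 2, 3, 4], [0.3, 0.3, 0.3, 0.3])
        _, _, r2 = distance_regression(s)
        assert r2 == pytest.approx(0.0)

    def test_matches_closed_form_ols(self, rng):
        d = rng.integers(-15, 15, size=25)
        eff = rng.integers(0, 101, size=25) / 100  # exact on the n_mice=100 grid
        s = self._samples(d, eff)
        slope, intercept, r2 = distance_regression(s)
        x = np.abs(d).astype(float)
        X = np.column_stack([np.ones(25), x])
        beta = np.linalg.lstsq(X, eff, rcond=None)[0]
        resid = eff - X @ beta
        r2_oracle = 1 - resid @ resid / np.sum((eff - eff.mean()) ** 2)
        assert slope == pytest.approx(beta[1])
        assert intercept == pytest.approx(beta[0])
        assert r2 == pytest.approx(r2_oracle)

    def test_zero_variance_distance_rejected(self):
        with pytest.raises(ValueError):
            distance_regression(self._samples([3, 3, 3], [0.1, 0.5, 0.9]))


def _planted_xy(rng, n=60, p=8, separation=4.0):
    """Linearly separable composition-style features."""
    y = np.tile([0, 1], n // 2)
    X = rng.normal(size=(n, p))
    X[:, 0] += separation * y
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(p)]), y


class TestForest:
    def test_planted_signal_low_oob(self, rng):
        X, y = _planted_xy(rng)
        fitted = train_forest(X, y, n_trees=200, seed=0)
        assert fitted.oob_error < 0.1
        assert fitted.feature_importances.idxmax() == "f0"
        assert fitted.feature_importances.sum() == pytest.approx(1.0)

    def test_permuted_labels_near_chance(self):
        oobs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = pd.DataFrame(r.normal(size=(60, 8)))
            y = np.tile([0, 1], 30)
            oobs.append(train_forest(X, r.permutation(y), n_trees=100, seed=seed).oob_error)
        assert np.mean(oobs) == pytest.approx(0.5, abs=0.1)

    def test_deterministic_under_seed(self, rng):
        X, y = _planted_xy(rng)
        a = train_forest(X, y, n_trees=50, seed=3)
        b = train_forest(X, y, n_trees=50, seed=3)
        assert a.oob_error == b.oob_error
        pd.testing.assert_series_equal(a.feature_importances, b.feature_importances)

    def test_oob_stable_when_doubling_trees(self, rng):
        X, y = _planted_xy(rng, n=80, separation=1.5)
        a = train_forest(X, y, n_trees=400, seed=0).oob_error
        b = train_forest(X, y, n_trees=800, seed=0).oob_error
        assert abs(a - b) < 0.05

    def test_single_class_rejected(self, rng):
        X, _ = _planted_xy(rng)
        with pytest.raises(ValueError):
            train_forest(X, np.zeros(len(X)), n_trees=10, seed=0)


class TestCrossValidate:
    def test_folds_disjoint_exhaustive_stratified(self, rng):
        y = np.array([0] * 18 + [1] * 12)
        folds = make_folds(y, k=5, seed=0)
        all_test = np.concatenate([te for _, te in folds])
        assert sorted(all_test) == list(range(30))
        global_ratio = y.mean()
        for _, te in folds:
            # class ratio within one sample of the global ratio
            assert abs(y[te].sum() - global_ratio * len(te)) <= 1

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="stratify"):
            make_folds(np.array([0] * 20 + [1] * 3), k=5)

    def test_planted_signal_high_auc_and_correct_counts(self, rng):
        X, y = _planted_xy(rng, n=100)
        report = cross_validate(X, y, k=5, seed=0, n_trees=150)
        assert report.roc_auc > 0.9
        assert report.correct <= report.n == 100
        assert sum(f.n_test for f in report.per_fold) == 100
        assert report.correct == sum(f.correct for f in report.per_fold)


class TestModelFamilyAndSweep:
    def test_family_dimensions_and_paired_folds(self, labelled_samples):
        reports = run_model_family(
            labelled_samples, ["G1", "G2", "G3", "G4"], n_trees=60, seed=0
        )
        assert [r.n_features for r in reports] == [20, 25, 29, 33]
        n = reports[0].n
        assert all(r.n == n for r in reports)

    def test_single_scheme_single_row(self, labelled_samples):
        reports = run_model_family(labelled_samples, ["M1"], n_trees=60, seed=0)
        assert len(reports) == 1 and reports[0].scheme == "M1"
        frame = mdl.reports_to_frame(reports)
        assert list(frame.index) == ["M1"]

    def test_sweep_point_count_and_k_range(self, labelled_samples):
        sweep = region_sweep_run(
            labelled_samples, "3prime", k_min=5, k_max=25, step=5, n_trees=40, seed=0
        )
        assert len(sweep.points) == 5
        assert list(sweep.ks) == [5, 10, 15, 20, 25]
        assert all(0 <= e <= 1 for e in sweep.oob_errors)

    def test_sweep_k_exceeding_arm_rejected(self, labelled_samples):
        with pytest.raises(ValueError, match="exceeds"):
            region_sweep_run(labelled_samples, "3prime", k_min=5, k_max=10_000, n_trees=10)


class TestFacade:
    def test_fit_summary_and_manifest(self, labelled_samples):
        res = HdrEfficiencyModel.from_samples(
            labelled_samples, "M1", n_trees=80, seed=1
        ).fit()
        text = res.summary()
        assert "M1" in text and "OOB error" in text
        manifest = res.manifest()
        assert manifest["scheme"] == "M1" and len(manifest["feature_names"]) == 40
        assert 0 <= res.oob_error <= 1 and 0 <= res.oob_error_per_tree <= 1

    def test_save_load_refuses_scheme_mismatch(self, labelled_samples, tmp_path):
        res = HdrEfficiencyModel.from_samples(
            labelled_samples, "G1", n_trees=40, seed=1
        ).fit()
        path = tmp_path / "model.joblib"
        mdl.save_model(res, path)
        loaded = mdl.load_model(path, expect_scheme="G1")
        assert loaded.oob_error == res.oob_error
        with pytest.raises(ValueError, match="scheme"):
            mdl.load_model(path, expect_scheme="M1")

    def test_roc_points_monotone(self, labelled_samples):
        res = HdrEfficiencyModel.from_samples(
            labelled_samples, "M1", n_trees=60, seed=2
        ).fit()
        X = mdl.build_feature_matrix(labelled_samples, "M1")
        y = labels_array(labelled_samples)
        roc = res.roc_points(X, y)
        assert (roc["fpr"].diff().dropna() >= 0).all()
        assert (roc["tpr"].diff().dropna() >= 0).all()
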