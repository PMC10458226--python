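import numpy as np
import pytest

from specfuse.axes import SpectralAxis, AxisKind
from specfuse.preprocess import Modality
from specfuse.fuse import SpectralDataset, fuse_early
from specfuse.classify import (
    PipelineConfig, CVResult, FoldPipeline,
    train_enet_classifier, train_svm_benchmark, repeated_cv,
    summarize, summarize_many,
)
from conftest import make_multinomial_problem


def small_dataset(n_per_class=20, p=30, K=3, seed=0, informative=6):
    gen = np.random.default_rng(seed)
    y = np.repeat([f"c{i}" for i in range(K)], n_per_class)
    codes = np.repeat(np.arange(K), n_per_class)
    X = gen.normal(size=(len(y), p))
    shifts = gen.normal(scale=2.5, size=(K, informative))
    X[:, :informative] += shifts[codes]
    axis = SpectralAxis(AxisKind.wavelength_nm, np.linspace(400, 600, p))
    return SpectralDataset(X, y.astype(object), Modality.libs, axis)


FAST = PipelineConfig(anova_keep=20, alpha_grid=(0.5,), n_lambdas=8,
                      tuning="fixed", fixed_lambda_ratio=0.1)


class TestEnetClassifier:
    def test_separated_classes_reach_perfect_training_accuracy(self):
        gen = np.random.default_rng(0)
        X = np.vstack([gen.normal(0, 0.1, size=(20, 2)),
                       gen.normal(5, 0.1, size=(20, 2))])
        y = np.array(["a"] * 20 + ["b"] * 20)
        clf = train_enet_classifier(X, y, alpha=0.5, lam=1e-3)
        assert np.mean(clf.predict(X) == y) == 1.0

    def test_probabilities_sum_to_one(self):
        X, y = make_multinomial_problem(seed=2)
        clf = train_enet_classifier(X, y, 0.5, 0.01)
        proba = clf.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_relabeling_classes_permutes_predictions_consistently(self):
        X, y = make_multinomial_problem(seed=3)
        clf = train_enet_classifier(X, y.astype(str), 0.5, 0.01)
        renamed = np.array([{"0": "z", "1": "m", "2": "a"}[v] for v in y.astype(str)])
        clf2 = train_enet_classifier(X, renamed, 0.5, 0.01)
        back = np.array([{"z": "0", "m": "1", "a": "2"}[v] for v in clf2.predict(X)])
        assert np.array_equal(back, clf.predict(X))

    def test_empty_feature_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_enet_classifier(np.empty((10, 0)), np.repeat([0, 1], 5), 0.5, 0.1)


class TestSVMBenchmark:
    def test_hand_solvable_margin_problem(self):
        # two points per class at distance 2 along x: margin plane x=0
        X = np.array([[-2.0, 0.0], [-1.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        y = np.array(["neg", "neg", "pos", "pos"])
        clf = train_svm_benchmark(X, y, C=10.0)
        assert np.array_equal(clf.predict(X), y)
        assert set(clf.support_) == {1, 2}  # the two inner points

    def test_duplicated_training_set_gives_same_decisions(self, rng):
        # separable data with a binding margin: duplication cannot move it
        X = np.array([[-2.0, 0.5], [-1.0, -0.5], [1.0, 0.3], [2.0, -0.1]])
        y = np.array(["neg", "neg", "pos", "pos"])
        a = train_svm_benchmark(X, y, C=100.0)
        b = train_svm_benchmark(np.vstack([X, X]), np.concatenate([y, y]), C=100.0)
        grid = rng.normal(scale=2.0, size=(50, 2))
        assert np.array_equal(a.predict(grid), b.predict(grid))

    def test_heavy_regularization_gives_majority_class(self):
        gen = np.random.default_rng(5)
        X = gen.normal(size=(30, 3))
        y = np.array([0] * 25 + [1] * 5)
        clf = train_svm_benchmark(X, y, C=1e-6)
        assert np.all(clf.predict(gen.normal(size=(20, 3))) == 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            train_svm_benchmark(np.ones((5, 2)), np.zeros(5))


class TestRepeatedCV:
    def test_deterministic_given_seeds(self):
        ds = small_dataset()
        a = repeated_cv(ds, FAST, k=5, sessions=2, seeds=[1, 2])
        b = repeated_cv(ds, FAST, k=5, sessions=2, seeds=[1, 2])
        assert a.mean_accuracy == b.mean_accuracy
        for ca, cb in zip(a.confusions, b.confusions):
            np.testing.assert_array_equal(ca, cb)

    def test_single_class_rejected(self):
        ds = small_dataset(K=1)
        with pytest.raises(ValueError, match="2 classes"):
            repeated_cv(ds, FAST, k=5, sessions=1, seeds=[1])

    def test_class_smaller_than_k_is_named(self):
        ds = small_dataset(n_per_class=4)
        with pytest.raises(ValueError, match="c0"):
            repeated_cv(ds, FAST, k=5, sessions=1, seeds=[1])

    def test_duplicate_seeds_warn(self):
        ds = small_dataset()
        with pytest.warns(UserWarning, match="duplicate"):
            repeated_cv(ds, FAST, k=5, sessions=2, seeds=[1, 1])

    def test_confusion_rows_sum_to_class_counts(self):
        ds = small_dataset()
        res = repeated_cv(ds, FAST, k=5, sessions=1, seeds=[3])
        assert res.confusions[0].sum() == ds.n_samples
        np.testing.assert_array_equal(res.confusions[0].sum(axis=1), 20)

    def test_svm_pipeline_runs(self):
        ds = small_dataset()
        cfg = PipelineConfig(anova_keep=20, tuning="fixed", classifier="svm",
                             svm_C_grid=(1.0,))
        res = repeated_cv(ds, cfg, k=5, sessions=1, seeds=[1])
        assert 0.5 < res.mean_accuracy <= 1.0

    def test_training_accuracy_dominates_cv_accuracy(self):
        ds = small_dataset(seed=6)
        res = repeated_cv(ds, FAST, k=5, sessions=1, seeds=[1])
        pipe = FoldPipeline(FAST, axis=ds.axis).fit(ds.matrix, ds.labels, seed=1)
        train_acc = np.mean(pipe.predict(ds.matrix) == ds.labels)
        assert train_acc >= res.mean_accuracy - 1e-9


class TestNoLeakage:
    def test_fold_fit_depends_only_on_training_rows(self):
        ds = small_dataset()
        X, y = ds.matrix, ds.labels
        tr = np.arange(0, 50)
        pipe1 = FoldPipeline(FAST, axis=ds.axis).fit(X[tr], y[tr], seed=9)
        pipe2 = FoldPipeline(FAST, axis=ds.axis).fit(X[tr], y[tr], seed=9)
        np.testing.assert_array_equal(pipe1.selected_columns, pipe2.selected_columns)
        cols_before = pipe1.selected_columns.copy()
        pipe1.predict(X[50:])
        np.testing.assert_array_equal(pipe1.selected_columns, cols_before)

    def test_hook_sees_identical_masks_regardless_of_test_labels(self):
        ds = small_dataset()
        seen = []
        repeated_cv(ds, FAST, k=5, sessions=1, seeds=[4],
                    fold_hook=lambda s, f, p: seen.append(p.selected_columns.copy()))
        shuffled = SpectralDataset(ds.matrix, ds.labels, ds.modality, ds.axis)
        seen2 = []
        repeated_cv(shuffled, FAST, k=5, sessions=1, seeds=[4],
                    fold_hook=lambda s, f, p: seen2.append(p.selected_columns.copy()))
        for a, b in zip(seen, seen2):
            np.testing.assert_array_equal(a, b)


class TestLateFusionPipeline:
    def test_late_strategy_selects_within_each_block(self):
        gen = np.random.default_rng(7)
        y = np.repeat(["a", "b", "c"], 20).astype(object)
        codes = np.repeat(np.arange(3), 20)
        libs_m = gen.normal(size=(60, 40))
        libs_m[:, :3] += 3.0 * codes[:, None]
        raman_m = gen.normal(size=(60, 25))
        raman_m[:, :3] += 3.0 * codes[:, None]
        libs = SpectralDataset(libs_m, y, Modality.libs,
                               SpectralAxis(AxisKind.wavelength_nm, np.linspace(350, 625, 40)))
        raman = SpectralDataset(raman_m, y, Modality.raman,
                                SpectralAxis(AxisKind.raman_shift_cm1, np.linspace(750, 2800, 25)))
        hyb = fuse_early(libs, raman)
        cfg = PipelineConfig(anova_keep=10, strategy="late", tuning="fixed",
                             fixed_lambda_ratio=0.05)
        pipe = FoldPipeline(cfg, axis=hyb.axis).fit(hyb.matrix, y, seed=0)
        origins = hyb.axis.origins[pipe.selected_columns]
        assert "libs" in origins and "raman" in origins
        acc = np.mean(pipe.predict(hyb.matrix) == y)
        assert acc > 0.9


class TestSummaries:
    def _result(self, per_class):
        per_class = np.asarray(per_class, dtype=float)
        S, K = per_class.shape
        macro = per_class.mean(axis=1)
        return CVResult(
            confusions=[np.eye(K, dtype=int) * 10 for _ in range(S)],
            per_class_accuracy=per_class,
            mean_accuracy=float(macro.mean()),
            sd_accuracy=float(np.std(macro, ddof=1)) if S > 1 else 0.0,
            micro_mean=float(macro.mean()), micro_sd=0.0,
            seeds=list(range(S)), classes=np.arange(K), settings={},
        )

    def test_two_session_hand_arithmetic(self):
        res = self._result([[0.8, 0.8], [0.9, 0.9]])
        table = summarize(res)
        assert table["macro_pct"].iloc[0] == "85.00 (7.07)"

    def test_all_correct_prints_100(self):
        res = self._result([[1.0, 1.0, 1.0]])
        assert summarize(res)["macro_pct"].iloc[0] == "100.00 (0.00)"

    def test_empty_result_rejected(self):
        res = self._result([[1.0]])
        res.confusions.clear()
        with pytest.raises(ValueError, match="empty"):
            summarize(res)

    def test_summary_table_over_settings(self):
        res = self._result([[0.5, 0.7]])
        table = summarize_many({"raman": res, "libs": res})
        assert list(table.index) == ["raman", "libs"]
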