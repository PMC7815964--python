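"""Experiment harness: partitioning, CV tuning, holdout evaluation, ranking,
persistence, and the determinism / no-leakage contracts."""

import numpy as np
import pytest

from bioautoml.errors import BioAutoMLError, IntegrityError
from bioautoml.metrics import MetricSet
from bioautoml.modeling import (
    AlgorithmSpec,
    CVPlan,
    ExperimentConfig,
    ModelResult,
    MulsetConfig,
    PartitionSpec,
    derive_seed,
    evaluate_holdout,
    load_model,
    make_folds,
    partition,
    rank_models,
    results_table,
    run_experiment,
    save_model,
    tune_and_train,
)
from bioautoml.synth import SynthSpec, make_classification_data

from conftest import make_dataset

FAST_CV = CVPlan(n_folds=5, n_repeats=1, seed=0)


def synth(n=80, p=5, effect=2.5, seed=0, balance=0.5):
    ds, _ = make_classification_data(
        SynthSpec(n_samples=n, n_features=p, n_informative=min(3, p),
                  effect_size=effect, class_balance=balance, seed=seed)
    )
    return ds


class TestPartition:
    def test_balanced_counts(self):
        ds = synth(n=80, seed=1)
        train, test = partition(ds, PartitionSpec(0.75, seed=0))
        assert train.n_samples == 60 and test.n_samples == 20
        assert train.y().sum() == 30 and test.y().sum() == 10

    def test_deterministic_given_seed(self):
        ds = synth(n=60, seed=2)
        t1, h1 = partition(ds, PartitionSpec(0.75, seed=5))
        t2, h2 = partition(ds, PartitionSpec(0.75, seed=5))
        assert t1.sample_ids == t2.sample_ids and h1.sample_ids == h2.sample_ids

    def test_different_seed_different_split(self):
        ds = synth(n=60, seed=2)
        t1, _ = partition(ds, PartitionSpec(0.75, seed=5))
        t2, _ = partition(ds, PartitionSpec(0.75, seed=6))
        assert t1.sample_ids != t2.sample_ids

    def test_unbalanced_archetype_counts(self):
        # 374 positives + 50 negatives at fraction 0.75
        ds, _ = make_classification_data(
            SynthSpec(n_samples=424, n_features=5, n_informative=2,
                      class_balance=374 / 424, seed=3,
                      positive_class="tumor", negative_class="normal")
        )
        train, test = partition(ds, PartitionSpec(0.75, seed=0))
        assert abs(train.y().sum() - round(374 * 0.75)) <= 1
        assert abs((train.n_samples - train.y().sum()) - round(50 * 0.75)) <= 1
        assert test.y().sum() > 0 and test.y().sum() < test.n_samples

    def test_union_is_all_disjoint(self):
        ds = synth(n=50, seed=4)
        train, test = partition(ds, PartitionSpec(0.6, seed=1))
        assert sorted(train.sample_ids + test.sample_ids) == sorted(ds.sample_ids)
        assert not set(train.sample_ids) & set(test.sample_ids)

    def test_tiny_class_rejected(self):
        ds = make_dataset(np.random.default_rng(0).normal(size=(5, 2)),
                          ["case"] * 4 + ["control"])
        with pytest.raises(BioAutoMLError, match="at least 2"):
            partition(ds, PartitionSpec(0.75, seed=0))


class TestFolds:
    def test_stratification_within_one_sample(self):
        ds = synth(n=100, seed=5, balance=0.3)
        folds = make_folds(ds, CVPlan(n_folds=10, n_repeats=1, seed=0))
        y = ds.y()
        overall = y.mean()
        for _, va in folds:
            fold_pos = y[va].sum()
            expected = overall * len(va)
            assert abs(fold_pos - expected) <= 1

    def test_fold_count_reduced_for_tiny_minority(self):
        ds = synth(n=30, seed=6, balance=0.2)  # 6 positives < 10 folds
        folds = make_folds(ds, CVPlan(n_folds=10, n_repeats=1, seed=0))
        assert len(folds) == 6


class TestTuneAndTrain:
    def test_separable_data_high_auroc(self, separable_dataset):
        handle, cv_mean, _, _, _ = tune_and_train(
            separable_dataset, AlgorithmSpec("sda"), FAST_CV, seed=0
        )
        assert cv_mean.auroc >= 0.99

    def test_single_grid_point_selected(self):
        ds = synth(seed=7)
        spec = AlgorithmSpec("knn", hyperparameter_grid={"n_neighbors": [7]})
        _, _, _, _, best = tune_and_train(ds, spec, FAST_CV, seed=0)
        assert best == {"n_neighbors": 7}

    def test_permuted_labels_near_chance(self):
        """Null simulation: mean cv AUROC over seeds stays in the chance band."""
        aucs = []
        for seed in range(8):
            ds, _ = make_classification_data(
                SynthSpec(n_samples=100, n_features=5, n_informative=0,
                          effect_size=0.0, seed=seed)
            )
            _, cv_mean, _, _, _ = tune_and_train(
                ds, AlgorithmSpec("sda", hyperparameter_grid={"shrinkage": ["auto"]}),
                FAST_CV, seed=seed,
            )
            aucs.append(cv_mean.auroc)
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_bad_metric_rejected(self):
        with pytest.raises(BioAutoMLError):
            tune_and_train(synth(), AlgorithmSpec("sda", selection_metric="nope"),
                           FAST_CV, seed=0)


class TestEvaluateHoldout:
    def test_perfect_model_on_separable_test(self, separable_dataset):
        train, test = partition(separable_dataset, PartitionSpec(0.75, seed=0))
        handle, _, _, _, _ = tune_and_train(train, AlgorithmSpec("sda"), FAST_CV, seed=0)
        ms = evaluate_holdout(handle, test)
        assert ms.auroc == 1.0
        assert ms.accuracy >= 0.95  # threshold calibration, not ranking, limits this
        assert ms.logloss < 0.3

    def test_holdout_close_to_cv_on_signal(self):
        gaps = []
        for seed in range(5):
            ds = synth(n=120, effect=1.8, seed=seed)
            train, test = partition(ds, PartitionSpec(0.75, seed=seed))
            _, cv_mean, _, _, _ = tune_and_train(
                train, AlgorithmSpec("sda"), FAST_CV, seed=seed
            )
            handle, _, _, _, _ = tune_and_train(
                train, AlgorithmSpec("sda"), FAST_CV, seed=seed
            )
            gaps.append(evaluate_holdout(handle, test).auroc - cv_mean.auroc)
        assert abs(np.mean(gaps)) < 0.1


class TestRunExperiment:
    def test_counts_resamples_times_algorithms(self):
        ds = synth(n=60, seed=8)
        res = run_experiment(ds, ExperimentConfig(
            algorithms=["sda", "naiveBayes"], cv=FAST_CV, seed=1))
        assert len(res) == 2

    def test_mulset_iterates_blocks(self, two_block_dataset):
        # blocks are too small to model; enlarge the toy pattern
        rng = np.random.default_rng(9)
        n = 40
        X = rng.normal(size=(n, 3))
        X[: n // 2, 2] = np.nan   # first half misses f3
        X[n // 2 :, 0] = np.nan   # second half misses f1
        ds = make_dataset(X, ["case", "control"] * (n // 2))
        cfg = ExperimentConfig(
            algorithms=["naiveBayes"], cv=CVPlan(3, 1, seed=0),
            mulset=MulsetConfig(enabled=True, min_samples=10, min_features=1),
            seed=2,
        )
        res = run_experiment(ds, cfg)
        assert len(res) == 3  # {f1,f2}, {f2,f3}, {f2}

    def test_serial_parallel_identical(self):
        ds = synth(n=60, seed=10)
        cfg_serial = ExperimentConfig(algorithms=["sda", "rf"], cv=FAST_CV,
                                      seed=3, n_jobs=1)
        cfg_par = ExperimentConfig(algorithms=["sda", "rf"], cv=FAST_CV,
                                   seed=3, n_jobs=2)
        t1 = results_table(run_experiment(ds, cfg_serial))
        t2 = results_table(run_experiment(ds, cfg_par))
        assert t1.equals(t2)

    def test_rerun_bitwise_identical(self):
        ds = synth(n=60, seed=11)
        cfg = ExperimentConfig(algorithms=["gbm"], cv=FAST_CV, seed=4)
        t1 = results_table(run_experiment(ds, cfg))
        t2 = results_table(run_experiment(ds, cfg))
        assert t1.equals(t2)

    def test_adding_algorithm_does_not_perturb_others(self):
        ds = synth(n=60, seed=12)
        t_small = results_table(run_experiment(
            ds, ExperimentConfig(algorithms=["sda"], cv=FAST_CV, seed=5)))
        t_big = results_table(run_experiment(
            ds, ExperimentConfig(algorithms=["sda", "knn"], cv=FAST_CV, seed=5)))
        sda_small = t_small[t_small.algorithm == "sda"].reset_index(drop=True)
        sda_big = t_big[t_big.algorithm == "sda"].reset_index(drop=True)
        assert sda_small.equals(sda_big)


class TestNoLeakage:
    def test_holdout_modification_leaves_cv_untouched(self):
        """Permuting or replacing holdout rows must not change cv metrics or
        the chosen hyperparameters (they are computed before the holdout is
        ever read)."""
        ds = synth(n=80, seed=13)
        train, test = partition(ds, PartitionSpec(0.75, seed=0))
        spec = AlgorithmSpec("sda")
        _, cv1, _, _, best1 = tune_and_train(train, spec, FAST_CV, seed=9)
        # scramble the holdout completely; train again from the same split
        rng = np.random.default_rng(0)
        scrambled = test.with_values(
            test.values.copy().apply(lambda c: rng.permutation(c.to_numpy()))
        )
        _, cv2, _, _, best2 = tune_and_train(train, spec, FAST_CV, seed=9)
        assert best1 == best2
        assert cv1.as_dict() == cv2.as_dict()
        # and the scrambled holdout still scores without error
        handle, _, _, _, _ = tune_and_train(train, spec, FAST_CV, seed=9)
        assert evaluate_holdout(handle, scrambled).auroc is not None


class TestRankModels:
    def _result(self, alg, cv_auroc, holdout_auroc=None, cv_prauc=None,
                holdout_prauc=None):
        return ModelResult(
            algorithm_id=alg, resample_id="r1",
            cv_metrics=MetricSet(auroc=cv_auroc, prauc=cv_prauc),
            cv_dispersion=MetricSet(), cv_fold_metrics=[],
            holdout_metrics=MetricSet(auroc=holdout_auroc, prauc=holdout_prauc),
            best_hyperparameters={}, model_handle=None,
        )

    def test_descending_order(self):
        rs = [self._result(a, v) for a, v in
              (("a", 0.8), ("b", 0.9), ("c", 0.7))]
        ranked = rank_models(rs, "auroc", "cv")
        assert [r.cv_metrics.auroc for r in ranked] == [0.9, 0.8, 0.7]

    def test_tie_broken_by_other_split(self):
        r1 = self._result("a", 0.8, cv_prauc=0.8, holdout_prauc=0.60)
        r2 = self._result("b", 0.8, cv_prauc=0.8, holdout_prauc=0.73)
        ranked = rank_models([r1, r2], "prauc", "cv")
        assert ranked[0].algorithm_id == "b"

    def test_undefined_sorts_last(self):
        rs = [self._result("a", None), self._result("b", 0.6)]
        assert rank_models(rs, "auroc", "cv")[0].algorithm_id == "b"

    def test_prauc_vs_auroc_orders_can_differ_but_reproduce(self):
        r1 = self._result("a", 0.95, cv_prauc=0.40)
        r2 = self._result("b", 0.90, cv_prauc=0.70)
        by_auroc = [r.algorithm_id for r in rank_models([r1, r2], "auroc", "cv")]
        by_prauc = [r.algorithm_id for r in rank_models([r1, r2], "prauc", "cv")]
        assert by_auroc == ["a", "b"] and by_prauc == ["b", "a"]
        assert by_prauc == [r.algorithm_id for r in rank_models([r1, r2], "prauc", "cv")]


class TestPersistence:
    def test_roundtrip_and_fingerprint(self, tmp_path, separable_dataset):
        train, test = partition(separable_dataset, PartitionSpec(0.75, seed=0))
        handle, cv_mean, cv_sd, folds, best = tune_and_train(
            train, AlgorithmSpec("rf"), FAST_CV, seed=0
        )
        result = ModelResult(
            algorithm_id="rf", resample_id="r", cv_metrics=cv_mean,
            cv_dispersion=cv_sd, cv_fold_metrics=folds,
            holdout_metrics=evaluate_holdout(handle, test),
            best_hyperparameters=best, model_handle=handle,
        )
        p = tmp_path / "m.model"
        save_model(result, p, fingerprint=test.select(sample_ids=test.sample_ids[:10]))
        loaded = load_model(p)
        assert loaded.best_hyperparameters == best
        assert loaded.cv_metrics.as_dict() == cv_mean.as_dict()
        got = loaded.model_handle.predict_scores(test)
        want = handle.predict_scores(test)
        assert np.allclose(got, want, atol=1e-12)

    def test_corrupted_file_raises_integrity_error(self, tmp_path):
        p = tmp_path / "bad.model"
        p.write_bytes(b"this is not a model")
        with pytest.raises(IntegrityError):
            load_model(p)

    def test_wrong_format_rejected(self, tmp_path):
        import pickle

        p = tmp_path / "other.model"
        with open(p, "wb") as fh:
            pickle.dump({"format": "something-else"}, fh)
        with pytest.raises(IntegrityError, match="not a"):
            load_model(p)


class TestSeeds:
    def test_derive_seed_stable_and_bounded(self):
        assert derive_seed("a", 1) == derive_seed("a", 1)
        assert derive_seed("a", 1) != derive_seed("a", 2)
        for i in range(100):
            assert 0 <= derive_seed("x", i) < 2**31
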