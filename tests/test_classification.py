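"""Fold schemes, nested tuning, posterior aggregation and CV metrics."""

import numpy as np
import pytest

from prograsp.classification import (
    ModelSpec,
    aggregate_subject,
    evaluate_subject_level,
    predict_posteriors,
    record_wise_folds,
    record_wise_intention_folds,
    run_cv,
    subject_wise_folds,
    tune_and_train,
)
from prograsp.synthetic import GeneratorConfig, generate_dataset

from conftest import make_toy_features


class TestRecordWiseFolds:
    @pytest.mark.parametrize("k,per_fold", [(4, 4), (8, 2), (16, 1)])
    def test_equal_per_subject_allocation(self, small_dataset, rng, k, per_fold):
        folds = record_wise_folds(small_dataset, k, rng)
        frame = small_dataset.frame.assign(fold=folds.fold_index)
        counts = frame.groupby(["subject", "fold"]).size()
        assert (counts == per_fold).all()

    def test_folds_partition_records(self, small_dataset, rng):
        folds = record_wise_folds(small_dataset, 4, rng)
        assert np.bincount(folds.fold_index).tolist() == [small_dataset.n_records // 4] * 4

    def test_non_dividing_k_rejected(self, small_dataset, rng):
        with pytest.raises(ValueError, match="divide"):
            record_wise_folds(small_dataset, 3, rng)


class TestIntentionFolds:
    def test_one_record_per_subject_intention_cell(self, small_dataset, rng):
        from prograsp.experiments import equate_pass_trials

        balanced = equate_pass_trials(small_dataset, rng)
        folds = record_wise_intention_folds(balanced, 4, rng)
        frame = balanced.frame.assign(fold=folds.fold_index)
        cell = frame.groupby(["subject", "intention", "fold"]).size()
        assert (cell == 1).all()

    def test_two_subject_toy_assignment(self, rng):
        ds = make_toy_features(n_per_group=1, records_per_subject=6, seed=5)
        frame = ds.frame.copy()
        frame["intention"] = np.tile(["place", "pour", "pass"], 4)
        from prograsp.dataset import FeatureDataset

        ds = FeatureDataset(frame)
        folds = record_wise_intention_folds(ds, 2, rng)
        assert np.bincount(folds.fold_index).tolist() == [6, 6]
        cell = ds.frame.assign(fold=folds.fold_index).groupby(
            ["subject", "intention", "fold"]
        ).size()
        assert (cell == 1).all()


class TestSubjectWiseFolds:
    def test_loso_default(self, small_dataset):
        folds = subject_wise_folds(small_dataset)
        assert folds.k == 8
        frame = small_dataset.frame.assign(fold=folds.fold_index)
        assert (frame.groupby("subject")["fold"].nunique() == 1).all()
        assert (frame.groupby("fold").size() == 16).all()

    def test_group_balanced_kfold(self, small_dataset, rng):
        folds = subject_wise_folds(small_dataset, k=4, rng=rng)
        frame = small_dataset.frame.assign(fold=folds.fold_index)
        per_fold = frame.drop_duplicates("subject").groupby(["fold", "group"]).size()
        assert (per_fold == 1).all()

    def test_k_exceeding_subjects_rejected(self, small_dataset, rng):
        with pytest.raises(ValueError, match="exceeds"):
            subject_wise_folds(small_dataset, k=9, rng=rng)


class TestTuneAndTrain:
    def test_separable_training_accuracy(self, toy_features):
        spec = ModelSpec.reduced("svm-g")
        model, _ = tune_and_train(toy_features, toy_features.groups, spec, None)
        assert (model.predict(toy_features.features) == toy_features.groups).mean() == 1.0

    def test_single_point_grid_selected(self, toy_features):
        spec = ModelSpec("svm-g", grid={"C": (3.0,), "gamma": (0.1,)})
        _, params = tune_and_train(toy_features, toy_features.groups, spec, None)
        assert params == {"C": 3.0, "gamma": 0.1}

    def test_inner_cv_prefers_provably_better_gamma(self, rng):
        # an absurdly narrow kernel memorizes training points and fails the
        # inner folds; exhaustive inner-CV evaluation is the oracle
        ds = make_toy_features(n_per_group=8, records_per_subject=2, seed=2)
        y = ds.groups
        grid = {"C": (1.0,), "gamma": (0.05, 1e4)}
        spec = ModelSpec("svm-g", grid=grid)
        inner = record_wise_folds(ds, 2, rng)
        scores = {}
        for gamma in grid["gamma"]:
            point = ModelSpec("svm-g", grid={"C": (1.0,), "gamma": (gamma,)})
            accs = []
            for f in range(inner.k):
                mask = inner.test_mask(f)
                model, _ = tune_and_train(ds.select(~mask), y[~mask], point, None)
                accs.append((model.predict(ds.features[mask]) == y[mask]).mean())
            scores[gamma] = np.mean(accs)
        assert scores[0.05] > scores[1e4]  # oracle: wide kernel generalizes
        _, chosen = tune_and_train(ds, y, spec, inner)
        assert chosen["gamma"] == 0.05

    def test_single_class_training_rejected(self, toy_features):
        asd_only = toy_features.restrict_group("ASD")
        with pytest.raises(ValueError, match="single class"):
            tune_and_train(asd_only, asd_only.groups, ModelSpec.reduced(), None)


class TestPosteriors:
    @pytest.fixture()
    def fitted(self, toy_features):
        model, _ = tune_and_train(
            toy_features, toy_features.groups, ModelSpec.reduced("svm-g"), None
        )
        return model

    def test_centroid_record_scores_high(self, fitted, toy_features):
        centroid = toy_features.features[toy_features.groups == "ASD"].mean(0, keepdims=True)
        assert predict_posteriors(fitted, centroid)[0] > 0.5

    def test_duplicate_records_equal_scores(self, fitted, toy_features):
        x = toy_features.features[:1]
        doubled = np.vstack([x, x])
        scores = predict_posteriors(fitted, doubled)
        assert scores[0] == scores[1]

    def test_binary_complement(self, fitted, toy_features):
        X = toy_features.features[:10]
        p_asd = predict_posteriors(fitted, X, positive="ASD")
        p_td = predict_posteriors(fitted, X, positive="TD")
        assert np.allclose(p_asd + p_td, 1.0, atol=1e-12)


class TestAggregation:
    @pytest.mark.parametrize(
        "posteriors,expected",
        [
            ((0.9, 0.8, 0.7), "ASD"),
            ((0.5, 0.5), "TD"),  # exact tie goes to the non-diagnosis side
            ([0.6] * 30 + [0.1] * 10, "TD"),  # mean 0.475
        ],
    )
    def test_averaged_posterior_rule(self, posteriors, expected):
        assert aggregate_subject(np.array(posteriors)) == expected

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            aggregate_subject(np.array([]))


class TestSubjectMetrics:
    def test_all_correct(self):
        truth = {f"s{i}": ("ASD" if i < 20 else "TD") for i in range(40)}
        assert evaluate_subject_level(dict(truth), truth) == (1.0, 1.0, 1.0)

    def test_partial_counts(self):
        truth = {f"s{i}": ("ASD" if i < 20 else "TD") for i in range(40)}
        preds = dict(truth)
        for i in list(range(5)) + list(range(20, 25)):  # 5 wrong per group
            preds[f"s{i}"] = "TD" if truth[f"s{i}"] == "ASD" else "ASD"
        assert evaluate_subject_level(preds, truth) == (0.75, 0.75, 0.75)

    def test_all_predicted_positive(self):
        truth = {f"s{i}": ("ASD" if i < 20 else "TD") for i in range(40)}
        preds = {s: "ASD" for s in truth}
        assert evaluate_subject_level(preds, truth) == (0.5, 1.0, 0.0)

    def test_unknown_subject_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            evaluate_subject_level({"x": "ASD"}, {"y": "ASD"})


class TestRunCV:
    def test_no_leakage_test_subject_cannot_move_the_model(self):
        ds = make_toy_features(n_per_group=4, records_per_subject=4, seed=7)
        target = "ASD00"
        train = ds.select(ds.subjects != target)
        spec = ModelSpec.reduced("svm-g")
        model_a, _ = tune_and_train(train, train.groups, spec, None)
        # wreck the held-out subject's features; the training view is identical
        frame = ds.frame.copy()
        frame.loc[frame["subject"] == target, ds.feature_columns] += 1e3
        from prograsp.dataset import FeatureDataset

        perturbed = FeatureDataset(frame)
        train_b = perturbed.select(perturbed.subjects != target)
        model_b, _ = tune_and_train(train_b, train_b.groups, spec, None)
        probe = ds.features[:8]
        assert np.allclose(
            predict_posteriors(model_a, probe), predict_posteriors(model_b, probe), atol=1e-12
        )

    def test_record_subject_dissociation_under_pure_identity_signal(self):
        # identity signatures with zero group effect: record-wise splits look
        # diagnostic, subject-wise splits stay near chance
        diffs = []
        for seed in range(3):
            cfg = GeneratorConfig(
                n_per_group=4, trials_per_block=4, seed=30 + seed, group_timing_shift=0.0
            )
            ds = generate_dataset(cfg)
            spec = ModelSpec.reduced("svm-g", seed=seed)
            rng = np.random.default_rng(seed)
            rw = run_cv(ds, record_wise_folds(ds, 4, rng), spec, rng=rng)
            sw = run_cv(ds, subject_wise_folds(ds), spec, rng=rng)
            diffs.append(rw.accuracy - sw.accuracy)
        assert np.mean(diffs) >= 0.3

    def test_schemes_agree_under_pure_group_effect(self):
        # no subject signatures, strong group separation: both schemes learn
        # the same boundary
        ds = make_toy_features(
            n_per_group=6, records_per_subject=4, separation=6.0, subject_scatter=0.0, seed=9
        )
        spec = ModelSpec.reduced("svm-g")
        rng = np.random.default_rng(1)
        rw = run_cv(ds, record_wise_folds(ds, 4, rng), spec, rng=rng)
        sw = run_cv(ds, subject_wise_folds(ds), spec, rng=rng)
        assert abs(rw.accuracy - sw.accuracy) <= 0.1
        assert rw.accuracy >= 0.9

    def test_deterministic_given_seed(self, small_dataset):
        spec = ModelSpec.reduced("svm-g", seed=4)
        accs = []
        for _ in range(2):
            rng = np.random.default_rng(4)
            folds = record_wise_folds(small_dataset, 4, rng)
            accs.append(run_cv(small_dataset, folds, spec, rng=rng).fold_accuracies)
        assert np.array_equal(accs[0], accs[1])

    @pytest.mark.parametrize("family", ["svm-lasso", "rf"])
    def test_alternative_model_families(self, toy_features, family):
        spec = ModelSpec.reduced(family, seed=0)
        rng = np.random.default_rng(0)
        res = run_cv(toy_features, subject_wise_folds(toy_features), spec, rng=rng)
        assert res.accuracy >= 0.9
        assert set(res.subject_predictions) == set(toy_features.frame["subject"])
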