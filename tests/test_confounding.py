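"""Permutation schemes, null geometry and hybrid cross-validation."""

import numpy as np
import pytest
from scipy import stats

from prograsp.classification import ModelSpec, record_wise_folds, subject_wise_folds, run_cv
from prograsp.confounding import (
    PermutationResult,
    block_permute_labels,
    confounding_report,
    hybrid_cv,
    identity_classification,
    permutation_p,
    permutation_test,
    record_permute_labels,
)
from prograsp.synthetic import GeneratorConfig, generate_dataset

from conftest import make_toy_features


class TestBlockPermutation:
    def test_one_label_per_subject_and_counts_preserved(self, small_dataset, rng):
        permuted = block_permute_labels(small_dataset, rng)
        per_subject = permuted.frame.groupby("subject")["group"].nunique()
        assert (per_subject == 1).all()
        table = permuted.subject_table()
        assert (table["group"] == "ASD").sum() == 4
        assert (table["group"] == "TD").sum() == 4

    def test_feature_rows_untouched(self, small_dataset, rng):
        permuted = block_permute_labels(small_dataset, rng)
        assert np.array_equal(permuted.features, small_dataset.features)

    def test_two_subject_assignments_uniform(self, rng):
        ds = make_toy_features(n_per_group=1, records_per_subject=3, seed=1)
        flips = 0
        for _ in range(1000):
            permuted = block_permute_labels(ds, rng)
            table = permuted.subject_table().set_index("subject")["group"]
            if table["ASD00"] == "TD":
                flips += 1
        assert flips / 1000 == pytest.approx(0.5, abs=0.05)


class TestRecordPermutation:
    def test_label_multiset_preserved(self, small_dataset, rng):
        permuted = record_permute_labels(small_dataset, "group", rng)
        assert sorted(permuted.groups) == sorted(small_dataset.groups)

    def test_seeded_reproducibility(self, small_dataset):
        a = record_permute_labels(small_dataset, "intention", np.random.default_rng(5))
        b = record_permute_labels(small_dataset, "intention", np.random.default_rng(5))
        assert np.array_equal(a.intentions, b.intentions)

    def test_breaks_subject_label_association(self, small_dataset, rng):
        # chi-square of the subject x label table hovers at its null
        # expectation (df) once labels are shuffled record-wise
        import pandas as pd

        statistics = []
        for _ in range(200):
            permuted = record_permute_labels(small_dataset, "group", rng)
            table = pd.crosstab(permuted.subjects, permuted.groups)
            statistics.append(stats.chi2_contingency(table).statistic)
        df = (8 - 1) * (2 - 1)
        assert np.mean(statistics) == pytest.approx(df, rel=0.25)


class TestPermutationP:
    def test_observed_below_entire_null(self):
        assert permutation_p(0.1, np.full(100, 0.5)) == 1.0

    def test_observed_above_entire_null(self):
        assert permutation_p(0.99, np.full(100, 0.5)) == pytest.approx(1 / 101)

    def test_p_never_zero(self, rng):
        assert permutation_p(2.0, rng.uniform(size=100)) > 0.0


class TestPermutationTest:
    def test_group_signal_detected_on_separable_data(self):
        ds = make_toy_features(n_per_group=5, records_per_subject=4, separation=6.0, seed=3)
        result = permutation_test(
            ds,
            lambda d, r: subject_wise_folds(d),
            ModelSpec.reduced("svm-g"),
            n_perm=19,
            rng=np.random.default_rng(0),
        )
        assert result.p_value == pytest.approx(1 / 20)
        assert result.observed == 1.0
        assert result.n_perm == 19

    def test_record_wise_null_sits_above_chance_on_identity_data(self):
        # the above-chance record-wise null is the identity-confounding
        # fingerprint
        cfg = GeneratorConfig(n_per_group=4, trials_per_block=4, seed=17, group_timing_shift=0.0)
        ds = generate_dataset(cfg)
        result = permutation_test(
            ds,
            lambda d, r: record_wise_folds(d, 4, r),
            ModelSpec.reduced("svm-g"),
            n_perm=30,
            rng=np.random.default_rng(1),
        )
        t = stats.ttest_1samp(result.null, 0.5, alternative="greater")
        assert t.pvalue < 0.01

    def test_invalid_n_perm(self, small_dataset):
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test(
                small_dataset,
                lambda d, r: subject_wise_folds(d),
                ModelSpec.reduced(),
                n_perm=0,
            )


class TestIdentityClassification:
    def test_perfect_on_duplicated_records(self):
        cfg = GeneratorConfig(
            n_per_group=2,
            trials_per_block=2,
            seed=4,
            trial_sd={},
            measurement_noise_mm=0.0,
        )
        ds = generate_dataset(cfg)
        result = identity_classification(ds, ModelSpec.reduced("svm-g"), k=2)
        assert result.accuracy == 1.0
        assert result.task == "identity"

    def test_single_record_subject_rejected(self, small_dataset):
        frame = small_dataset.frame.drop(index=range(1, 16))
        from prograsp.dataset import FeatureDataset

        ds = FeatureDataset(frame)
        with pytest.raises(ValueError, match="at least 2"):
            identity_classification(ds, ModelSpec.reduced())


class TestHybridCV:
    def test_outer_subject_never_in_inner_folds(self, monkeypatch):
        ds = make_toy_features(n_per_group=3, records_per_subject=4, seed=6)
        seen = []
        from prograsp import classification as cl

        original = cl.tune_and_train

        def spy(train, y, spec, inner):
            seen.append(set(train.subjects))
            return original(train, y, spec, inner)

        monkeypatch.setattr("prograsp.confounding.run_cv", cl.run_cv)
        monkeypatch.setattr(cl, "tune_and_train", spy)
        hybrid_cv(ds, ModelSpec("svm-g", grid={"C": (1.0,), "gamma": (0.05, 0.5)}), inner_k=2)
        all_subjects = set(ds.frame["subject"])
        # one outer iteration per subject; its training view excludes it
        missing = [all_subjects - s for s in seen]
        assert all(len(m) >= 1 for m in missing)
        held_out = set().union(*[m for m in missing if len(m) == 1])
        assert held_out == all_subjects

    def test_agrees_with_subject_wise_under_pure_group_effect(self):
        ds = make_toy_features(
            n_per_group=5, records_per_subject=4, separation=6.0, subject_scatter=0.0, seed=8
        )
        spec = ModelSpec.reduced("svm-g")
        hybrid = hybrid_cv(ds, spec, np.random.default_rng(2), inner_k=2)
        loso = run_cv(ds, subject_wise_folds(ds), spec, rng=np.random.default_rng(2))
        assert abs(hybrid.accuracy - loso.accuracy) <= 0.1

    def test_deterministic_given_seed(self):
        ds = make_toy_features(n_per_group=3, records_per_subject=4, seed=10)
        spec = ModelSpec.reduced("svm-g")
        a = hybrid_cv(ds, spec, np.random.default_rng(9), inner_k=2)
        b = hybrid_cv(ds, spec, np.random.default_rng(9), inner_k=2)
        assert np.array_equal(a.fold_accuracies, b.fold_accuracies)


class TestConfoundingReport:
    def _perm(self, null, observed, cv_scheme):
        return PermutationResult(
            observed=observed,
            null=np.asarray(null),
            permutation_scheme="subject-block",
            cv_scheme=cv_scheme,
            p_value=permutation_p(observed, np.asarray(null)),
        )

    def test_confounded_without_group_signal(self, rng):
        record = self._perm(0.75 + rng.normal(0, 0.01, 100), 0.76, "record-wise")
        subject = self._perm(0.5 + rng.normal(0, 0.05, 100), 0.55, "subject-wise")
        report = confounding_report(record, subject)
        assert report["identity_confounding"]
        assert not report["group_signal_record_wise"]

    def test_group_signal_without_confounding(self, rng):
        record = self._perm(0.5 + rng.normal(0, 0.03, 100), 0.75, "record-wise")
        subject = self._perm(0.5 + rng.normal(0, 0.05, 100), 0.75, "subject-wise")
        report = confounding_report(record, subject)
        assert not report["identity_confounding"]
        assert report["group_signal_record_wise"]
        assert report["group_signal_subject_wise"]

    def test_neither_flag_at_chance(self, rng):
        record = self._perm(0.5 + rng.normal(0, 0.03, 100), 0.5, "record-wise")
        subject = self._perm(0.5 + rng.normal(0, 0.05, 100), 0.5, "subject-wise")
        report = confounding_report(record, subject)
        assert not report["identity_confounding"]
        assert not report["group_signal_record_wise"]
        assert not report["group_signal_subject_wise"]

    def test_scheme_mismatch_rejected(self, rng):
        record = self._perm(np.full(10, 0.5), 0.5, "record-wise")
        with pytest.raises(ValueError, match="scheme mismatch"):
            confounding_report(record, record)
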