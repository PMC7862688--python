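"""Identity-confounding diagnostics.

When repeated movements of the same child appear in both training and
test sets (record-wise splits), a classifier can learn each child's
idiosyncratic movement signature and read the diagnostic label off the
identity, inflating apparent group accuracy. This module quantifies that
confound three ways:

* **identity classification** -- train record-wise classifiers to predict
  *who* moved rather than which group they belong to;
* **subject-block permutation nulls** -- permute the diagnostic label of
  each subject as a block (all of a child's records flip together). This
  destroys any label--movement relationship while preserving the
  identity--label confound, so a record-wise null distribution centred
  above the 0.5 chance level is direct evidence of identity confounding,
  whereas the subject-wise null stays at chance;
* **hybrid cross-validation** -- record-wise hyper-parameter tuning inside
  a subject-wise outer loop, measuring how record-wise-tuned models fare
  on genuinely unseen children.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .classification import (
    CVResult,
    FoldAssignment,
    ModelSpec,
    record_wise_folds,
    run_cv,
    subject_wise_folds,
)
from .dataset import FeatureDataset


@dataclass
class PermutationResult:
    """Observed statistic, permutation null and p-value of one test."""

    observed: float
    null: np.ndarray
    permutation_scheme: str  # subject-block | record-level
    cv_scheme: str  # record-wise | subject-wise | hybrid
    p_value: float
    seed: int | None = None

    def __post_init__(self) -> None:
        self.null = np.asarray(self.null, dtype=float)
        if self.null.size < 1:
            raise ValueError("null distribution is empty")
        if np.any((self.null < 0) | (self.null > 1)):
            raise ValueError("null accuracies must lie in [0, 1]")

    @property
    def n_perm(self) -> int:
        return int(self.null.size)

    @property
    def null_mean(self) -> float:
        return float(self.null.mean())

    def to_bundle(self) -> dict:
        return {
            "observed": self.observed,
            "null": self.null.tolist(),
            "permutation_scheme": self.permutation_scheme,
            "cv_scheme": self.cv_scheme,
            "p_value": self.p_value,
            "seed": self.seed,
        }


def permutation_p(observed: float, null: np.ndarray) -> float:
    """Add-one permutation p-value: (1 + #{null >= observed}) / (1 + n_perm).

    One-sided (null at least as large as observed); bounded away from 0,
    equal to 1 when the observed statistic undercuts the whole null.
    """
    null = np.asarray(null, dtype=float)
    return (1 + int(np.sum(null >= observed))) / (1 + null.size)


def block_permute_labels(ds: FeatureDataset, rng: np.random.Generator) -> FeatureDataset:
    """Permute diagnostic labels subject-as-block.

    The multiset of subject-level labels is shuffled uniformly across
    subjects (group sizes preserved); every record of a subject carries
    that subject's permuted label; feature rows are untouched.
    """
    table = ds.subject_table().sort_values("subject").reset_index(drop=True)
    permuted = rng.permutation(table["group"].to_numpy())
    mapping = dict(zip(table["subject"], permuted))
    return ds.with_groups(np.array([mapping[s] for s in ds.subjects]))


def record_permute_labels(
    ds: FeatureDataset, label_column: str, rng: np.random.Generator
) -> FeatureDataset:
    """Permute a label column uniformly across records.

    Breaks both the group--movement and the identity--label association;
    per-label counts are preserved. Permuting ``group`` this way yields a
    diagnostic dataset in which subjects straddle labels, so the
    within-subject consistency check is waived on the result.
    """
    if ds.n_records == 0:
        raise ValueError("cannot permute an empty dataset")
    frame = ds.frame.copy()
    frame[label_column] = rng.permutation(frame[label_column].to_numpy())
    return FeatureDataset(frame, validate_group=label_column != "group")


def permutation_test(
    ds: FeatureDataset,
    folds_builder,
    spec: ModelSpec,
    permutation_scheme: str = "subject-block",
    n_perm: int = 100,
    rng: np.random.Generator | None = None,
    task: str = "group",
    seed: int | None = None,
    **cv_kwargs,
) -> PermutationResult:
    """Permutation test of cross-validated accuracy against chance.

    ``folds_builder(ds, rng)`` supplies the fold assignment; the observed
    statistic is the CV accuracy on the true labels, and the null is the
    same statistic on ``n_perm`` relabelled datasets (subject-block for
    group-task nulls, record-level for intention-style tasks). Folds are
    always drawn from the *original* dataset's structure -- permutation
    shuffles labels inside the cross-validation design, it does not
    redesign the folds around the shuffled labels. The p-value uses the
    add-one convention p = (1 + #{null >= observed}) / (1 + n_perm),
    which can never report exactly zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    observed_cv = run_cv(ds, folds_builder(ds, rng), spec, task=task, rng=rng, **cv_kwargs)
    null = np.empty(n_perm)
    for i in range(n_perm):
        if permutation_scheme == "subject-block":
            permuted = block_permute_labels(ds, rng)
        elif permutation_scheme == "record-level":
            permuted = record_permute_labels(ds, "group" if task == "group" else task, rng)
        else:
            raise ValueError(f"unknown permutation scheme {permutation_scheme!r}")
        null[i] = run_cv(
            permuted, folds_builder(ds, rng), spec, task=task, rng=rng, **cv_kwargs
        ).accuracy
    return PermutationResult(
        observed=observed_cv.accuracy,
        null=null,
        permutation_scheme=permutation_scheme,
        cv_scheme=observed_cv.scheme,
        p_value=permutation_p(observed_cv.accuracy, null),
        seed=seed,
    )


def identity_classification(
    ds: FeatureDataset,
    spec: ModelSpec,
    k: int = 10,
    rng: np.random.Generator | None = None,
) -> CVResult:
    """Record-wise CV predicting *subject identity* (one class per subject).

    Record-level accuracy near 1 with 40 classes demonstrates that the
    features carry strong individual signatures; the chance reference is
    1/n_subjects.
    """
    counts = ds.frame.groupby("subject").size()
    if (counts < 2).any():
        raise ValueError("every subject needs at least 2 records for record-wise folding")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    folds = record_wise_folds(ds, k, rng)
    return run_cv(ds, folds, spec, task="identity", rng=rng)


def hybrid_cv(
    ds: FeatureDataset,
    spec: ModelSpec,
    rng: np.random.Generator | None = None,
    inner_k: int = 10,
) -> CVResult:
    """Leave-one-subject-out testing with record-wise inner tuning.

    The held-out subject never enters any inner fold; only the tuning
    split inside the 39 training subjects mixes records of a subject
    across folds. Contrast with a fully subject-wise run (same outer
    folds) to measure what record-wise tuning costs on unseen children.
    """
    if len(ds.subject_table()) < 3:
        raise ValueError("hybrid CV needs at least 3 subjects")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    folds = subject_wise_folds(ds)
    folds = FoldAssignment("hybrid", folds.k, folds.fold_index)
    return run_cv(ds, folds, spec, rng=rng, inner_scheme="record-wise", inner_k=inner_k)


def confounding_report(
    record_perm: PermutationResult,
    subject_perm: PermutationResult,
    alpha: float = 0.05,
) -> dict:
    """Joint reading of the two scheme-matched permutation tests.

    Identity confounding is flagged when the record-wise subject-block
    null sits significantly above the 0.5 chance level (one-sample
    one-sided t test); genuine group information is read off each
    observed accuracy's position in its own null.
    """
    if record_perm.cv_scheme != "record-wise" or subject_perm.cv_scheme not in (
        "subject-wise",
        "hybrid",
    ):
        raise ValueError(
            "scheme mismatch: expected a record-wise and a subject-wise permutation result, got "
            f"{record_perm.cv_scheme!r} and {subject_perm.cv_scheme!r}"
        )
    null = record_perm.null
    if np.ptp(null) == 0:
        confounded = bool(null[0] > 0.5)
        t_p = 0.0 if confounded else 1.0
    else:
        t_stat = stats.ttest_1samp(null, 0.5, alternative="greater")
        t_p = float(t_stat.pvalue)
        confounded = t_p <= alpha
    return {
        "identity_confounding": confounded,
        "record_null_mean": record_perm.null_mean,
        "record_null_vs_chance_p": t_p,
        "subject_null_mean": subject_perm.null_mean,
        "group_signal_record_wise": record_perm.p_value <= alpha,
        "group_signal_subject_wise": subject_perm.p_value <= alpha,
        "record_wise_p": record_perm.p_value,
        "subject_wise_p": subject_perm.p_value,
    }
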