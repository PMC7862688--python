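"""Model/Results front end for the classification analyses.

:class:`MovementClassification` is configured from a feature dataset
(task, fold scheme, classifier family) and ``fit()`` returns a
:class:`ClassificationResults` carrying the cross-validated estimates,
their bootstrap uncertainties and a printable summary. Permutation
nulls and diagnostic plots hang off the same two objects.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .classification import (
    CVResult,
    FoldAssignment,
    ModelSpec,
    record_wise_folds,
    record_wise_intention_folds,
    run_cv,
    subject_wise_folds,
)
from .confounding import PermutationResult, hybrid_cv, permutation_test
from .dataset import FeatureDataset
from .experiments import bootstrap_sem

_SCHEMES = ("record-wise", "subject-wise", "hybrid")


class MovementClassification:
    """Cross-validated movement classification, statsmodels style.

    Parameters
    ----------
    dataset:
        Analysis-ready feature table.
    task:
        ``group`` (ASD vs TD, subject-level scoring), ``intention``
        (3-class, within one group) or ``identity`` (one class per
        subject).
    scheme:
        ``record-wise``, ``subject-wise`` or ``hybrid``.
    k:
        Fold count; defaults to 10 for record-wise and leave-one-subject-
        out for subject-wise splits.
    model:
        ``svm-g`` (Gaussian-kernel SVM, default), ``svm-lasso`` or ``rf``.
    reduced_grid:
        Use a single-point hyper-parameter grid (skips nested tuning);
        intended for permutation nulls and other repeated refits.
    """

    def __init__(
        self,
        dataset: FeatureDataset,
        task: str = "group",
        scheme: str = "subject-wise",
        k: int | None = None,
        model: str = "svm-g",
        grid: dict | None = None,
        reduced_grid: bool = False,
        seed: int = 0,
    ) -> None:
        if scheme not in _SCHEMES:
            raise ValueError(f"unknown scheme {scheme!r}; expected one of {_SCHEMES}")
        dataset.validate_features()
        self.dataset = dataset
        self.task = task
        self.scheme = scheme
        self.k = k
        self.seed = seed
        if reduced_grid:
            self.spec = ModelSpec.reduced(model, seed=seed)
        else:
            self.spec = ModelSpec(family=model, grid=grid, seed=seed)

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_features_csv(cls, path: str | Path, **kwargs) -> "MovementClassification":
        ds, nan_flags = pio.read_features(path)
        if nan_flags.any():
            ds = ds.select(~nan_flags)
        return cls(ds, **kwargs)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "MovementClassification":
        return cls(FeatureDataset(frame), **kwargs)

    # -- fitting -----------------------------------------------------------
    def _build_folds(self, ds: FeatureDataset, rng: np.random.Generator) -> FoldAssignment:
        if self.scheme == "record-wise":
            k = self.k or 10
            if self.task == "intention":
                return record_wise_intention_folds(ds, k, rng)
            return record_wise_folds(ds, k, rng)
        folds = subject_wise_folds(ds, self.k, rng)
        if self.scheme == "hybrid":
            return FoldAssignment("hybrid", folds.k, folds.fold_index)
        return folds

    def fit(self) -> "ClassificationResults":
        rng = np.random.default_rng(self.seed)
        if self.scheme == "hybrid":
            cv = hybrid_cv(self.dataset, self.spec, rng)
        else:
            folds = self._build_folds(self.dataset, rng)
            cv = run_cv(self.dataset, folds, self.spec, task=self.task, rng=rng)
        sem_rng = np.random.default_rng(self.seed)
        cv.accuracy_sem = bootstrap_sem(cv.fold_accuracies, rng=sem_rng)
        return ClassificationResults(self, cv)

    def permutation_null(
        self, n_perm: int = 100, permutation_scheme: str | None = None
    ) -> PermutationResult:
        """Permutation test of this configuration against chance.

        Group-task nulls permute diagnosis subject-as-block; intention
        and identity nulls permute labels record by record.
        """
        if permutation_scheme is None:
            permutation_scheme = "subject-block" if self.task == "group" else "record-level"
        rng = np.random.default_rng(self.seed)
        kwargs = {}
        if self.scheme == "hybrid":
            kwargs = {"inner_scheme": "record-wise", "inner_k": 10}
        return permutation_test(
            self.dataset,
            self._build_folds,
            self.spec,
            permutation_scheme=permutation_scheme,
            n_perm=n_perm,
            rng=rng,
            task=self.task,
            seed=self.seed,
            **kwargs,
        )


class ClassificationResults:
    """Cross-validation estimates with uncertainties and reporting helpers."""

    def __init__(self, model: MovementClassification, cv: CVResult) -> None:
        self.model = model
        self._cv = cv

    # expose the estimates
    @property
    def accuracy(self) -> float:
        return self._cv.accuracy

    @property
    def accuracy_sem(self) -> float | None:
        return self._cv.accuracy_sem

    @property
    def sensitivity(self) -> float | None:
        return self._cv.sensitivity

    @property
    def specificity(self) -> float | None:
        return self._cv.specificity

    @property
    def fold_accuracies(self) -> np.ndarray:
        return self._cv.fold_accuracies

    @property
    def subject_predictions(self) -> dict | None:
        return self._cv.subject_predictions

    @property
    def record_table(self) -> pd.DataFrame:
        return self._cv.record_table

    def summary(self) -> str:
        cv = self._cv
        lines = [
            "Movement classification results",
            "=" * 46,
            f"{'task':<22}{cv.task}",
            f"{'scheme':<22}{cv.scheme} (k={cv.k})",
            f"{'model':<22}{self.model.spec.family}",
            f"{'records':<22}{len(cv.record_table)}",
            f"{'subjects':<22}{self.model.dataset.frame['subject'].nunique()}",
            "-" * 46,
            f"{'accuracy':<22}{cv.accuracy:.3f}"
            + (f" +/- {cv.accuracy_sem:.3f} (SEM)" if cv.accuracy_sem is not None else ""),
        ]
        if cv.sensitivity is not None:
            lines.append(f"{'sensitivity':<22}{cv.sensitivity:.3f}")
            lines.append(f"{'specificity':<22}{cv.specificity:.3f}")
        lines.append("=" * 46)
        return "\n".join(lines)

    def save(self, path: str | Path, name: str = "classification") -> None:
        bundle = {"experiment": name, "seed": self.model.seed, **self._cv.to_bundle()}
        pio.write_results(bundle, path)

    def plot_fold_accuracies(self, ax=None):
        """Bar plot of per-fold accuracy with the chance line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.bar(np.arange(len(self.fold_accuracies)), self.fold_accuracies, color="tab:blue")
        chance = 0.5 if self._cv.task == "group" else None
        if chance is not None:
            ax.axhline(chance, ls="--", color="grey", label="chance")
            ax.legend()
        ax.set_xlabel("fold")
        ax.set_ylabel("accuracy")
        ax.set_ylim(0, 1.05)
        return ax


def plot_permutation_null(perm: PermutationResult, ax=None):
    """Histogram of the permutation null with the observed accuracy marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.hist(perm.null, bins=20, color="lightgrey", edgecolor="grey")
    ax.axvline(perm.observed, color="purple", label=f"observed = {perm.observed:.2f}")
    ax.axvline(0.5, ls="--", color="grey", label="chance 0.5")
    ax.set_xlabel("accuracy")
    ax.set_ylabel("permutations")
    ax.set_title(f"{perm.cv_scheme} CV, {perm.permutation_scheme} null (p = {perm.p_value:.3f})")
    ax.legend()
    return ax
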