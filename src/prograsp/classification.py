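"""Classifiers, cross-validation schemes and subject-level scoring.

Three fold schemes are implemented:

* **record-wise** -- individual movements of a subject are spread across
  folds (each fold holds an equal number of records from every subject),
  so the same child contributes to both training and test sets;
* **subject-wise** -- all records of a subject share one fold
  (leave-one-subject-out by default, or a group-balanced k-fold), which
  neutralizes identity leakage;
* **hybrid** -- subject-wise outer testing with record-wise inner tuning
  (see :mod:`prograsp.confounding`).

Hyper-parameters are tuned by nested cross-validation: within each outer
training set, each grid point is scored by leave-one-fold-out accuracy
over the inner folds and the best point (ties broken toward the least
complex model) is refit on the full training set. Feature z-scoring uses
training-fold statistics only, so no test information leaks into the fit.

Subject-level scoring follows the averaged-posterior rule: a subject's
predicted group is ASD when the mean posterior score of that subject's
held-out movements exceeds 0.5 (an exact 0.5 tie goes to TD, the
conservative non-diagnosis side).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, LinearSVC

from .dataset import FeatureDataset

POSITIVE_CLASS = "ASD"

FAMILIES = ("svm-g", "svm-lasso", "rf")

_DEFAULT_GRIDS = {
    "svm-g": {"C": (0.1, 1.0, 10.0, 100.0), "gamma": tuple(np.logspace(-3, 1, 5))},
    "svm-lasso": {"C": tuple(np.logspace(-3, 1, 7))},
    "rf": {"n_estimators": (500,), "max_features": ("sqrt", 0.33)},
}

#: single-point grids for permutation nulls and other hot loops
_REDUCED_GRIDS = {
    "svm-g": {"C": (10.0,), "gamma": (0.02,)},
    "svm-lasso": {"C": (0.1,)},
    "rf": {"n_estimators": (200,), "max_features": ("sqrt",)},
}


@dataclass
class ModelSpec:
    """Classifier family plus its hyper-parameter grid."""

    family: str = "svm-g"
    grid: dict[str, tuple] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}; expected one of {FAMILIES}")
        if self.grid is None:
            self.grid = {k: tuple(v) for k, v in _DEFAULT_GRIDS[self.family].items()}
        if any(len(v) == 0 for v in self.grid.values()) or not self.grid:
            raise ValueError("hyper-parameter grid must be non-empty")

    @classmethod
    def reduced(cls, family: str = "svm-g", seed: int = 0) -> "ModelSpec":
        return cls(family=family, grid={k: tuple(v) for k, v in _REDUCED_GRIDS[family].items()}, seed=seed)

    def grid_points(self) -> list[dict]:
        """Grid points in deterministic least-complex-first order.

        SVMs iterate by ascending C then ascending gamma (smoothest
        decision surface first); a strict-improvement argmax then selects
        the simplest model among inner-CV ties.
        """
        keys = sorted(self.grid)
        values = [self.grid[k] for k in keys]
        points = [dict(zip(keys, combo)) for combo in product(*values)]

        def complexity(pt: dict):
            return tuple(pt[k] if isinstance(pt[k], (int, float)) else 0 for k in keys)

        return sorted(points, key=complexity)

    def build(self, params: dict) -> Pipeline:
        if self.family == "svm-g":
            est = SVC(kernel="rbf", **params)
        elif self.family == "svm-lasso":
            est = LinearSVC(penalty="l1", dual=False, **params)
        else:
            est = RandomForestClassifier(random_state=self.seed, n_jobs=1, **params)
        return Pipeline([("scale", StandardScaler()), ("clf", est)])


@dataclass
class FoldAssignment:
    """A cross-validation split annotated with its scheme."""

    scheme: str  # record-wise | subject-wise | hybrid
    k: int
    fold_index: np.ndarray  # per-record fold id in 0..k-1

    def __post_init__(self) -> None:
        self.fold_index = np.asarray(self.fold_index, dtype=int)
        present = np.unique(self.fold_index)
        if not np.array_equal(present, np.arange(self.k)):
            raise ValueError(f"fold indices {present} do not partition 0..{self.k - 1}")

    def test_mask(self, fold: int) -> np.ndarray:
        return self.fold_index == fold


def record_wise_folds(
    ds: FeatureDataset, k: int, rng: np.random.Generator
) -> FoldAssignment:
    """Deal each subject's records evenly at random across k folds.

    Requires k to divide every subject's record count, so that each fold
    contains the same number of movements from each subject (4 per
    subject at k = 10, 1 at k = 40 in the full design).
    """
    fold_index = np.full(ds.n_records, -1, dtype=int)
    for _, idx in _subject_indices(ds):
        if len(idx) % k:
            raise ValueError(
                f"fold count {k} does not divide per-subject record count {len(idx)}"
            )
        shuffled = rng.permutation(idx)
        per = len(idx) // k
        for f in range(k):
            fold_index[shuffled[f * per : (f + 1) * per]] = f
    return FoldAssignment("record-wise", k, fold_index)


def record_wise_intention_folds(
    ds: FeatureDataset, k: int, rng: np.random.Generator
) -> FoldAssignment:
    """Intention-balanced record-wise folds for the 3-class decoding task.

    Each fold receives an equal number of movements from every
    (subject, intention) cell -- one each in the 10-trials-per-intention
    design with k = 10.
    """
    fold_index = np.full(ds.n_records, -1, dtype=int)
    frame = ds.frame
    for (_, _), idx in frame.groupby(["subject", "intention"], sort=True).indices.items():
        if len(idx) % k:
            raise ValueError(
                f"fold count {k} does not divide a (subject, intention) cell of {len(idx)} records"
            )
        shuffled = rng.permutation(idx)
        per = len(idx) // k
        for f in range(k):
            fold_index[shuffled[f * per : (f + 1) * per]] = f
    return FoldAssignment("record-wise", k, fold_index)


def subject_wise_folds(
    ds: FeatureDataset, k: int | None = None, rng: np.random.Generator | None = None
) -> FoldAssignment:
    """Assign whole subjects to folds: LOSO by default, else group-balanced k-fold.

    In the balanced k-fold, subjects are shuffled within group and dealt
    round-robin, keeping the ASD:TD ratio within one subject per fold.
    """
    table = ds.subject_table()
    n_subjects = len(table)
    if k is None:
        k = n_subjects
    if k > n_subjects:
        raise ValueError(f"k={k} exceeds number of subjects {n_subjects}")
    subject_fold: dict[str, int] = {}
    if k == n_subjects:
        order = np.sort(table["subject"].to_numpy())
        subject_fold = {s: i for i, s in enumerate(order)}
    else:
        if rng is None:
            raise ValueError("rng required for group-balanced k-fold")
        slot = 0
        for group in sorted(table["group"].unique()):
            members = np.sort(table.loc[table["group"] == group, "subject"].to_numpy())
            for s in rng.permutation(members):
                subject_fold[s] = slot % k
                slot += 1
    fold_index = np.array([subject_fold[s] for s in ds.subjects])
    return FoldAssignment("subject-wise", k, fold_index)


def _subject_indices(ds: FeatureDataset):
    return sorted(ds.frame.groupby("subject", sort=True).indices.items())


# -- nested tuning ---------------------------------------------------------

def tune_and_train(
    train: FeatureDataset,
    y_train: np.ndarray,
    spec: ModelSpec,
    inner_folds: FoldAssignment | None,
) -> tuple[Pipeline, dict]:
    """Select hyper-parameters by inner leave-one-fold-out CV, refit on all training data.

    A single-point grid skips the inner loop. Returns the fitted pipeline
    and the selected grid point.
    """
    X = train.features
    y = np.asarray(y_train)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contain a single class")
    points = spec.grid_points()
    if len(points) == 1:
        best = points[0]
    else:
        if inner_folds is None:
            raise ValueError("inner folds required for a multi-point grid")
        best, best_score = None, -np.inf
        for pt in points:
            scores = []
            for f in range(inner_folds.k):
                mask = inner_folds.test_mask(f)
                if mask.all() or not mask.any():
                    continue
                if len(np.unique(y[~mask])) < 2:
                    continue
                model = spec.build(pt)
                model.fit(X[~mask], y[~mask])
                scores.append(np.mean(model.predict(X[mask]) == y[mask]))
            score = float(np.mean(scores)) if scores else -np.inf
            if score > best_score:  # strict: first (least complex) point wins ties
                best, best_score = pt, score
    final = spec.build(best)
    final.fit(X, y)
    return final, best


def predict_posteriors(model: Pipeline, X: np.ndarray, positive: str = POSITIVE_CLASS) -> np.ndarray:
    """Per-record posterior score of the positive class, in [0, 1].

    Random forests report their vote fraction; SVMs report a logistic
    squashing of the signed decision margin (monotone in the margin, 0.5
    exactly on the decision boundary).
    """
    clf = model.named_steps["clf"]
    classes = list(clf.classes_)
    if positive not in classes:
        raise ValueError(f"positive class {positive!r} absent from model classes {classes}")
    if hasattr(clf, "predict_proba"):
        proba = model.predict_proba(X)
        return proba[:, classes.index(positive)]
    decision = model.decision_function(X)
    if decision.ndim != 1:
        raise ValueError("posterior scores are defined for binary tasks only")
    sign = 1.0 if classes.index(positive) == 1 else -1.0
    return expit(sign * decision)


def aggregate_subject(posteriors: np.ndarray, positive: str = POSITIVE_CLASS) -> str:
    """Averaged-posterior rule: mean > 0.5 -> ASD, otherwise TD (ties to TD)."""
    posteriors = np.asarray(posteriors, dtype=float)
    if posteriors.size == 0:
        raise ValueError("cannot aggregate an empty posterior set")
    negative = [g for g in ("ASD", "TD") if g != positive][0]
    return positive if posteriors.mean() > 0.5 else negative


def evaluate_subject_level(
    predictions: dict[str, str], truth: dict[str, str], positive: str = POSITIVE_CLASS
) -> tuple[float, float, float]:
    """Accuracy, sensitivity and specificity over subjects.

    Sensitivity is the fraction of ASD subjects classified ASD among all
    ASD subjects; specificity the analogue for TD.
    """
    unknown = set(predictions) - set(truth)
    if unknown:
        raise ValueError(f"predictions for unknown subject(s): {sorted(unknown)}")
    subjects = sorted(predictions)
    correct = np.array([predictions[s] == truth[s] for s in subjects])
    is_pos = np.array([truth[s] == positive for s in subjects])
    accuracy = float(correct.mean())
    sensitivity = float(correct[is_pos].mean()) if is_pos.any() else float("nan")
    specificity = float(correct[~is_pos].mean()) if (~is_pos).any() else float("nan")
    return accuracy, sensitivity, specificity


@dataclass
class CVResult:
    """Outcome of one cross-validated classification run."""

    task: str
    scheme: str
    k: int
    record_table: pd.DataFrame  # record, subject, truth, prediction/posterior, fold
    fold_accuracies: np.ndarray
    accuracy: float
    sensitivity: float | None
    specificity: float | None
    accuracy_sem: float | None
    subject_predictions: dict[str, str] | None
    selected_params: list[dict] = field(default_factory=list)

    def to_bundle(self) -> dict:
        return {
            "task": self.task,
            "scheme": self.scheme,
            "k": self.k,
            "fold_accuracies": list(map(float, self.fold_accuracies)),
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy_sem": self.accuracy_sem,
            "subject_predictions": self.subject_predictions,
        }


def _inner_folds_for(
    ds_train: FeatureDataset,
    outer: FoldAssignment,
    train_mask: np.ndarray,
    inner_scheme: str,
    rng: np.random.Generator,
    inner_k: int | None = None,
) -> FoldAssignment:
    """Inner tuning folds over one outer training set.

    For record-wise outer splits the remaining outer folds are reused
    (tune on all but one training fold, validate on the last); otherwise
    folds of the requested scheme are drawn afresh on the training set.
    """
    if inner_scheme == "reuse-outer":
        inner_ids = outer.fold_index[train_mask]
        remap = {f: i for i, f in enumerate(np.unique(inner_ids))}
        return FoldAssignment(outer.scheme, len(remap), np.array([remap[f] for f in inner_ids]))
    if inner_scheme == "record-wise":
        counts = ds_train.frame.groupby("subject").size()
        k = inner_k or int(np.gcd.reduce(counts.to_numpy()))
        if k < 2:
            raise ValueError("cannot build record-wise inner folds: per-subject counts coprime")
        return record_wise_folds(ds_train, k, rng)
    if inner_scheme == "subject-wise":
        return subject_wise_folds(ds_train, inner_k, rng)
    raise ValueError(f"unknown inner scheme {inner_scheme!r}")


def run_cv(
    ds: FeatureDataset,
    folds: FoldAssignment,
    spec: ModelSpec,
    task: str = "group",
    rng: np.random.Generator | None = None,
    inner_scheme: str | None = None,
    inner_k: int | None = None,
    bootstrap_sem_fn=None,
) -> CVResult:
    """Nested cross-validation with subject-level aggregation.

    For the binary group task, each fold's records receive posterior
    scores, subjects present in the fold are classified by the averaged
    posterior of their held-out movements, and the fold accuracy is the
    fraction of those subjects classified correctly. Sensitivity and
    specificity are computed from the pooled per-subject predictions
    (each subject's posteriors averaged over all of its held-out records
    in the whole pass). For the multi-class intention and identity tasks
    accuracy is the fraction of correctly classified records.
    """
    if folds.fold_index.shape[0] != ds.n_records:
        raise ValueError("fold assignment does not match dataset size")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    y = ds.labels(task)
    binary = task == "group"
    records = []
    selected = []
    fold_accs = np.empty(folds.k)
    for f in range(folds.k):
        test_mask = folds.test_mask(f)
        train_mask = ~test_mask
        ds_train = ds.select(train_mask)
        inner = None
        if len(spec.grid_points()) > 1:
            scheme = inner_scheme or ("reuse-outer" if folds.scheme == "record-wise" else "subject-wise")
            inner = _inner_folds_for(ds_train, folds, train_mask, scheme, rng, inner_k)
        model, params = tune_and_train(ds_train, y[train_mask], spec, inner)
        selected.append(params)
        X_test = ds.features[test_mask]
        test_idx = np.flatnonzero(test_mask)
        if binary:
            post = predict_posteriors(model, X_test)
            for i, p in zip(test_idx, post):
                records.append((int(i), ds.subjects[i], y[i], float(p), f))
            fold_frame = pd.DataFrame(
                {"subject": ds.subjects[test_mask], "truth": y[test_mask], "posterior": post}
            )
            by_subj = fold_frame.groupby("subject")
            preds = {s: aggregate_subject(g["posterior"].to_numpy()) for s, g in by_subj}
            truths = {s: g["truth"].iloc[0] for s, g in by_subj}
            fold_accs[f] = np.mean([preds[s] == truths[s] for s in preds])
        else:
            pred = model.predict(X_test)
            for i, p in zip(test_idx, pred):
                records.append((int(i), ds.subjects[i], y[i], p, f))
            fold_accs[f] = float(np.mean(pred == y[test_mask]))

    columns = ["record", "subject", "truth", "posterior" if binary else "prediction", "fold"]
    record_table = pd.DataFrame(records, columns=columns)
    if binary:
        pooled = record_table.groupby("subject")
        subject_preds = {s: aggregate_subject(g["posterior"].to_numpy()) for s, g in pooled}
        truth = {s: g["truth"].iloc[0] for s, g in pooled}
        _, sens, spec_ = evaluate_subject_level(subject_preds, truth)
    else:
        subject_preds, sens, spec_ = None, None, None
    sem = float(bootstrap_sem_fn(fold_accs)) if bootstrap_sem_fn is not None else None
    return CVResult(
        task=task,
        scheme=folds.scheme,
        k=folds.k,
        record_table=record_table,
        fold_accuracies=fold_accs,
        accuracy=float(fold_accs.mean()),
        sensitivity=sens,
        specificity=spec_,
        accuracy_sem=sem,
        subject_predictions=subject_preds,
        selected_params=selected,
    )
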