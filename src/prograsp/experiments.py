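"""End-to-end experiment drivers and small reporting statistics.

The analyses cover: 3-class intention decoding within each diagnosis
group; group classification under record-wise and subject-wise splits
with sign-test comparisons; learning curves over training-set sizes;
per-intention group decoding; and the statistical utilities used for
reporting (exact paired sign test, bootstrap SEM, pooled two-sample t
from summary statistics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .classification import (
    CVResult,
    ModelSpec,
    record_wise_folds,
    record_wise_intention_folds,
    run_cv,
    subject_wise_folds,
    tune_and_train,
    predict_posteriors,
    aggregate_subject,
    evaluate_subject_level,
)
from .confounding import PermutationResult, permutation_test
from .dataset import FeatureDataset


# -- reporting statistics --------------------------------------------------

@dataclass
class SummaryStats:
    """Mean, SD and n of one group, as printed in a demographics table."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("SD must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")


def sign_test(paired_a, paired_b) -> float:
    """Two-tailed exact paired-sample sign test.

    Ties are discarded; the p-value is the exact two-sided binomial tail
    for the number of positive differences under P = 0.5. All ties give
    p = 1.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("paired samples must be non-empty and of equal length")
    diff = a - b
    n = int(np.sum(diff != 0))
    if n == 0:
        return 1.0
    k = int(np.sum(diff > 0))
    return float(stats.binomtest(k, n, 0.5, alternative="two-sided").pvalue)


def bootstrap_sem(values, n_boot: int = 1000, rng: np.random.Generator | None = None) -> float:
    """Standard error of the mean by bootstrap: SD of resampled means."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot bootstrap an empty sample")
    if rng is None:
        rng = np.random.default_rng(0)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    return float(values[idx].mean(axis=1).std(ddof=0))


def pooled_t(a: SummaryStats, b: SummaryStats) -> tuple[float, int]:
    """Equal-variance two-sample t statistic from summary statistics.

    Returns (t, df) with df = n_a + n_b - 2. A zero pooled variance with
    a non-zero mean difference yields signed infinity with a warning.
    """
    df = a.n + b.n - 2
    pooled_var = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    diff = a.mean - b.mean
    if pooled_var == 0:
        if diff == 0:
            return 0.0, df
        import warnings

        warnings.warn("zero pooled variance with non-zero mean difference", RuntimeWarning)
        return float(np.sign(diff) * np.inf), df
    t = diff / np.sqrt(pooled_var * (1 / a.n + 1 / b.n))
    return float(t), df


# -- experiment drivers ----------------------------------------------------

def equate_pass_trials(ds: FeatureDataset, rng: np.random.Generator) -> FeatureDataset:
    """Randomly keep half the trials of each pass block to balance intentions.

    With two pass blocks, the pass intention holds twice the movements of
    place and pour; random subsampling of half of each pass block (5 of
    10 trials in the full design) equates the three classes for
    intention decoding.
    """
    frame = ds.frame
    keep = np.ones(len(frame), dtype=bool)
    for (subject, block), idx in frame.groupby(["subject", "block"], sort=True).indices.items():
        if block in ("pass1", "pass2"):
            if len(idx) < 2:
                raise ValueError(
                    f"subject {subject} block {block} has {len(idx)} trials; need >= 2"
                )
            drop = rng.choice(idx, size=len(idx) - len(idx) // 2, replace=False)
            keep[drop] = False
    return ds.select(keep)


def run_intention_experiment(
    ds: FeatureDataset,
    group: str,
    spec: ModelSpec,
    rng: np.random.Generator,
    n_perm: int = 100,
    k: int = 10,
) -> tuple[CVResult, PermutationResult]:
    """3-class intention decoding within one diagnosis group.

    Pass trials are subsampled to equate class counts (600 records in the
    full design), folds are intention-balanced record-wise splits, and
    significance comes from a record-level label permutation null.
    Accuracy is the fraction of correctly classified trials.
    """
    sub = equate_pass_trials(ds.restrict_group(group), rng)
    folds_builder = lambda d, r: record_wise_intention_folds(d, k, r)
    result = run_cv(sub, folds_builder(sub, rng), spec, task="intention", rng=rng)
    perm = permutation_test(
        sub,
        folds_builder,
        spec,
        permutation_scheme="record-level",
        n_perm=n_perm,
        rng=rng,
        task="intention",
    )
    return result, perm


def run_group_experiment(
    ds: FeatureDataset,
    spec: ModelSpec,
    rng: np.random.Generator,
    record_ks: tuple[int, ...] = (10, 40),
) -> dict:
    """Group classification under record-wise (k = 10, 40) and subject-wise splits.

    Returns the three CV results plus two-tailed sign tests comparing the
    schemes on matched per-subject correctness (the pairing unit that is
    defined for every scheme).
    """
    results: dict[str, CVResult] = {}
    for k in record_ks:
        folds = record_wise_folds(ds, k, rng)
        results[f"record-wise-{k}"] = run_cv(ds, folds, spec, rng=rng)
    results["subject-wise"] = run_cv(ds, subject_wise_folds(ds), spec, rng=rng)

    truth = dict(zip(ds.subject_table()["subject"], ds.subject_table()["group"]))
    subjects = sorted(truth)

    def correctness(res: CVResult) -> np.ndarray:
        return np.array(
            [1.0 if res.subject_predictions[s] == truth[s] else 0.0 for s in subjects]
        )

    comparisons = {}
    names = list(results)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            comparisons[f"{a} vs {b}"] = sign_test(
                correctness(results[a]), correctness(results[b])
            )
    return {"results": results, "sign_tests": comparisons}


def run_learning_curve(
    ds: FeatureDataset,
    spec: ModelSpec,
    rng: np.random.Generator,
    sizes: tuple[int, ...] = (4, 10, 20, 39),
    repeats: int = 20,
) -> dict:
    """Subject-level accuracy as a function of training-set size.

    For each repeat a nested chain of group-balanced training sets is
    drawn (the 4-subject set is contained in the 10-subject set, and so
    on, reducing between-size sampling variance); each classifier is
    tested on all held-out subjects. The subject-wise variant trains only
    on the drawn subjects' records; the record-wise variant additionally
    sees the test subjects' remaining records in its training pool, which
    is what lets identity signatures leak. Training sets of n - 1
    subjects reduce to leave-one-subject-out.
    """
    table = ds.subject_table()
    n_subjects = len(table)
    if max(sizes) > n_subjects - 1:
        raise ValueError("training sizes must leave at least one test subject")
    truth = dict(zip(table["subject"], table["group"]))
    by_group = {
        g: np.sort(table.loc[table["group"] == g, "subject"].to_numpy())
        for g in sorted(table["group"].unique())
    }
    accs = {"subject-wise": {s: [] for s in sizes}, "record-wise": {s: [] for s in sizes}}
    draws: list[dict[int, list[str]]] = []
    multi_grid = len(spec.grid_points()) > 1
    for _ in range(repeats):
        orders = {g: rng.permutation(m) for g, m in by_group.items()}
        # one half-split of every subject's records per repeat, for the
        # record-wise variant
        half_mask = np.zeros(ds.n_records, dtype=bool)
        for _, idx in sorted(ds.frame.groupby("subject", sort=True).indices.items()):
            half_mask[rng.permutation(idx)[: len(idx) // 2]] = True
        repeat_draws: dict[int, list[str]] = {}
        for size in sorted(sizes):
            half, odd = divmod(size, 2)
            take = dict.fromkeys(orders, half)
            if odd:  # nearest balanced split; the extra subject's group is drawn
                take[list(orders)[int(rng.integers(0, len(orders)))]] += 1
            train_set = set(np.concatenate([orders[g][: take[g]] for g in orders]))
            repeat_draws[int(size)] = sorted(train_set)
            in_train_set = np.isin(ds.subjects, sorted(train_set))
            for variant in ("subject-wise", "record-wise"):
                if variant == "subject-wise":
                    train_mask = in_train_set
                    eval_mask = ~in_train_set
                else:
                    train_mask = in_train_set | (~in_train_set & half_mask)
                    eval_mask = ~in_train_set & ~half_mask
                train = ds.select(train_mask)
                inner = subject_wise_folds(train) if multi_grid else None
                model, _ = tune_and_train(train, train.groups, spec, inner)
                post = predict_posteriors(model, ds.features[eval_mask])
                subj = ds.subjects[eval_mask]
                preds = {s: aggregate_subject(post[subj == s]) for s in np.unique(subj)}
                acc, _, _ = evaluate_subject_level(preds, truth)
                accs[variant][size].append(acc)
        draws.append(repeat_draws)
    summary = {
        scheme: {int(s): float(np.mean(v)) for s, v in sizes_acc.items()}
        for scheme, sizes_acc in accs.items()
    }
    summary["raw"] = accs
    summary["train_sets"] = draws
    return summary


def run_intention_specific(
    ds: FeatureDataset,
    spec: ModelSpec,
    rng: np.random.Generator,
    n_perm: int = 100,
) -> dict:
    """Group decoding separately within each intention, subject-wise CV.

    Place and pour subsets carry one block each (400 records in the full
    design); pass keeps both blocks (800). Each run gets a subject-block
    permutation p-value.
    """
    out = {}
    for intention in ("place", "pour", "pass"):
        sub = ds.restrict_intention(intention)
        if sub.n_records == 0:
            raise ValueError(f"no records for intention {intention!r}")
        folds_builder = lambda d, r: subject_wise_folds(d)
        result = run_cv(sub, folds_builder(sub, rng), spec, rng=rng)
        perm = permutation_test(
            sub, folds_builder, spec, permutation_scheme="subject-block",
            n_perm=n_perm, rng=rng,
        )
        out[intention] = {"cv": result, "permutation": perm}
    return out
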