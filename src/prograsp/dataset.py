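"""Movement-by-feature table: the unit of all classification analyses.

A :class:`FeatureDataset` wraps a pandas DataFrame with one row per
movement, metadata columns (subject, group, block, trial, intention) and
a fixed-width block of feature columns (f001.. by convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

META_COLUMNS = ("subject", "group", "block", "trial", "intention")


@dataclass
class FeatureDataset:
    """Table of movements x kinematic features with subject/group/intention labels.

    Recorded data satisfy "group constant within subject"; record-level
    label permutations deliberately break it, so they construct the
    dataset with ``validate_group=False``.
    """

    frame: pd.DataFrame
    validate_group: bool = True

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"feature table missing required columns: {missing}")
        if self.validate_group:
            by_subject = self.frame.groupby("subject", sort=False)["group"].nunique()
            if (by_subject > 1).any():
                bad = by_subject[by_subject > 1].index.tolist()
                raise ValueError(f"group label not constant within subject(s): {bad}")
        self.frame = self.frame.reset_index(drop=True)

    # -- accessors ---------------------------------------------------------
    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c not in META_COLUMNS]

    @property
    def features(self) -> np.ndarray:
        return self.frame[self.feature_columns].to_numpy(dtype=float)

    @property
    def subjects(self) -> np.ndarray:
        return self.frame["subject"].to_numpy()

    @property
    def groups(self) -> np.ndarray:
        return self.frame["group"].to_numpy()

    @property
    def intentions(self) -> np.ndarray:
        return self.frame["intention"].to_numpy()

    @property
    def n_records(self) -> int:
        return len(self.frame)

    def labels(self, task: str) -> np.ndarray:
        """Target labels for a classification task: group, intention or identity."""
        if task == "group":
            return self.groups
        if task == "intention":
            return self.intentions
        if task == "identity":
            return self.subjects
        raise ValueError(f"unknown task {task!r}; expected group, intention or identity")

    def subject_table(self) -> pd.DataFrame:
        """One row per subject with its group label."""
        return (
            self.frame[["subject", "group"]]
            .drop_duplicates("subject")
            .reset_index(drop=True)
        )

    def select(self, mask: np.ndarray) -> "FeatureDataset":
        return FeatureDataset(
            self.frame.loc[np.asarray(mask)].reset_index(drop=True),
            validate_group=self.validate_group,
        )

    def restrict_group(self, group: str) -> "FeatureDataset":
        return self.select(self.groups == group)

    def restrict_intention(self, intention: str) -> "FeatureDataset":
        return self.select(self.intentions == intention)

    def with_groups(self, new_groups: np.ndarray) -> "FeatureDataset":
        """Copy of the dataset with the group column replaced (used by permutations)."""
        frame = self.frame.copy()
        frame["group"] = np.asarray(new_groups)
        return FeatureDataset(frame)

    def validate_features(self) -> None:
        feats = self.features
        if feats.size and not np.all(np.isfinite(feats)):
            n_bad = int(np.sum(~np.isfinite(feats).all(axis=1)))
            raise ValueError(f"{n_bad} record(s) contain non-finite features")

    def __len__(self) -> int:
        return self.n_records
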