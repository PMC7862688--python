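"""Readers and writers for trajectory CSVs, feature tables and result bundles.

Trajectory dialect: comma-separated UTF-8, one row per (frame, marker),
header exactly ``subject,group,block,trial,frame,marker,x,y,z``;
coordinates in mm with z vertical. Long format tolerates per-marker gaps.

Trials with poor marker reconstruction -- more than 10% of frames missing
any marker, or any gap longer than 100 ms -- are excluded and enumerated
in the returned exclusion log; shorter gaps are filled by cubic
interpolation before filtering.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .dataset import META_COLUMNS, FeatureDataset
from .kinematics import BLOCKS, GROUPS, MARKERS, TrialTrajectory

TRAJECTORY_COLUMNS = ("subject", "group", "block", "trial", "frame", "marker", "x", "y", "z")

#: exclusion thresholds for poor marker reconstruction
MAX_MISSING_FRACTION = 0.10
MAX_GAP_S = 0.10


@dataclass
class ExclusionLog:
    """Trials dropped by the reader, with the reason for each."""

    excluded: list[dict] = field(default_factory=list)

    def add(self, subject: str, block: str, trial: int, reason: str) -> None:
        self.excluded.append(
            {"subject": subject, "block": block, "trial": trial, "reason": reason}
        )

    def __len__(self) -> int:
        return len(self.excluded)


class FormatError(ValueError):
    """Input file violates the declared on-disk dialect."""


def read_trajectories(
    path: str | Path, fs_hz: float = 100.0
) -> tuple[list[TrialTrajectory], ExclusionLog]:
    """Read a long-format trajectory CSV into per-trial marker arrays.

    Returns one :class:`TrialTrajectory` per (subject, block, trial) that
    passes reconstruction quality control, plus an :class:`ExclusionLog`
    of dropped trials. Never drops rows silently.
    """
    df = pd.read_csv(path, dtype={"subject": str})
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"trajectory file missing required column(s): {missing}")

    unknown_markers = set(df["marker"].unique()) - set(MARKERS)
    if unknown_markers:
        raise FormatError(f"unknown marker name(s): {sorted(unknown_markers)}")
    unknown_groups = set(df["group"].unique()) - set(GROUPS)
    if unknown_groups:
        raise FormatError(f"unknown group label(s): {sorted(unknown_groups)}")
    unknown_blocks = set(df["block"].unique()) - set(BLOCKS)
    if unknown_blocks:
        raise FormatError(f"unknown block name(s): {sorted(unknown_blocks)}")

    by_subject = df.groupby("subject")["group"].nunique()
    if (by_subject > 1).any():
        raise FormatError(
            f"group not constant within subject(s): {by_subject[by_subject > 1].index.tolist()}"
        )

    trials: list[TrialTrajectory] = []
    log = ExclusionLog()
    max_gap_frames = int(round(MAX_GAP_S * fs_hz))
    for (subject, group, block, trial), sub in df.groupby(
        ["subject", "group", "block", "trial"], sort=True
    ):
        n_frames = int(sub["frame"].max()) + 1
        markers: dict[str, np.ndarray] = {}
        reason = None
        for name in MARKERS:
            rows = sub[sub["marker"] == name]
            if rows["frame"].duplicated().any():
                raise FormatError(
                    f"duplicate (frame, marker) rows for marker {name!r} in "
                    f"subject={subject} block={block} trial={trial}"
                )
            present = rows["frame"].to_numpy(dtype=int)
            n_missing = n_frames - len(present)
            if n_missing > MAX_MISSING_FRACTION * n_frames:
                reason = (
                    f"poor reconstruction: marker {name!r} missing on "
                    f"{n_missing}/{n_frames} frames"
                )
                break
            gap = _longest_gap(present, n_frames)
            if gap > max_gap_frames:
                reason = (
                    f"poor reconstruction: marker {name!r} has a "
                    f"{gap * 1000 / fs_hz:.0f} ms gap"
                )
                break
            xyz = rows[["x", "y", "z"]].to_numpy(dtype=float)
            markers[name] = _fill_gaps(present, xyz, n_frames)
        if reason is not None:
            log.add(subject, block, int(trial), reason)
            continue
        trials.append(
            TrialTrajectory(
                subject_id=subject,
                group=group,
                block=block,
                trial=int(trial),
                markers=markers,
                fs_hz=fs_hz,
            )
        )
    return trials, log


def _longest_gap(present: np.ndarray, n_frames: int) -> int:
    """Longest run of consecutive missing frames for one marker."""
    mask = np.zeros(n_frames, dtype=bool)
    mask[present] = True
    longest = run = 0
    for ok in mask:
        run = 0 if ok else run + 1
        longest = max(longest, run)
    return longest


def _fill_gaps(present: np.ndarray, xyz: np.ndarray, n_frames: int) -> np.ndarray:
    if len(present) == n_frames:
        return xyz
    order = np.argsort(present)
    spline = CubicSpline(present[order], xyz[order], axis=0)
    return spline(np.arange(n_frames))


def write_trajectories(trials: list[TrialTrajectory], path: str | Path) -> None:
    """Write trials in the long-format trajectory dialect."""
    rows = []
    for t in trials:
        for name in MARKERS:
            arr = t.markers[name]
            for frame in range(arr.shape[0]):
                rows.append(
                    (t.subject_id, t.group, t.block, t.trial, frame, name, *arr[frame])
                )
    pd.DataFrame(rows, columns=list(TRAJECTORY_COLUMNS)).to_csv(
        path, index=False, float_format="%.17g"
    )


# -- feature tables --------------------------------------------------------

def write_features(dataset: FeatureDataset, path: str | Path) -> None:
    """Write a feature table losslessly (17 significant digits)."""
    lengths = {len(dataset.feature_columns)}
    if not lengths:
        raise FormatError("feature table has no feature columns")
    dataset.frame.to_csv(path, index=False, float_format="%.17g")


def read_features(path: str | Path) -> tuple[FeatureDataset, np.ndarray]:
    """Read a feature table; returns the dataset and a per-row NaN flag.

    NaN feature values survive the round trip and are flagged on read so
    the caller decides whether to drop or repair them.
    """
    df = pd.read_csv(path, dtype={"subject": str})
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"feature file missing required column(s): {missing}")
    ds = FeatureDataset(df)
    feats = ds.features
    nan_flags = (
        ~np.isfinite(feats).all(axis=1) if feats.size else np.zeros(len(df), dtype=bool)
    )
    return ds, nan_flags


# -- result bundles --------------------------------------------------------

def write_results(bundle: dict, path: str | Path) -> None:
    """Serialize an experiment result bundle to JSON.

    Rejects non-finite metric values so a silent NaN never reaches disk.
    """
    _check_finite(bundle, "bundle")
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(bundle, fh, indent=2, default=_to_jsonable)


def read_results(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def _check_finite(obj, keypath: str) -> None:
    if isinstance(obj, dict):
        for k, v in obj.items():
            _check_finite(v, f"{keypath}.{k}")
    elif isinstance(obj, (list, tuple, np.ndarray)):
        for i, v in enumerate(obj):
            _check_finite(v, f"{keypath}[{i}]")
    elif isinstance(obj, (float, np.floating)) and not math.isfinite(obj):
        raise ValueError(f"non-finite metric at {keypath}")


def _to_jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"cannot serialize {type(obj)!r}")
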