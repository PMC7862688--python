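"""Synthetic reach-to-grasp generator with hierarchical structure.

Generates marker-level movement datasets whose statistical structure
mirrors what the classification analyses assume about real prospective
grasping data:

* **subject signatures** -- per-subject random effects on duration,
  amplitude, peak-speed timing, peak aperture, aperture timing and wrist
  arc height, consistent across that subject's trials;
* **group effect** -- a shift in the temporal setting of the wrist-speed
  landmarks (ASD-like profiles reach peak speed, and hence peak
  deceleration, later in the movement);
* **intention modulation** -- per-intention offsets on peak aperture,
  duration and landmark timing, so the onward action (place, pour, pass)
  is decodable from the reach;
* **trial noise** -- within-subject parameter jitter plus isotropic
  Gaussian marker measurement noise.

The wrist transport is a minimum-jerk-family profile: the speed curve is
a beta-shaped bell v(tau) proportional to tau^(a-1) (1-tau)^(b-1) with
a + b = 6, whose mode is placed at the subject's landmark fraction c via
a = 1 + 4c, b = 5 - 4c. At c = 0.5 this is exactly the minimum-jerk
speed profile 30 d tau^2 (1-tau)^2 / T with peak 15 d / (8 T), giving
closed-form oracles for the extraction pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import betainc

from .dataset import FeatureDataset
from .kinematics import (
    BLOCK_INTENTION,
    BLOCKS,
    FS_HZ,
    MARKERS,
    TrialTrajectory,
    extract_profile,
    feature_names,
)

#: generative parameters that carry subject and trial random effects
PARAM_NAMES = (
    "duration",
    "amplitude",
    "timing",
    "aperture",
    "aperture_timing",
    "height",
    "rest_aperture",
    "base_height",
)

_DEFAULT_SUBJECT_SD = {
    "duration": 0.08,  # s
    "amplitude": 15.0,  # mm
    "timing": 0.02,  # fraction of duration
    "aperture": 8.0,  # mm
    "aperture_timing": 0.02,  # fraction
    "height": 6.0,  # mm
    "rest_aperture": 4.0,  # mm (hand-size signature)
    "base_height": 10.0,  # mm (posture signature)
}

_DEFAULT_INTENTION_EFFECTS = {
    "place": {"aperture": 0.0, "duration": 0.0, "timing": 0.0},
    "pour": {"aperture": -10.0, "duration": 0.08, "timing": -0.01},
    "pass": {"aperture": 10.0, "duration": -0.04, "timing": 0.02},
}

#: rigid marker offsets from the wrist (mm); thumb/index_tip are placed
#: symmetrically about the grasp point so their distance equals the
#: aperture curve exactly.
_MARKER_OFFSETS = {
    "index_mcp": (15.0, 60.0, 10.0),
    "little_mcp": (-25.0, 55.0, 5.0),
    "little_tip": (-30.0, 90.0, 5.0),
    "wrist": (0.0, 0.0, 0.0),
    "dorsum": (-5.0, 35.0, 12.0),
    "hand_ref": (5.0, 20.0, 20.0),
}
_GRASP_POINT = (20.0, 95.0, 0.0)  # midpoint between thumb and index tip


@dataclass
class GeneratorConfig:
    """Study-design and effect-size parameters of the generator.

    Defaults reproduce the study design: 20 subjects per group, 4 blocks
    (place, pour, pass x2) of 10 trials, a 440 mm reach, and a small
    ASD-later timing shift with between-subject parameter variability ten
    times the trial-to-trial variability (the identity-signature regime).
    """

    n_per_group: int = 20
    blocks: tuple[str, ...] = BLOCKS
    trials_per_block: int = 10
    reach_amplitude: float = 440.0  # mm
    mean_duration: float = 1.0  # s
    mean_timing: float = 0.5  # fraction of duration at peak wrist speed
    mean_aperture: float = 85.0  # mm peak grip aperture
    rest_aperture: float = 30.0  # mm
    mean_aperture_timing: float = 0.7  # fraction at peak aperture
    mean_height: float = 30.0  # mm wrist arc amplitude
    group_timing_shift: float = 0.05  # ASD peak landmarks later by this fraction
    group_effect_intentions: tuple[str, ...] = ("place", "pour", "pass")
    intention_effects: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_INTENTION_EFFECTS.items()}
    )
    subject_sd: dict = field(default_factory=lambda: dict(_DEFAULT_SUBJECT_SD))
    trial_sd: dict = field(
        default_factory=lambda: {k: v / 10.0 for k, v in _DEFAULT_SUBJECT_SD.items()}
    )
    measurement_noise_mm: float = 0.5
    pad_s: float = 0.4  # stationary rest before and after the movement
    fs_hz: float = FS_HZ
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 1 or self.trials_per_block < 1:
            raise ValueError("n_per_group and trials_per_block must be >= 1")
        if not -0.3 < self.group_timing_shift < 0.3:
            raise ValueError("group_timing_shift must lie in (-0.3, 0.3)")
        for name, table in (("subject_sd", self.subject_sd), ("trial_sd", self.trial_sd)):
            for key, value in table.items():
                if value < 0:
                    raise ValueError(f"{name}[{key!r}] is negative")
        if self.mean_duration <= 0 or self.reach_amplitude <= 0:
            raise ValueError("mean_duration and reach_amplitude must be positive")
        if self.measurement_noise_mm < 0:
            raise ValueError("measurement_noise_mm must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["blocks"] = list(self.blocks)
        d["group_effect_intentions"] = list(self.group_effect_intentions)
        return d


@dataclass
class SubjectParams:
    """One subject's idiosyncratic generative parameters (the identity signature)."""

    subject_id: str
    group: str
    params: dict[str, float]

    def __post_init__(self) -> None:
        if self.params["duration"] <= 0:
            raise ValueError("subject duration must be positive")
        if self.params["amplitude"] <= 0:
            raise ValueError("subject amplitude must be positive")


def sample_subjects(config: GeneratorConfig, rng: np.random.Generator) -> list[SubjectParams]:
    """Draw per-subject parameters: population mean + independent Gaussian random effects.

    The group timing shift is stored per subject but applied per trial,
    only to intentions listed in ``config.group_effect_intentions``.
    """
    config.validate()
    means = {
        "duration": config.mean_duration,
        "amplitude": config.reach_amplitude,
        "timing": config.mean_timing,
        "aperture": config.mean_aperture,
        "aperture_timing": config.mean_aperture_timing,
        "height": config.mean_height,
        "rest_aperture": config.rest_aperture,
        "base_height": 0.0,
    }
    subjects = []
    for group in ("ASD", "TD"):
        for i in range(config.n_per_group):
            params = {
                name: means[name] + rng.normal(0.0, config.subject_sd.get(name, 0.0))
                for name in PARAM_NAMES
            }
            params["duration"] = max(params["duration"], 0.3)
            params["amplitude"] = max(params["amplitude"], 50.0)
            subjects.append(
                SubjectParams(subject_id=f"{group}{i + 1:02d}", group=group, params=params)
            )
    return subjects


def _beta_bump(tau: np.ndarray, mode: float) -> np.ndarray:
    """Unit-peak beta-shaped bump with the given mode, a + b = 6."""
    a = 1.0 + 4.0 * mode
    b = 5.0 - 4.0 * mode
    log_peak = (a - 1) * np.log(mode) + (b - 1) * np.log(1 - mode)
    with np.errstate(divide="ignore", invalid="ignore"):
        logv = (a - 1) * np.log(tau) + (b - 1) * np.log(1 - tau) - log_peak
    out = np.exp(logv)
    out[(tau <= 0) | (tau >= 1)] = 0.0
    return out


def generate_trial(
    subject: SubjectParams,
    block: str,
    trial: int,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> TrialTrajectory:
    """Simulate one reach-to-grasp trial of a subject.

    Wrist transport follows the beta-bell speed profile with the trial's
    landmark fraction; grip aperture opens and closes along a unit-peak
    bump; the wrist arcs vertically; the full marker cloud rides rigidly
    on the wrist with thumb/index separation equal to the aperture curve;
    stationary rest padding surrounds the movement so onset and offset
    detection is exercised; i.i.d. Gaussian jitter is added per frame.
    """
    intention = BLOCK_INTENTION[block]
    effects = config.intention_effects.get(intention, {})
    p = {
        name: subject.params[name] + rng.normal(0.0, config.trial_sd.get(name, 0.0))
        for name in PARAM_NAMES
    }
    p["duration"] += effects.get("duration", 0.0)
    p["aperture"] += effects.get("aperture", 0.0)
    p["timing"] += effects.get("timing", 0.0)
    if subject.group == "ASD" and intention in config.group_effect_intentions:
        p["timing"] += config.group_timing_shift
    duration = max(p["duration"], 0.3)
    timing = float(np.clip(p["timing"], 0.15, 0.85))
    ap_timing = float(np.clip(p["aperture_timing"], 0.2, 0.95))
    rest_aperture = max(p["rest_aperture"], 10.0)
    peak_aperture = max(p["aperture"], rest_aperture + 5.0)

    dt = 1.0 / config.fs_hz
    n_pad = int(round(config.pad_s * config.fs_hz))
    n_move = int(round(duration * config.fs_hz))
    n_frames = 2 * n_pad + n_move + 1
    t = np.arange(n_frames) * dt
    tau = np.clip((t - config.pad_s) / duration, 0.0, 1.0)

    # forward progress = regularized incomplete beta (integral of the speed bell)
    a = 1.0 + 4.0 * timing
    b = 5.0 - 4.0 * timing
    y = p["amplitude"] * betainc(a, b, tau)
    z = p["base_height"] + p["height"] * np.sin(np.pi * tau)
    x = np.zeros(n_frames)
    wrist = np.column_stack([x, y, z])

    aperture = rest_aperture + (peak_aperture - rest_aperture) * _beta_bump(tau, ap_timing)

    markers: dict[str, np.ndarray] = {}
    for name, off in _MARKER_OFFSETS.items():
        markers[name] = wrist + np.asarray(off)
    grasp = wrist + np.asarray(_GRASP_POINT)
    half = np.column_stack([aperture / 2.0, np.zeros(n_frames), np.zeros(n_frames)])
    markers["thumb"] = grasp - half
    markers["index_tip"] = grasp + half

    if config.measurement_noise_mm > 0:
        for name in MARKERS:
            markers[name] = markers[name] + rng.normal(
                0.0, config.measurement_noise_mm, size=(n_frames, 3)
            )

    return TrialTrajectory(
        subject_id=subject.subject_id,
        group=subject.group,
        block=block,
        trial=trial,
        markers={name: markers[name] for name in MARKERS},
        fs_hz=config.fs_hz,
    )


def generate_dataset(
    config: GeneratorConfig, return_trajectories: bool = False
) -> FeatureDataset | tuple[list[TrialTrajectory], FeatureDataset]:
    """Full factorial dataset: subjects x blocks x trials, with extracted features.

    With the default design this yields 2 x 20 subjects x 4 blocks x 10
    trials = 1600 movements. Features come through the same extraction
    pipeline used for recorded data, so generator effects are measured,
    not copied, into the feature table.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    subjects = sample_subjects(config, rng)
    names = feature_names()
    rows = []
    trajectories: list[TrialTrajectory] = []
    for subject in subjects:
        for block in config.blocks:
            for trial in range(1, config.trials_per_block + 1):
                traj = generate_trial(subject, block, trial, config, rng)
                if return_trajectories:
                    trajectories.append(traj)
                profile = extract_profile(traj)
                rows.append(
                    {
                        "subject": subject.subject_id,
                        "group": subject.group,
                        "block": block,
                        "trial": trial,
                        "intention": traj.intention,
                        **dict(zip(names, profile.flatten())),
                    }
                )
    dataset = FeatureDataset(pd.DataFrame(rows))
    if return_trajectories:
        return trajectories, dataset
    return dataset


def minimum_jerk_peak_speed(amplitude_mm: float, duration_s: float) -> float:
    """Closed-form peak speed 15 d / (8 T) of a minimum-jerk reach."""
    return 15.0 * amplitude_mm / (8.0 * duration_s)
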