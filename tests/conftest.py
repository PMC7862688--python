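"""Shared fixtures: small synthetic datasets and toy feature tables."""

import matplotlib

matplotlib.use("Agg")

import numpy as np
import pandas as pd
import pytest

from prograsp.dataset import FeatureDataset
from prograsp.kinematics import feature_names
from prograsp.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def full_default_dataset():
    """The full study design (40 subjects x 40 records) at generator defaults."""
    return generate_dataset(GeneratorConfig(seed=97))


@pytest.fixture(scope="session")
def small_dataset():
    """8 subjects x 16 records through the full generator + extraction pipeline."""
    cfg = GeneratorConfig(n_per_group=4, trials_per_block=4, seed=11)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def signature_dataset():
    """Identity-signature regime with zero group effect (8 subjects x 16 records)."""
    cfg = GeneratorConfig(n_per_group=4, trials_per_block=4, seed=13, group_timing_shift=0.0)
    return generate_dataset(cfg)


def make_toy_features(
    n_per_group=10,
    records_per_subject=4,
    separation=4.0,
    subject_scatter=0.0,
    n_features=6,
    seed=0,
):
    """Gaussian feature table: group mean shift +/- separation/2 on feature 0."""
    rng = np.random.default_rng(seed)
    names = feature_names()[:n_features]
    rows = []
    for group, sign in (("ASD", 1.0), ("TD", -1.0)):
        for i in range(n_per_group):
            center = rng.normal(0, subject_scatter, n_features)
            center[0] += sign * separation / 2.0
            for t in range(records_per_subject):
                feats = center + rng.normal(0, 0.5, n_features)
                rows.append(
                    {
                        "subject": f"{group}{i:02d}",
                        "group": group,
                        "block": "place",
                        "trial": t + 1,
                        "intention": "place",
                        **dict(zip(names, feats)),
                    }
                )
    return FeatureDataset(pd.DataFrame(rows))


@pytest.fixture
def toy_features():
    return make_toy_features()
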