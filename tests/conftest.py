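"""Shared fixtures: small synthetic cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from ncscreen.expression_io import split_samples
from ncscreen.stability_select import StabilityParams, select_stable_features
from ncscreen.synthetic_data import SyntheticConfig, generate_cohort

PLANTED_CONFIG = SyntheticConfig(
    n_classes=2,
    samples_per_class=(50, 50, 50),
    n_features=200,
    n_informative=10,
    effect_size=3.0,
    seed=7,
)

NOISE_CONFIG = SyntheticConfig(
    n_classes=2,
    samples_per_class=(50, 50, 50),
    n_features=200,
    n_informative=10,
    effect_size=0.0,
    seed=7,
)


@pytest.fixture(scope="session")
def planted_cohort():
    """Three-class cohort (normal + 2 cancer types) with 10 strong markers."""
    matrix, labels, truth = generate_cohort(PLANTED_CONFIG)
    return matrix, np.asarray(labels), truth


@pytest.fixture(scope="session")
def noise_cohort():
    """Same layout with effect_size 0: no feature carries signal."""
    matrix, labels, truth = generate_cohort(NOISE_CONFIG)
    return matrix, np.asarray(labels), truth


@pytest.fixture(scope="session")
def planted_panel(planted_cohort):
    """Frequency-ranked panel from a quick stability-selection run."""
    matrix, labels, _ = planted_cohort
    panel, counts = select_stable_features(
        matrix, labels, StabilityParams(m=2, n=20, seed=1)
    )
    return panel, counts


@pytest.fixture(scope="session")
def planted_split(planted_cohort):
    matrix, _, _ = planted_cohort
    return split_samples(matrix.n_samples, seed=3)
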