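"""Shared fixtures: small deterministic signals and cached synthetic cohorts.

Cohort-level fixtures are session-scoped because simulation plus
detection of a 35-min recording takes about a second per patient and
several acceptance checks share the same cohorts.
"""
from __future__ import annotations

import numpy as np
import pytest

from alphawatch.config import PipelineConfig
from alphawatch.pipeline import patient_features
from alphawatch.synthetic import IES_GROUP, NO_IES_GROUP, generate_patient


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig()


def sine(freq: float, fs: float = 64.0, duration: float = 20.0, amp: float = 1.0):
    t = np.arange(0.0, duration, 1.0 / fs)
    return amp * np.sin(2 * np.pi * freq * t)


@pytest.fixture(scope="session")
def ies_cohort():
    """15 IES-group patients (features + ground truth), seeds 1-15."""
    out = []
    for seed in range(1, 16):
        rec, truth = generate_patient(IES_GROUP, seed=seed)
        out.append((patient_features(rec), truth))
    return out


@pytest.fixture(scope="session")
def no_ies_cohort():
    """15 noIES-group patients (features + ground truth), seeds 16-30."""
    out = []
    for seed in range(16, 31):
        rec, truth = generate_patient(NO_IES_GROUP, seed=seed)
        out.append((patient_features(rec), truth))
    return out


@pytest.fixture(scope="session")
def ies_cohort_20():
    """20 IES-group patients (features + ground truth), seeds 31-50."""
    out = []
    for seed in range(31, 51):
        rec, truth = generate_patient(IES_GROUP, seed=seed)
        out.append((patient_features(rec), truth))
    return out
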