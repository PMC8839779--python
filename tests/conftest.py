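"""Shared fixtures: synthetic cohorts at two scales.

``small_table`` (5 subjects, reduced frame size and physio rate) keeps the
structural and statistical tests fast; ``default_table`` is the full
19-subject cohort under the default stress-effect preset, shared by the
classifier-level tests.  Both are session-scoped: the cohorts are generated
once per run.
"""

from __future__ import annotations

import numpy as np
import pytest

from thermostress.classify import FeatureTable
from thermostress.pipeline import compute_feature_table
from thermostress.synthgen import CohortConfig


def small_config(**overrides) -> CohortConfig:
    kwargs = dict(
        n_subjects=5,
        session_duration_s=180.0,
        fs_thermal=5.0,
        fs_physio=100.0,
        frame_size=(48, 48),
        seed=11,
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


@pytest.fixture(scope="session")
def small_cfg() -> CohortConfig:
    return small_config()


@pytest.fixture(scope="session")
def small_table(small_cfg) -> FeatureTable:
    return compute_feature_table(small_cfg)


@pytest.fixture(scope="session")
def default_cfg() -> CohortConfig:
    return CohortConfig(n_subjects=19, seed=0)


@pytest.fixture(scope="session")
def default_table(default_cfg) -> FeatureTable:
    """Feature table of the full default-preset cohort (19 subjects)."""
    return compute_feature_table(default_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
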