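"""Shared fixtures: small simulated cohorts reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from polyverify.features import build_feature_table
from polyverify.model import TrainConfig, screening_covariates, train_two_level
from polyverify.simulate import SimConfig, simulate_cohort

TINY_TOPICS = ("drug_abuse", "corruption", "debt")


def tiny_config(**overrides) -> SimConfig:
    """A small but fully structured cohort: 3 topics, 2 tests, 2x2 questions."""
    kwargs = dict(
        n_screenings=12,
        topics=TINY_TOPICS,
        tests_per_screening=2,
        questions_per_topic_per_test=2,
        repetitions_per_question=2,
        deception_prevalence=0.3,
        effect_size=2.0,
        seed=42,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


def micro_config(**overrides) -> SimConfig:
    """The smallest legal screening: 1 test, 2 topics, 1 question, 1 repetition."""
    kwargs = dict(
        n_screenings=1,
        topics=("drug_abuse", "corruption"),
        tests_per_screening=1,
        questions_per_topic_per_test=1,
        repetitions_per_question=1,
        deception_prevalence=0.3,
        effect_size=1.0,
        seed=0,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def tiny_cohort():
    return simulate_cohort(tiny_config())


@pytest.fixture(scope="session")
def tiny_rows(tiny_cohort):
    screenings, _, _ = tiny_cohort
    return build_feature_table(screenings)


@pytest.fixture(scope="session")
def tiny_cov(tiny_cohort):
    screenings, _, alt = tiny_cohort
    return screening_covariates(screenings, alt)


@pytest.fixture(scope="session")
def tiny_results(tiny_rows, tiny_cov):
    return train_two_level(tiny_rows, tiny_cov, config=TrainConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
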