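"""Shared fixtures: small synthetic participants, trials and tasks."""

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import affectloop as al
from affectloop import metalearn as ml

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

FS = 100.0


@pytest.fixture(scope="session")
def participant():
    return al.sample_participant(al.PopulationPrior(), seed=7, participant_id="sub-t")


@pytest.fixture(scope="session")
def trial(participant):
    return al.generate_trial(
        participant, al.EmotionPoint(0.75, 0.25), fs=FS, seed=11
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Two participants x 25 pieces: smallest setup that can exercise
    support/query splits (support_size=20 needs > 20 pieces)."""
    return al.build_cohort(2, "train25", fs=FS, seed=3)


@pytest.fixture(scope="session")
def small_tasks(small_cohort):
    return [ml.featurize_task(t) for t in small_cohort]
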