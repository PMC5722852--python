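"""Shared fixtures: small seeded synthetic sessions.

All fixtures are generated programmatically; nothing is loaded from disk.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import neckernet as nn

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: Effect amplitude (uV) of the strongly separable condition: large enough
#: that the biphasic component dominates single-trial background noise.
STRONG_EFFECT = 40.0


@pytest.fixture(scope="session")
def small_profile() -> nn.SubjectProfile:
    return nn.generate_subject_profile(11, 1)


@pytest.fixture(scope="session")
def small_session(small_profile):
    """40-trial button-design session with EOG artifacts (fs = 250 Hz)."""
    rec, events = nn.generate_session(small_profile, 40)
    rec = nn.inject_eog(rec, small_profile)
    return rec, events


@pytest.fixture(scope="session")
def clean_session(small_profile):
    """40-trial session without EOG artifacts."""
    return nn.generate_session(small_profile, 40)


@pytest.fixture(scope="session")
def small_trials(small_session):
    rec, events = small_session
    return nn.preprocess_session(rec, events)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250925)
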