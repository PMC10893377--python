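"""Shared fixtures: synthetic sessions generated once per test run."""

import dataclasses

import numpy as np
import pytest
from hypothesis import settings

from earval.synthetic import SessionSpec, generate_session

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def aep_session():
    """Full 200-trial auditory evoked potential session, seed 4."""
    return generate_session(SessionSpec("aep", seed=4))


@pytest.fixture(scope="session")
def aep_session_clean():
    """Same timing as :func:`aep_session` but with zero noise."""
    spec = SessionSpec("aep", seed=4)
    spec = dataclasses.replace(
        spec, effect=dataclasses.replace(spec.effect, noise_rms_uv=0.0))
    return generate_session(spec)


@pytest.fixture(scope="session")
def alpha_session():
    return generate_session(SessionSpec("alpha_block", seed=2))


@pytest.fixture(scope="session")
def assr_session():
    return generate_session(SessionSpec("assr", seed=3))


@pytest.fixture(scope="session")
def ssvep_session():
    return generate_session(SessionSpec("ssvep", seed=7))


@pytest.fixture(scope="session")
def eog_session():
    return generate_session(SessionSpec("eog", seed=6))


@pytest.fixture(scope="session")
def eog_session_quiet():
    """EOG session with low background noise, for projection-geometry
    checks of the small (1-5 µV) saccade steps."""
    spec = SessionSpec("eog", seed=11)
    spec = dataclasses.replace(
        spec, effect=dataclasses.replace(spec.effect, noise_rms_uv=2.0))
    return generate_session(spec)


@pytest.fixture(scope="session")
def oddball_session():
    return generate_session(SessionSpec("aep_oddball", seed=8))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
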