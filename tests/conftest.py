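import numpy as np
import pytest

from placeseq.session import MazeConfig
from placeseq.synthetic import GeneratorSpec, generate_run_session, generate_sleep_session, make_session_set


@pytest.fixture(scope="session")
def small_day():
    """A compact 8-session synthetic day shared by integration tests."""
    spec = GeneratorSpec(n_units=25, n_laps=4, sleep_duration_s=120, seed=1)
    sset, truth = make_session_set(spec)
    return spec, sset, truth


@pytest.fixture(scope="session")
def run_session():
    """One run session with single-field units (clean precession geometry)."""
    spec = GeneratorSpec(n_units=20, fields_per_unit=1, n_laps=6, seed=2)
    sess, gt = generate_run_session(spec, MazeConfig(), "Run1")
    return spec, sess, gt


@pytest.fixture(scope="session")
def sleep_session():
    """One sleep session with injected template frames."""
    spec = GeneratorSpec(n_units=25, sleep_duration_s=300, seed=4)
    sess, gt = generate_sleep_session(spec)
    return spec, sess, gt


@pytest.fixture
def rng():
    return np.random.default_rng(0)
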