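import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from thermarousal import (FilterConfig, LandmarkScheme, SyntheticScenario,
                          align_streams, simulate_participant)
from thermarousal.synthetic import _face_template


@pytest.fixture(scope="session")
def scheme():
    return LandmarkScheme()


@pytest.fixture(scope="session")
def template_face(scheme):
    """Neutral upright 106-point landmark frame."""
    return _face_template(scheme)


@pytest.fixture(scope="session")
def short_participant():
    """One quiet 30-second participant with a single mid-track episode."""
    scn = SyntheticScenario(duration_s=30.0, n_episodes=1,
                            episode_duration_s=(8.0, 10.0),
                            refractory_s=1.0, seed=11)
    return scn, simulate_participant(scn, 0)


@pytest.fixture(scope="session")
def short_alignment(short_participant):
    scn, _ = short_participant
    return align_streams(scn.n_visible, scn.n_thermal)


@pytest.fixture
def filter_cfg():
    return FilterConfig()
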