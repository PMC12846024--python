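import pytest

from tactile_reject.models import train_bundle, split_trials
from tactile_reject.pipeline import RunConfig
from tactile_reject.preprocess import extract_trial_features
from tactile_reject.reject import decide_trials
from tactile_reject.synthetic_data import SessionSpec, generate_session


@pytest.fixture(scope="session")
def tiny_spec():
    """A fast-but-complete session: all three categories, 8 trials/motion."""
    return SessionSpec(trials_per_motion=8, rest_duration=6.0, seed=123)


@pytest.fixture(scope="session")
def tiny_recording(tiny_spec):
    return generate_session(tiny_spec, session_id="T1")


@pytest.fixture(scope="session")
def tiny_features(tiny_recording):
    return extract_trial_features(tiny_recording)


@pytest.fixture(scope="session")
def tiny_split(tiny_features):
    return split_trials(tiny_features, fraction=0.5, seed=1)


@pytest.fixture(scope="session")
def tiny_bundle(tiny_split):
    train, test = tiny_split
    return train_bundle(train, test)


@pytest.fixture(scope="session")
def tiny_decisions(tiny_bundle, tiny_split):
    _, test = tiny_split
    return decide_trials(tiny_bundle, test)


@pytest.fixture(scope="session")
def default_config():
    return RunConfig()
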