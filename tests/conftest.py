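import pytest
from hypothesis import settings

import eogspeller as eg

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")
from eogspeller.synthetic import TrialSpec

TOY_CORPUS = "ich bin hier. ich bin froh. du bist hier."


@pytest.fixture(scope="session")
def layout():
    return eg.default_layout()


@pytest.fixture(scope="session")
def corpus_model():
    return eg.default_corpus_model()


@pytest.fixture(scope="session")
def toy_model():
    return eg.build_model(eg.normalize_text(TOY_CORPUS))


def make_session_features(amplitude, seed, n_yes=10, n_no=10):
    """Generate one synthetic session and extract its feature vectors."""
    rec, labels = eg.generate_session(
        n_yes, n_no, TrialSpec(amplitude=amplitude), seed=seed)
    feats = [eg.trial_features(rec, tid) for tid in rec.trial_ids]
    return feats, labels


@pytest.fixture(scope="session")
def strong_model():
    """A validated model trained on a high-amplitude (200 µV) session."""
    feats, labels = make_session_features(200.0, seed=7)
    return eg.train_model(feats, labels, seed=7)
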