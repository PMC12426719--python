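import numpy as np
import pytest

from hypnodense import (
    FOUR_STAGE,
    FIVE_STAGE,
    AnalysisConfig,
    Hypnodensity,
    Hypnogram,
    osa_like,
    rbd_like,
    simulate_cohort,
)


@pytest.fixture
def four_stage():
    return FOUR_STAGE


@pytest.fixture
def five_stage():
    return FIVE_STAGE


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_prob_vector(rng, k=4):
    return rng.dirichlet(np.ones(k))


@pytest.fixture
def tiny_hypnogram():
    return Hypnogram.from_labels(["W", "W", "N1+N2", "N1+N2", "R"], FOUR_STAGE)


@pytest.fixture
def onehot_hypnodensity(tiny_hypnogram):
    probs = np.eye(4)[tiny_hypnogram.codes]
    return Hypnodensity(probs, FOUR_STAGE)


@pytest.fixture(scope="session")
def contrast_cohort():
    """Small two-group cohort with the default presets; shared across tests."""
    return simulate_cohort(
        {"rbd_like": rbd_like(), "osa_like": osa_like()},
        n_subjects=6,
        n_epochs=240,
        seed=42,
    )


@pytest.fixture
def default_config():
    return AnalysisConfig()
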