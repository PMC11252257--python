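import numpy as np
import pytest

from dissolvenn import (
    GeneratorConfig,
    TrainConfig,
    generate_study,
    reference_profile,
    study_table,
    train_lm,
)
from dissolvenn.profiles import example_predicted_profile


@pytest.fixture(scope="session")
def marketed_reference():
    """The packaged 10-point marketed-product reference profile."""
    return reference_profile()


@pytest.fixture(scope="session")
def optimized_prediction():
    """The packaged predicted profile of the optimized formulation."""
    return example_predicted_profile()


@pytest.fixture(scope="session")
def study_batches():
    """The 17 (batch_id, Formulation) pairs of the packaged study table."""
    return study_table()


@pytest.fixture(scope="session")
def default_study(study_batches):
    """One seeded synthetic dissolution study over the 17 batches."""
    cfg = GeneratorConfig(seed=1)
    return generate_study([f for _, f in study_batches], cfg)


@pytest.fixture(scope="session")
def trained_surrogate(default_study):
    """A 6-10-10 surrogate trained once and shared across tests."""
    return train_lm(default_study, TrainConfig(seed=1))
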