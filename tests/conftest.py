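"""Shared fixtures: small synthetic datasets and quickly trained task models.

Everything heavy is session-scoped so the expensive steps (descriptor
computation, model training) run once for the whole suite.
"""

import warnings

import pytest

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=FutureWarning)

from oximescreen.fixtures import FixtureSpec, generate_logbb_fixture, generate_sppo_fixture
from oximescreen.tasks import (
    assemble_bbb_dataset,
    assemble_reactivation_dataset,
    train_bbb_model,
    train_reactivation_model,
)

# compact settings for tests that need a trained model but not peak accuracy
FAST_TRAIN = dict(
    rs_sizes=(4, 9, 20),
    grid={"n_estimators": [300], "max_depth": [3], "learning_rate": [0.1]},
    cv=3,
)


@pytest.fixture(scope="session")
def small_spec():
    return FixtureSpec(seed=11, n_sppos=36, n_logbb=240, noise_rate=0.05)


@pytest.fixture(scope="session")
def sppo_fixture(small_spec):
    return generate_sppo_fixture(small_spec)


@pytest.fixture(scope="session")
def logbb_fixture(small_spec):
    return generate_logbb_fixture(small_spec)


@pytest.fixture(scope="session")
def reactivation_dataset(sppo_fixture):
    return assemble_reactivation_dataset(
        sppo_fixture.measurements, sppo_fixture.sppos, sppo_fixture.ops
    )


@pytest.fixture(scope="session")
def reactivation_result(reactivation_dataset):
    return train_reactivation_model(reactivation_dataset, seed=11, **FAST_TRAIN)


@pytest.fixture(scope="session")
def bbb_result(logbb_fixture):
    return train_bbb_model(assemble_bbb_dataset(logbb_fixture.table), seed=11, **FAST_TRAIN)
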