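import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from shapcompare import (
    ModelSpec,
    SyntheticConfig,
    generate_fingerprint_dataset,
    make_toy_game,
    split_trials,
    tune_and_train,
)

settings.register_profile(
    "ci",
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

FAST_RFC_GRID = {"min_samples_leaf": [1], "min_samples_split": [2], "n_estimators": [50]}


@pytest.fixture(scope="session")
def worked_game():
    """2-player game with hand-enumerated Shapley values (1.5, 2.5)."""
    return make_toy_game({(): 0.0, (0,): 1.0, (1,): 2.0, (0, 1): 4.0})


@pytest.fixture(scope="session")
def small_dataset():
    """Planted-signal dataset small enough for every downstream stage."""
    return generate_fingerprint_dataset(
        SyntheticConfig(
            n_per_class=40, n_features=24, n_informative=6,
            p_on_background=0.1, p_on_active=0.85, p_on_inactive=0.1, seed=11,
        )
    )


@pytest.fixture(scope="session")
def small_split(small_dataset):
    return split_trials(small_dataset.labels, n_trials=1, seed=3)[0]


@pytest.fixture(scope="session")
def trained_rfc(small_dataset, small_split):
    return tune_and_train(
        small_dataset.X(), small_dataset.labels, small_split,
        ModelSpec("RFC", grid=dict(FAST_RFC_GRID)), seed=7,
    )
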