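import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fermsense as fs

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fast_config() -> fs.PipelineConfig:
    """Small-budget pipeline config shared by the slower integration tests."""
    return fs.PipelineConfig(
        max_train_samples=40, pop_size=4, max_iter=5, cv_folds=2, seed=0
    )


@pytest.fixture(scope="session")
def small_study() -> fs.SyntheticStudy:
    return fs.make_multicondition_study(q_sources=2, seed=0)


@pytest.fixture(scope="session")
def small_ensemble(small_study, fast_config) -> fs.EnsembleModel:
    return fs.build_ensemble(small_study, fast_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
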