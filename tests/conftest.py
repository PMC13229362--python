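import numpy as np
import pytest

from seedpolish.seeds import GAConfig, SeedSet, SpacedSeed, ga_design
from seedpolish.synthetic import generate_genome


@pytest.fixture(scope="session")
def small_genome() -> str:
    return generate_genome(50_000, rng_seed=5)


@pytest.fixture(scope="session")
def seed_set_k21() -> SeedSet:
    return ga_design(21, 3, GAConfig(n_generations=40, rng_seed=0))


@pytest.fixture(scope="session")
def seed_set_k15() -> SeedSet:
    return ga_design(15, 3, GAConfig(n_generations=40, rng_seed=1))


@pytest.fixture(scope="session")
def tiny_model(small_genome, seed_set_k15):
    """A quickly trained classifier for pipeline-level tests (k=15)."""
    from seedpolish.model import ModelConfig, synthesize_training_set, train_model

    train_sets = [
        ga_design(15, 3, GAConfig(n_generations=40, rng_seed=s)) for s in (1, 2, 3, 4)
    ]
    ds = synthesize_training_set(
        [small_genome], train_sets, w=5, n_samples=2500, rng_seed=7
    )
    return train_model(ds, ModelConfig(n_epochs=8, rng_seed=0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
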