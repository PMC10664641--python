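import numpy as np
import pytest

from nichegoal import (
    AtomDistribution,
    BreedState,
    DesireProfile,
    Environment,
    GeneticParameters,
    InfluencingVariables,
    Niche,
    Subniche,
    Trait,
    TraitSpace,
)


def simple_env(**physical) -> Environment:
    """A minimal environment with a couple of named dimensions."""
    return Environment(
        DesireProfile(emotional={"companionship": 0.8}),
        InfluencingVariables(
            physical_env={"feed_quality": 1.0, **physical},
            market={"milk_price": 0.4},
        ),
    )


def random_genetics(rng: np.random.Generator, K: int) -> GeneticParameters:
    """Random SPD (G, P) pair with heritabilities strictly below 1."""
    A = rng.standard_normal((K, K))
    P = A @ A.T + K * np.eye(K)
    B = rng.standard_normal((K, K))
    G0 = B @ B.T + 0.1 * np.eye(K)
    c = 0.5 * float(np.min(np.diag(P) / np.diag(G0)))
    return GeneticParameters(G=c * G0, P=P)


@pytest.fixture
def env():
    return simple_env()


@pytest.fixture
def two_trait_state(env):
    traits = TraitSpace((
        Trait("yield", "production", "kg"),
        Trait("temperament", "behaviour", "score"),
    ))
    gen = GeneticParameters(
        G=np.array([[2.0, 0.3], [0.3, 1.0]]),
        P=np.array([[4.0, 0.5], [0.5, 2.0]]),
    )
    return BreedState(trait_space=traits, mu_c=np.array([10.0, 5.0]),
                      genetics=gen)


@pytest.fixture
def one_atom_niche(env):
    sub = Subniche("owners", AtomDistribution(((env, 1.0),)), size=100.0)
    return Niche(subniches=(sub,), producer_env=env)
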