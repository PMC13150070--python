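import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import medbo as mb

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def chain_spec():
    """2-nutrient toy: biomass demands (1, 2), asymmetric prices."""
    return mb.ToyGemSpec(
        n_nutrients=2,
        pathway_yields=(1.0, 2.0),
        prices=(1.0, 0.5),
        box_upper=(4.0, 4.0),
    )


@pytest.fixture(scope="session")
def chain_model(chain_spec):
    model, closed_form = mb.make_toy_gem(chain_spec)
    return model, closed_form


@pytest.fixture(scope="session")
def chain_medium(chain_spec):
    return mb.toy_medium_spec(chain_spec)


@pytest.fixture(scope="session")
def branch_spec():
    """Toy with a product branch competing for nutrient 0's pool."""
    return mb.ToyGemSpec(
        n_nutrients=2,
        pathway_yields=(1.0, 2.0),
        product_branch=(0, 1.0),
        prices=(1.0, 0.5),
        box_upper=(4.0, 4.0),
    )


@pytest.fixture(scope="session")
def branch_model(branch_spec):
    model, closed_form = mb.make_toy_gem(branch_spec)
    return model, closed_form


@pytest.fixture(scope="session")
def growth_objective(chain_model):
    model, _ = chain_model
    return mb.make_combined_objective(model, 1.0)


@pytest.fixture(scope="session")
def small_run(chain_model, chain_medium, growth_objective):
    """One small but complete optimization run, shared across tests."""
    model, _ = chain_model
    spec, prices = chain_medium
    config = mb.OptimizationConfig(n_init=8, n_iter=3, batch_size=2, seed=11)
    dataset = mb.run(model, spec, prices, growth_objective, ("growth", "cost"), config)
    return dataset, config


def brute_force_mask(Y):
    """Reference dominance check: explicit pairwise double loop."""
    Y = np.asarray(Y, float)
    n = Y.shape[0]
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if np.all(Y[j] >= Y[i]) and np.any(Y[j] > Y[i]):
                mask[i] = False
                break
    return mask
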