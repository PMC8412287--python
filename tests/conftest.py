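import numpy as np
import pytest

from surname_affinity import network, synthetic, tucker


@pytest.fixture(scope="session")
def small_params():
    # small endogamous population; filters loosened to its scale
    return synthetic.RegistryParams(
        n_individuals=5_000, n_surnames=120, n_blocks=80,
        endogamy=0.9, stratum_count=10, seed=11,
    )


@pytest.fixture(scope="session")
def small_records(small_params):
    return synthetic.sample_registry(small_params)


@pytest.fixture(scope="session")
def small_filter():
    return network.FilterParams(k_security=2.0, min_occurrence=5, kcore_k=2)


@pytest.fixture(scope="session")
def small_kg(small_records, small_filter):
    return network.build_kg(small_records, small_filter)


@pytest.fixture(scope="session")
def small_model(small_kg):
    """A lightly trained model over the small KG, shared by ranking and
    neighborhood tests that only need plausible (not converged) scores."""
    config = tucker.TrainConfig(
        d_e=12, d_r=6, epochs=30, dropouts=(0.0, 0.0, 0.0),
        batch_size=64, seed=5, eval_every=1000,
    )
    model, _ = tucker.train(
        small_kg.triplet_list(), config, relations=list(network.RELATIONS)
    )
    return model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_tucker_model(rng, n_e=6, n_r=3, d_e=4, d_r=3, named=True):
    return tucker.TuckerModel(
        E=rng.normal(0, 1, (n_e, d_e)),
        R=rng.normal(0, 1, (n_r, d_r)),
        W=rng.normal(0, 1, (d_e, d_r, d_e)),
        entities=[f"e{i}" for i in range(n_e)] if named else None,
        relations=[f"r{j}" for j in range(n_r)] if named else None,
    )
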