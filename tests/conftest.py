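import numpy as np
import pytest

from dropvae import DropoutVAE, SimConfig, simulate_counts
from dropvae.data_io import ExpressionMatrix

#: Seed of the shared benchmark scenario used by the heavier end-to-end tests.
BENCH_SEED = 101


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, layer="raw"):
    values = np.asarray(values)
    return ExpressionMatrix(
        values,
        [f"c{i}" for i in range(values.shape[0])],
        [f"g{j}" for j in range(values.shape[1])],
        layer=layer,
    )


@pytest.fixture(scope="session")
def bench_sim():
    """The benchmark simulation: 600x300, 4 clusters, 60% dropout."""
    return simulate_counts(SimConfig(seed=BENCH_SEED))


@pytest.fixture(scope="session")
def bench_fit(bench_sim):
    """Model trained once on the benchmark scenario; shared across tests."""
    model = DropoutVAE.from_counts(bench_sim.corrupted_matrix())
    results = model.fit(seed=BENCH_SEED)
    return model, results
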