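import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tripcausal as tc

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1_spec():
    return tc.table1_spec()


@pytest.fixture(scope="session")
def table1_dag(table1_spec):
    return tc.CausalDAG.from_weight_matrix(
        table1_spec.weights, table1_spec.nodes, categories=table1_spec.categories
    )


@pytest.fixture(scope="session")
def table1_trips(table1_spec):
    """One standardized-scale simulated table at the study's sample size."""
    return tc.simulate_trips(table1_spec, 1638, seed=42)


def standardized(df):
    out, _ = tc.standardize(df)
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
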