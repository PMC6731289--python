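import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from biogasnet.abundance import SAMPLE_INDEX_NAMES

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_frame(values, plants=None, features=None):
    """Samples x features abundance frame with a (plant, replicate) index."""
    values = np.asarray(values, dtype=float)
    n_samp, n_feat = values.shape
    if plants is None:
        plants = ["P1"] * n_samp
    reps = {}
    tuples = []
    for p in plants:
        reps[p] = reps.get(p, 0) + 1
        tuples.append((p, reps[p]))
    if features is None:
        features = [f"F{j}" for j in range(n_feat)]
    return pd.DataFrame(
        values,
        index=pd.MultiIndex.from_tuples(tuples, names=SAMPLE_INDEX_NAMES),
        columns=pd.Index(features, name="feature_id"),
    )


@pytest.fixture(scope="session")
def benchmark_dataset():
    """The default planted-structure benchmark (30 species, 40 replicates)."""
    from biogasnet import benchmark_network_config, simulate_dataset

    cfg = benchmark_network_config(seed=1)
    X, annotation, metadata, truth = simulate_dataset(cfg)
    return cfg, X, annotation, metadata, truth


@pytest.fixture(scope="session")
def benchmark_species_table(benchmark_dataset):
    from biogasnet.abundance import aggregate

    _, X, annotation, _, _ = benchmark_dataset
    return aggregate(X, annotation, level="species")


@pytest.fixture(scope="session")
def benchmark_network(benchmark_species_table):
    """Fitted co-occurrence network on the benchmark table (shared: ~10 s)."""
    from biogasnet import CooccurrenceNetwork

    return CooccurrenceNetwork(seed=1).fit(benchmark_species_table)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
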