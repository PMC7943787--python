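import numpy as np
import pandas as pd
import pytest

from abxtol import CountTable, ExperimentDesign, make_baseline_community, simulate_experiment


@pytest.fixture(scope="session")
def community():
    return make_baseline_community(n_taxa=100, seed=42)


@pytest.fixture(scope="session")
def mini_experiment():
    """Small but complete simulated study: counts, taxonomy, metadata, qpcr."""
    design = ExperimentDesign(n_treated=8, n_control=4, days=(0, 2, 4, 6),
                              window=(2, 6), nonresponder_frac=0.5,
                              collapse_magnitude=3.5, depth=5_000, seed=7)
    params = make_baseline_community(n_taxa=60, seed=7)
    return simulate_experiment(design, params)


@pytest.fixture()
def toy_table():
    return CountTable(pd.DataFrame(
        [[5, 3, 4], [10, 0, 20], [1, 1, 1]],
        index=["s1", "s2", "s3"], columns=["t1", "t2", "t3"]))


def random_count_table(rng: np.random.Generator, n_samples=6, n_taxa=8, max_count=50):
    data = rng.integers(0, max_count, size=(n_samples, n_taxa))
    return CountTable(pd.DataFrame(
        data, index=[f"s{i}" for i in range(n_samples)],
        columns=[f"t{j}" for j in range(n_taxa)]))
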