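import numpy as np
import pandas as pd
import pytest

from stagefx import synthetic as syn


@pytest.fixture(scope="session")
def small_config():
    return syn.SimulationConfig(n_genes=300, cohort_size=8, affected_fraction=0.05)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return syn.make_truth(small_config, seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_truth, small_config):
    counts, samples = syn.simulate_counts(small_truth, small_config)
    return counts, samples


@pytest.fixture(scope="session")
def small_genome(small_truth, small_config):
    return syn.simulate_genome(small_truth, small_config)


@pytest.fixture()
def toy_counts_tsv(tmp_path):
    path = tmp_path / "counts.tsv"
    df = pd.DataFrame(
        {"s1": [10, 0, 5], "s2": [2, 3, 7]},
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
    )
    df.to_csv(path, sep="\t")
    return path
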