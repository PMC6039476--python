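import numpy as np
import pandas as pd
import pytest

from cernet import SimulationConfig, simulate_dataset
from cernet.pipeline import PipelineInputs, run_pipeline


@pytest.fixture(scope="session")
def planted_dataset():
    """Default study conditions, seed 42: the planted-truth dataset used by
    every end-to-end check."""
    return simulate_dataset(SimulationConfig(rng_seed=42))


@pytest.fixture(scope="session")
def planted_result(planted_dataset):
    ds = planted_dataset
    inputs = PipelineInputs(
        counts=ds.counts,
        design=ds.design,
        mirna_seqs=ds.mirna_seqs,
        target_seqs=ds.target_seqs,
        annotation=ds.annotation,
        gene_sets=ds.gene_sets,
    )
    return run_pipeline(inputs)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rna(rng, length):
    return "".join(np.array(list("ACGU"))[rng.integers(0, 4, size=length)])


def random_dna(rng, length):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
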