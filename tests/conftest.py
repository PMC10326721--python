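import numpy as np
import pytest

from ribovb import (
    FitControl,
    PairedCountTable,
    SimulationConfig,
    build_design,
    fit,
    simulate,
)


def make_tiny_table(counts=None, n_genes=3):
    """Deterministic hand-built table: 2 conditions x 2 samples each."""
    if counts is None:
        rng = np.random.default_rng(123)
        counts = rng.poisson(20.0, size=(n_genes, 8))
    sample_ids = ["c1", "c2", "t1", "t2"]
    return PairedCountTable(
        gene_ids=[f"g{i}" for i in range(counts.shape[0])],
        counts=np.asarray(counts),
        sample_ids=sample_ids,
        condition={"c1": "control", "c2": "control",
                   "t1": "treatment", "t2": "treatment"},
        col_sample=[s for s in sample_ids for _ in range(2)],
        col_prep=["mRNA", "RPF"] * 4,
        reference="control",
    )


@pytest.fixture
def tiny_table():
    return make_tiny_table()


@pytest.fixture(scope="session")
def sim_a_small():
    """Scheme-A dataset small enough for fast unit tests."""
    return simulate(SimulationConfig(scheme="A_poisson", G=400, n=2, seed=7))


@pytest.fixture(scope="session")
def fit_a_small(sim_a_small):
    return fit(sim_a_small.table)


@pytest.fixture(scope="session")
def design_a_small(sim_a_small):
    return build_design(sim_a_small.table)
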