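import numpy as np
import pytest
from hypothesis import settings

import groseqtools as gt
from groseqtools.genome_io import ReadSet

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset() -> gt.SimDataset:
    """A fast, low-depth dataset for unit tests."""
    cfg = gt.SimConfig(
        seed=11,
        n_genes=60,
        genome_length=8_000_000,
        reads_per_sample=100_000,
        n_sites=40,
    )
    return gt.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def standard_dataset() -> gt.SimDataset:
    """The documented standard fixture: 500 genes, 10% planted at fold 6,
    dispersion 0.05, 2 replicates/condition, 1e6 reads/sample."""
    return gt.simulate_dataset(gt.SimConfig(seed=7))


@pytest.fixture(scope="session")
def standard_pooled(standard_dataset) -> ReadSet:
    """All samples of the standard fixture pooled (for depth-hungry indices)."""
    return ReadSet.pooled(list(standard_dataset.samples.values()))
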