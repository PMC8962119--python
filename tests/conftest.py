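import numpy as np
import pytest

from orchardqg.genotypes import GenotypeTable
from orchardqg.synthetic_data import default_truth, simulate_orchard


@pytest.fixture(scope="session")
def small_table() -> GenotypeTable:
    """Three individuals, two loci, one missing call."""
    return GenotypeTable(
        individuals=["a", "b", "c"],
        groups={"a": "PT", "b": "PT", "c": "HC"},
        loci=["L1", "L2"],
        calls={
            ("a", "L1"): (1, 1),
            ("a", "L2"): (2, 3),
            ("b", "L1"): (1, 2),
            ("b", "L2"): (3, 3),
            ("c", "L1"): (2, 2),
            ("c", "L2"): None,
        },
    )


@pytest.fixture(scope="session")
def orchard():
    """Paper-scale synthetic orchard: 60 mothers x 5 offspring, 7 loci."""
    truth = default_truth(seed=42)
    table, pedigree = simulate_orchard(truth)
    return truth, table, pedigree


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
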