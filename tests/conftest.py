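import numpy as np
import pytest

from cdpscreen.synthetic_data import SortSeqSimConfig


@pytest.fixture(scope="session")
def small_config() -> SortSeqSimConfig:
    """A scaled-down sort-seq simulation for fast unit tests."""
    return SortSeqSimConfig(
        n_peptides=300,
        total_cells=60_000,
        reads_per_gate=300_000,
        seed=11,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
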