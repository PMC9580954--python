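import numpy as np
import pandas as pd
import pytest

from asvembed.fixtures import CommunityModel, make_reference
from asvembed.io_formats import CountTable, SequenceSet


@pytest.fixture(scope="session")
def tiny_model() -> CommunityModel:
    return CommunityModel(n_blocks=2, taxa_per_block=5, seed=42)


@pytest.fixture(scope="session")
def tiny_reference(tiny_model):
    """10 taxa in 2 blocks, 80 samples — enough for alignment and
    embedding smoke paths without slowing the suite."""
    return make_reference(tiny_model, n_samples=80)


@pytest.fixture
def small_counts() -> CountTable:
    return CountTable(
        pd.DataFrame(
            [[3.0, 0.0, 1.0], [0.0, 2.0, 5.0]],
            index=["s1", "s2"],
            columns=["A", "B", "C"],
        )
    )


@pytest.fixture
def three_seqs() -> SequenceSet:
    return SequenceSet({"a": "ACGT", "b": "GGGTTT", "c": "ACGTACGTNN"})
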