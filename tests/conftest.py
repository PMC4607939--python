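import numpy as np
import pandas as pd
import pytest

from ecoturn.simulate import SimConfig, generate_dataset
from ecoturn.tables import CommunityTable


@pytest.fixture
def small_counts():
    """A tiny hand-built count table (3 OTUs x 3 samples)."""
    return pd.DataFrame(
        [[6, 2, 0], [2, 2, 0], [0, 2, 5]],
        index=["otuA", "otuB", "otuC"],
        columns=["s1", "s2", "s3"],
    )


@pytest.fixture
def small_table(small_counts):
    taxonomy = {
        "otuA": "k__Bacteria; p__Proteobacteria; c__Alpha; o__Rhodo; f__Rhodobacteraceae; g__; s__",
        "otuB": "k__Bacteria; p__Bacteroidetes; c__Flavo; o__Flavo; f__Flavobacteriaceae; g__; s__",
        "otuC": "k__Bacteria; p__Bacteroidetes",
    }
    return CommunityTable(small_counts, taxonomy)


@pytest.fixture(scope="session")
def tiny_sim():
    """A small two-site simulated dataset shared across tests."""
    cfg = SimConfig(n_otus_pool=80, n_sites=2, n_timepoints=4, n_replicates=2,
                    reads_per_sample=500, sampling_days=(1, 6, 60, 66), seed=7)
    return generate_dataset(cfg)
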