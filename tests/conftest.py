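import numpy as np
import pandas as pd
import pytest

from hermetia import synthetic as syn
from hermetia.community import AbundanceTable


@pytest.fixture(scope="session")
def trial():
    """One deterministic default feeding-trial simulation (noise-free)."""
    return syn.simulate_trial(seed=11)


@pytest.fixture(scope="session")
def gut_table():
    """Default gut community simulation, rarefied to the smallest sample."""
    from hermetia import community as cm

    meta = syn.default_gut_metadata()
    table = syn.simulate_communities(syn.CommunitySpec(seed=5), meta)
    return cm.rarefy(table, int(table.depths.min()), seed=5)


@pytest.fixture()
def tiny_table():
    """Hand-sized count table with two diet groups."""
    counts = pd.DataFrame(
        [[10, 0, 5], [8, 1, 4], [12, 0, 6],
         [0, 9, 2], [1, 11, 3], [0, 10, 2]],
        index=[f"s{i}" for i in range(6)],
        columns=["t1", "t2", "t3"],
    )
    meta = pd.DataFrame({"diet": ["A"] * 3 + ["B"] * 3,
                         "day": [2, 4, 6] * 2,
                         "replicate": [1, 2, 3] * 2},
                        index=counts.index)
    return AbundanceTable(counts, metadata=meta)


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """A written fixture bundle (shared across io/cli tests)."""
    out = tmp_path_factory.mktemp("bundle")
    return syn.make_fixture_bundle(seed=17, out_dir=out, n_taxa=40,
                                   depth_mean=3000.0)
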