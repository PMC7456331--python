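import dendropy
import numpy as np
import pytest

from metacom import (
    OtuTable,
    SampleDesign,
    SyntheticScenario,
    patristic_distances,
    simulate_metacommunity,
)
import pandas as pd


@pytest.fixture
def toy_table() -> OtuTable:
    """Two samples over three taxa; Bray-Curtis between them is exactly 0.5."""
    return OtuTable(
        ["t1", "t2", "t3"], ["s1", "s2"], np.array([[6, 2], [2, 2], [0, 4]])
    )


@pytest.fixture
def small_tree() -> dendropy.Tree:
    return dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick")


@pytest.fixture
def triangle_distances():
    """Hand-set patristic distances d(1,2)=2, d(1,3)=6, d(2,3)=4."""
    from metacom.phylo import PhyloDistances

    return PhyloDistances(
        ["x1", "x2", "x3"],
        np.array([[0.0, 2.0, 6.0], [2.0, 0.0, 4.0], [6.0, 4.0, 0.0]]),
    )


@pytest.fixture
def study_design() -> SampleDesign:
    """One system-day block shaped like the emulated study: 9 fish, 3 tank
    water, 3 incoming water and 3 feed samples."""
    rows = []
    for tank in (1, 2, 3):
        for rep in (1, 2, 3):
            rows.append((f"f{tank}{rep}", "fish", "FTS", str(tank), 8))
        rows.append((f"w{tank}", "tank_water", "FTS", str(tank), 8))
        rows.append((f"i{tank}", "incoming_water", "FTS", str(tank), 8))
        rows.append((f"d{tank}", "feed", "FTS", str(tank), 8))
    return SampleDesign(
        pd.DataFrame(rows, columns=["sample_id", "sample_type", "system", "tank", "day"])
    )


@pytest.fixture(scope="session")
def neutral_dataset():
    """Small neutral metacommunity (one day, all sample types), frozen seed."""
    sc = SyntheticScenario(regime="neutral", days=(8,), seed=7)
    return simulate_metacommunity(sc)


@pytest.fixture(scope="session")
def neutral_pdist(neutral_dataset):
    return patristic_distances(neutral_dataset.tree).subset(
        neutral_dataset.table.taxon_ids
    )
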