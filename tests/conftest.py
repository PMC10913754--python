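import dendropy
import numpy as np
import pandas as pd
import pytest

from ecoassembly.containers import CommunityTable


def tree_from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


@pytest.fixture
def toy_tree():
    """Three-tip worked tree: ((A:1,B:1):1,C:2);"""
    return tree_from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def toy_table():
    return CommunityTable(pd.DataFrame(
        [[1, 2, 3], [2, 0, 1]], index=["s1", "s2"], columns=["A", "B", "C"]))


@pytest.fixture
def random_table():
    rng = np.random.default_rng(7)
    counts = rng.integers(0, 30, size=(6, 10))
    counts[:, 0] += 3  # no empty rows
    return CommunityTable(pd.DataFrame(
        counts, index=[f"s{i}" for i in range(6)],
        columns=[f"T{j}" for j in range(10)]))
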