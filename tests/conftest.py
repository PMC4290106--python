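import numpy as np
import pytest

from avigc.io import OrthologAlignment, read_tree


@pytest.fixture
def toy_coding():
    return OrthologAlignment(
        ortholog_id="toy", kind="coding",
        sequences={"a": "ATGGCC", "b": "ATGGCG"})


@pytest.fixture
def tree3():
    """((A,B),C) with supports and unit-ish branch lengths."""
    return read_tree("((A:1,B:1)90:0.5,C:1.5);", "substitutions")


@pytest.fixture
def rng():
    return np.random.default_rng(20140549)


def balanced_tree(n_cherries, cherry_len, deep_len, units="my"):
    """Caterpillar of cherries: ((a1,b1),((a2,b2),(...)))."""
    parts = [f"(a{i}:1,b{i}:1)n{i}:{cherry_len}"
             for i in range(1, n_cherries + 1)]
    nwk = parts[0]
    for p in parts[1:]:
        nwk = f"({nwk},{p}):{deep_len}"
    return read_tree(nwk + ";", units)
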