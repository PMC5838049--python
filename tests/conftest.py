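import numpy as np
import pandas as pd
import pytest

from commassembly import TraitTable, read_newick, simulate_tree


@pytest.fixture
def three_tip_tree():
    """((A:1,B:1):1,C:2); -- the canonical worked example."""
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def five_tip_tree():
    """Asymmetric 5-tip tree used for frozen cross-checks."""
    return read_newick("((A:1.5,B:0.5):0.7,((C:0.9,D:1.1):0.4,E:2.0):0.3);")


def random_mixed_table(rng: np.random.Generator, n_species: int,
                       n_cont: int = 2, n_bin: int = 3,
                       missing_frac: float = 0.0) -> TraitTable:
    """A random mixed continuous/binary trait table for oracle tests."""
    species = [f"s{i:02d}" for i in range(n_species)]
    data = {}
    types = {}
    for j in range(n_cont):
        data[f"c{j}"] = rng.normal(size=n_species) * rng.uniform(0.5, 20)
        types[f"c{j}"] = "continuous"
    for j in range(n_bin):
        data[f"b{j}"] = rng.integers(0, 2, size=n_species).astype(float)
        types[f"b{j}"] = "binary"
    df = pd.DataFrame(data, index=species)
    if missing_frac > 0:
        mask = rng.random(df.shape) < missing_frac
        df = df.mask(mask)
    return TraitTable(df, types)


@pytest.fixture
def mixed_table():
    return random_mixed_table(np.random.default_rng(7), 10)


@pytest.fixture
def tree128():
    """A fixed 128-tip pure-birth tree shared by calibration tests."""
    return simulate_tree(128, seed=11)
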