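import numpy as np
import pandas as pd
import pytest

import holophylo as hp
from holophylo.formats import TraitMatrix


@pytest.fixture(scope="session")
def small_sim():
    """8-taxon simulated dataset with known tree, rates and traits."""
    cfg = hp.SimConfig(n_taxa=8, seed=42, n_sites=500, alpha=0.5, n_traits=100)
    tree = hp.simulate_tree(cfg)
    alignment, true_rates = hp.simulate_alignment(tree, cfg)
    return dict(config=cfg, tree=tree, alignment=alignment, true_rates=true_rates)


@pytest.fixture()
def quartet_trees():
    t1 = hp.tree_from_newick("((A:0.2,B:0.2):0.1,(C:0.2,D:0.2):0.1);")
    t2 = hp.tree_from_newick("((A:0.2,C:0.2):0.1,(B:0.2,D:0.2):0.1);")
    t3 = hp.tree_from_newick("((A:0.2,D:0.2):0.1,(B:0.2,C:0.2):0.1);")
    return t1, t2, t3


@pytest.fixture()
def toy_traits():
    df = pd.DataFrame(
        [[1, 1, 0, 0], [0, 0, 1, 1], [1, 1, 0, 1]],
        index=["s1", "s2", "s3"],
        columns=["g1", "g2", "g3", "g4"],
    )
    return TraitMatrix(df)


def random_rooted_tree(rng, n_leaves):
    """Random rooted binary tree via sequential leaf attachment."""
    cfg = hp.SimConfig(n_taxa=n_leaves, seed=int(rng.integers(2**31)))
    return hp.simulate_tree(cfg)
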