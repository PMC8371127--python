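"""Dollo reconstruction vs the exhaustive single-gain minimal-loss oracle."""

import numpy as np
import pandas as pd
import pytest

import holophylo as hp
from holophylo.dollo import dollo_reconstruct, gain_loss_table, node_percentages
from holophylo.formats import TraitMatrix


def brute_force_min_losses(tree, leaf_states: dict) -> int | None:
    """Enumerate every single-gain node assignment; return minimal losses.

    An assignment is valid when the state-1 nodes form a connected
    subtree entered by at most one 0->1 transition (the root being 1
    counts as the gain) and the leaves match the observed pattern.
    Returns None for the absent-everywhere pattern.
    """
    nodes = list(tree.preorder_node_iter())
    n = len(nodes)
    idx = {id(x): i for i, x in enumerate(nodes)}
    parent = np.array(
        [idx[id(x.parent_node)] if x.parent_node else -1 for x in nodes]
    )
    leaf_idx = {
        lf.taxon.label: idx[id(lf)] for lf in tree.leaf_node_iter()
    }
    if not any(leaf_states.values()):
        return None
    best = None
    for mask in range(1 << n):
        states = np.array([(mask >> i) & 1 for i in range(n)], dtype=np.int8)
        if any(states[leaf_idx[lab]] != s for lab, s in leaf_states.items()):
            continue
        child_gain = sum(
            1
            for i in range(n)
            if parent[i] >= 0 and states[i] == 1 and states[parent[i]] == 0
        )
        gains = int(states[0] == 1) + child_gain
        if gains != 1:
            continue
        losses = sum(
            1
            for i in range(n)
            if parent[i] >= 0 and states[i] == 0 and states[parent[i]] == 1
        )
        best = losses if best is None else min(best, losses)
    return best


def matrix_for(tree, possessors, trait="g1"):
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    df = pd.DataFrame(
        {trait: [1 if s in possessors else 0 for s in leaves]}, index=leaves
    )
    return TraitMatrix(df)


def test_everywhere_trait_has_no_losses():
    tree = hp.tree_from_newick("((A,B),(C,(D,E)));", rooted=True)
    m = dollo_reconstruct(tree, matrix_for(tree, {"A", "B", "C", "D", "E"}))
    assert (m.presence == 1).all()
    assert m.gain_node[0] is not None
    assert m.loss_branches[0] == []


def test_worked_example_two_losses():
    tree = hp.tree_from_newick("((A,B),(C,(D,E)));", rooted=True)
    m = dollo_reconstruct(tree, matrix_for(tree, {"A", "B", "D"}))
    present = {lab for lab, p in zip(m.node_labels, m.presence[:, 0]) if p}
    assert m.gain_node[0] == m.node_labels[0]  # gain at the root
    assert present == {"N0", "N1", "A", "B", "N2", "N3", "D"}
    assert sorted(m.loss_branches[0]) == ["C", "E"]


def test_absent_everywhere_and_single_possessor():
    tree = hp.tree_from_newick("((A,B),(C,(D,E)));", rooted=True)
    m = dollo_reconstruct(tree, matrix_for(tree, set()))
    assert m.gain_node[0] is None and (m.presence == 0).all()

    m2 = dollo_reconstruct(tree, matrix_for(tree, {"C"}))
    assert m2.gain_node[0] == "C"
    assert m2.presence.sum() == 1
    table = gain_loss_table(m2)
    assert table.loc["C", "gains"] == 1 and table["losses"].sum() == 0


def test_errors_unrooted_and_unknown_species():
    unrooted = hp.tree_from_newick("((A,B),(C,D));", rooted=False)
    with pytest.raises(ValueError, match="rooted"):
        dollo_reconstruct(unrooted, matrix_for(unrooted, {"A"}))
    tree = hp.tree_from_newick("((A,B),(C,D));", rooted=True)
    df = pd.DataFrame({"g1": [1, 0]}, index=["A", "ZZ"])
    with pytest.raises(ValueError, match="ZZ"):
        dollo_reconstruct(tree, TraitMatrix(df))


def test_matches_exhaustive_oracle_on_random_instances():
    rng = np.random.default_rng(99)
    for _ in range(150):
        n_leaves = int(rng.integers(3, 9))
        tree = hp.simulate_tree(
            hp.SimConfig(n_taxa=n_leaves, seed=int(rng.integers(2**31)))
        )
        leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
        pattern = {lab: int(rng.integers(2)) for lab in leaves}
        m = dollo_reconstruct(
            tree,
            TraitMatrix(pd.DataFrame({"g": [pattern[s] for s in leaves]}, index=leaves)),
        )
        oracle = brute_force_min_losses(tree, pattern)
        if oracle is None:
            assert m.gain_node[0] is None
        else:
            assert len(m.loss_branches[0]) == oracle


def test_presence_is_connected_subtree_and_gains_conserved():
    cfg = hp.SimConfig(n_taxa=10, seed=55, loss_prob=0.3, n_traits=80)
    tree = hp.simulate_tree(cfg)
    traits, _ = hp.simulate_traits(tree, cfg)
    m = dollo_reconstruct(tree, traits)
    idx = {lab: i for i, lab in enumerate(m.node_labels)}
    for t in range(m.n_traits):
        present = {lab for lab in m.node_labels if m.presence[idx[lab], t]}
        if m.gain_node[t] is None:
            assert not present
            continue
        # connectivity: every present node except the gain has a present parent
        for lab in present:
            if lab != m.gain_node[t]:
                assert m.parent_of[lab] in present
    n_gained = sum(g is not None for g in m.gain_node)
    assert gain_loss_table(m)["gains"].sum() == n_gained
    assert n_gained == int((traits.data.sum(axis=0) > 0).sum())


def test_all_zero_outgroup_leaves_reconstruction_unchanged():
    rng = np.random.default_rng(7)
    for _ in range(20):
        tree = hp.simulate_tree(hp.SimConfig(n_taxa=6, seed=int(rng.integers(2**31))))
        leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
        data = pd.DataFrame(
            rng.integers(0, 2, size=(6, 10)),
            index=leaves,
            columns=[f"g{i}" for i in range(10)],
        )
        m_in = dollo_reconstruct(tree, TraitMatrix(data))
        rooted_with_og = hp.tree_from_newick(
            f"(OUT:1.0,{hp.write_tree(tree).strip().rstrip(';')}:0.1);", rooted=True
        )
        data_og = pd.concat(
            [data, pd.DataFrame(0, index=["OUT"], columns=data.columns)]
        )
        m_out = dollo_reconstruct(rooted_with_og, TraitMatrix(data_og))
        idx_out = {lab: i for i, lab in enumerate(m_out.node_labels)}
        idx_in = {lab: i for i, lab in enumerate(m_in.node_labels)}
        for lab in leaves:
            assert np.array_equal(
                m_in.presence[idx_in[lab]], m_out.presence[idx_out[lab]]
            )
        assert m_out.presence[idx_out["OUT"]].sum() == 0


def test_node_percentages_trivial_and_families():
    tree = hp.tree_from_newick("((A,B),(C,D));", rooted=True)
    leaves = list("ABCD")
    data = pd.DataFrame(1, index=leaves, columns=["g1", "g2", "g3"])
    m = dollo_reconstruct(tree, TraitMatrix(data))
    pct = node_percentages(m)
    assert (pct["percentage"] == 100.0).all()

    # family denominator: g1+g2 in one family, g3 alone
    fam = pd.Series({"g1": "F1", "g2": "F1", "g3": "F2"})
    data2 = pd.DataFrame(
        {"g1": [1, 0, 0, 0], "g2": [0, 0, 0, 0], "g3": [1, 1, 1, 1]}, index=leaves
    )
    m2 = dollo_reconstruct(tree, TraitMatrix(data2))
    pct_t = node_percentages(m2, "traits")
    pct_f = node_percentages(m2, "families", family_of=fam)
    assert pct_t.loc["A", "present_count"] == 2
    assert pct_f.loc["A", "present_count"] == 2  # both families present at A
    assert pct_f.loc["C", "present_count"] == 1
    assert pct_f.loc["C", "percentage"] == 50.0


def test_category_stratified_counts_decompose():
    cfg = hp.SimConfig(n_taxa=8, seed=77, loss_prob=0.25, n_traits=60)
    tree = hp.simulate_tree(cfg)
    traits, _ = hp.simulate_traits(tree, cfg)
    cats = pd.Series(
        ["c1"] * 20 + ["c2"] * 20 + ["c3"] * 20, index=traits.traits
    )
    full = dollo_reconstruct(tree, TraitMatrix(traits.data, cats))
    table = gain_loss_table(full)
    for cat in ("c1", "c2", "c3"):
        sub_traits = [t for t in traits.traits if cats[t] == cat]
        sub = dollo_reconstruct(tree, TraitMatrix(traits.data[sub_traits]))
        sub_table = gain_loss_table(sub)
        assert table[f"gains_{cat}"].equals(sub_table["gains"])
        assert table[f"losses_{cat}"].equals(sub_table["losses"])
    assert (
        table[["gains_c1", "gains_c2", "gains_c3"]].sum(axis=1).equals(table["gains"])
    )
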