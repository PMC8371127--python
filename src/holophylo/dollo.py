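"""Dollo-parsimony ancestral gene-content reconstruction.

Under Dollo parsimony a binary character (gene/protein presence) is
gained exactly once and can only be lost thereafter.  On a rooted
species tree the minimal-loss reconstruction is closed-form: the gain
sits at the most recent common ancestor of the possessors, an internal
node is in state 1 iff it descends from (or is) the gain node and its
subtree still contains a possessor, and one loss is charged to every
branch leading from a present node into an entirely absent subtree.

The module reports, per node, the reconstructed repertoire size and its
percentage of the total trait set (optionally stratified by functional
category), and per branch the gain/loss event counts — the quantities a
gene-content evolution figure is drawn from.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats import TraitMatrix, label_internal_nodes

__all__ = ["AncestralStateMap", "dollo_reconstruct", "node_percentages", "gain_loss_table"]


def _node_label(node) -> str:
    return node.taxon.label if node.is_leaf() else node.label


@dataclass
class AncestralStateMap:
    """Reconstruction result over one rooted tree and trait matrix."""

    node_labels: list[str]  # preorder
    trait_labels: list[str]
    presence: np.ndarray  # (n_nodes, n_traits) 0/1
    gain_node: list  # per trait: node label or None (absent everywhere)
    loss_branches: list  # per trait: list of child-node labels of loss edges
    parent_of: dict  # node label -> parent label (root absent)
    categories: pd.Series | None = None

    @property
    def n_traits(self) -> int:
        return self.presence.shape[1]

    def present_counts(self) -> pd.Series:
        return pd.Series(self.presence.sum(axis=1), index=self.node_labels)

    def loss_count(self, trait: str) -> int:
        return len(self.loss_branches[self.trait_labels.index(trait)])


def dollo_reconstruct(tree, traits: TraitMatrix) -> AncestralStateMap:
    """Single-gain minimal-loss ancestral presence for every trait.

    Every species in the matrix must be a leaf of the rooted tree; extra
    tree leaves are treated as lacking every trait.
    """
    if not tree.is_rooted:
        raise ValueError("Dollo reconstruction requires a rooted tree")
    label_internal_nodes(tree)
    leaf_set = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = set(traits.species) - leaf_set
    if missing:
        raise ValueError(
            f"species in matrix absent from tree: {sorted(missing)}"
        )

    nodes = list(tree.preorder_node_iter())
    labels = [_node_label(n) for n in nodes]
    index = {lab: i for i, lab in enumerate(labels)}
    parent_of = {
        _node_label(n): _node_label(n.parent_node)
        for n in nodes
        if n.parent_node is not None
    }
    children = {
        _node_label(n): [_node_label(c) for c in n.child_nodes()] for n in nodes
    }

    n_nodes, n_traits = len(nodes), len(traits.traits)
    data = traits.data
    # possessor indicator per (node, trait): does the node's subtree hold one?
    has_possessor = np.zeros((n_nodes, n_traits), dtype=bool)
    for node in tree.postorder_node_iter():
        i = index[_node_label(node)]
        if node.is_leaf():
            lab = node.taxon.label
            if lab in data.index:
                has_possessor[i] = data.loc[lab].to_numpy() > 0
        else:
            for c in node.child_nodes():
                has_possessor[i] |= has_possessor[index[_node_label(c)]]

    presence = np.zeros((n_nodes, n_traits), dtype=np.int8)
    gain_node: list = [None] * n_traits
    loss_branches: list = [[] for _ in range(n_traits)]
    for t in range(n_traits):
        if not has_possessor[0, t]:
            continue  # absent everywhere
        # gain node = MRCA of possessors: walk down while exactly one
        # child subtree holds them all
        node = nodes[0]
        while not node.is_leaf():
            kids = [
                c
                for c in node.child_nodes()
                if has_possessor[index[_node_label(c)], t]
            ]
            if len(kids) != 1:
                break
            node = kids[0]
        g = index[_node_label(node)]
        gain_node[t] = labels[g]
        # present iff in gain subtree and subtree holds a possessor
        stack = [node]
        while stack:
            cur = stack.pop()
            i = index[_node_label(cur)]
            if has_possessor[i, t]:
                presence[i, t] = 1
                stack.extend(cur.child_nodes())
            else:
                loss_branches[t].append(_node_label(cur))

    return AncestralStateMap(
        node_labels=labels,
        trait_labels=list(traits.traits),
        presence=presence,
        gain_node=gain_node,
        loss_branches=loss_branches,
        parent_of=parent_of,
        categories=traits.categories,
    )


def node_percentages(
    state_map: AncestralStateMap,
    denominator: str = "traits",
    family_of: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-node repertoire size and percentage (reported to 0.1).

    ``denominator="traits"`` divides by the total number of traits in
    the input matrix (absent-everywhere traits included).  With
    ``denominator="families"`` and a trait -> family map, a family
    counts as present at a node when any of its member traits is, and
    the denominator is the number of families.
    """
    if denominator == "traits":
        counts = state_map.present_counts()
        total = state_map.n_traits
    elif denominator == "families":
        if family_of is None:
            raise ValueError("family denominator needs a trait -> family map")
        fam = family_of.reindex(state_map.trait_labels)
        if fam.isna().any():
            raise ValueError("family map does not cover every trait")
        groups = pd.get_dummies(fam).to_numpy(dtype=bool)  # (traits, families)
        present_any = (state_map.presence.astype(bool) @ groups) > 0
        counts = pd.Series(present_any.sum(axis=1), index=state_map.node_labels)
        total = groups.shape[1]
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    pct = np.round(100.0 * counts / total, 1)
    return pd.DataFrame(
        {"present_count": counts, "percentage": pct},
        index=pd.Index(state_map.node_labels, name="node"),
    )


def gain_loss_table(state_map: AncestralStateMap) -> pd.DataFrame:
    """Per-branch gain and loss counts (per category too, if mapped).

    Branches are identified by their child node label; the gain of a
    trait is recorded on the branch ending at its gain node.
    """
    gains = pd.Series(0, index=state_map.node_labels, dtype=int)
    losses = pd.Series(0, index=state_map.node_labels, dtype=int)
    by_cat: dict[str, dict[str, pd.Series]] = {}
    cats = state_map.categories
    for t, trait in enumerate(state_map.trait_labels):
        cat = cats.get(trait) if cats is not None else None
        if cat is not None and cat not in by_cat:
            by_cat[cat] = {
                "gains": pd.Series(0, index=state_map.node_labels, dtype=int),
                "losses": pd.Series(0, index=state_map.node_labels, dtype=int),
            }
        g = state_map.gain_node[t]
        if g is not None:
            gains[g] += 1
            if cat is not None:
                by_cat[cat]["gains"][g] += 1
        for child in state_map.loss_branches[t]:
            losses[child] += 1
            if cat is not None:
                by_cat[cat]["losses"][child] += 1
    out = pd.DataFrame(
        {"gains": gains, "losses": losses},
        index=pd.Index(state_map.node_labels, name="branch_to"),
    )
    for cat in sorted(by_cat):
        out[f"gains_{cat}"] = by_cat[cat]["gains"]
        out[f"losses_{cat}"] = by_cat[cat]["losses"]
    return out
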