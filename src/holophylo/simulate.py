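"""Synthetic trees, alignments and Dollo trait matrices with ground truth.

The generator emulates the study conditions the downstream stages are
built for: a rooted species tree with optional artificially elongated
terminal branches (the long-branch-attraction scenario typical of
fast-evolving parasitic lineages), amino-acid alignments with
gamma-distributed among-site rate variation under the Poisson model,
and binary trait matrices evolved under a single-gain,
irreversible-loss (Dollo) process.

Randomness: one master seed in :class:`SimConfig`; each operation draws
from its own deterministic sub-stream (``numpy.random.SeedSequence``
spawn keys), so e.g. regenerating the alignment never perturbs the
traits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .formats import AMINO_ACIDS, Alignment, TraitMatrix, label_internal_nodes
from .likelihood import POISSON_SCALE

__all__ = ["SimConfig", "simulate_tree", "simulate_alignment", "simulate_traits"]

_STREAM_TREE, _STREAM_ALIGNMENT, _STREAM_TRAITS = 0, 1, 2


@dataclass
class SimConfig:
    """Knobs of the synthetic-data generator.

    Defaults describe a small but non-trivial study: a 12-taxon Yule
    tree of unit height, 2000 sites with strong rate heterogeneity
    (alpha = 0.5, the regime in which slow-fast stripping is
    informative), and 200 Dollo traits gained at the root with a 10%
    per-branch loss probability.
    """

    n_taxa: int = 12
    birth_rate: float = 1.0
    seed: int = 0
    tree_height: float = 1.0
    long_branch_taxa: dict = field(default_factory=dict)  # label -> factor >= 1
    alpha: float = 0.5
    n_sites: int = 2000
    loss_prob: float = 0.1
    n_traits: int = 200
    gain_node: str = "root"

    def __post_init__(self) -> None:
        if self.birth_rate <= 0 or self.tree_height <= 0:
            raise ValueError("birth_rate and tree_height must be positive")
        if self.alpha <= 0:
            raise ValueError("gamma shape alpha must be positive")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if not 0.0 <= self.loss_prob < 1.0:
            raise ValueError("loss_prob must lie in [0, 1)")
        for label, factor in self.long_branch_taxa.items():
            if factor < 1.0:
                raise ValueError(f"elongation factor for {label!r} must be >= 1")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(stream,))
        )


def taxon_labels(n_taxa: int) -> list[str]:
    width = len(str(n_taxa))
    return [f"t{i + 1:0{width}d}" for i in range(n_taxa)]


def simulate_tree(config: SimConfig) -> dendropy.Tree:
    """Fixed-n Yule tree, rescaled to ``tree_height``, with elongations.

    A pure-birth process is run forward until exactly ``n_taxa`` extant
    lineages exist (waiting times Exp(k * birth_rate), splitting a
    uniformly chosen lineage), the tree is made ultrametric at the final
    time, branch lengths are rescaled so the root-to-tip height equals
    ``tree_height`` exactly, and the terminal branches named in
    ``long_branch_taxa`` are multiplied by their elongation factor.
    Internal nodes receive stable preorder labels N0, N1, ...
    """
    if config.n_taxa < 3:
        raise ValueError("need n_taxa >= 3")
    rng = config.rng(_STREAM_TREE)
    labels = taxon_labels(config.n_taxa)
    unknown = set(config.long_branch_taxa) - set(labels)
    if unknown:
        raise ValueError(f"unknown long-branch taxa: {sorted(unknown)}")

    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    root = tree.seed_node
    root.split_time = 0.0  # overwritten when the root itself splits
    active = [root]
    t = 0.0
    while len(active) < config.n_taxa:
        t += rng.exponential(1.0 / (len(active) * config.birth_rate))
        node = active.pop(rng.integers(len(active)))
        node.split_time = t
        for _ in range(2):
            child = node.new_child()
            active.append(child)
    # final segment so terminal branches have positive length
    t += rng.exponential(1.0 / (config.n_taxa * config.birth_rate))

    # assign edge lengths from split times; leaves end at time t
    def node_time(n):
        return getattr(n, "split_time", t)

    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node.edge.length = None
            continue
        node.edge.length = node_time(node) - node_time(node.parent_node)
    # shuffle leaf label assignment so label order carries no topology signal
    leaves = list(tree.leaf_node_iter())
    for leaf, lab in zip(leaves, rng.permutation(labels)):
        leaf.taxon = taxa.get_taxon(lab)
    # exact height rescale (root node sits at its own split time)
    scale = config.tree_height / (t - root.split_time)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    for leaf in tree.leaf_node_iter():
        factor = config.long_branch_taxa.get(leaf.taxon.label)
        if factor is not None:
            leaf.edge.length *= factor
    label_internal_nodes(tree)
    return tree


def _evolve_states(tree, rng, rates: np.ndarray, n_states: int = 20):
    """Evolve site patterns down the tree; returns leaf label -> codes."""
    n_sites = len(rates)
    states = {id(tree.seed_node): rng.integers(n_states, size=n_sites)}
    out = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            if node.is_leaf():
                out[node.taxon.label] = states[id(node)]
            continue
        parent = states[id(node.parent_node)]
        t = node.edge.length or 0.0
        stay = rng.random(n_sites) < np.exp(-POISSON_SCALE * rates * t)
        child = np.where(stay, parent, rng.integers(n_states, size=n_sites))
        states[id(node)] = child
        if node.is_leaf():
            out[node.taxon.label] = child
    return out


def simulate_alignment(tree, config: SimConfig):
    """Alignment with gamma-heterogeneous site rates; returns ground truth.

    Each site draws its relative rate from a mean-one gamma(alpha)
    distribution (recorded and returned); characters then evolve down
    the tree under the Poisson model at that rate, root states uniform.

    Returns
    -------
    (Alignment, np.ndarray)
        The alignment (taxa in sorted label order) and the true per-site
        rates.
    """
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None and (edge.length or 0.0) <= 0:
            raise ValueError("simulate_alignment needs strictly positive branch lengths")
    rng = config.rng(_STREAM_ALIGNMENT)
    rates = rng.gamma(shape=config.alpha, scale=1.0 / config.alpha, size=config.n_sites)
    leaf_codes = _evolve_states(tree, rng, rates)
    labels = sorted(leaf_codes)
    aa = np.array(list(AMINO_ACIDS), dtype="U1")
    chars = np.stack([aa[leaf_codes[lab]] for lab in labels])
    return Alignment(labels, chars), rates


def simulate_traits(tree, config: SimConfig):
    """Binary traits under a single-gain, irreversible-loss process.

    Every trait gains state 1 at ``config.gain_node`` (a node label, or
    "root") and is lost independently on each descendant branch with
    probability ``loss_prob``; once lost it never returns.

    Returns
    -------
    (TraitMatrix, dict)
        Leaf states as a TraitMatrix and the full node-label -> 0/1
        vector ground truth (internal nodes included).
    """
    import pandas as pd

    if not tree.is_rooted:
        raise ValueError("simulate_traits requires a rooted tree")
    label_internal_nodes(tree)
    rng = config.rng(_STREAM_TRAITS)

    def node_label(n):
        return n.taxon.label if n.is_leaf() else n.label

    if config.gain_node == "root":
        gain = tree.seed_node
    else:
        gain = None
        for node in tree.preorder_node_iter():
            if node_label(node) == config.gain_node:
                gain = node
                break
        if gain is None:
            raise ValueError(f"gain node {config.gain_node!r} not found in tree")

    n = config.n_traits
    states: dict[str, np.ndarray] = {}
    in_gain_subtree = {id(x) for x in gain.preorder_iter()}
    for node in tree.preorder_node_iter():
        if node is gain:
            states[node_label(node)] = np.ones(n, dtype=np.int8)
        elif id(node) in in_gain_subtree:
            parent = states[node_label(node.parent_node)]
            lost = rng.random(n) < config.loss_prob
            states[node_label(node)] = np.where(lost, 0, parent).astype(np.int8)
        else:
            states[node_label(node)] = np.zeros(n, dtype=np.int8)
    leaf_rows = {
        lf.taxon.label: states[lf.taxon.label] for lf in tree.leaf_node_iter()
    }
    labels = sorted(leaf_rows)
    traits = [f"trait{i + 1}" for i in range(n)]
    df = pd.DataFrame(
        np.stack([leaf_rows[lab] for lab in labels]), index=labels, columns=traits
    )
    return TraitMatrix(df), states
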