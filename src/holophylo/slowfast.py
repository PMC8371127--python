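"""The slow-fast procedure: strip fast sites, re-infer, trace support.

Sites are ranked once by their posterior-mean rate on the full
alignment; the fastest are then removed cumulatively in fixed
fractional steps (5% by default, giving 19 reduced datasets plus the
full one).  For every step a tree is re-inferred with bootstrap
resampling and the support of each named topological hypothesis (an
unrooted split) is recorded, producing the support-versus-removal
curves that expose long-branch-attraction artefacts: genuine clades
keep high support as fast sites go, while artefactual long-branch
groupings decay.

Tree inference here is distance-based (neighbor joining on
maximum-likelihood Poisson distances) and sits behind one function so a
heavier ML engine can be swapped in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj

from .formats import Alignment, Hypothesis, MISSING_CODE, tree_from_newick, tree_splits
from .likelihood import poisson_distance
from .site_rates import SiteRateProfile, posterior_mean_rates

__all__ = [
    "SupportCurve",
    "strip_sites",
    "ml_distance_matrix",
    "infer_tree",
    "split_support",
    "support_curve",
]


@dataclass
class SupportCurve:
    """Support (%) per hypothesis as a function of fraction removed."""

    steps: np.ndarray  # fractions removed, strictly increasing from 0.0
    n_sites_remaining: np.ndarray
    support: dict  # hypothesis name -> np.ndarray of percentages

    def to_table(self):
        import pandas as pd

        out = pd.DataFrame(
            {"fraction_removed": self.steps, "n_sites": self.n_sites_remaining}
        )
        for name, values in self.support.items():
            out[name] = values
        return out


def rank_sites_by_rate(profile: SiteRateProfile) -> np.ndarray:
    """Site indices from fastest to slowest; rate ties broken by lower index."""
    # stable sort on negated rates keeps ascending index order within ties
    return np.argsort(-profile.rates, kind="stable")


def strip_sites(
    alignment: Alignment, profile: SiteRateProfile, step: float = 0.05
) -> list[Alignment]:
    """Cumulative fast-site removal in fractional steps.

    Subset ``k`` (1-based) drops the ``ceil(k * step * n_sites)``
    highest-rate sites; subsets are produced while at least
    ``step * n_sites`` sites remain, so ``step = 0.05`` yields 19
    reduced alignments.  Surviving sites keep their original order.
    """
    if not 0.0 < step < 1.0:
        raise ValueError("step must lie strictly between 0 and 1")
    if profile.n_sites != alignment.n_sites:
        raise ValueError("rate profile length does not match alignment")
    n = alignment.n_sites
    order = rank_sites_by_rate(profile)
    subsets = []
    k = 1
    while True:
        n_remove = math.ceil(k * step * n - 1e-9)
        remaining = n - n_remove
        if remaining < step * n - 1e-9 or remaining < 1:
            break
        keep = np.setdiff1d(np.arange(n), order[:n_remove])
        subsets.append(alignment.subset_sites(keep))
        k += 1
    return subsets


def ml_distance_matrix(alignment: Alignment, max_distance: float = 10.0) -> np.ndarray:
    """Pairwise ML Poisson distances on jointly non-missing sites."""
    enc = alignment.encoded()
    present = enc != MISSING_CODE
    n = alignment.n_taxa
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = present[i] & present[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    "no jointly non-missing sites for pair "
                    f"({alignment.taxa[i]!r}, {alignment.taxa[j]!r})"
                )
            p = float((enc[i][both] != enc[j][both]).sum()) / m
            d[i, j] = d[j, i] = poisson_distance(p, max_distance)
    return d


def _nj_tree(d: np.ndarray, taxa: list[str]) -> dendropy.Tree:
    skb = nj(DistanceMatrix(d, ids=taxa))
    for node in skb.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    tree = tree_from_newick(str(skb), rooted=False)
    return tree


def infer_tree(
    alignment: Alignment,
    method: str = "nj",
    n_bootstrap: int = 0,
    seed: int = 0,
    max_distance: float = 10.0,
):
    """Point tree plus bootstrap trees from site-resampled alignments.

    Neighbor joining on ML Poisson distances; deterministic given
    ``seed``.  Returns ``(tree, bootstrap_trees)``.
    """
    if method != "nj":
        raise ValueError(f"unknown tree inference method {method!r}")
    if alignment.n_taxa < 4:
        raise ValueError("tree inference needs at least 4 taxa")
    point = _nj_tree(ml_distance_matrix(alignment, max_distance), alignment.taxa)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_bootstrap):
        idx = rng.integers(alignment.n_sites, size=alignment.n_sites)
        resampled = alignment.subset_sites(idx)
        boots.append(
            _nj_tree(ml_distance_matrix(resampled, max_distance), alignment.taxa)
        )
    return point, boots


def split_support(bootstrap_trees, hypothesis: Hypothesis) -> float:
    """Percentage of trees whose unrooted split set contains the clade."""
    if not bootstrap_trees:
        raise ValueError("no bootstrap trees supplied")
    first_labels = None
    count = 0
    for tree in bootstrap_trees:
        labels = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
        if first_labels is None:
            first_labels = labels
            hypothesis.validate(labels)
        elif labels != first_labels:
            raise ValueError("bootstrap trees do not share one leaf set")
        clade = hypothesis.clade
        if min(labels) in clade:
            clade = labels - clade
        if frozenset(clade) in tree_splits(tree):
            count += 1
    return 100.0 * count / len(bootstrap_trees)


def support_curve(
    alignment: Alignment,
    tree,
    hypotheses,
    step: float = 0.05,
    n_bootstrap: int = 100,
    seed: int = 0,
    K: int = 4,
    alpha: float | None = None,
    fractions: list | None = None,
) -> SupportCurve:
    """Full slow-fast run: rates once, then strip / re-infer / count.

    ``fractions`` may restrict the evaluation to selected removal
    fractions (always including whichever are requested); by default
    every cumulative step from 0 is evaluated.  Rates are estimated on
    the full alignment under the fixed input tree and reused for all
    strips.
    """
    for h in hypotheses:
        h.validate(alignment.taxa)
    profile = posterior_mean_rates(tree, alignment, alpha=alpha, K=K)
    subsets = strip_sites(alignment, profile, step)
    all_alns = [alignment] + subsets
    all_fracs = [round(k * step, 10) for k in range(len(all_alns))]
    if fractions is not None:
        wanted = {round(f, 10) for f in fractions}
        pick = [i for i, f in enumerate(all_fracs) if f in wanted]
    else:
        pick = list(range(len(all_alns)))
    steps, n_remain = [], []
    support: dict[str, list] = {h.name: [] for h in hypotheses}
    for i in pick:
        aln = all_alns[i]
        _, boots = infer_tree(aln, "nj", n_bootstrap=n_bootstrap, seed=seed + i)
        steps.append(all_fracs[i])
        n_remain.append(aln.n_sites)
        for h in hypotheses:
            support[h.name].append(split_support(boots, h))
    return SupportCurve(
        steps=np.array(steps),
        n_sites_remaining=np.array(n_remain),
        support={k: np.array(v) for k, v in support.items()},
    )
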