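"""Felsenstein pruning under the 20-state Poisson (equal-rates) model.

The substitution model is the amino-acid analogue of Jukes–Cantor:
all exchangeabilities and equilibrium frequencies equal, rate
normalized to one expected substitution per unit branch length.  Its
transition kernel has the closed form

    P_ij(t) = (1 - e)/20 + e * delta_ij,   e = exp(-(20/19) * t),

which lets every pruning message be computed as an axpy instead of a
matrix product: for a child with partial-likelihood rows ``L`` the
message is ``(1 - e)/20 * sum_j(L_j) + e * L_i``.

Missing characters ('-', 'X', '?') are marginalized: their partial
likelihood is the all-ones vector.  Computations are vectorized over
sites and log-scaled per node so long trees never underflow.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammainc, logsumexp
from scipy.stats import gamma as gamma_dist

from .formats import Alignment, MISSING_CODE

__all__ = [
    "PruningEngine",
    "site_loglik",
    "gamma_category_rates",
    "poisson_distance",
    "POISSON_SCALE",
]

#: Rate constant of the 20-state Poisson model (q_ii = -20/19 at rate 1).
POISSON_SCALE = 20.0 / 19.0

_N_STATES = 20


def gamma_category_rates(alpha: float, K: int) -> np.ndarray:
    """Mean rates of ``K`` equiprobable categories of a mean-one gamma.

    The discrete-gamma approximation of among-site rate variation: the
    gamma(alpha, alpha) density is cut at its K-quantiles and each
    category is represented by its conditional mean, so the K rates
    average exactly to 1.
    """
    if alpha <= 0:
        raise ValueError("gamma shape alpha must be positive")
    if K < 1:
        raise ValueError("need at least one rate category")
    if K == 1:
        return np.ones(1)
    edges = gamma_dist.ppf(np.arange(1, K) / K, a=alpha, scale=1.0 / alpha)
    upper = gammainc(alpha + 1.0, np.append(edges * alpha, np.inf))
    lower = gammainc(alpha + 1.0, np.insert(edges * alpha, 0, 0.0))
    return K * (upper - lower)


class PruningEngine:
    """Per-site log-likelihoods for one alignment on one (fixed) topology.

    The tree is flattened once into postorder arrays; branch lengths can
    be overridden per call, which is what the constrained-topology
    branch-length optimizer exploits.
    """

    def __init__(self, tree, alignment: Alignment):
        rows = {t: i for i, t in enumerate(alignment.taxa)}
        missing = [
            lf.taxon.label
            for lf in tree.leaf_node_iter()
            if lf.taxon.label not in rows
        ]
        if missing:
            raise ValueError(
                f"taxa in tree absent from alignment: {sorted(missing)}"
            )
        self.alignment = alignment
        nodes = list(tree.postorder_node_iter())
        self._index = {id(n): i for i, n in enumerate(nodes)}
        self.n_nodes = len(nodes)
        self._children: list[list[int]] = []
        self._leaf_row = np.full(self.n_nodes, -1, dtype=int)
        lengths = np.zeros(self.n_nodes)
        self.edge_nodes: list[int] = []  # nodes with a parent (one edge each)
        for i, node in enumerate(nodes):
            self._children.append(
                [self._index[id(c)] for c in node.child_nodes()]
            )
            if node.is_leaf():
                self._leaf_row[i] = rows[node.taxon.label]
            if node.parent_node is not None:
                lengths[i] = node.edge.length or 0.0
                self.edge_nodes.append(i)
        self.branch_lengths = lengths
        self._root = self.n_nodes - 1
        enc = alignment.encoded()
        self.n_sites = alignment.n_sites
        # leaf partials built lazily per leaf: one-hot or ones for missing
        self._leaf_partials: dict[int, np.ndarray] = {}
        for i in range(self.n_nodes):
            r = self._leaf_row[i]
            if r < 0:
                continue
            codes = enc[r]
            part = np.zeros((self.n_sites, _N_STATES))
            obs = codes != MISSING_CODE
            part[obs, codes[obs].astype(int)] = 1.0
            part[~obs, :] = 1.0
            self._leaf_partials[i] = part

    def site_logliks(
        self, rate: float = 1.0, branch_lengths: np.ndarray | None = None
    ) -> np.ndarray:
        """Per-site log-likelihood at a single relative rate."""
        if rate <= 0:
            raise ValueError("rate must be positive")
        bl = self.branch_lengths if branch_lengths is None else branch_lengths
        e = np.exp(-POISSON_SCALE * rate * bl)
        partials = [None] * self.n_nodes
        log_scale = np.zeros(self.n_sites)
        for i in range(self.n_nodes):
            if self._leaf_row[i] >= 0:
                partials[i] = self._leaf_partials[i]
                continue
            prod = None
            for c in self._children[i]:
                child = partials[c]
                msg = ((1.0 - e[c]) / _N_STATES) * child.sum(
                    axis=1, keepdims=True
                ) + e[c] * child
                prod = msg if prod is None else prod * msg
                partials[c] = None  # free memory
            # rescale to dodge underflow on deep trees
            mx = prod.max(axis=1)
            mx[mx == 0.0] = 1.0
            prod /= mx[:, None]
            log_scale += np.log(mx)
            partials[i] = prod
        root = partials[self._root]
        return np.log(root.mean(axis=1)) + log_scale

    def mixture_site_logliks(
        self,
        rates: np.ndarray,
        branch_lengths: np.ndarray | None = None,
        return_components: bool = False,
    ):
        """Per-site log-likelihoods under an equal-weight rate mixture."""
        rates = np.asarray(rates, dtype=float)
        comp = np.stack(
            [self.site_logliks(r, branch_lengths) for r in rates]
        )  # (K, n_sites)
        mix = logsumexp(comp, axis=0) - np.log(len(rates))
        if return_components:
            return mix, comp
        return mix


def site_loglik(tree, alignment: Alignment, rate: float = 1.0) -> np.ndarray:
    """Per-site log-likelihoods of ``alignment`` on ``tree`` at one rate."""
    return PruningEngine(tree, alignment).site_logliks(rate)


def poisson_distance(p_mismatch: np.ndarray, max_distance: float = 10.0):
    """ML pairwise distance under the Poisson model.

    ``d = -(19/20) ln(1 - (20/19) p)`` for observed mismatch fraction
    ``p``; saturated pairs (argument of the log non-positive) are capped
    at ``max_distance``.
    """
    p = np.asarray(p_mismatch, dtype=float)
    arg = 1.0 - POISSON_SCALE * p
    with np.errstate(divide="ignore", invalid="ignore"):
        d = -np.log(arg) / POISSON_SCALE
    d = np.where(arg <= 0.0, max_distance, d)
    return np.minimum(d, max_distance)
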