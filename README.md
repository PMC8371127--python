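# holophylo

Downstream inference machinery for deep phylogenomics of Fungi and their
unicellular relatives (Holomycota), where fast-evolving parasitic lineages
(microsporidia, rozellids, sanchytrid-like taxa) produce long branches that
distort deep nodes of the species tree. The package implements the
robustness and gene-content analyses that sit *after* alignment and initial
tree inference:

- **Per-site rate estimation** under a discrete-gamma model on a fixed tree,
- the **slow-fast procedure**: progressive removal of the fastest-evolving
  sites with bootstrap support curves for named topological hypotheses,
- **RELL bootstrap and AU (approximately-unbiased) topology tests** from
  per-site log-likelihood vectors,
- **Dollo-parsimony reconstruction** of ancestral gene content (single gain,
  irreversible losses) with per-node repertoire percentages and per-branch
  gain/loss dynamics,
- **binary-profile comparative statistics**: presence/absence distances,
  principal coordinate analysis, Ward clustering, heatmap ordering,
- and a **synthetic-data generator** (Yule trees with elongated branches,
  gamma-heterogeneous amino-acid alignments, Dollo trait matrices) so every
  stage is testable against known ground truth.

## The statistics at the core

Under the 20-state Poisson model with relative rate $r$ the transition
probability is $P_{ij}(t) = \tfrac{1-e}{20} + e\,\delta_{ij}$ with
$e = \exp(-\tfrac{20}{19} r t)$; per-site likelihoods come from Felsenstein
pruning with missing characters marginalized. Among-site rate variation uses
$K$ equiprobable categories of a mean-one $\Gamma(\alpha)$ distribution, and
each site's rate is its posterior mean
$\hat r_s = \sum_k r_k P(x_s \mid r_k) / \sum_k P(x_s \mid r_k)$.
The slow-fast procedure ranks sites by $\hat r_s$ and removes the fastest
5% cumulatively (19 reduced datasets), re-inferring a tree with bootstrap at
each step and counting the frequency of each hypothesis' bipartition.
The AU test resamples per-site log-likelihoods at scales
$r \in \{0.5,\dots,1.4\}$, fits $\Phi^{-1}(1-\mathrm{BP}_r) \approx
d\sqrt{r} + c/\sqrt{r}$ by weighted least squares, and reports
$p_{AU} = 1 - \Phi(d - c)$. Dollo parsimony places each trait's gain at the
most recent common ancestor of its possessors and charges one loss per
branch into every absent subtree.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (`python analysis/01_simulate.py`, then 02–06). The slow-fast stage
(`analysis/03_slowfast.py`) analyses a 12-taxon, 2000-site alignment
simulated on a tree whose terminals `t01` and `t12` — unrelated in the
generating topology — were elongated 8-fold. It prints the support curve:

```
 fraction_removed  n_sites  long_branch_pair  true_pair
             0.00     2000             100.0        0.0
             0.35     1300             100.0        0.0
             0.50     1000               0.0       78.0
             0.95      100               0.0      100.0

artefactual clade support: 100% with all sites, 0% after removing the fastest 50%
```

With all sites, bootstrap places the two long branches together 100% of the
time — a pure long-branch-attraction artefact, since they are maximally
separated in the true tree. Stripping the fastest half of the sites
collapses that support to 0% while the genuine `t01+t02` clade rises to
high support: exactly the diagnostic pattern the procedure exists to
expose. The companion stages print the fitted shape
(`alpha_hat = 0.506`, truth 0.5; Spearman 0.90 between estimated and true
site rates), AU tests that keep the generating topology
(`p_AU = 1.0`) and reject both rearrangements (`p_AU = 0.0`,
`delta_lnL ≈ 91`), and a Dollo reconstruction whose internal states differ
from the generating process in only 73 of 2200 node-states.

A `holophylo` CLI exposes the same stages
(`holophylo simulate|rates|slowfast|autest|dollo|profiles|run`); see
`holophylo --help`.

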