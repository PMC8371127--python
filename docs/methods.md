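# Methods

## Substitution model and likelihood core

All likelihood computations use the 20-state Poisson model: equal
exchangeabilities, equal equilibrium frequencies (1/20), rate matrix
normalized to one expected substitution per unit branch length, so
`P_ij(t) = (1-e)/20 + e·δ_ij` with `e = exp(-(20/19)·r·t)`. The closed-form
kernel lets every pruning message be an elementwise axpy rather than a
matrix product, and gives exact reference values for tests (e.g. the
probability that two taxa separated by total length `t` show the same
residue is `1/20 + (19/20)·exp(-(20/19)·r·t)`). Gap (`-`), unknown (`X`)
and ambiguous (`?`) characters are one missing state and are marginalized
(partial likelihood = 1 for every residue). Partial likelihoods are
rescaled per node and the log accumulated, so deep trees and low rates
never underflow.

This is deliberately simpler than the profile-mixture models used for
real deep-phylogenomics matrices. The slow-fast procedure consumes only
the *ranks* of per-site rates, and rank order is robust to the
exchangeability matrix; the AU machinery operates on per-site
log-likelihood differences whose resampling behaviour does not depend on
the model family. Mixture models (C-series, free-rate) and branch-length
re-optimization for rate estimation are out of scope.

## Among-site rate variation and posterior-mean rates

Rate heterogeneity is the discrete-gamma approximation: `K` equiprobable
categories of a mean-one gamma(`alpha`, `alpha`) density, each represented
by its conditional mean (not median), computed from regularized incomplete
gamma functions so the K rates average to exactly 1. Default `K = 4`, the
field convention. `alpha` is fitted by bounded scalar maximization of the
total mixture log-likelihood over `alpha ∈ [0.02, 100]` (optimized in
log-space, tolerance 1e-5, reproducible to ~1e-4). Branch lengths are
taken from the input tree as-is: the procedure models rate estimation on a
fixed, previously inferred tree.

Degenerate input (e.g. all-invariant columns) pins the estimate at a
boundary and raises a warning. For fully invariant data the likelihood
increases as rates shrink, so the estimate pins the *lower* bound — the
boundary warning, not the specific bound, is the contract.

Per-site rates are posterior means over categories with a uniform prior.
Identical columns get identical rates by construction; each rate lies
within [lowest, highest] category rate.

## Slow-fast procedure

Sites are ranked once, on the full alignment, by posterior-mean rate
(ties broken toward lower site index, which makes stripping
deterministic). Subsets are cumulative: subset `k` removes the
`ceil(k·step·n)` fastest sites (ceiling guarantees progress on tiny
alignments), generated while at least `step·n` sites remain — at the
default `step = 0.05` this yields 19 reduced datasets plus the full one.
Rates are *not* recomputed per subset; the ranking from the full
alignment is reused throughout, matching the one-pass design of the
procedure this reimplements.

Per-subset trees come from neighbor joining on maximum-likelihood Poisson
distances, `d = -(19/20)·ln(1 - (20/19)·p̂)` on jointly non-missing site
pairs, capped at 10 substitutions/site when saturated; bootstrap trees
resample sites with replacement (deterministic per seed). Distance-NJ is
a desk-scale stand-in for per-subset ML tree search and sits behind a
single function (`slowfast.infer_tree`) so a heavier engine can be
dropped in. Support of a hypothesis is the percentage of bootstrap trees
whose unrooted split set contains the hypothesis bipartition; splits are
normalized to the side not containing the lexicographically smallest
taxon, so complement labellings are identical by construction.

The distance formula assumes rate homogeneity across sites. Under strong
gamma heterogeneity it *underestimates* long distances, which is exactly
what makes elongated terminal branches attract — the package's synthetic
long-branch scenario (two unrelated terminals elongated 8x over short
internals) reproduces the artefact at full support and its collapse once
the fastest half of the sites is removed.

## RELL and the AU test

Candidate topologies are supplied fully resolved; "constrained search" is
reduced to evaluating the supplied resolutions. Branch lengths are
optimized per topology by coordinate-wise bounded Brent minimization
(edge lengths in [1e-8, 20], initialized at max(input, 0.05), sweeps until
the total log-likelihood improves by < 1e-6). RELL resampling draws site
counts from a multinomial, computes per-topology sums, and assigns each
replicate's credit to the argmax with exact ties split fractionally
(unbiased under symmetric ties).

The AU p-value uses ten scales 0.5–1.4 (configurable; resample size
`ceil(r·n)`), 10,000 replicates per scale by default (reduced in
calibration loops). Winning frequencies are clamped to
[0.5/n_rep, 1 − 0.5/n_rep]; `z_r = Φ⁻¹(1 − BP_r)` is regressed on
`(√r, 1/√r)` with weights `n_rep·φ(z)²/(BP(1−BP))` (the delta-method
binomial variance); `p_AU = 1 − Φ(d − c)` clamped to [0,1]. Topologies
with BP 0 or 1 at every scale are reported as p = 0 or 1 with a
`degenerate` flag rather than a failed fit. Under a permutation null of
equal-total topologies the measured rejection rate at α = 0.05 is
conservative (≈ 0 in the calibration run of 100 datasets).

## Dollo reconstruction

A trait's gain node is the MRCA of its possessors; a node is present iff
it lies in the gain subtree and its own subtree still contains a
possessor; one loss is charged per branch from a present node into an
absent subtree. Gains sit at nodes, losses on branches strictly below the
gain node, and the root edge never carries a loss. Traits with no
possessors stay in the denominator of percentage reports but are marked
absent everywhere. Per-node percentages default to the trait count;
a trait→family map switches the denominator to families (a family is
present where any member trait is). This construction is provably the
single-gain minimal-loss assignment; the test suite checks it against
exhaustive enumeration of all node assignments on 1000+ random instances
with up to 8 leaves.

## Binary-profile statistics

Species distances: `jaccard`, `simple_matching`, or the default
`pearson_complement` = 1 − φ (phi = Pearson correlation of two binary
vectors via the 2×2 contingency), range [0, 2] left unclamped because the
downstream clustering operates on the correlations themselves. Constant
(all-0/all-1) profiles have undefined φ; they get distance 0 to identical
profiles and 1 otherwise, with a warning.

PCoA is classical metric scaling implemented directly (double-center
−D²/2, symmetric eigendecomposition): non-positive eigenvalues are
dropped (no Cailliez/Lingoes correction) with their relative mass
reported, coordinates are eigenvectors scaled by √eigenvalue, and each
axis' first non-zero loading is made positive so output is
sign-deterministic. A test cross-checks eigenvalues and coordinates
against scikit-bio's implementation.

Ward clustering uses scipy's `ward` linkage (Ward.D2 semantics — squared
distances inside the update): species on 1 − Pearson distances, traits
("orthologs") on Euclidean distances between binary columns. Items are
fed in ascending label order so ties resolve deterministically.
`heatmap_order` applies dendrogram leaf orders without touching values.

## Synthetic-data generator

The generator's defaults describe the regime the pipeline targets:
12-taxon Yule trees (pure birth, exact-n construction, leaf labels
shuffled so label order carries no signal) rescaled so root-to-tip height
is exactly `tree_height = 1.0` substitutions/site; per-site rates drawn
from mean-one gamma with `alpha = 0.5` (strong heterogeneity, the regime
where slow-fast stripping is informative); 2000 sites; Dollo traits
gained at the root with `loss_prob = 0.1` per branch. Long-branch
emulation multiplies named terminal branches only (factor ≥ 1); covarion
or heterotachy effects are not modelled. One master seed; each operation
draws from its own spawned substream, so regenerating one artifact never
perturbs another.

What passing tests on this generator do *not* show: real alignments have
unequal amino-acid frequencies, exchangeability structure, site-profile
heterogeneity, indel patterns and non-independent sites; real orthology
matrices contain annotation noise and horizontally patchy presence that
the pure Dollo process lacks. The tests establish that the machinery is
correct under its stated model, not that the model suffices for any
particular empirical matrix.

## Problem sizes

The test suite and acceptance script run at deliberately modest sizes
chosen to make every stochastic check cheap while keeping Monte-Carlo
error well inside the asserted bands: 8–12 taxa, 300–5000 sites,
100 bootstrap replicates, 1000–10,000 RELL replicates per scale,
1000 random Dollo instances, 10-seed repetition for recovery-rate
claims. All thresholds (Spearman ≥ 0.8, ≥ 9/10 topology recoveries,
null rejection ≤ 0.10, ≥ 7/10 long-branch support drops) are properties
of the method at those sizes, verified by running it.

## Known limitations

- Poisson likelihoods only; no empirical exchangeabilities or mixtures.
- NJ replaces ML tree search in the slow-fast loop (pluggable).
- Constrained topologies must be supplied resolved; no constrained search.
- PCoA drops negative eigenvalues rather than correcting the matrix.
- The Dollo module assumes the input tree is correct and rooted; it does
  not propagate phylogenetic uncertainty into gain/loss counts.
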