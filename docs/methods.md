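# Methods

`phylopathx` implements exploratory phylogenetic path analysis: instead of
comparing a handful of hand-specified causal models, it enumerates *every*
directed acyclic graph (DAG) over the study variables that satisfies the
user's causal constraints, scores each by phylogenetic d-separation, and
summarises the best-fitting set as a conditionally averaged path model.
This note records the statistical model, the numerical choices, and the
limits of what the synthetic-data experiments demonstrate.

## Phylogenetic regression

All conditional-independence tests and path-coefficient estimates are
generalised least squares fits

    beta_hat = (X' S^-1 X)^-1 X' S^-1 y

with the error covariance `S` derived from the phylogeny.  The base matrix
is the Brownian-motion variance-covariance (shared root-to-MRCA path
lengths).  Two one-parameter transforms are available:

- **Pagel's lambda** (default): off-diagonal entries multiplied by
  `lambda in [0, 1]`; `lambda = 0` is independence, `lambda = 1` the full
  Brownian expectation.  On an ultrametric tree `lambda = 0` reduces PGLS
  exactly to OLS (on a non-ultrametric tree it is a weighted LS with tip
  depths as variances).
- **Ornstein-Uhlenbeck-style decay** (`transform="ou"`): correlations decay
  as `exp(-alpha * d_ij)` with patristic distance, `alpha in [1e-6, 50]` by
  default.  The fitted parameter is reported as `alpha` when this transform
  is selected.

The transform parameter is set to its maximum-profile-likelihood value: a
21-point grid over the bounds followed by bounded scalar minimisation inside
the best bracket, which guarantees the returned optimum is no worse than any
grid point.  Wald t-tests use `n - p` residual degrees of freedom with the
residual variance estimated as `rss_gls / (n - p)`.  p-values are clamped to
`>= 1e-16` before any logarithm so Fisher's C stays finite.

Binary (0/1) variables enter d-separation tests through the **linear** GLS
by default — the convention of regression-based path analysis on binary
data: deterministic, fast, and well calibrated in our null simulations.  An
approximate phylogenetic **logistic** fit is provided separately
(`phylo_logistic_fit`): quasi-likelihood IRLS with working covariance
`W^1/2 R W^1/2` (`R` the phylogenetic correlation at a fixed transform
parameter, default 1).  At parameter 0 it reduces exactly to ordinary
logistic IRLS; complete separation triggers a warning and a Firth-style
working-response adjustment.  It is documented as approximate and is not
used inside the search.

Missing data: listwise deletion per regression in the bivariate screen, but
*global* listwise deletion across all model variables in the path search, so
every candidate model is scored on the same `n` (CICc comparisons require a
common sample size).

## d-separation, Fisher's C, CICc

For each candidate DAG the basis set contains one claim per non-adjacent
pair {x, y}: x independent of y given the union of the parents of x and y.
The response of the testing regression is whichever variable is later in the
model's topological order (ties broken by declared variable order).  Each
claim's p-value is the Wald p of the partner variable's coefficient.  Claims
are canonicalised (unordered pair + sorted conditioning set + response) and
cached process-wide, so each distinct regression is fitted at most once per
search; a cache on/off equality test guards correctness.

Model score: `C = -2 * sum(ln p_k)`, chi-square with `2k` degrees of freedom
under the model, and

    CICc = C + 2 q n / (n - 1 - q)

with `q = |edges| + |nodes|` by default (configurable to `|edges|`).
Models within 2 CICc of the best are retained and given Akaike weights
`exp(-delta/2)` (normalised).

Note the penalty arithmetic: adding one edge removes one claim whose
expected contribution to C is 2 under the null while the CICc penalty grows
by about `2n/(n-1-q)` (about 2.07 at n = 300).  Exhaustive search over all
DAGs therefore keeps superset models of the truth near the CICc boundary by
construction; the coefficient CI filter, not the information criterion, is
what removes their spurious edges from the averaged model.

## Conditional model averaging

Path coefficients are fitted by regressing each node on its parents with all
variables standardised (mean 0, SD 1), so coefficients are comparable across
paths and drawable as proportional arrow widths.  For every directed path in
at least one retained model, the conditional average is the weighted mean
over only the models containing it (weights renormalised within that
subset); the averaged SE is Buckland's unconditional form
`sum_i w_i sqrt(se_i^2 + (b_i - b_bar)^2)`, which includes the
between-model variance.  The 95% CI is `estimate +/- 1.96 * SE` (normal
approximation); paths whose CI crosses zero are listed as excluded, and
pairs present in both orientations across the retained set are flagged
bidirectional.  Full averaging (absent paths count as zero) and unweighted
averaging are available options.

## Phylogenetic signal and distance tests

**Fritz-Purvis D** for binary traits: nodal values are means of daughter
values computed tips-to-root; `d_obs` sums |difference| over all unordered
daughter pairs at each internal node (polytomies contribute every pair; a
seeded random-bifurcation alternative was considered unnecessary because
the all-pairs rule is deterministic and order-invariant).  D scales `d_obs`
between the means of two simulated benchmarks — tip shuffling (D = 1) and
Brownian evolution thresholded at the observed prevalence (D = 0) — with
999 permutations each by default.  Because nodal values are linear in tip
states, the whole calculation vectorises as one matrix product per
benchmark batch.  Permutation p-values are floored at `1/(B+1)` and every
result carries its seed.  On very shallow, highly polytomous trees (e.g. a
two-level classification with many families) the two benchmark means nearly
coincide — between-family daughter pairs at the root dominate `d_obs` — so
D's denominator approaches zero and the statistic is uninformative there;
it is well behaved on mostly-bifurcating trees of realistic depth.

**Mantel test**: raw upper-triangle cross-product `z` and standardised
Pearson `r` are both reported; the one-tailed p-value comes from jointly
permuting rows and columns of the second matrix (9,999 permutations by
default).  The geographic-patterning statistic of comparative studies is
implemented as this Mantel `z`; published values of that form are not
expected to be reproduced without the original data, since the exact test
behind them is typically unstated.  Geographic distances are haversine
great circles with Earth radius 6371 km.

## Trees from classifications

A nested classification (e.g. a language catalogue's family/branch levels)
becomes a tree by sharing an internal node for every shared prefix of
groups.  Each level contributes one unit of branch length and tip edges are
padded so all root-to-tip depths equal `max levels + 1` (ultrametric);
single-member groups collapse onto their tip, so singleton families attach
at the root.  This unit-per-level convention is a declared default — sources
rarely state branch lengths for classification trees — and Grafen's
clade-size scaling is available as an option.  Construction is invariant to
row order.  Newick inputs with missing branch lengths have them filled with
1.0 (with a warning).

## Synthetic data

The generator draws exogenous variables as Brownian traits (multivariate
normal with the tree's correlation), builds each endogenous variable as the
coefficient-weighted sum of its standardised parents plus a residual whose
phylogenetic correlation is `noise_signal` (default 0.7), and produces
binary variables by thresholding the latent variable at the exact quantile
matching the target prevalence — so fixture marginals match declared counts
exactly, and the binary mechanism coincides with the D statistic's
Brownian-threshold null.  Two tree models are provided: birth-death (the
final inter-speciation interval is completed with one extra exponential
waiting time so terminal branches are never zero-length, which would make
the Brownian covariance singular) and classification-like (random family
sizes joined at the root with unit depths).

The bundled 68-taxon fixture mirrors the shape of a cross-cultural
hunter-gatherer study: 35 families, six variables (two continuous
environmental, four binary socio-cultural), specialists present in 48/68
and food storage in 34/68, a generating DAG in which environment drives
pathogen load and social leadership, those drive food storage, and food
storage drives specialists, plus the two constraint patterns of that study
design (the environmental pair mutually exogenous; pathogen load shielded
from socio-cultural causes).  It is synthetic throughout — no claim is made
that its effect sizes match any published estimates.

### What the recovery experiment shows — and what it cannot

The parameter-recovery benchmark (`recovery_benchmark`) uses a five-variable
DAG whose every edge is *compelled* by the constraints: edges out of the
mutually exogenous pair and out of the shielded variable cannot be legally
reversed.  This is deliberate.  The orientation of an edge between two
unconstrained variables is not identifiable from observational likelihood:
a model reversing it plus one compensating edge fits the data essentially as
well, lands within the 2-CICc band, and contributes a genuinely strong
coefficient for the reversed direction — which the averaging step then
correctly reports as a bidirectional pair.  A recovery experiment can only
ask for what is identifiable, so the benchmark DAG places all six edges
under constraint protection (n = 300 tips, standardised path coefficients
0.8).  Under those conditions every true edge is recovered with a 95% CI
excluding zero in >= 80% of replicates and false edges rarely reach
significance.  On small samples shaped like real cross-cultural data
(n = 68, binary endpoints) the same pipeline typically does *not* pin down
the full generating structure — directions among unconstrained
socio-cultural variables stay ambiguous, which is faithful to how the
method behaves on real data.

## Numerical and engineering choices

- Enumeration iterates subsets of the constraint-permitted edge list with a
  Kahn acyclicity check; generation order is deterministic and restartable.
  A guard (7 nodes / 25 permitted edges, overridable) protects against
  combinatorial blow-up.  The model space includes disconnected DAGs ("all
  possible models"); a connectivity filter is optional.
- Near-singular covariances (nearly coincident tips) get a proportional
  jitter of `1e-8 * mean(diag)` on Cholesky failure.
- Scoring ties break by smaller C, then fewer edges, then lexicographic
  edge list, so reports are byte-identical across runs.
- All stochastic outputs (D, Mantel, generators) are driven by explicit
  seeds; identical seeds give bit-identical results.

## Problem sizes used in the shipped experiments

Formula checks run instantly; enumeration oracles go up to 4 unconstrained
nodes (543 DAGs) plus the 6-variable constrained study pattern (153,600
DAGs, which the package reports as its own count for that constraint
pattern); D calibration uses a 128-tip tree with 200 replicates per
benchmark; the null calibration of the search uses 60 datasets of 4
independent traits on 200 tips; recovery uses 10 replicates of the
5-variable benchmark at n = 300.  These sizes make the full pipeline's
statistical properties measurable while keeping the shipped test suite
fast.

## Known limitations

- Fisher's C treats basis-set p-values as independent; claims sharing
  variables are positively dependent, and the measured model-level
  rejection rate under the null (~0.03) is slightly conservative.
- The logistic variant does not profile the correlation parameter and its
  SEs are naive quasi-likelihood Walds.
- No latent variables, correlated errors, or Markov-equivalence-class
  reduction; exhaustiveness over labelled DAGs is the point.
- CICc's AIC-like penalty does not consistently eliminate superset models;
  interpretation should lean on the averaged model's CI filter and the
  bidirectional-pair flags, not on the identity of the single best model.
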