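# Methods

This note documents the models and procedures `hubsig` implements, the
parameters that matter, the synthetic data the tests run on, and the design
choices made where the design was genuinely open. Everything quantitative
stated here is computed by the test suite or `scripts/acceptance.py`.

## The statistic

For each gene *g* and group (aggressiveness class H/L, or individual cancer
type), the **normalized count** is the fraction of the group's samples in
which *g* is called upregulated, and the **normalized connections** value is

    NormConnections(g) = NormCount(g) × degree(g),

with `degree(g)` the gene's number of distinct partners in the reference
protein–protein interactome. The product behaves as a frequency-weighted PPI
score: at any moment the interactions a protein actually performs are
expected to scale with how often it is present and how many partners it can
engage. Genes never upregulated in a group are kept with NormCount = 0
rather than dropped — class-exclusive genes are candidate severity markers
and must survive into downstream stages. Invariants maintained everywhere:
0 ≤ NormCount ≤ 1 and NormConnections ≤ degree; duplicating every sample of
a group leaves both unchanged.

## Upregulation calling (per tumor–control pair)

Each tumor sample is compared only with its matched control:

1. counts are divided by coding-sequence length, then scaled per sample so
   length-normalized values sum to 1e6 (CPM-like; a numeric factor can
   replace this, `scale=1.0` disables scaling);
2. log differential = log2((tumor + c) / (control + c)) with pseudocount
   c = 0.5 (configurable); exactly antisymmetric under swapping the pair;
3. the pair's critical value is `mean + z(1 − α) · sd` of its own
   log-differential distribution at α = 0.025; genes strictly above it are
   upregulated. An empirical (1 − α)-quantile rule is available
   (`rule="quantile"`); the two are not claimed equivalent, and the
   parametric rule is the documented default. A degenerate (zero-variance)
   distribution falls back to the quantile with a warning.

Calibration: on negative-binomial null cohorts the log-ratio distribution is
a leptokurtic mixture across expression levels (low-count genes contribute
heavy tails), so the normal-tail rule calls slightly *fewer* than α of the
genes — about 1.2–1.5% at α = 2.5% under the default generator — which the
acceptance suite verifies stays within α ± 3 binomial standard errors at the
simulated problem size (1,000 genes × 200 pairs). Monotonicity (smaller α
never adds calls) holds by construction.

## Variance filter

Only genes upregulated in both classes have a comparable spread; their
cross-class variance is the unbiased sample variance over the two class
values, i.e. (x_H − x_L)² / 2, and genes with variance strictly > 0.005 are
kept. Genes present in exactly one class are always kept. The quantity the
variance is computed on defaults to the normalized count, with a switch to
normalized connections (`on="norm_connections"`); the two readings are both
defensible and the choice is exposed rather than hidden.

## Hub boundary

The search asks for the (connections, frequency) corner that is occupied by
H-class genes only: over candidate thresholds taken from the observed H
values, maximize the number of H genes with NormConnections ≥ c and
NormCount ≥ f subject to zero L genes satisfying both; ties prefer larger c,
then larger f. Both comparisons are inclusive. On tables of ≤ 200 genes the
grid search is tested equal to exhaustive brute force; with no feasible
exclusive corner it returns an empty gene list and objective 0. The
objective is a named plug-in point (`objective="exclusive"` is the default
and currently only rule).

## Cross-type rank tests

Within each pathway, the interactome degrees of the upregulated genes
observed in each cancer type are compared across types with Kruskal–Wallis
(tie-corrected H, chi-squared null with k − 1 df) and pairwise Wilcoxon
rank-sum tests; pairwise p-values are Bonferroni-multiplied by the number of
pairs in that pathway and capped at 1. By default each upregulation *event*
contributes one observation, so a gene seen in ten samples of a type counts
ten times; `per_gene=True` collapses to distinct genes. Exact rank-sum nulls
are used when both groups have ≤ 25 observations and no ties; otherwise the
normal approximation with continuity correction. For small inputs the exact
p-values are tested against full permutation enumeration.

## PCA and hierarchical clustering

The feature matrix has one row per cancer type (six in the default design),
one column per variance-selected gene, and NormConnections values computed
with *per-type* denominators (the class-level normalization is kept for
scoring; per-type rows are what a type-resolved ordination needs). Absent
gene-in-type cells are 0.

Components come from the SVD of the column-centered matrix (centering on,
scaling off, both configurable); component standard deviations are singular
values / sqrt(n − 1), proportions are squared-singular-value shares, and at
most min(rows − 1, columns) components are kept. Loadings are sign-fixed so
each component's largest-magnitude loading is positive. A gene's
contribution to a component is its squared-loading share (%), summing to 100
within each component; its share of **total** variance weights contributions
by component proportions, and its share of **captured** variance divides the
retained-component part by the cumulative proportion of the retained
components (3 by default). These definitions reproduce the worked rule that
a gene holding 50% of a component that holds 70% of the variance carries
35% of the total. Small matrices are tested against a brute-force covariance
eigendecomposition at 1e−10.

Hierarchical clustering uses manhattan (L1) distances between the same rows
with complete linkage (the linkage is configurable; an option clusters the
retained PC coordinates instead of the raw rows). The reported purity is the
majority-class fraction of the two top-level branches — 1.0 means the cut
reproduces the H/L partition exactly.

## Random-forest classification

Samples are feature vectors over the selected genes: the gene's interactome
degree if upregulated in the sample, else 0 (raw connection counts, not
class-normalized values, so each sample's vector is independent of its
cohort). The forest uses Gini-impurity splitting with mtry = 8 candidate
features per split and ntree = 50 trees, each grown on a bootstrap resample,
and is evaluated purely out-of-bag: each sample is predicted by the trees
whose bootstrap missed it, so no train/test split exists. The seed is an
explicit required parameter recorded in the result. Importances are
scikit-learn's mean decrease in impurity, i.e. the normalized (summing to 1
across features) variant of the classical mean-decrease-Gini total;
rankings, which are what the analysis consumes, are unaffected by the
normalization. A sample left in every bootstrap (probability ≈ (1 − e⁻¹)⁵⁰
per sample) receives the majority class and is counted in `n_never_oob`.

## Network mapping

The union of the top PCA-contributing and top Gini-ranked genes is mapped
onto the full interactome as an induced subgraph. Components are labeled
deterministically (largest first; equal sizes break toward the
lexicographically smallest member set). Nodes whose *full-interactome*
degree falls below `min_degree_full` (default 10 — a heuristic
reconstruction: the published analysis set aside degree-3 and degree-7 genes
while keeping a degree-21 gene, and states no threshold) are excluded before
drawing. A selected gene outside the major component is reconnected by
searching the full interactome for paths to the component whose
intermediaries are *non-selected* proteins; the default policy returns every
shortest such path (several may exist), `policy="all_simple"` returns all
simple paths within the `max_intermediaries` bound (default 6). On graphs of
≤ 50 nodes the shortest-path results are tested against exhaustive
simple-path enumeration. Exports are GraphML (round-trip safe with
annotations) and SIF, both Cytoscape-readable; edges are undirected
throughout.

## Synthetic data: what it emulates, what it does not

No generative model exists for the real patient cohorts, so every
distributional choice below is a stand-in chosen once:

- **Interactome**: preferential attachment (clique seed of m + 1 nodes, m
  degree-weighted distinct attachments per new node), giving the heavy
  right degree tail of signaling networks. Default 2,000 genes, m = 2. Any
  heavy-tailed generator would do; this one is seeded and simple.
- **Pathways**: eight named pathways of 100 genes sharing a common core of
  `round(overlap × size)` genes, so pairwise overlaps are exact and the
  0 / 1 extremes mean disjoint / identical.
- **Cohort**: six pseudo-tissues with the sample sizes of the real design
  (27/48/50 H, 31/56/48 L; 125 vs 135 per class). Non-hub pathway genes get
  a class-shared baseline frequency uniform on [0.02, 0.45]; genes above the
  90th degree percentile are planted as H-enriched hubs (0.8 in H vs 0.25 in
  L — the strong-effect regime); 15% of non-hub genes are made
  class-exclusive by zeroing one class (mostly H-only, mirroring the real
  asymmetry); mild per-type multiplicative jitter (±15%) keeps the six rows
  distinguishable. Upregulation is independent Bernoulli per gene and
  sample.
- **Paired counts**: Gamma–Poisson with common dispersion (variance
  μ + φμ²), log-normal baseline expression, counts proportional to
  coding-sequence length (uniform 300–3,000 nt), planted genes at a fixed
  tumor/control fold change.

What this does *not* emulate: gene–gene expression correlation, tissue
composition and batch effects, dispersion–mean trends, overlapping biology
between pathways beyond set overlap, or any relation between a gene's degree
and its expression level beyond the planted enrichment. Passing tests
therefore demonstrate that the pipeline's machinery recovers structure it is
pointed at — calibrated calling, exact boundary search, class separation and
classification under planted effects — not that real cohorts contain such
structure.

## Problem sizes and numerical choices

Test and acceptance simulations use 500–2,000-gene interactomes, 260-sample
cohorts, 200 pairs × 1,000 genes for calling calibration, 20 replicates for
separation rates and 10–20 seeds for forest properties; these sizes make the
statistical properties measurable while keeping the default suite quick.
Tolerances: PCA vs eigendecomposition 1e−10; reconstruction 1e−8; printed
one-decimal table values ±0.05; binomial properties at 3 standard errors.
Tie-breaks are always deterministic (documented above); all randomness flows
from explicit integer seeds through `numpy.random.default_rng`, and derived
stage seeds are drawn below 2³¹.

## Known limitations

- The upregulation caller is a deliberate simplification of the original
  read-mapping pipeline: no alignment, no cross-sample dispersion modeling,
  per-pair thresholds only.
- The published real-data headline numbers (783 pathway genes, PC
  proportions 0.475/0.219/0.194, the 9 exclusive hubs at (27, 0.73)) depend
  on the TCGA cohorts and the 2017 IntAct interactome and are reference
  behavior, not desk-reproducible targets; the package reproduces the
  arithmetic their tables print from their stated inputs.
- Gini importance is biased toward features with more distinct values; with
  many correlated planted hubs the importance mass spreads across them,
  which is why the importance-recovery property is defined against few
  informative genes versus pure noise.
- The hub-boundary exclusivity objective returns one corner; near-ties on
  real data would deserve inspection of the full (c, f) frontier.
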