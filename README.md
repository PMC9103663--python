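# hubsig

Frequency-weighted interactome hub signatures of tumor aggressiveness.

Aggressive tumors tend to upregulate highly connected signaling proteins
(hubs) more often than mild ones. `hubsig` implements an analysis pipeline
that quantifies this: starting from per-sample lists of upregulated genes in
tumors grouped into a highly aggressive (H) and a less aggressive (L) class,
it restricts attention to the genes of the WNT pathway and seven cross-linked
signaling pathways (EGF, FGF, HEDGEHOG, mTOR, NF-κB, NOTCH, TGF-β), scores
each gene by *frequency × connectivity*, and asks which genes separate the
two classes.

The core statistic, per gene *g* and group (class or cancer type):

```
NormCount(g)        = (# samples in the group where g is upregulated) / group size
NormConnections(g)  = NormCount(g) × degree(g)
```

where `degree(g)` is the gene's number of interaction partners in a
reference protein–protein interactome. On top of this sit:

- a **variance filter** (cross-class variance of normalized counts > 0.005;
  class-exclusive genes always kept),
- a **hub-boundary grid search** for the (connections, frequency) corner
  occupied exclusively by H-class genes,
- **Kruskal–Wallis / pairwise Wilcoxon (Bonferroni)** comparisons of
  connection counts across cancer types within each pathway,
- **PCA** of the cancer-type × gene NormConnections matrix with per-gene
  squared-loading contribution percentages and variance shares, plus
  **hierarchical clustering** (manhattan distance) of the cancer types,
- a **random-forest classifier** (mtry = 8, ntree = 50, out-of-bag
  evaluation) of individual samples into H/L with mean-decrease-Gini gene
  importances,
- **sub-interactome mapping** of the selected genes: induced subgraph,
  major component, low-connectivity exclusion, and shortest bridging paths
  through non-selected intermediary proteins.

A fully seeded synthetic-data module (scale-free interactome grown by
preferential attachment, overlapping pathway annotations, class-structured
Bernoulli upregulation with planted hub enrichment, negative-binomial paired
counts with planted fold-changes) makes every stage testable end to end; a
simplified per-pair upregulation caller (length normalization, log
differential, normal-tail critical value at α = 0.025) covers the step from
paired count tables to upregulated gene sets.

Intended users: computational biologists exploring class-level expression /
network signatures, and anyone wanting a reproducible, tested reference for
the frequency × connectivity scoring approach.

## Worked example

```python
from hubsig.synthcohort import (generate_interactome, generate_pathways,
                                default_design, generate_cohort)
from hubsig.model import HubSignatureModel

inter = generate_interactome(n_genes=2000, edges_per_new_node=2, seed=7)
pathways = generate_pathways(inter, genes_per_pathway=100,
                             overlap_fraction=0.2, seed=8)
design = default_design(inter, pathways, seed=9)   # 125 H / 135 L samples
profiles, truth = generate_cohort(design, inter)

results = HubSignatureModel(profiles, inter, pathways).fit(seed=1)
print(results.summary())
```

prints

```
Hub signature analysis
==========================================================
Pathway genes observed        660  (H-only 53, L-only 34, shared 573)
Variance-filtered genes       190  (threshold 0.005)
Hub boundary (conn, freq)     (1.61, 0.536)  -> 77 H-exclusive hubs
PC variance proportions       0.949, 0.018, 0.013  (cumulative 0.981)
HC 2-branch class purity      1.000
Class scores (H / L)          477.9 / 149.9  (H larger by 69%)
RFC OOB error                 0.00%  (H 0.000, L 0.000; mtry=8, ntree=50)
Network major component       2 genes of 11; 9 bridged back
```

Reading this: 660 pathway genes were upregulated somewhere in the cohort, of
which 53 appear only in H samples and 34 only in L. After variance
filtering, 190 genes remain. 77 genes sit above the hub boundary — they are
frequent *and* connected in H while no L gene matches both thresholds. PC1
carries almost all the between-type variance (the planted hub enrichment is
a strong, one-dimensional effect here), the two-branch cut of the dendrogram
reproduces the H/L split exactly (purity 1.0), the summed
frequency × connectivity score of the top contributing genes is 69% larger
in H, and the forest classifies every sample's class correctly out-of-bag.
`results.top_pca_genes()`, `results.top_rfc_genes()`, the per-stage tables
on `results`, and `hubsig.plot.plot_pca / plot_dendrogram /
plot_importances` give the detail.

The same flow is scriptable: `hubsig simulate`, `hubsig fit`,
`hubsig score`, `hubsig upcall`, `hubsig network`, or `hubsig run --config
config.yaml` for the whole pipeline with a manifest of parameters, seeds and
input digests.

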