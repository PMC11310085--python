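# Methods

## Overview

`contextppi` builds cell type-specific protein-protein interaction (PPI)
networks from a single-cell expression atlas and a reference interactome,
organizes the cell types and tissues into a metagraph, and trains a
multiscale graph attention model that places every (protein, cell type)
pair, every cell type and every tissue into one embedding space. The
embeddings are then interrogated post hoc (spatial enrichment, tissue
hierarchy retrieval, cross-context similarity) and fine-tuned for
cell-type-specific therapeutic-target prioritization.

All experiments in the test suite and the acceptance script run on
synthetic data with planted structure; real atlases and interactome
releases are deliberately out of scope for the bundled experiments.

## Network construction

**Activated genes.** For a cell type c, each gene is scored by a
tie-corrected Wilcoxon rank-sum z statistic comparing its expression in
cells of c against all other cells. Per iteration, a fraction (default
0.8) of cells is subsampled without replacement — stratified within the
target group and the rest so both survive — genes are ranked by the
statistic (ties broken lexicographically by gene id for determinism), and
the top K are flagged. A gene is *activated* when flagged in at least 90%
of N = 10 iterations. K and N are configuration parameters; the subsampled
iteration is what makes the 90% retention rule meaningful.

**Context networks.** The reference interactome is induced on the
activated genes and restricted to its largest connected component.
Networks below a minimum size are rejected with a reason rather than
raising. The production default minimum is 1,000 proteins; fixture-scale
studies use 20.

**Cell-cell communication.** A ligand-receptor (LR) pair (l, r) supports
communication from cell type A to B when the statistic
mean expression of l in A x mean expression of r in B exceeds the null
built by shuffling cell-type labels (default 1,000 permutations over a
25% stratified cell subsample). A CC edge joins any pair of retained cell
types with at least one LR p-value below alpha = 0.001. This is a
deliberately simplified permutation test, not a reimplementation of a
full communication-inference tool.

**Metagraph.** Cell types link to the tissue their cells were sampled
from (CT edges); tissues carry the ontology's parent-child edges (TT)
restricted to sampled tissues plus all ancestors up to the root. The
tissue edges always form one rooted tree.

## The multiscale attention model

Two layers; each layer runs a four-step cycle:

1. **Protein-level attention** on every context network, with GATv2-style
   scores `a^T LeakyReLU(W_l h_u + W_r h_v)`, softmax-normalized over the
   neighborhood (self-loop included), multi-head (K = 8). Each context has
   its own `W`, `a`. The first layer concatenates heads; the output layer
   averages them.
2. **Bridge, proteins to cell type.** Attention weights gamma (softmax of a
   GATv2-style compatibility between the cell-type embedding and each of
   its proteins) pool the context's protein embeddings into the cell-type
   embedding. Because the layer changes dimensionality, metagraph nodes
   pass through a learned projection `U` at the same step; this projection
   is the package's dimension-alignment choice, shared by cell types and
   tissues within a layer.
3. **Metagraph attention** per edge type (CC, CT, TC, TT) with per-type
   parameters, mixed by edge-type weights beta computed from shared
   parameters `s, M, b` via `m_r = sum_u s^T tanh(M h_u^r + b)` and a
   softmax over the edge types incident to each node kind.
4. **Bridge, cell type to protein.** Each protein embedding is incremented
   by its gamma-scaled cell-type embedding.

Layer-norm follows the first layer and batch-norm the output layer (both
switchable, no learnable affine parameters). Output batch statistics are
computed jointly across all contexts: normalizing each context separately
would zero every context's mean and erase exactly the between-context
separation the center loss builds. Proteins share one learnable Gaussian
feature vector across contexts; cell types initialize at the mean of their
proteins' features and tissues at the mean of already-initialized
metagraph neighbors, resolved in breadth-first order from the
cell-type-attached tissues outward.

The functional form of the bridge attention is this package's choice
(GATv2-style compatibility with a dedicated shared parameter set); only
the existence of learned gamma weights is fixed by the architecture's
contract. Edges are scored by a bilinear decoder
`sigma(sum_k z_u[k] r_i[k] z_v[k])` with one edge-type embedding `r_i` per
type (PP shared across contexts, plus CC, CT, TC, TT).

## Training

PP edges split 80/10/10 per context; metagraph edges are all used for
training (they are few and carry the organization). Negatives are
structured corruptions of one endpoint at a 1:1 ratio, resampled each
epoch; validation/test negatives are fixed once. Validation and test edges
are masked out of the message-passing graph during training.

Loss: `L = theta L_ppi + lambda L_center + (1 - theta)(L_celltype +
L_tissue)` with summed binary cross-entropy link terms per edge type and a
center loss `sum ||z_u - z_c||^2` over proteins incident to train edges.
Optimization is Adam with L2 weight decay 1e-5. The two task
learning rates (link prediction and cell-type classification) are realized
as a single optimizer at the link rate with the center-loss gradient
scaled by `lr_center / lr_link`. Model selection picks the epoch with the
best validation link AUROC, ties broken by the Calinski-Harabasz score of
protein embeddings labeled by context; how to combine the two criteria is
not fixed by the architecture, and primary/tie-break is this package's
rule. Final embeddings are produced from the full (unmasked) graphs with
the selected parameters.

Default hyperparameters are the full-scale configuration
(feature dim 1,024, output 16, 8 heads, dropout 0.6, lr 0.01/0.1, lambda
0.1, weight decay 1e-5, 250 epochs). The fixture configuration used by the
tests and the acceptance script scales this to desk size: feature dim 64,
output 16, dropout 0.2, 200 epochs, and `lr_center = lr_link = 0.01`. The
center rate matters: with ~55 proteins per context and a 16-d output, the
full-scale center rate (10x the link rate) collapses each context onto its
center within tens of epochs, destroying link prediction; equalizing the
rates keeps the effective center weight at lambda = 0.1.

## Synthetic data: what it emulates, and what it does not

The generator plants every signal the pipeline is later asked to recover:

- **Reference interactome**: a stochastic block model; each cell type owns
  three dense sub-blocks (p_in = 0.6) of 15 proteins, weakly
  interconnected (p_out = 0.01). The sub-block structure matters: a single
  Erdos-Renyi community has no learnable within-context topology, making
  held-out link prediction impossible at any model capacity.
- **Broadly active proteins**: a shared pool of 28 proteins, each active
  on a contiguous window (breadth 1 to 4, balanced design with
  deterministic window starts) of the cell-type chain ct1-...-ct5. Pool
  proteins interact with pool proteins whose windows overlap and with
  block proteins of their window types. This encodes two observations
  about real interactomes: a protein active in few cell types is active
  in *related* ones, and it keeps much of its interaction neighborhood
  across them, whereas a broadly active protein's partners diverge by
  context. This is what makes cross-context similarity decline with
  context count in the trained space. Breadth is capped below the number
  of cell types because a gene elevated in every type is not
  differentially expressed anywhere and could never be recovered as a
  marker.
- **Atlas**: Poisson counts (negative binomial optional via a dispersion
  parameter), marker genes at `base_rate x marker_fold` in their cell
  type(s), `base_rate` elsewhere. Defaults: 5 cell types, 100 cells each,
  base rate 1, fold 10.
- **Tissue ontology**: a 12-leaf binary tree; the five cell types sit on
  evenly spaced leaves, so chain-adjacent cell types are also close in
  the tissue hierarchy.
- **LR pairs**: ligands from the first type's own-community markers,
  receptors from the second's, planted along the chain.
- **Target labels**: a logistic model with elevated log-odds (+3) for
  proteins in the causal cell type's community, base rate 0.15 elsewhere.

Not emulated: depth variation, doublets, ambient RNA, batch effects,
realistic interactome degree distributions, protein complexes. Passing
tests therefore demonstrate that the machinery recovers planted signal at
desk scale, not that it reproduces full-scale results on real data.

## Evaluation choices

- **Tissue distances**: ontology distance is the sum of both nodes'
  shortest paths to their lowest common ancestor; embedding distance is
  cosine. The null shuffles ontology node identities (10 times by
  default).
- **Spatial enrichment**: pairwise cosine similarity thresholded into a
  graph, largest connected component, neighborhoods as shortest-path
  balls of radius `0.15 x` the maximum pairwise distance, hypergeometric
  enrichment of the focal context's label with Benjamini-Hochberg
  correction, NES = min(-log10 p_adj, 16)/16. Path lengths are weighted
  by cosine distance (1 - similarity): on desk-scale graphs the
  thresholded graph is often dense enough that unweighted hop distances
  saturate at one or two, which would make every neighborhood either a
  singleton or the whole population. Desk-scale evaluations sample 15
  focal + 25 per background context (keeping the focal label a minority,
  as it is at full scale where 50 focal nodes sit among ~1,500
  background) and use threshold 0.05 so all context clusters stay in one
  component; the function's defaults remain the full-scale settings
  (50/10, threshold 0.3).
- **Permutation test**: the p-value is the plain fraction of permuted
  gaps at or above the observed gap; the conservative (k+1)/(n+1) variant
  is available behind a flag. Under exchangeability a single draw's
  one-sided p is uniform (not 0.5); only its expectation over draws is
  0.5, which is what the calibration test checks.
- **APR@K**: computed in exact rational arithmetic; `r` is the number of
  relevant items within the top K and APR@K = 0 when r = 0. Promotion of
  a relevant item within the top K never lowers the score; promotion
  across the K boundary can, because r changes.

## Fine-tuning

Labels live on protein identities; records are (protein, context)
embeddings. Splits are by protein identity (60/20/20, stratified by
label), then positives are greedily reassigned so each context keeps at
least one positive per split where feasible; contexts without any
positive are flagged unscorable. The scorer is a two-hidden-layer MLP
(16/16, ReLU, dropout 0.5 and layer-norm between input and hidden layer)
trained with binary cross-entropy, best epoch by validation AUPRC.
Contexts are ranked by APR@5 on their held-out test records, averaged
over seeds (3 in fixture runs, 10 by default at full scale).

## Numerical infrastructure

The model and the MLP are trained with a small reverse-mode automatic
differentiation engine over numpy arrays (`contextppi._autograd`),
providing dense linear algebra, elementwise nonlinearities and the
gather/segment primitives needed for per-neighborhood softmax. Every
primitive is verified against central finite differences in the test
suite. Softmaxes subtract the per-segment maximum (as a constant) for
stability; BCE probabilities are clamped at 1e-12 from both ends;
divergence (non-finite loss or embeddings) aborts with the layer
identified.

## Known limitations

- Full-graph training only; no mini-batching or neighbor sampling, so
  the implementation is for desk-scale studies and method development.
- The spatial-enrichment procedure asserts a statistical contract
  (planted clusters enrich, label-randomized nulls do not), not parity
  with any particular reference implementation.
- The bilinear decoder's PP edge-type embedding is shared across
  contexts; whether it should be context-specific is an open modelling
  choice.
- Problem sizes in the bundled experiments (5 cell types, ~60 proteins
  per context, 200 epochs, 3 seeds) are the package's chosen desk-scale
  study conditions.
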