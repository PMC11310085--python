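# contextppi

Proteins do different jobs in different cell types, but most protein
representation learning produces a single context-free vector per protein.
`contextppi` builds **cell type-specific protein interaction networks**
from a single-cell expression atlas and a reference interactome, links the
cell types and tissues into a **metagraph** (cell-cell communication,
cell-tissue provenance, tissue-hierarchy edges), and trains a **multiscale
graph attention network** that embeds every (protein, cell type) pair —
plus every cell type and tissue — into one shared space. On top of the
embeddings it provides the corresponding analyses: spatial enrichment of
embedding regions, zero-shot tissue-hierarchy retrieval, cross-context
similarity trends, contextualization of structure-based protein vectors,
and fine-tuned, cell-type-specific therapeutic-target ranking.

It is aimed at computational biologists who want a transparent,
desk-scale, fully testable implementation of contextual protein
representation learning: every input can be simulated with planted ground
truth, and every claim the package makes is checked against that truth.

## The model in brief

For each cell type $c_i$ with PPI network $G_{c_i}$, a two-layer attention
model updates protein embeddings

$$h_u \leftarrow \mathrm{AGG}\Big(\sigma\Big(\sum_{v \in N(u)} \alpha_{u,v} W^{PP} h_v\Big)\Big),$$

with GATv2-style attention $\alpha$ over the neighborhood (self-loop
included) and per-context parameters. Attention weights $\gamma_{c_i,u}$
pool each context's proteins into its cell-type embedding; metagraph
attention propagates over CC/CT/TC/TT edges with edge-type mixing weights
$\beta$; and the updated cell-type embedding is pushed back,
$h_u \leftarrow h_u + \gamma_{c_i,u} h_{c_i}$. Edges are scored by a
bilinear decoder $\hat y_{u,v} = \sigma(z_u \cdot r_i \cdot z_v)$ and the
loss combines the three biological scales,

$$\mathcal{L} = \theta\,\mathcal{L}_{\mathrm{ppi}} + \lambda\,\mathcal{L}_{\mathrm{center}} + (1-\theta)\,(\mathcal{L}_{\mathrm{celltype}} + \mathcal{L}_{\mathrm{tissue}}),$$

where the center loss $\sum_{c_i}\sum_{u \in V_{c_i}} \lVert z_u - z_{c_i}\rVert_2^2$
pulls each protein toward its cell-type center, separating contexts in the
latent space. Gradients come from a small numpy reverse-mode autodiff
engine included in the package; see `docs/methods.md` for the full model,
training and evaluation description.

## Worked example

```python
from contextppi.synthetic import generate_fixture
from contextppi.pipeline import build_study, pretrain_study
from contextppi.evaluation import tissue_distance_correlation

fixture = generate_fixture(seed=1)          # atlas + interactome + ontology,
study = build_study(fixture, seed=1)        # activation -> networks -> metagraph
result = pretrain_study(study, seed=1)      # multiscale attention pretraining
print(result.summary())
corr = tissue_distance_correlation(
    result.embedding_space.tissue, fixture.ontology, seed=0
)
print(f"tissue rho = {corr.spearman_rho:.2f}  (p = {corr.spearman_p:.1e})")
```

prints (numbers from this exact run):

```
Multiscale embedding pretraining
========================================
contexts:            5
proteins (unique):   253
representations:     295
tissues:             16
epochs run:          200
best epoch:          11
val link AUROC:      0.9570
test link AUROC:     0.9076
final L_ppi:         474.0846
final L_center:      997.4613
final L_celltype:    4.7252
final L_tissue:      21.2459
tissue rho = 0.52  (p = 1.7e-09)
```

The study has 5 planted cell types over a 253-protein interactome; 295
(protein, cell type) representations are learned jointly with 5 cell-type
and 16 tissue embeddings. Held-out protein-interaction edges are predicted
with AUROC 0.91, and tissue embedding distances correlate with
tissue-ontology distances (Spearman rho 0.52) — the embedding space has
absorbed the planted cellular and tissue organization.

The same pipeline is scriptable from the shell:

```bash
contextppi simulate --out study/ --seed 1
contextppi construct --data study/ --out nets/ --top-k 60 --min-size 20 --seed 1
contextppi train --networks-dir nets/ --metagraph nets/metagraph.tsv --out run/ --seed 1
contextppi finetune --embeddings run/embeddings.tsv --labels study/labels.tsv --out ft/ --k 5
contextppi evaluate tissue-corr --embeddings run/embeddings.tsv --ontology study/tissues.tsv
```

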