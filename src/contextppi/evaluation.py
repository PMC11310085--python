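"""Post hoc analyses of the contextual embedding space.

Covers the organization statistics reported for the trained space: the
tissue-ontology distance correlation with a shuffled-hierarchy null, the
cross-context similarity trend, a spatial enrichment analysis of the
embedding similarity graph (hypergeometric neighborhoods with BH
correction), structure-representation contextualization, and the one-sided
permutation test on binding-score gaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats
from sklearn.metrics.pairwise import cosine_similarity
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TissueOntologyView",
    "PatchMatrix",
    "EnrichmentReport",
    "TissueCorrelation",
    "tissue_ontology_distance",
    "tissue_distance_correlation",
    "cross_context_similarity",
    "spatial_enrichment",
    "reduce_patch_matrix",
    "contextualize_structure",
    "score_gap_permutation_test",
    "pairwise_cosine",
]


@dataclass
class TissueOntologyView:
    """Rooted tissue tree: nodes, child -> parent map and the root."""

    parent: dict[str, str]

    def __post_init__(self):
        roots = set(self.parent.values()) - set(self.parent)
        if len(roots) != 1:
            raise ValueError(f"ontology must have exactly one root, got {roots}")
        self.root = roots.pop()
        self.nodes = set(self.parent) | {self.root}
        # acyclicity: every chain must reach the root
        for n in self.parent:
            seen = {n}
            cur = n
            while cur != self.root:
                cur = self.parent[cur]
                if cur in seen:
                    raise ValueError("ontology contains a cycle")
                seen.add(cur)

    def depth_chain(self, node: str) -> list[str]:
        chain = [node]
        while chain[-1] != self.root:
            chain.append(self.parent[chain[-1]])
        return chain


def tissue_ontology_distance(t1: str, t2: str, ontology) -> int:
    """Sum of both nodes' path lengths to their lowest common ancestor."""
    view = ontology if isinstance(ontology, TissueOntologyView) else TissueOntologyView(dict(ontology))
    if t1 not in view.nodes or t2 not in view.nodes:
        raise KeyError(f"unknown tissue in {t1!r}, {t2!r}")
    c1, c2 = view.depth_chain(t1), view.depth_chain(t2)
    anc2 = {n: i for i, n in enumerate(c2)}
    for i, n in enumerate(c1):
        if n in anc2:
            return i + anc2[n]
    raise RuntimeError("no common ancestor found")  # unreachable on a tree


def pairwise_cosine(vectors: np.ndarray) -> np.ndarray:
    """Symmetric cosine similarity matrix with an exactly-unit diagonal."""
    vectors = np.asarray(vectors, dtype=float)
    norms = np.linalg.norm(vectors, axis=1)
    if np.any(norms == 0):
        raise ValueError("cosine similarity undefined for zero vectors")
    sim = cosine_similarity(vectors)
    np.fill_diagonal(sim, 1.0)
    return (sim + sim.T) / 2.0


@dataclass
class TissueCorrelation:
    spearman_rho: float
    spearman_p: float
    ks_statistic: float
    ks_p: float
    null_rhos: np.ndarray  # shuffled-ontology correlation distribution


def tissue_distance_correlation(
    tissue_embeddings: dict[str, np.ndarray],
    ontology,
    n_shuffles: int = 10,
    seed: int = 0,
) -> TissueCorrelation:
    """Correlate embedding cosine distances with tissue-ontology distances.

    Also compares the embedding-distance distribution to distances between
    standard-normal random vectors (two-sample KS) and builds a null of
    Spearman correlations by shuffling the ontology node identities.
    """
    names = sorted(tissue_embeddings)
    if len(names) < 3:
        raise ValueError("need at least 3 tissues")
    view = ontology if isinstance(ontology, TissueOntologyView) else TissueOntologyView(dict(ontology))
    vecs = np.vstack([tissue_embeddings[t] for t in names])
    cos_dist = 1.0 - pairwise_cosine(vecs)
    iu = np.triu_indices(len(names), k=1)
    emb_d = cos_dist[iu]
    onto_d = np.array(
        [
            tissue_ontology_distance(names[i], names[j], view)
            for i, j in zip(*iu)
        ],
        dtype=float,
    )
    rho, pval = scipy.stats.spearmanr(emb_d, onto_d)

    rng = np.random.default_rng(seed)
    rand = rng.standard_normal(vecs.shape)
    rand_d = (1.0 - pairwise_cosine(rand))[iu]
    ks_stat, ks_p = scipy.stats.ks_2samp(emb_d, rand_d)

    null = []
    for _ in range(n_shuffles):
        perm = rng.permutation(len(names))
        onto_shuf = np.array(
            [
                tissue_ontology_distance(names[perm[i]], names[perm[j]], view)
                for i, j in zip(*iu)
            ],
            dtype=float,
        )
        null.append(scipy.stats.spearmanr(emb_d, onto_shuf)[0])
    return TissueCorrelation(
        spearman_rho=float(rho),
        spearman_p=float(pval),
        ks_statistic=float(ks_stat),
        ks_p=float(ks_p),
        null_rhos=np.array(null),
    )


def cross_context_similarity(space) -> tuple[pd.DataFrame, float, float]:
    """Mean pairwise cosine similarity of each multi-context protein's
    embeddings, and the Spearman trend against its context count.

    Returns (per-protein table, spearman rho, p-value)."""
    by_protein: dict[str, list[np.ndarray]] = {}
    for (p, _c), vec in space.protein.items():
        by_protein.setdefault(p, []).append(vec)
    rows = []
    for p, vecs in sorted(by_protein.items()):
        if len(vecs) < 2:
            continue
        sim = pairwise_cosine(np.vstack(vecs))
        iu = np.triu_indices(len(vecs), k=1)
        rows.append((p, len(vecs), float(sim[iu].mean())))
    if not rows:
        raise ValueError("no protein appears in >= 2 contexts")
    df = pd.DataFrame(rows, columns=["protein", "n_contexts", "mean_similarity"])
    if df["n_contexts"].nunique() > 1:
        rho, pval = scipy.stats.spearmanr(df["n_contexts"], df["mean_similarity"])
    else:
        rho, pval = np.nan, np.nan
    return df, float(rho), float(pval)


@dataclass
class EnrichmentReport:
    context: str
    mean_nes: float
    max_nes: float
    n_enriched: int
    neighborhood_pvalues: np.ndarray  # BH-adjusted, one per neighborhood
    nes: np.ndarray
    n_nodes: int


def spatial_enrichment(
    space,
    context: str,
    threshold: float = 0.3,
    radius_frac: float = 0.15,
    alpha: float = 0.05,
    sample_sizes: tuple[int, int] = (50, 10),
    seed: int = 0,
    labels: dict | None = None,
) -> EnrichmentReport:
    """Spatial enrichment of a cell-type label over the embedding graph.

    Samples ``sample_sizes[0]`` embeddings from the focal context and
    ``sample_sizes[1]`` from every other context, links pairs with cosine
    similarity >= ``threshold``, keeps the largest connected component, and
    tests each shortest-path-ball neighborhood (radius = ``radius_frac`` x
    the maximum finite pairwise distance) for overrepresentation of the
    focal label with a hypergeometric test, BH-corrected. The neighborhood
    enrichment score is min(-log10 p_adj, 16) / 16.

    ``labels`` optionally overrides the per-(protein, context) binary label
    (used for label-randomized nulls).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    rng = np.random.default_rng(seed)
    keys_by_ctx: dict[str, list] = {}
    for key in sorted(space.protein):
        keys_by_ctx.setdefault(key[1], []).append(key)
    if context not in keys_by_ctx:
        raise ValueError(f"unknown context {context!r}")
    chosen: list = []
    for c, keys in sorted(keys_by_ctx.items()):
        k = sample_sizes[0] if c == context else sample_sizes[1]
        k = min(k, len(keys))
        sel = rng.choice(len(keys), size=k, replace=False)
        chosen.extend(keys[i] for i in sorted(sel))
    vecs = np.vstack([space.protein[k] for k in chosen])
    lab = np.array(
        [
            (labels[k] if labels is not None else int(k[1] == context))
            for k in chosen
        ]
    )
    sim = pairwise_cosine(vecs)
    adj = sim >= threshold
    np.fill_diagonal(adj, False)
    g = nx.Graph()
    g.add_nodes_from(range(len(vecs)))
    for i, j in zip(*np.nonzero(np.triu(adj))):
        # cosine-distance edge weights keep neighborhoods local even when
        # the thresholded graph is dense (hop distances saturate at 1-2)
        g.add_edge(int(i), int(j), weight=max(1.0 - sim[i, j], 1e-9))
    if g.number_of_edges() == 0:
        raise ValueError("similarity graph empty; lower the threshold")
    lcc = max(nx.connected_components(g), key=lambda c: (len(c), min(c)))
    nodes = sorted(lcc)
    sub = g.subgraph(nodes)
    spl = dict(nx.all_pairs_dijkstra_path_length(sub, weight="weight"))
    max_d = max(d for row in spl.values() for d in row.values())
    radius = radius_frac * max_d
    lab_lcc = lab[nodes]
    n_pop = len(nodes)
    k_pop = int(lab_lcc.sum())
    pvals = []
    for u in nodes:
        ball = [v for v, d in spl[u].items() if d <= radius]
        n_ball = len(ball)
        k_ball = int(lab[np.array(ball)].sum())
        # P(X >= k_ball) drawing n_ball from pop with k_pop successes
        pvals.append(scipy.stats.hypergeom.sf(k_ball - 1, n_pop, k_pop, n_ball))
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    with np.errstate(divide="ignore"):
        nes = np.minimum(-np.log10(np.maximum(p_adj, 1e-300)), 16.0) / 16.0
    return EnrichmentReport(
        context=context,
        mean_nes=float(nes.mean()),
        max_nes=float(nes.max()),
        n_enriched=int((p_adj < alpha).sum()),
        neighborhood_pvalues=p_adj,
        nes=nes,
        n_nodes=n_pop,
    )


@dataclass
class PatchMatrix:
    """Per-patch structure vectors for one protein (P patches x d dims)."""

    protein: str
    patches: np.ndarray
    binding_scores: np.ndarray | None = None

    def __post_init__(self):
        self.patches = np.atleast_2d(np.asarray(self.patches, dtype=float))
        if self.patches.shape[0] < 1 or self.patches.shape[1] < 1:
            raise ValueError("patch matrix must be P x d with P, d >= 1")
        if self.binding_scores is not None:
            self.binding_scores = np.asarray(self.binding_scores, dtype=float)
            if len(self.binding_scores) != self.patches.shape[0]:
                raise ValueError("binding_scores length must equal patch count")


def reduce_patch_matrix(patch: PatchMatrix, k: int = 200) -> np.ndarray:
    """Keep the k patches most likely to be in the binding site and take the
    per-patch median across dimensions, giving a length-k vector."""
    P = patch.patches.shape[0]
    if k > P:
        raise ValueError(f"k={k} exceeds patch count {P}")
    scores = (
        patch.binding_scores
        if patch.binding_scores is not None
        else patch.patches[:, 0]
    )
    order = np.argsort(-scores, kind="stable")[:k]
    kept = patch.patches[order]
    return np.median(kept, axis=1)


def contextualize_structure(
    struct_vec: np.ndarray, context_embeddings: dict[str, np.ndarray]
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Concatenate a structure vector with each contextual embedding, and
    with the across-context mean for the context-free variant."""
    struct_vec = np.asarray(struct_vec, dtype=float)
    if struct_vec.size == 0 or not context_embeddings:
        raise ValueError("need a nonempty structure vector and >= 1 context")
    per_context = {
        c: np.concatenate([struct_vec, np.asarray(v, dtype=float)])
        for c, v in sorted(context_embeddings.items())
    }
    mean_emb = np.mean([np.asarray(v, float) for v in context_embeddings.values()], axis=0)
    context_free = np.concatenate([struct_vec, mean_emb])
    return per_context, context_free


def score_gap_permutation_test(
    binding_scores,
    nonbinding_scores,
    n_iter: int = 100_000,
    seed: int = 0,
    add_one: bool = False,
) -> tuple[float, float]:
    """One-sided permutation test on mean(binding) - mean(nonbinding).

    The p-value is the fraction of label permutations whose gap is >= the
    observed gap (``add_one`` switches to the conservative (k+1)/(n+1)
    estimator).
    """
    b = np.asarray(binding_scores, dtype=float)
    nb = np.asarray(nonbinding_scores, dtype=float)
    if b.size == 0 or nb.size == 0 or n_iter < 1:
        raise ValueError("both score lists must be nonempty and n_iter >= 1")
    observed = float(b.mean() - nb.mean())
    pooled = np.concatenate([b, nb])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_iter):
        perm = rng.permutation(pooled)
        gap = perm[: b.size].mean() - perm[b.size :].mean()
        if gap >= observed:
            count += 1
    p = (count + 1) / (n_iter + 1) if add_one else count / n_iter
    return observed, float(p)
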