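"""Cell type-specific PPI networks and the cell-type/tissue metagraph.

A gene is *activated* in a cell type when it ranks among the top-K genes by
a Wilcoxon rank-sum statistic (cells of the type vs all other cells) in at
least a ``retention`` fraction of subsampled iterations. Each cell type's
network is the largest connected component of the reference interactome
induced on its activated genes; small networks are rejected.

Cell types and tissues form a metagraph: cell-cell (CC) edges supported by a
significantly expressed ligand-receptor pair under a permutation test,
cell-tissue (CT) provenance edges, and tissue-tissue (TT) ontology edges up
to the root.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "ActivationResult",
    "CellTypePPINetwork",
    "RejectedNetwork",
    "Metagraph",
    "compute_gene_activation",
    "build_celltype_network",
    "lr_significance_test",
    "build_metagraph",
]


@dataclass
class ActivationResult:
    gene: str
    statistics: list[float]  # per-iteration rank-sum z statistic
    flagged: list[bool]  # per-iteration membership in the top-K
    retention_fraction: float
    activated: bool


@dataclass
class CellTypePPINetwork:
    context: str
    nodes: list[str]
    edges: set[tuple[str, str]]  # sorted unordered pairs
    provenance: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        node_set = set(self.nodes)
        for u, v in self.edges:
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge ({u},{v}) references unknown node")

    @property
    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


@dataclass
class RejectedNetwork:
    context: str
    reason: str
    n_nodes: int


@dataclass
class Metagraph:
    cell_types: set[str]
    tissues: set[str]
    cc_edges: set[tuple[str, str]]  # sorted unordered cell-type pairs
    ct_edges: set[tuple[str, str]]  # (cell type, tissue)
    tt_edges: set[tuple[str, str]]  # (child tissue, parent tissue)

    def validate(self) -> None:
        for a, b in self.cc_edges:
            if a not in self.cell_types or b not in self.cell_types:
                raise ValueError("CC edge endpoints must be cell types")
        for c, t in self.ct_edges:
            if c not in self.cell_types or t not in self.tissues:
                raise ValueError("CT edges must link a cell type to a tissue")
        parents: dict[str, str] = {}
        for child, parent in self.tt_edges:
            if child not in self.tissues or parent not in self.tissues:
                raise ValueError("TT edge endpoints must be tissues")
            if child in parents:
                raise ValueError(f"tissue {child} has multiple parents")
            parents[child] = parent
        roots = self.tissues - set(parents)
        if self.tt_edges and len(roots) != 1:
            raise ValueError(f"tissue edges must form one rooted tree, roots={roots}")
        uncovered = self.cell_types - {c for c, _ in self.ct_edges}
        if uncovered:
            raise ValueError(f"cell types without a tissue edge: {uncovered}")

    @property
    def root(self) -> str | None:
        children = {c for c, _ in self.tt_edges}
        roots = self.tissues - children
        return min(roots) if roots else None


def _ranksum_z(counts: np.ndarray, target_mask: np.ndarray) -> np.ndarray:
    """Tie-corrected Wilcoxon rank-sum z statistic per gene (rows).

    Positive z means higher expression in the target cells.
    """
    n1 = int(target_mask.sum())
    n2 = counts.shape[1] - n1
    n = n1 + n2
    ranks = scipy.stats.rankdata(counts, axis=1)
    r1 = ranks[:, target_mask].sum(axis=1)
    mu = n1 * (n + 1) / 2.0
    tie_term = np.zeros(counts.shape[0])
    for i in range(counts.shape[0]):
        _, t = np.unique(counts[i], return_counts=True)
        tie_term[i] = np.sum(t**3 - t)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    z = np.zeros(counts.shape[0])
    nz = var > 0
    z[nz] = (r1[nz] - mu) / np.sqrt(var[nz])
    return z


def compute_gene_activation(
    atlas,
    context: str,
    top_k: int,
    n_iterations: int = 10,
    subsample_frac: float = 0.8,
    retention: float = 0.9,
    seed: int = 0,
) -> list[ActivationResult]:
    """Iterated rank-sum activation test for one cell type.

    Each iteration subsamples ``subsample_frac`` of the cells (within the
    target type and the rest separately, so both groups survive), ranks
    genes by the rank-sum statistic of target-vs-rest expression, and flags
    the top ``top_k``. A gene is activated when flagged in at least
    ``retention`` of the iterations. Ties in the ranking are broken by gene
    id for determinism.
    """
    if top_k > len(atlas.gene_ids):
        raise ValueError("top_k exceeds the number of genes")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if not atlas.counts.any():
        raise ValueError("count matrix is all zero")
    target_idx = atlas.cells_of_type(context)
    if len(target_idx) < 2:
        raise ValueError(f"context {context!r} has fewer than 2 cells")
    rest_idx = np.setdiff1d(np.arange(len(atlas.cell_ids)), target_idx)
    if len(rest_idx) < 1:
        raise ValueError("no reference cells outside the target type")

    rng = np.random.default_rng(seed)
    genes = np.array(atlas.gene_ids)
    lex_order = np.argsort(genes)  # tie-break: lexicographic gene id
    lex_rank = np.empty(len(genes))
    lex_rank[lex_order] = np.arange(len(genes))

    stats = np.zeros((len(genes), n_iterations))
    flagged = np.zeros((len(genes), n_iterations), dtype=bool)
    for it in range(n_iterations):
        t_sub = rng.choice(
            target_idx, size=max(2, int(round(subsample_frac * len(target_idx)))),
            replace=False,
        )
        r_sub = rng.choice(
            rest_idx, size=max(1, int(round(subsample_frac * len(rest_idx)))),
            replace=False,
        )
        cols = np.concatenate([t_sub, r_sub])
        mask = np.zeros(len(cols), dtype=bool)
        mask[: len(t_sub)] = True
        z = _ranksum_z(atlas.counts[:, cols], mask)
        stats[:, it] = z
        order = np.lexsort((lex_rank, -z))  # z desc, then gene id asc
        flagged[order[:top_k], it] = True

    results = []
    for i, g in enumerate(genes):
        frac = float(flagged[i].mean())
        results.append(
            ActivationResult(
                gene=str(g),
                statistics=list(stats[i]),
                flagged=list(flagged[i]),
                retention_fraction=frac,
                activated=bool(frac >= retention),
            )
        )
    return results


def build_celltype_network(
    activated_genes: set[str],
    reference_edges: list[tuple[str, str]],
    min_size: int = 1000,
    context: str = "",
    provenance: dict[str, float] | None = None,
) -> CellTypePPINetwork | RejectedNetwork:
    """Induce the reference interactome on activated genes; keep the LCC.

    Returns the network when its largest connected component has at least
    ``min_size`` proteins, otherwise a :class:`RejectedNetwork` with the
    reason (never an exception for an empty activated set).
    """
    if not reference_edges:
        raise ValueError("reference edge list is empty")
    ref = nx.Graph()
    ref.add_edges_from(reference_edges)
    sub = ref.subgraph(set(activated_genes) & set(ref.nodes))
    if sub.number_of_nodes() == 0:
        return RejectedNetwork(context, "no activated genes in reference", 0)
    lcc = max(nx.connected_components(sub), key=lambda c: (len(c), min(c)))
    if len(lcc) < min_size:
        return RejectedNetwork(
            context, f"largest component has {len(lcc)} < {min_size} proteins", len(lcc)
        )
    comp = sub.subgraph(lcc)
    prov = provenance or {}
    return CellTypePPINetwork(
        context=context,
        nodes=sorted(comp.nodes),
        edges={tuple(sorted(e)) for e in comp.edges},
        provenance={g: prov.get(g, 1.0) for g in comp.nodes},
    )


def lr_significance_test(
    atlas,
    lr_pairs: list[tuple[str, str]],
    n_permutations: int = 1000,
    subsample_frac: float = 0.25,
    alpha: float = 0.001,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation test for ligand-receptor communication between cell types.

    For an ordered cell-type pair (A, B) and LR pair (l, r) the statistic is
    mean expression of l in A times mean expression of r in B; the null is
    built by shuffling cell-type labels. Both orientations of every
    unordered cell-type pair are tested. Returns one row per (ordered pair,
    LR pair) with the observed statistic and permutation p-value.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    gene_index = {g: i for i, g in enumerate(atlas.gene_ids)}
    for l, r in lr_pairs:
        if l not in gene_index or r not in gene_index:
            raise ValueError(f"LR gene missing from atlas: {l}/{r}")
    rng = np.random.default_rng(seed)
    cell_types = atlas.cell_types

    # stratified subsample so every cell type keeps cells
    keep: list[int] = []
    for ct in cell_types:
        idx = atlas.cells_of_type(ct)
        size = max(2, int(round(subsample_frac * len(idx))))
        keep.extend(rng.choice(idx, size=size, replace=False))
    keep = np.array(sorted(keep))
    labels = np.array([atlas.cell_type[atlas.cell_ids[i]] for i in keep])
    genes_used = sorted({g for p in lr_pairs for g in p})
    gi = {g: k for k, g in enumerate(genes_used)}
    expr = atlas.counts[[gene_index[g] for g in genes_used]][:, keep].astype(float)

    def type_means(lab: np.ndarray) -> np.ndarray:
        out = np.zeros((len(cell_types), len(genes_used)))
        for a, ct in enumerate(cell_types):
            out[a] = expr[:, lab == ct].mean(axis=1)
        return out

    obs_means = type_means(labels)
    null_means = np.zeros((n_permutations,) + obs_means.shape)
    for p in range(n_permutations):
        null_means[p] = type_means(rng.permutation(labels))

    rows = []
    for a_i, a in enumerate(cell_types):
        for b_i, b in enumerate(cell_types):
            if a == b:
                continue
            for l, r in lr_pairs:
                obs = obs_means[a_i, gi[l]] * obs_means[b_i, gi[r]]
                null = null_means[:, a_i, gi[l]] * null_means[:, b_i, gi[r]]
                pval = float(np.mean(null >= obs))
                rows.append((a, b, l, r, float(obs), pval))
    df = pd.DataFrame(
        rows,
        columns=["cell_type_a", "cell_type_b", "ligand", "receptor", "statistic", "p_value"],
    )
    df.attrs["alpha"] = alpha
    return df


def build_metagraph(
    celltype_networks: list[CellTypePPINetwork],
    lr_results: pd.DataFrame,
    atlas,
    ontology: dict[str, str],
    alpha: float = 0.001,
) -> Metagraph:
    """Assemble the cell-type/tissue metagraph.

    CC edges link retained cell types with any LR p-value below ``alpha``;
    CT edges link each cell type to the tissue(s) its cells were sampled
    from; TT edges are the ontology restricted to sampled tissues plus all
    ancestors up to the root.
    """
    cell_types = {n.context for n in celltype_networks}
    cc = set()
    sig = lr_results[lr_results["p_value"] < alpha]
    for a, b in zip(sig["cell_type_a"], sig["cell_type_b"]):
        if a in cell_types and b in cell_types:
            cc.add(tuple(sorted((a, b))))

    ct = set()
    sampled_tissues = set()
    for c in sorted(cell_types):
        idx = atlas.cells_of_type(c)
        if len(idx) == 0:
            raise ValueError(f"cell type {c!r} absent from atlas metadata")
        tissues = {atlas.tissue[atlas.cell_ids[i]] for i in idx}
        if not tissues:
            raise ValueError(f"cell type {c!r} has no tissue annotation")
        for t in tissues:
            ct.add((c, t))
            sampled_tissues.add(t)

    included = set(sampled_tissues)
    for t in sampled_tissues:  # ancestor closure through the root
        node = t
        while node in ontology:
            node = ontology[node]
            included.add(node)
    tt = {(child, parent) for child, parent in ontology.items() if child in included}

    mg = Metagraph(
        cell_types=cell_types,
        tissues=included,
        cc_edges=cc,
        ct_edges=ct,
        tt_edges=tt,
    )
    mg.validate()
    return mg
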