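"""Synthetic single-cell / interactome fixtures with planted ground truth.

Every generator is a pure function of its arguments (including the seed), so
fixtures are reproducible and every downstream stage of the pipeline can be
tested against known planted structure:

* a stochastic-block-model reference interactome (planted communities),
* a count atlas with marker genes elevated ``marker_fold``-fold in their own
  cell type (Poisson by default, negative binomial via ``dispersion``),
* a rooted tissue ontology tree whose leaves host the cell types,
* ligand-receptor pairs drawn from marker genes of planted cell-type pairs,
* binary therapeutic-target labels enriched in one causal cell type's
  planted community.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "SyntheticTruth",
    "CellAtlas",
    "generate_reference_ppi",
    "generate_atlas",
    "generate_tissue_ontology",
    "generate_lr_pairs",
    "generate_target_labels",
    "generate_fixture",
    "Fixture",
]


@dataclass
class SyntheticTruth:
    """Planted ground truth recorded by the generators, for recovery tests."""

    marker_genes: dict[str, set[str]] = field(default_factory=dict)
    planted_lr_edges: set[tuple[str, str]] = field(default_factory=set)
    community_assignment: dict[str, int] = field(default_factory=dict)
    causal_context: str | None = None
    seed: int = 0


@dataclass
class CellAtlas:
    """Gene-by-cell counts with one cell type and one tissue per cell."""

    counts: np.ndarray  # genes x cells, nonnegative integers
    gene_ids: list[str]
    cell_ids: list[str]
    cell_type: dict[str, str]
    tissue: dict[str, str]

    def __post_init__(self):
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("count matrix dimensions do not match annotations")
        missing = [c for c in self.cell_ids if c not in self.cell_type or c not in self.tissue]
        if missing:
            raise ValueError(f"cells missing annotations: {missing[:5]}")

    def cells_of_type(self, cell_type: str) -> np.ndarray:
        return np.array(
            [i for i, c in enumerate(self.cell_ids) if self.cell_type[c] == cell_type]
        )

    @property
    def cell_types(self) -> list[str]:
        seen = dict.fromkeys(self.cell_type[c] for c in self.cell_ids)
        return list(seen)


def _protein_name(i: int) -> str:
    return f"P{i:04d}"


def generate_reference_ppi(
    n_proteins: int,
    n_communities: int,
    p_in: float,
    p_out: float,
    seed: int,
) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """Reference interactome as a stochastic block model.

    Returns the undirected edge list of the largest connected component and
    the community assignment of the retained proteins.
    """
    if not (0 <= p_out < p_in <= 1):
        raise ValueError("require 0 <= p_out < p_in <= 1")
    if not (n_proteins >= n_communities >= 1):
        raise ValueError("require n_proteins >= n_communities >= 1")
    sizes = [n_proteins // n_communities] * n_communities
    for i in range(n_proteins % n_communities):
        sizes[i] += 1
    probs = [
        [p_in if i == j else p_out for j in range(n_communities)]
        for i in range(n_communities)
    ]
    g = nx.stochastic_block_model(sizes, probs, seed=seed)
    community = {}
    offset = 0
    for ci, size in enumerate(sizes):
        for k in range(size):
            community[offset + k] = ci
        offset += size
    lcc = max(nx.connected_components(g), key=lambda c: (len(c), min(c)))
    g = g.subgraph(lcc)
    edges = sorted(
        (tuple(sorted((_protein_name(u), _protein_name(v))))) for u, v in g.edges()
    )
    truth = {_protein_name(u): community[u] for u in sorted(lcc)}
    return edges, truth


def generate_atlas(
    reference_genes: list[str],
    cell_types: list[str],
    cells_per_type: int,
    n_markers: int,
    marker_fold: float,
    base_rate: float,
    seed: int,
    *,
    marker_overlap: float = 0.0,
    marker_candidates: dict[str, list[str]] | None = None,
    overlap_pool: list[str] | None = None,
    markers: dict[str, set[str]] | None = None,
    leaf_tissues: list[str] | None = None,
    dispersion: float | None = None,
) -> tuple[CellAtlas, SyntheticTruth]:
    """Simulate a count atlas with planted marker genes.

    Marker genes of a cell type have mean ``base_rate * marker_fold`` in
    cells of that type and ``base_rate`` elsewhere. When ``marker_overlap``
    is positive, that fraction of each type's markers is drawn (per type,
    independently) from a shared pool, so pool genes end up elevated in a
    varying number of cell types. Counts are Poisson, or negative binomial
    when ``dispersion`` (inverse size) is given.
    """
    if marker_fold < 1:
        raise ValueError("marker_fold must be >= 1")
    if not 0 <= marker_overlap < 1:
        raise ValueError("marker_overlap must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_overlap = int(round(n_markers * marker_overlap))
    n_unique = n_markers - n_overlap

    if markers is not None:
        markers = {ct: set(markers[ct]) for ct in cell_types}
    elif marker_candidates is not None:
        markers = {}
        pool = list(overlap_pool or [])
        for ct in cell_types:
            own = list(marker_candidates[ct])[:n_unique]
            extra = (
                sorted(rng.choice(pool, size=n_overlap, replace=False))
                if n_overlap
                else []
            )
            markers[ct] = set(own) | set(extra)
    else:
        markers = {}
        need = n_unique * len(cell_types) + (n_markers if n_overlap else 0)
        if need > len(reference_genes):
            raise ValueError("too few genes for the requested marker layout")
        pool = list(reference_genes[: n_markers if n_overlap else 0])
        cursor = len(pool)
        for ct in cell_types:
            own = reference_genes[cursor : cursor + n_unique]
            cursor += n_unique
            extra = (
                sorted(rng.choice(pool, size=n_overlap, replace=False))
                if n_overlap
                else []
            )
            markers[ct] = set(own) | set(extra)

    if leaf_tissues is None:
        leaf_tissues = [f"tissue_{ct}" for ct in cell_types]
    tissue_of_type = {
        ct: leaf_tissues[i % len(leaf_tissues)] for i, ct in enumerate(cell_types)
    }

    gene_index = {g: i for i, g in enumerate(reference_genes)}
    n_genes = len(reference_genes)
    n_cells = cells_per_type * len(cell_types)
    rates = np.full((n_genes, n_cells), float(base_rate))
    cell_ids, cell_type_of, tissue_of = [], {}, {}
    for t_idx, ct in enumerate(cell_types):
        cols = slice(t_idx * cells_per_type, (t_idx + 1) * cells_per_type)
        rows = [gene_index[g] for g in markers[ct] if g in gene_index]
        rates[rows, cols] = base_rate * marker_fold
        for j in range(cells_per_type):
            cid = f"cell_{ct}_{j:04d}"
            cell_ids.append(cid)
            cell_type_of[cid] = ct
            tissue_of[cid] = tissue_of_type[ct]

    if dispersion is None:
        counts = rng.poisson(rates)
    else:
        # NB as gamma-Poisson with mean `rates`, variance mean*(1+dispersion*mean)
        shape = 1.0 / dispersion
        counts = rng.poisson(rng.gamma(shape, rates / shape))

    atlas = CellAtlas(
        counts=counts.astype(np.int64),
        gene_ids=list(reference_genes),
        cell_ids=cell_ids,
        cell_type=cell_type_of,
        tissue=tissue_of,
    )
    truth = SyntheticTruth(marker_genes=markers, seed=seed)
    return atlas, truth


def generate_tissue_ontology(
    n_leaves: int, branching: int, seed: int = 0
) -> dict[str, str]:
    """Rooted tissue tree as a child -> parent map.

    Leaves are named ``leaf_*`` (attachable to cell types), internal nodes
    ``node_*``, and the root ``root``. Built by recursively splitting the
    leaf set into ``branching`` groups.
    """
    if n_leaves < 1:
        raise ValueError("n_leaves must be >= 1")
    if branching < 2:
        raise ValueError("branching must be >= 2")
    parent: dict[str, str] = {}
    counter = [0]

    def split(leaves: list[str], parent_name: str) -> None:
        if len(leaves) == 1:
            parent[leaves[0]] = parent_name
            return
        k = min(branching, len(leaves))
        groups = np.array_split(np.array(leaves, dtype=object), k)
        for grp in groups:
            grp = list(grp)
            if len(grp) == 1:
                parent[grp[0]] = parent_name
            else:
                counter[0] += 1
                name = f"node_{counter[0]:02d}"
                parent[name] = parent_name
                split(grp, name)

    leaves = [f"leaf_{i:02d}" for i in range(n_leaves)]
    split(leaves, "root")
    return parent


def ontology_leaves(parent_of: dict[str, str]) -> list[str]:
    parents = set(parent_of.values())
    return sorted(c for c in parent_of if c not in parents)


def generate_lr_pairs(
    marker_genes: dict[str, set[str]],
    cell_type_pairs: list[tuple[str, str]],
    pairs_per_edge: int,
    seed: int,
) -> tuple[list[tuple[str, str]], set[tuple[str, str]]]:
    """Plant ligand-receptor pairs between chosen cell-type pairs.

    Ligands come from the first type's markers and receptors from the second
    type's, so the planted communication edges are detectable from expression.
    """
    rng = np.random.default_rng(seed)
    pairs: list[tuple[str, str]] = []
    planted: set[tuple[str, str]] = set()
    for a, b in cell_type_pairs:
        lig_pool = sorted(marker_genes[a] - marker_genes[b])
        rec_pool = sorted(marker_genes[b] - marker_genes[a])
        if not lig_pool or not rec_pool:
            raise ValueError(f"cell types {a},{b} lack distinct markers for LR pairs")
        for _ in range(pairs_per_edge):
            pairs.append(
                (str(rng.choice(lig_pool)), str(rng.choice(rec_pool)))
            )
        planted.add(tuple(sorted((a, b))))
    return sorted(set(pairs)), planted


def generate_target_labels(
    proteins_per_context: dict[str, list[str]],
    causal_context: str,
    effect: float,
    pos_frac: float,
    seed: int,
    community_assignment: dict[str, int] | None = None,
) -> tuple[dict[str, int], str]:
    """Binary target labels from a logistic model on planted communities.

    The log-odds of a positive label gain ``effect`` for proteins in the
    causal context's majority community; elsewhere the base rate is
    ``pos_frac``. Returns (labels, causal_context).
    """
    if causal_context not in proteins_per_context:
        raise ValueError(f"unknown causal context {causal_context!r}")
    if not 0 < pos_frac < 1:
        raise ValueError("pos_frac must be in (0, 1)")
    members = proteins_per_context[causal_context]
    if not members:
        raise ValueError("causal context has no proteins")
    rng = np.random.default_rng(seed)
    all_proteins = sorted({p for ps in proteins_per_context.values() for p in ps})
    if community_assignment:
        comms = [community_assignment.get(p) for p in members]
        vals, counts = np.unique(
            [c for c in comms if c is not None], return_counts=True
        )
        causal_comm = vals[np.argmax(counts)]
        in_causal = {
            p for p in all_proteins if community_assignment.get(p) == causal_comm
        }
    else:
        in_causal = set(members)
    base_logit = np.log(pos_frac / (1 - pos_frac))
    labels = {}
    for p in all_proteins:
        logit = base_logit + (effect if p in in_causal else 0.0)
        prob = 1.0 / (1.0 + np.exp(-logit))
        labels[p] = int(rng.random() < prob)
    return labels, causal_context


@dataclass
class Fixture:
    """A complete synthetic study: all pipeline inputs plus planted truth."""

    atlas: CellAtlas
    reference_edges: list[tuple[str, str]]
    ontology: dict[str, str]
    lr_pairs: list[tuple[str, str]]
    labels: dict[str, int]
    truth: SyntheticTruth


def generate_fixture(
    seed: int,
    *,
    n_cell_types: int = 5,
    block_size: int = 15,
    blocks_per_type: int = 3,
    p_in: float = 0.6,
    p_out: float = 0.01,
    cells_per_type: int = 100,
    n_pool: int = 28,
    marker_fold: float = 10.0,
    base_rate: float = 1.0,
    n_ontology_leaves: int = 12,
    lr_pairs_per_edge: int = 3,
    label_effect: float = 3.0,
    pos_frac: float = 0.15,
) -> Fixture:
    """Generate the standard planted study used throughout testing.

    Defaults give 5 cell types with ~50-60 activated proteins each. Every
    cell type owns ``blocks_per_type`` dense interactome blocks (so each
    context network has learnable sub-community topology), plus one shared
    block whose genes are markers in a varying number of cell types (so
    proteins span 1..5 contexts). A 12-leaf tissue tree hosts the cell
    types, ligand-receptor pairs are planted between consecutive cell types,
    and target labels concentrate in the first cell type's community.
    The recorded community assignment is at cell-type granularity
    (0 = shared pool, i = the i-th cell type's community).
    """
    rng = np.random.default_rng(seed)
    n_blocks = n_cell_types * blocks_per_type
    edges, fine = generate_reference_ppi(
        n_proteins=block_size * n_blocks,
        n_communities=n_blocks,
        p_in=p_in,
        p_out=p_out,
        seed=int(rng.integers(2**31 - 1)),
    )
    # coarse community = owning cell type (labels and recovery tests use this)
    community = {g: b // blocks_per_type + 1 for g, b in fine.items()}
    cell_types = [f"ct{i}" for i in range(1, n_cell_types + 1)]
    by_comm: dict[int, list[str]] = {}
    for g in sorted(community):
        by_comm.setdefault(community[g], []).append(g)
    candidates = {ct: by_comm[i + 1] for i, ct in enumerate(cell_types)}

    # Shared-pool proteins model broadly active proteins. Each is active on
    # a contiguous window of the cell-type chain (proteins active in few
    # cell types are active in *related* ones, as in real atlases); breadth
    # is capped below the number of cell types because a gene elevated in
    # every type has no differential signal and could never qualify as a
    # marker under the activation definition.
    pool = [f"S{i:03d}" for i in range(n_pool)]
    breadth_cycle = list(range(1, n_cell_types))
    window: dict[str, set[str]] = {}
    for i, g in enumerate(pool):
        b = breadth_cycle[i % len(breadth_cycle)]
        # balanced design: window starts sweep the chain deterministically
        start = (i // len(breadth_cycle)) % (n_cell_types - b + 1)
        window[g] = set(cell_types[start : start + b])

    # Pool interactions mirror activity: two pool proteins interact when
    # their activity windows overlap (so a narrowly active protein keeps
    # much of its neighborhood across its few, related contexts), and each
    # pool protein has partners inside the blocks of its window types (a
    # broadly active protein's neighborhood diverges across contexts).
    edges = list(edges)
    for g in pool:
        community[g] = 0
        for ct in sorted(window[g]):
            partners = rng.choice(candidates[ct], size=2, replace=False)
            for p in partners:
                edges.append(tuple(sorted((g, str(p)))))
    for i, g in enumerate(pool):
        for h in pool[i + 1 :]:
            if window[g] & window[h]:
                edges.append(tuple(sorted((g, h))))
    edges = sorted(set(edges))
    genes = sorted(community)

    markers = {ct: set(candidates[ct]) for ct in cell_types}
    for g in pool:
        for ct in window[g]:
            markers[ct].add(g)

    ontology = generate_tissue_ontology(n_ontology_leaves, branching=2)
    leaves = ontology_leaves(ontology)
    leaf_for_types = [
        leaves[int(i * len(leaves) / n_cell_types)] for i in range(n_cell_types)
    ]

    atlas, truth = generate_atlas(
        reference_genes=genes,
        cell_types=cell_types,
        cells_per_type=cells_per_type,
        n_markers=0,
        marker_fold=marker_fold,
        base_rate=base_rate,
        seed=int(rng.integers(2**31 - 1)),
        markers=markers,
        leaf_tissues=leaf_for_types,
    )
    truth.community_assignment = community

    ct_pairs = [
        (cell_types[i], cell_types[i + 1]) for i in range(len(cell_types) - 1)
    ]
    # LR genes come from own-community markers only, so planted CC edges
    # stay specific to the intended cell-type pair
    own_markers = {ct: set(candidates[ct]) for ct in cell_types}
    lr, planted = generate_lr_pairs(
        own_markers, ct_pairs, lr_pairs_per_edge, int(rng.integers(2**31 - 1))
    )
    truth.planted_lr_edges = planted

    proteins_per_context = {ct: sorted(truth.marker_genes[ct]) for ct in cell_types}
    labels, causal = generate_target_labels(
        proteins_per_context,
        causal_context=cell_types[0],
        effect=label_effect,
        pos_frac=pos_frac,
        seed=int(rng.integers(2**31 - 1)),
        community_assignment=community,
    )
    truth.causal_context = causal
    truth.seed = seed

    return Fixture(
        atlas=atlas,
        reference_edges=edges,
        ontology=ontology,
        lr_pairs=lr,
        labels=labels,
        truth=truth,
    )
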