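"""Readers and writers for the on-disk exchange formats.

Counts travel as Matrix Market sparse matrices with TSV gene/cell sidecars;
graphs, ligand-receptor pairs, ontologies, labels and embeddings are plain
TSV. Everything round-trips bit-identically so generated fixtures can be fed
back through the pipeline from disk.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


def write_atlas(atlas, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(outdir / "counts.mtx", sp.csr_matrix(atlas.counts))
    pd.DataFrame({"gene_id": atlas.gene_ids}).to_csv(
        outdir / "genes.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        {
            "cell_id": atlas.cell_ids,
            "cell_type": [atlas.cell_type[c] for c in atlas.cell_ids],
            "tissue": [atlas.tissue[c] for c in atlas.cell_ids],
        }
    ).to_csv(outdir / "cells.tsv", sep="\t", index=False)


def read_atlas(indir):
    from .synthetic import CellAtlas

    indir = Path(indir)
    counts = np.asarray(scipy.io.mmread(indir / "counts.mtx").todense()).astype(int)
    genes = pd.read_csv(indir / "genes.tsv", sep="\t")
    cells = pd.read_csv(indir / "cells.tsv", sep="\t")
    return CellAtlas(
        counts=counts,
        gene_ids=list(genes["gene_id"]),
        cell_ids=list(cells["cell_id"]),
        cell_type=dict(zip(cells["cell_id"], cells["cell_type"])),
        tissue=dict(zip(cells["cell_id"], cells["tissue"])),
    )


def write_edge_list(edges, path, columns=("protein_a", "protein_b")) -> None:
    df = pd.DataFrame(sorted(tuple(sorted(e)) for e in edges), columns=list(columns))
    df.to_csv(path, sep="\t", index=False)


def read_edge_list(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    return [tuple(sorted((str(a), str(b)))) for a, b in df.itertuples(index=False)]


def write_ontology(parent_of, path) -> None:
    rows = sorted((child, parent) for child, parent in parent_of.items())
    pd.DataFrame(rows, columns=["child", "parent"]).to_csv(path, sep="\t", index=False)


def read_ontology(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["child"].astype(str), df["parent"].astype(str)))


def write_lr_pairs(pairs, path) -> None:
    pd.DataFrame(sorted(pairs), columns=["ligand", "receptor"]).to_csv(
        path, sep="\t", index=False
    )


def read_lr_pairs(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    return [(str(l), str(r)) for l, r in df.itertuples(index=False)]


def write_labels(labels, path) -> None:
    rows = sorted(labels.items())
    pd.DataFrame(rows, columns=["protein", "label"]).to_csv(path, sep="\t", index=False)


def read_labels(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    return {str(p): int(v) for p, v in zip(df["protein"], df["label"])}


def write_truth(truth, path) -> None:
    payload = {
        "marker_genes": {k: sorted(v) for k, v in truth.marker_genes.items()},
        "planted_lr_edges": sorted(sorted(p) for p in truth.planted_lr_edges),
        "community_assignment": truth.community_assignment,
        "causal_context": truth.causal_context,
        "seed": truth.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path):
    from .synthetic import SyntheticTruth

    payload = json.loads(Path(path).read_text())
    return SyntheticTruth(
        marker_genes={k: set(v) for k, v in payload["marker_genes"].items()},
        planted_lr_edges={tuple(sorted(p)) for p in payload["planted_lr_edges"]},
        community_assignment=dict(payload["community_assignment"]),
        causal_context=payload["causal_context"],
        seed=payload["seed"],
    )


def write_metagraph(metagraph, path) -> None:
    rows = []
    for a, b in sorted(tuple(sorted(e)) for e in metagraph.cc_edges):
        rows.append((a, b, "CC"))
    for c, t in sorted(metagraph.ct_edges):
        rows.append((c, t, "CT"))
    for a, b in sorted(metagraph.tt_edges):
        rows.append((a, b, "TT"))
    pd.DataFrame(rows, columns=["src", "dst", "edge_type"]).to_csv(
        path, sep="\t", index=False
    )


def read_metagraph(path):
    from .networks import Metagraph

    df = pd.read_csv(path, sep="\t")
    cc, ct, tt = set(), set(), set()
    for src, dst, kind in df.itertuples(index=False):
        src, dst = str(src), str(dst)
        if kind == "CC":
            cc.add(tuple(sorted((src, dst))))
        elif kind == "CT":
            ct.add((src, dst))
        else:
            tt.add((src, dst))
    cell_types = {c for e in cc for c in e} | {c for c, _ in ct}
    tissues = {t for _, t in ct} | {t for e in tt for t in e}
    return Metagraph(
        cell_types=cell_types, tissues=tissues, cc_edges=cc, ct_edges=ct, tt_edges=tt
    )


def write_embeddings(space, path) -> None:
    """Flat TSV: entity_kind, context, entity_id, d0..d{k-1}."""
    rows = []
    dim = space.dim
    for (protein, context), vec in sorted(space.protein.items()):
        rows.append(["protein", context, protein] + list(vec))
    for ct, vec in sorted(space.cell_type.items()):
        rows.append(["cell_type", "", ct] + list(vec))
    for t, vec in sorted(space.tissue.items()):
        rows.append(["tissue", "", t] + list(vec))
    cols = ["entity_kind", "context", "entity_id"] + [f"d{i}" for i in range(dim)]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_embeddings(path):
    from .model import EmbeddingSpace

    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    dims = [c for c in df.columns if c.startswith("d")]
    protein, cell_type, tissue = {}, {}, {}
    for row in df.itertuples(index=False):
        vec = np.array([getattr(row, d) for d in dims])
        if row.entity_kind == "protein":
            protein[(str(row.entity_id), str(row.context))] = vec
        elif row.entity_kind == "cell_type":
            cell_type[str(row.entity_id)] = vec
        else:
            tissue[str(row.entity_id)] = vec
    return EmbeddingSpace(
        protein=protein, cell_type=cell_type, tissue=tissue, dim=len(dims)
    )
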