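"""Multiscale graph attention network over context PPI networks and the
cell-type/tissue metagraph.

Architecture (two layers; each layer runs the full cycle):

1. *Protein-level attention* — a GATv2-style multi-head attention pass on
   every cell type's PPI network, with its own per-context parameters and a
   self-loop on every protein.
2. *Bridge, proteins -> cell type* — attention weights ``gamma`` pool each
   context's protein embeddings into its cell-type embedding.
3. *Metagraph attention* — per-edge-type attention (CC, CT, TC, TT) whose
   outputs are mixed by edge-type weights ``beta`` computed from shared
   parameters (s, M, b) via a tanh gate.
4. *Bridge, cell type -> protein* — each protein embedding is incremented
   by its ``gamma``-scaled, metagraph-informed cell-type embedding.

Head aggregation concatenates the K heads in the first layer and averages
them in the output layer. Protein identities share one learnable Gaussian
feature vector across all contexts that contain them; cell-type embeddings
start as the mean of their proteins' features and tissue embeddings as the
mean of their metagraph neighbors'. A bilinear decoder
``sigma(sum_k z_u[k] r_i[k] z_v[k])`` scores edges of type i.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autograd import Tensor, segment_softmax, segment_sum
from .networks import CellTypePPINetwork, Metagraph

__all__ = [
    "ModelConfig",
    "ModelState",
    "EmbeddingSpace",
    "MultiscaleGAT",
    "init_embeddings",
    "decode_edge",
]

EDGE_TYPES = ("PP", "CC", "CT", "TC", "TT")


@dataclass
class ModelConfig:
    """Architecture hyperparameters (defaults follow the pretrained setup;
    use :func:`contextppi.training.fixture_config` for desk-scale runs)."""

    feature_dim: int = 1024
    out_dim: int = 16
    heads: int = 8
    dropout: float = 0.6
    layer_norm: bool = True
    batch_norm: bool = True
    leaky_slope: float = 0.2

    def __post_init__(self):
        if self.feature_dim % self.heads:
            raise ValueError("feature_dim must be divisible by heads")


@dataclass
class ModelState:
    """Embeddings plus attention weights recorded on the last forward pass."""

    protein: dict[str, dict[str, np.ndarray]]  # context -> protein -> vector
    cell_type: dict[str, np.ndarray]
    tissue: dict[str, np.ndarray]
    alpha: dict = field(default_factory=dict)  # (layer, context) -> per-edge weights
    alpha_mg: dict = field(default_factory=dict)  # (layer, relation) -> weights
    beta: dict = field(default_factory=dict)  # (layer, relation) -> scalar
    gamma: dict = field(default_factory=dict)  # (layer, context) -> per-protein


@dataclass
class EmbeddingSpace:
    """Final representations: one vector per (protein, context), cell type
    and tissue."""

    protein: dict[tuple[str, str], np.ndarray]  # (protein, context) -> vector
    cell_type: dict[str, np.ndarray]
    tissue: dict[str, np.ndarray]
    dim: int

    def contexts_of(self, protein: str) -> list[str]:
        return sorted(c for (p, c) in self.protein if p == protein)


def _glorot(rng: np.random.Generator, *shape) -> Tensor:
    scale = np.sqrt(2.0 / sum(shape)) if len(shape) > 1 else np.sqrt(1.0 / shape[0])
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


def decode_edge(z_u, r_i, z_v):
    """Bilinear edge decoder: logit = sum_k z_u[k] * r_i[k] * z_v[k].

    Accepts numpy arrays (returns floats) or autograd tensors (returns
    tensors); 1-D inputs are treated as single edges, 2-D as batches.
    """
    if isinstance(z_u, Tensor) or isinstance(z_v, Tensor) or isinstance(r_i, Tensor):
        prod = z_u * r_i * z_v
        logit = prod.sum(axis=prod.data.ndim - 1)
        return logit, logit.sigmoid()
    z_u, r_i, z_v = np.asarray(z_u), np.asarray(r_i), np.asarray(z_v)
    if z_u.shape[-1] != z_v.shape[-1] or z_u.shape[-1] != r_i.shape[-1]:
        raise ValueError("decoder inputs must share their last dimension")
    logit = (z_u * r_i * z_v).sum(axis=-1)
    return logit, 1.0 / (1.0 + np.exp(-logit))


def _tissue_bfs_order(metagraph: Metagraph) -> list[str]:
    """Tissues ordered outward from the cell-type-attached leaves, so each
    tissue's initial embedding can average already-initialized neighbors."""
    neighbors: dict[str, set[str]] = {t: set() for t in metagraph.tissues}
    for child, parent in metagraph.tt_edges:
        neighbors[child].add(parent)
        neighbors[parent].add(child)
    attached = sorted({t for _, t in metagraph.ct_edges})
    order, seen = [], set()
    frontier = attached
    while frontier:
        nxt = []
        for t in frontier:
            if t in seen:
                continue
            seen.add(t)
            order.append(t)
            nxt.extend(sorted(neighbors[t] - seen))
        frontier = nxt
    for t in sorted(metagraph.tissues - seen):  # disconnected safety net
        order.append(t)
    return order


class MultiscaleGAT:
    """The multiscale attention model: holds parameters and graph wiring.

    ``forward`` runs the two-layer cycle and returns per-context protein,
    cell-type and tissue embeddings as autograd tensors along with a
    :class:`ModelState` snapshot of every attention weight family.
    """

    def __init__(
        self,
        networks: list[CellTypePPINetwork],
        metagraph: Metagraph,
        config: ModelConfig | None = None,
        seed: int = 0,
    ):
        if not networks:
            raise ValueError("need at least one context network")
        self.config = config or ModelConfig()
        self.networks = {n.context: n for n in networks}
        self.contexts = sorted(self.networks)
        self.metagraph = metagraph
        rng = np.random.default_rng(seed)

        # --- node bookkeeping ------------------------------------------------
        self.proteins = sorted({p for n in networks for p in n.nodes})
        self.pidx = {p: i for i, p in enumerate(self.proteins)}
        self.ctx_nodes = {c: list(self.networks[c].nodes) for c in self.contexts}
        self.ctx_pidx = {
            c: np.array([self.pidx[p] for p in self.ctx_nodes[c]])
            for c in self.contexts
        }
        mg_cts = sorted(metagraph.cell_types)
        mg_tissues = _tissue_bfs_order(metagraph)
        self.mg_nodes = mg_cts + mg_tissues
        self.mg_idx = {n: i for i, n in enumerate(self.mg_nodes)}
        self.n_ct = len(mg_cts)
        self.mg_cts = mg_cts
        self.mg_tissues = mg_tissues

        # --- message-passing edge arrays ------------------------------------
        self._ctx_edges_full = {
            c: self._edge_arrays(self.ctx_nodes[c], self.networks[c].edges)
            for c in self.contexts
        }
        self.mg_rel_edges = self._metagraph_edge_arrays()

        # --- parameters ------------------------------------------------------
        cfg = self.config
        K = cfg.heads
        d1 = cfg.feature_dim // K  # layer-1 head dim; concat restores feature_dim
        self.dims = [cfg.feature_dim, cfg.feature_dim, cfg.out_dim]
        self.head_dims = [d1, cfg.out_dim]
        self.params: dict[str, Tensor] = {}
        self.params["features"] = Tensor(
            rng.normal(0.0, 1.0, size=(len(self.proteins), cfg.feature_dim)),
            requires_grad=True,
        )
        for c in self.contexts:
            for l in range(2):
                din, dh = self.dims[l], self.head_dims[l]
                self.params[f"pp/{c}/l{l}/Wl"] = _glorot(rng, din, K * dh)
                self.params[f"pp/{c}/l{l}/Wr"] = _glorot(rng, din, K * dh)
                self.params[f"pp/{c}/l{l}/a"] = _glorot(rng, K, dh)
        for rel in ("CC", "CT", "TC", "TT"):
            for l in range(2):
                dout = self.dims[l + 1]
                dh = self.head_dims[l]
                self.params[f"mg/{rel}/l{l}/Wl"] = _glorot(rng, dout, K * dh)
                self.params[f"mg/{rel}/l{l}/Wr"] = _glorot(rng, dout, K * dh)
                self.params[f"mg/{rel}/l{l}/a"] = _glorot(rng, K, dh)
        for l in range(2):  # edge-type attention, shared across edge types
            dout = self.dims[l + 1]
            self.params[f"beta/l{l}/s"] = _glorot(rng, dout)
            self.params[f"beta/l{l}/M"] = _glorot(rng, dout, dout)
            self.params[f"beta/l{l}/b"] = Tensor(np.zeros(dout), requires_grad=True)
        for l in range(2):  # attention bridge, shared across contexts
            din, dout = self.dims[l], self.dims[l + 1]
            self.params[f"bridge/l{l}/Wc"] = _glorot(rng, din, dout)
            self.params[f"bridge/l{l}/Wu"] = _glorot(rng, dout, dout)
            self.params[f"bridge/l{l}/a"] = _glorot(rng, dout)
            self.params[f"bridge/l{l}/U"] = _glorot(rng, din, dout)
        for et in EDGE_TYPES:
            self.params[f"decoder/r_{et}"] = Tensor(
                rng.normal(0.0, 1.0, size=(cfg.out_dim,)), requires_grad=True
            )

    # -- graph wiring ----------------------------------------------------------

    @staticmethod
    def _edge_arrays(nodes: list[str], edges: set[tuple[str, str]]):
        idx = {p: i for i, p in enumerate(nodes)}
        src, dst = [], []
        for u, v in sorted(edges):
            src += [idx[u], idx[v]]
            dst += [idx[v], idx[u]]
        for i in range(len(nodes)):  # self-attention loop
            src.append(i)
            dst.append(i)
        return np.array(src), np.array(dst)

    def _metagraph_edge_arrays(self):
        mg = self.metagraph
        rel: dict[str, tuple[list[int], list[int]]] = {
            r: ([], []) for r in ("CC", "CT", "TC", "TT")
        }
        for a, b in sorted(mg.cc_edges):
            ia, ib = self.mg_idx[a], self.mg_idx[b]
            rel["CC"][0].extend([ia, ib])
            rel["CC"][1].extend([ib, ia])
        for c in self.mg_cts:  # self loops on same-kind relations
            i = self.mg_idx[c]
            rel["CC"][0].append(i)
            rel["CC"][1].append(i)
        for c, t in sorted(mg.ct_edges):
            ic, it = self.mg_idx[c], self.mg_idx[t]
            rel["CT"][0].append(it)  # tissue -> cell type messages
            rel["CT"][1].append(ic)
            rel["TC"][0].append(ic)  # cell type -> tissue messages
            rel["TC"][1].append(it)
        for child, parent in sorted(mg.tt_edges):
            ic, ip = self.mg_idx[child], self.mg_idx[parent]
            rel["TT"][0].extend([ic, ip])
            rel["TT"][1].extend([ip, ic])
        for t in self.mg_tissues:
            i = self.mg_idx[t]
            rel["TT"][0].append(i)
            rel["TT"][1].append(i)
        return {r: (np.array(s), np.array(d)) for r, (s, d) in rel.items()}

    # -- building blocks -------------------------------------------------------

    def _gat(self, x: Tensor, src, dst, n: int, Wl, Wr, a, head_dim: int, concat: bool):
        """One GATv2 multi-head attention pass over an edge list.

        Returns (updated embeddings, per-edge attention weights array)."""
        K = self.config.heads
        hs = x @ Wl  # target/self projection
        hr = x @ Wr  # neighbor projection (also the message values)
        E = len(src)
        pre = (hs.gather(dst) + hr.gather(src)).leaky_relu(self.config.leaky_slope)
        scores = (pre.reshape(E, K, head_dim) * a.reshape(1, K, head_dim)).sum(axis=2)
        alpha = segment_softmax(scores, dst, n)  # (E, K)
        msg = hr.gather(src).reshape(E, K, head_dim) * alpha.reshape(E, K, 1)
        agg = segment_sum(msg, dst, n).relu()  # sigma before head aggregation
        if concat:
            out = agg.reshape(n, K * head_dim)
        else:
            out = agg.mean(axis=1)
        return out, alpha.data.copy()

    def _beta(self, h_by_rel: dict[str, Tensor], layer: int):
        """Edge-type mixing weights from the shared (s, M, b) gate."""
        s = self.params[f"beta/l{layer}/s"]
        M = self.params[f"beta/l{layer}/M"]
        b = self.params[f"beta/l{layer}/b"]
        ms = []
        rels = sorted(h_by_rel)
        for r in rels:
            gate = (h_by_rel[r] @ M.reshape(M.shape[0], M.shape[1]) + b).tanh()
            ms.append((gate * s).sum())
        # softmax over the edge types of this node kind
        mx = max(m.data for m in ms)
        exps = [(m - float(mx)).exp() for m in ms]
        denom = exps[0]
        for e in exps[1:]:
            denom = denom + e
        return {r: e / denom for r, e in zip(rels, exps)}

    def _norm(self, x: Tensor, kind: str) -> Tensor:
        eps = 1e-5
        if kind == "layer":  # per-row standardization
            mu = x.mean(axis=1, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=1, keepdims=True)
            return (x - mu) / (var + eps).sqrt()
        mu = x.mean(axis=0, keepdims=True)  # batch: per-feature across nodes
        var = ((x - mu) ** 2).mean(axis=0, keepdims=True)
        return (x - mu) / (var + eps).sqrt()

    def _dropout(self, x: Tensor, rng: np.random.Generator | None) -> Tensor:
        p = self.config.dropout
        if rng is None or p <= 0:
            return x
        keep = (rng.random(x.data.shape) >= p) / (1.0 - p)
        return x * Tensor(keep)

    # -- forward ---------------------------------------------------------------

    def initial_metagraph_embeddings(self, p_emb: dict[str, Tensor]) -> Tensor:
        """Cell types start at the mean of their proteins' embeddings; tissues
        at the mean of already-initialized metagraph neighbors (BFS outward
        from the cell-type-attached tissues)."""
        rows = []
        for c in self.mg_cts:
            if c in p_emb:
                rows.append(p_emb[c].mean(axis=0, keepdims=True))
            else:
                rows.append(Tensor(np.zeros((1, self.dims[0]))))
        ct_block = rows
        done: dict[str, Tensor] = {c: r for c, r in zip(self.mg_cts, ct_block)}
        neigh: dict[str, list[str]] = {t: [] for t in self.mg_tissues}
        for c, t in self.metagraph.ct_edges:
            neigh[t].append(c)
        for child, parent in self.metagraph.tt_edges:
            neigh[child].append(parent)
            neigh[parent].append(child)
        for t in self.mg_tissues:  # BFS order guarantees an initialized neighbor
            avail = [done[n] for n in sorted(set(neigh[t])) if n in done]
            if avail:
                acc = avail[0]
                for a in avail[1:]:
                    acc = acc + a
                done[t] = acc * (1.0 / len(avail))
            else:
                done[t] = Tensor(np.zeros((1, self.dims[0])))
        from ._autograd import concat as cat

        return cat([done[n] for n in self.mg_nodes], axis=0)

    def forward(
        self,
        train: bool = False,
        rng: np.random.Generator | None = None,
        message_edges: dict[str, set[tuple[str, str]]] | None = None,
    ):
        """Run the two-layer multiscale cycle.

        ``message_edges`` optionally restricts each context's message-passing
        graph (used to hide validation/test edges during training). Returns
        (per-context protein tensors, metagraph tensor, state snapshot).
        """
        cfg = self.config
        drop_rng = rng if train and cfg.dropout > 0 else None
        state = ModelState(protein={}, cell_type={}, tissue={})

        ctx_edges = {}
        for c in self.contexts:
            if message_edges is not None and c in message_edges:
                ctx_edges[c] = self._edge_arrays(self.ctx_nodes[c], message_edges[c])
            else:
                ctx_edges[c] = self._ctx_edges_full[c]

        p_emb = {
            c: self.params["features"].gather(self.ctx_pidx[c]) for c in self.contexts
        }
        mg_x = self.initial_metagraph_embeddings(p_emb)

        for l in range(2):
            dh = self.head_dims[l]
            concat_heads = l == 0
            # 1. protein-level attention per context
            new_p = {}
            for c in self.contexts:
                src, dst = ctx_edges[c]
                out, alpha = self._gat(
                    p_emb[c], src, dst, len(self.ctx_nodes[c]),
                    self.params[f"pp/{c}/l{l}/Wl"],
                    self.params[f"pp/{c}/l{l}/Wr"],
                    self.params[f"pp/{c}/l{l}/a"],
                    dh, concat_heads,
                )
                new_p[c] = out
                state.alpha[(l, c)] = (src, dst, alpha)

            # 2. bridge: pool proteins into their cell type (and align dims)
            Wc = self.params[f"bridge/l{l}/Wc"]
            Wu = self.params[f"bridge/l{l}/Wu"]
            a_b = self.params[f"bridge/l{l}/a"]
            U = self.params[f"bridge/l{l}/U"]
            gamma: dict[str, Tensor] = {}
            mg_rows: list[Tensor] = []
            dout = self.dims[l + 1]
            for ci, c in enumerate(self.mg_cts):
                h_ci = mg_x.gather([self.mg_idx[c]])  # (1, din)
                base = h_ci @ U
                if c in new_p:
                    comp = (h_ci @ Wc + new_p[c] @ Wu).leaky_relu(cfg.leaky_slope)
                    score = (comp * a_b.reshape(1, dout)).sum(axis=1)
                    g = segment_softmax(
                        score.reshape(-1, 1), np.zeros(len(self.ctx_nodes[c]), int), 1
                    )
                    gamma[c] = g
                    pooled = (new_p[c] * g).sum(axis=0, keepdims=True).relu()
                    mg_rows.append(base + pooled)
                    state.gamma[(l, c)] = g.data.ravel().copy()
                else:
                    mg_rows.append(base)
            for t in self.mg_tissues:
                mg_rows.append(mg_x.gather([self.mg_idx[t]]) @ U)
            from ._autograd import concat as cat

            mg_h = cat(mg_rows, axis=0)  # (n_mg, dout)

            # 3. metagraph attention with edge-type mixing
            h_rel: dict[str, Tensor] = {}
            for rel in ("CC", "CT", "TC", "TT"):
                src, dst = self.mg_rel_edges[rel]
                out, alpha = self._gat(
                    mg_h, src, dst, len(self.mg_nodes),
                    self.params[f"mg/{rel}/l{l}/Wl"],
                    self.params[f"mg/{rel}/l{l}/Wr"],
                    self.params[f"mg/{rel}/l{l}/a"],
                    dh, concat_heads,
                )
                # mean-aggregated metagraph heads keep dout = K*dh only at l=0
                h_rel[rel] = out
                state.alpha_mg[(l, rel)] = (src, dst, alpha)
            beta_ct = self._beta({r: h_rel[r] for r in ("CC", "CT")}, l)
            beta_ti = self._beta({r: h_rel[r] for r in ("TC", "TT")}, l)
            for r, v in {**beta_ct, **beta_ti}.items():
                state.beta[(l, r)] = float(v.data)
            ct_sel = np.arange(self.n_ct)
            ti_sel = np.arange(self.n_ct, len(self.mg_nodes))
            mg_new_ct = (
                h_rel["CC"].gather(ct_sel) * beta_ct["CC"]
                + h_rel["CT"].gather(ct_sel) * beta_ct["CT"]
            )
            mg_new_ti = (
                h_rel["TT"].gather(ti_sel) * beta_ti["TT"]
                + h_rel["TC"].gather(ti_sel) * beta_ti["TC"]
            )
            mg_x = cat([mg_new_ct, mg_new_ti], axis=0)

            # 4. bridge back: impose metagraph structure onto proteins
            for c in self.contexts:
                ci = self.mg_idx[c]
                h_ci = mg_x.gather([ci])
                new_p[c] = new_p[c] + gamma[c] * h_ci

            # inter-layer normalization and dropout
            if l == 0:
                if cfg.layer_norm:
                    new_p = {c: self._norm(v, "layer") for c, v in new_p.items()}
                    mg_x = self._norm(mg_x, "layer")
                new_p = {c: self._dropout(v, drop_rng) for c, v in new_p.items()}
                mg_x = self._dropout(mg_x, drop_rng)
            elif cfg.batch_norm:
                # joint batch statistics across all contexts, so per-context
                # mean offsets (the signal the center loss builds) survive
                from ._autograd import concat as cat2

                stacked = cat2([new_p[c] for c in self.contexts], axis=0)
                stacked = self._norm(stacked, "batch")
                offset = 0
                for c in self.contexts:
                    n_c = len(self.ctx_nodes[c])
                    new_p[c] = stacked.gather(np.arange(offset, offset + n_c))
                    offset += n_c
                if len(self.mg_nodes) > 1:
                    mg_x = self._norm(mg_x, "batch")
            p_emb = new_p

        for c in self.contexts:
            if not np.isfinite(p_emb[c].data).all():
                raise FloatingPointError(f"non-finite protein embeddings in {c}")
        if not np.isfinite(mg_x.data).all():
            raise FloatingPointError("non-finite metagraph embeddings")

        state.protein = {
            c: {p: p_emb[c].data[i].copy() for i, p in enumerate(self.ctx_nodes[c])}
            for c in self.contexts
        }
        state.cell_type = {
            c: mg_x.data[self.mg_idx[c]].copy() for c in self.mg_cts
        }
        state.tissue = {t: mg_x.data[self.mg_idx[t]].copy() for t in self.mg_tissues}
        return p_emb, mg_x, state

    # -- convenience -----------------------------------------------------------

    def embedding_space(self, p_emb=None, mg_x=None) -> EmbeddingSpace:
        if p_emb is None:
            p_emb, mg_x, _ = self.forward(train=False)
        protein = {}
        for c in self.contexts:
            for i, p in enumerate(self.ctx_nodes[c]):
                protein[(p, c)] = p_emb[c].data[i].copy()
        return EmbeddingSpace(
            protein=protein,
            cell_type={c: mg_x.data[self.mg_idx[c]].copy() for c in self.mg_cts},
            tissue={t: mg_x.data[self.mg_idx[t]].copy() for t in self.mg_tissues},
            dim=self.config.out_dim,
        )

    def decoder_vector(self, edge_type: str) -> Tensor:
        return self.params[f"decoder/r_{edge_type}"]

    def parameter_groups(self) -> dict[str, list[str]]:
        groups: dict[str, list[str]] = {}
        for name in self.params:
            groups.setdefault(name.split("/")[0], []).append(name)
        return groups


def init_embeddings(
    networks: list[CellTypePPINetwork],
    metagraph: Metagraph,
    dim: int,
    seed: int = 0,
) -> ModelState:
    """Initial embeddings before any attention pass: one shared Gaussian
    vector per protein identity, cell types at the mean of their proteins,
    tissues at the mean of their initialized metagraph neighbors."""
    if not networks:
        raise ValueError("need at least one context network")
    rng = np.random.default_rng(seed)
    proteins = sorted({p for n in networks for p in n.nodes})
    feats = {p: rng.normal(0.0, 1.0, size=dim) for p in proteins}
    protein = {n.context: {p: feats[p].copy() for p in n.nodes} for n in networks}
    cell_type = {
        n.context: np.mean([feats[p] for p in n.nodes], axis=0) for n in networks
    }
    for c in metagraph.cell_types - set(cell_type):
        cell_type[c] = np.zeros(dim)
    tissue: dict[str, np.ndarray] = {}
    neigh: dict[str, list[str]] = {t: [] for t in metagraph.tissues}
    for c, t in metagraph.ct_edges:
        neigh[t].append(c)
    for child, parent in metagraph.tt_edges:
        neigh[child].append(parent)
        neigh[parent].append(child)
    for t in _tissue_bfs_order(metagraph):
        vals = [
            cell_type[n] if n in cell_type else tissue[n]
            for n in sorted(set(neigh[t]))
            if n in cell_type or n in tissue
        ]
        tissue[t] = np.mean(vals, axis=0) if vals else np.zeros(dim)
    return ModelState(protein=protein, cell_type=cell_type, tissue=tissue)
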