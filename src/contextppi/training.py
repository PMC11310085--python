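"""Self-supervised pretraining of the multiscale attention model.

Edges of every context PPI network are split 80/10/10 into train /
validation / test; metagraph edges are all kept for training because there
are few of them and they carry the cell-type/tissue organization. Negatives
are structured corruptions of one endpoint at a 1:1 ratio. The loss is

    L = theta * L_ppi + lambda * L_center + (1 - theta) * (L_celltype + L_tissue)

with binary cross-entropy link terms per edge type and a center loss pulling
each protein embedding toward its cell-type embedding. Validation/test edges
are masked from the message-passing graph during training. The best epoch is
chosen by validation link AUROC, ties broken by the Calinski-Harabasz score
of protein embeddings labeled by context.

``MultiscaleEmbeddingModel`` wraps all of this in a fit()/results interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import calinski_harabasz_score, roc_auc_score

from ._autograd import Tensor, concat
from .model import EmbeddingSpace, ModelConfig, MultiscaleGAT, decode_edge
from .networks import CellTypePPINetwork, Metagraph

__all__ = [
    "TrainingConfig",
    "fixture_config",
    "EdgeSplit",
    "split_edges",
    "sample_negatives",
    "loss_ppi",
    "loss_center",
    "loss_metagraph",
    "loss_total",
    "train",
    "MultiscaleEmbeddingModel",
    "PretrainResults",
]

_EPS = 1e-12


@dataclass
class TrainingConfig:
    """Optimization settings; architecture lives in :class:`ModelConfig`.

    ``lr_center`` is the learning rate of the cell-type classification
    (center loss) task, applied as a per-loss gradient scale relative to
    ``lr_link`` on a single Adam optimizer.
    """

    theta: float = 0.5
    lam: float = 0.1
    lr_link: float = 0.01
    lr_center: float = 0.1
    epochs: int = 250
    weight_decay: float = 1e-5
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    resample_negatives: bool = True
    model: ModelConfig = field(default_factory=ModelConfig)

    def __post_init__(self):
        if not (0 <= self.theta <= 1 and 0 <= self.lam <= 1):
            raise ValueError("theta and lambda must lie in [0, 1]")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def fixture_config(epochs: int = 200, theta: float = 0.5) -> TrainingConfig:
    """Desk-scale settings: 64-d features, 8-d output, light dropout, and a
    center-loss rate equal to the link rate (tens of proteins per context
    collapse onto their cell-type center under the full-scale rate)."""
    return TrainingConfig(
        theta=theta,
        epochs=epochs,
        lr_center=0.01,
        model=ModelConfig(feature_dim=64, out_dim=16, heads=8, dropout=0.2),
    )


@dataclass
class EdgeSplit:
    train: dict[str, set[tuple[str, str]]]
    val: dict[str, set[tuple[str, str]]]
    test: dict[str, set[tuple[str, str]]]
    train_proteins: dict[str, set[str]]  # proteins incident to train edges

    def check(self, networks: dict[str, CellTypePPINetwork]) -> None:
        for c, net in networks.items():
            tr, va, te = self.train[c], self.val[c], self.test[c]
            assert tr | va | te == net.edges
            assert not (tr & va) and not (tr & te) and not (va & te)


def split_edges(
    networks: list[CellTypePPINetwork],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> EdgeSplit:
    """Random per-context train/validation/test split of PP edges."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    train, val, test, tp = {}, {}, {}, {}
    for net in sorted(networks, key=lambda n: n.context):
        edges = sorted(net.edges)
        if len(edges) < 3:
            raise ValueError(f"context {net.context} has < 3 edges")
        perm = rng.permutation(len(edges))
        n = len(edges)
        n_val = int(round(fractions[1] * n))
        n_test = int(round(fractions[2] * n))
        if n >= 10:
            n_val, n_test = max(1, n_val), max(1, n_test)
        n_train = n - n_val - n_test
        idx = [edges[i] for i in perm]
        train[net.context] = set(idx[:n_train])
        val[net.context] = set(idx[n_train : n_train + n_val])
        test[net.context] = set(idx[n_train + n_val :])
        tp[net.context] = {u for e in train[net.context] for u in e}
    return EdgeSplit(train=train, val=val, test=test, train_proteins=tp)


def sample_negatives(
    nodes: list[str],
    all_edges: set[tuple[str, str]],
    positives: set[tuple[str, str]] | list[tuple[str, str]],
    seed: int | np.random.Generator = 0,
) -> list[tuple[str, str]]:
    """One corrupted pair per positive: replace one endpoint uniformly with
    a node not adjacent to the kept endpoint (1:1 negative ratio)."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    node_arr = sorted(nodes)
    adj: dict[str, set[str]] = {n: {n} for n in node_arr}
    for u, v in all_edges:
        adj[u].add(v)
        adj[v].add(u)
    if all(len(adj[n]) >= len(node_arr) for n in node_arr):
        raise ValueError("graph is complete; no negative edges exist")
    negatives = []
    for u, v in sorted(positives):
        kept = u
        candidates = [w for w in node_arr if w not in adj[kept]]
        if not candidates:  # full neighborhood: corrupt the other endpoint
            kept = v
            candidates = [w for w in node_arr if w not in adj[kept]]
        w = candidates[int(rng.integers(len(candidates)))]
        negatives.append(tuple(sorted((kept, w))))
    return negatives


def _bce_sum(probs, labels):
    """Summed binary cross-entropy; probabilities clamped away from {0, 1}."""
    labels = np.asarray(labels, dtype=float)
    if isinstance(probs, Tensor):
        p = probs.clip(_EPS, 1.0 - _EPS)
        y = Tensor(labels)
        return -(y * p.log() + (1.0 - y) * (1.0 - p).log()).sum()
    p = np.clip(np.asarray(probs, dtype=float), _EPS, 1.0 - _EPS)
    return float(-(labels * np.log(p) + (1 - labels) * np.log(1 - p)).sum())


def loss_ppi(probs, labels):
    """BCE over all contexts' positive and negative PP edges (flattened)."""
    return _bce_sum(probs, labels)


def loss_center(protein_z, celltype_z, membership):
    """Sum of squared distances from each (train) protein embedding to its
    cell-type embedding. Accepts tensors or arrays.

    ``membership``: context -> list of row indices into that context's
    protein matrix to include.
    """
    total = None
    for c in sorted(membership):
        rows = list(membership[c])
        if not rows:
            continue
        z = protein_z[c]
        zc = celltype_z[c]
        if isinstance(z, Tensor):
            diff = z.gather(rows) - zc
            term = (diff * diff).sum()
        else:
            diff = np.asarray(z)[rows] - np.asarray(zc)
            term = float((diff**2).sum())
        total = term if total is None else total + term
    if total is None:
        return 0.0
    return total


def loss_metagraph(probs_by_type, labels_by_type):
    """Per-edge-type BCE, summed per biological scale.

    Returns (L_celltype, L_tissue) = (L_CC + L_CT, L_TT + L_TC). Missing
    edge types contribute zero.
    """

    def term(et):
        if et not in probs_by_type or len(labels_by_type[et]) == 0:
            return 0.0
        return _bce_sum(probs_by_type[et], labels_by_type[et])

    return term("CC") + term("CT"), term("TT") + term("TC")


def loss_total(l_ppi, l_center, l_celltype, l_tissue, theta: float, lam: float):
    """L = theta*L_ppi + lambda*L_center + (1-theta)*(L_celltype + L_tissue)."""
    if not (0 <= theta <= 1 and 0 <= lam <= 1):
        raise ValueError("theta and lambda must lie in [0, 1]")
    return theta * l_ppi + lam * l_center + (1 - theta) * (l_celltype + l_tissue)


class Adam:
    """Adam with decoupled L2 weight decay on a named parameter dict."""

    def __init__(self, params: dict[str, Tensor], lr: float, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad + self.wd * p.data
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _metagraph_sets(metagraph: Metagraph):
    """Positive edges per decoded edge type, and candidate nodes per kind."""
    cts = sorted(metagraph.cell_types)
    tis = sorted(metagraph.tissues)
    pos = {
        "CC": sorted(metagraph.cc_edges),
        "CT": sorted(metagraph.ct_edges),
        "TC": sorted((t, c) for c, t in metagraph.ct_edges),
        "TT": sorted(metagraph.tt_edges),
    }
    dst_kind = {"CC": cts, "CT": tis, "TC": cts, "TT": tis}
    und = {
        "CC": {tuple(sorted(e)) for e in metagraph.cc_edges},
        "CT": set(metagraph.ct_edges),
        "TC": {(t, c) for c, t in metagraph.ct_edges},
        "TT": set(metagraph.tt_edges) | {(p, c) for c, p in metagraph.tt_edges},
    }
    return pos, dst_kind, und


def _sample_mg_negatives(pos, dst_kind, existing, rng):
    """Corrupt the destination within its node kind, 1:1."""
    neg = {}
    for et, edges in pos.items():
        out = []
        pool = dst_kind[et]
        for u, v in edges:
            cands = [
                w
                for w in pool
                if w != u
                and (u, w) not in existing[et]
                and (et != "CC" or tuple(sorted((u, w))) not in existing[et])
            ]
            if not cands:
                continue
            out.append((u, cands[int(rng.integers(len(cands)))]))
        neg[et] = out
    return neg


def _decode_pairs(emb: Tensor, index: dict[str, int], pairs, r: Tensor):
    """Vectorized bilinear decoding of node pairs against one edge type."""
    u_idx = [index[u] for u, _ in pairs]
    v_idx = [index[v] for _, v in pairs]
    _, prob = decode_edge(emb.gather(u_idx), r.reshape(1, -1), emb.gather(v_idx))
    return prob


@dataclass
class PretrainResults:
    """Outcome of pretraining: embeddings, history and the selected epoch."""

    embedding_space: EmbeddingSpace
    history: pd.DataFrame
    best_epoch: int
    val_auroc: float
    test_auroc: float
    config: TrainingConfig
    split: EdgeSplit
    model: MultiscaleGAT

    def summary(self) -> str:
        h = self.history.iloc[-1]
        lines = [
            "Multiscale embedding pretraining",
            "=" * 40,
            f"contexts:            {len(self.model.contexts)}",
            f"proteins (unique):   {len(self.model.proteins)}",
            f"representations:     {sum(len(v) for v in self.model.ctx_nodes.values())}",
            f"tissues:             {len(self.model.mg_tissues)}",
            f"epochs run:          {len(self.history)}",
            f"best epoch:          {self.best_epoch}",
            f"val link AUROC:      {self.val_auroc:.4f}",
            f"test link AUROC:     {self.test_auroc:.4f}",
            f"final L_ppi:         {h['L_ppi']:.4f}",
            f"final L_center:      {h['L_center']:.4f}",
            f"final L_celltype:    {h['L_celltype']:.4f}",
            f"final L_tissue:      {h['L_tissue']:.4f}",
        ]
        return "\n".join(lines)


def train(
    networks: list[CellTypePPINetwork],
    metagraph: Metagraph,
    config: TrainingConfig | None = None,
    seed: int = 0,
) -> PretrainResults:
    """Full-graph gradient pretraining with best-epoch model selection."""
    cfg = config or TrainingConfig()
    rng = np.random.default_rng(seed)
    model = MultiscaleGAT(
        networks, metagraph, cfg.model, seed=int(rng.integers(2**31 - 1))
    )
    split = split_edges(networks, cfg.fractions, seed=int(rng.integers(2**31 - 1)))
    nets = {n.context: n for n in networks}

    # fixed validation/test negatives; train negatives resampled per epoch
    eval_neg = {}
    for part, edges in (("val", split.val), ("test", split.test)):
        eval_neg[part] = {
            c: sample_negatives(nets[c].nodes, nets[c].edges, edges[c], rng)
            for c in model.contexts
        }
    mg_pos, mg_dst_kind, mg_existing = _metagraph_sets(metagraph)

    opt = Adam(model.params, lr=cfg.lr_link, weight_decay=cfg.weight_decay)
    center_scale = cfg.lr_center / cfg.lr_link if cfg.lr_link > 0 else 1.0
    membership = {
        c: [
            i
            for i, p in enumerate(model.ctx_nodes[c])
            if p in split.train_proteins[c]
        ]
        for c in model.contexts
    }

    history = []
    best = (-np.inf, -np.inf, 0)
    best_params: dict[str, np.ndarray] = {}
    train_neg = {
        c: sample_negatives(nets[c].nodes, nets[c].edges, split.train[c], rng)
        for c in model.contexts
    }
    mg_neg = _sample_mg_negatives(mg_pos, mg_dst_kind, mg_existing, rng)

    for epoch in range(cfg.epochs):
        if cfg.resample_negatives and epoch > 0:
            train_neg = {
                c: sample_negatives(nets[c].nodes, nets[c].edges, split.train[c], rng)
                for c in model.contexts
            }
            mg_neg = _sample_mg_negatives(mg_pos, mg_dst_kind, mg_existing, rng)

        p_emb, mg_x, _ = model.forward(
            train=True, rng=rng, message_edges=split.train
        )
        ctx_index = {
            c: {p: i for i, p in enumerate(model.ctx_nodes[c])}
            for c in model.contexts
        }

        # protein-level link prediction
        prob_parts, labels = [], []
        for c in model.contexts:
            pairs = sorted(split.train[c]) + train_neg[c]
            pr = _decode_pairs(
                p_emb[c], ctx_index[c], pairs, model.decoder_vector("PP")
            )
            prob_parts.append(pr.reshape(-1, 1))
            labels.extend([1] * len(split.train[c]) + [0] * len(train_neg[c]))
        prob_flat = concat(prob_parts, axis=0).reshape(-1)
        l_ppi = loss_ppi(prob_flat, labels)

        # center loss toward cell-type embeddings
        celltype_rows = {
            c: mg_x.gather([model.mg_idx[c]]).reshape(-1) for c in model.contexts
        }
        l_center = loss_center(p_emb, celltype_rows, membership)

        # metagraph link prediction
        probs_by_type, labels_by_type = {}, {}
        for et in ("CC", "CT", "TC", "TT"):
            pairs = mg_pos[et] + mg_neg[et]
            if not pairs:
                labels_by_type[et] = []
                continue
            probs_by_type[et] = _decode_pairs(
                mg_x, model.mg_idx, pairs, model.decoder_vector(et)
            )
            labels_by_type[et] = [1] * len(mg_pos[et]) + [0] * len(mg_neg[et])
        l_celltype, l_tissue = loss_metagraph(probs_by_type, labels_by_type)

        # the center-loss learning rate enters as a gradient scale
        grad_loss = loss_total(
            l_ppi, l_center * center_scale, l_celltype, l_tissue, cfg.theta, cfg.lam
        )
        if isinstance(grad_loss, Tensor):
            if not np.isfinite(grad_loss.data).all():
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: "
                    f"ppi={float(getattr(l_ppi, 'data', l_ppi))}"
                )
            opt.zero_grad()
            grad_loss.backward()
            opt.step()

        # ---- evaluation for model selection --------------------------------
        p_ev, mg_ev, _ = model.forward(train=False, message_edges=split.train)
        val_scores, val_labels = [], []
        for c in model.contexts:
            lut = ctx_index[c]
            pairs = sorted(split.val[c]) + eval_neg["val"][c]
            pe = p_ev[c].data
            _, pr = decode_edge(
                pe[[lut[u] for u, _ in pairs]],
                model.decoder_vector("PP").data,
                pe[[lut[v] for _, v in pairs]],
            )
            val_scores.extend(pr)
            val_labels.extend([1] * len(split.val[c]) + [0] * len(eval_neg["val"][c]))
        val_auroc = roc_auc_score(val_labels, val_scores)
        if len(model.contexts) >= 2:
            zs = np.vstack([p_ev[c].data for c in model.contexts])
            cls = np.concatenate(
                [[i] * len(model.ctx_nodes[c]) for i, c in enumerate(model.contexts)]
            )
            ch = calinski_harabasz_score(zs, cls)
        else:
            ch = 0.0
        history.append(
            {
                "epoch": epoch,
                "L_ppi": float(getattr(l_ppi, "data", l_ppi)),
                "L_center": float(getattr(l_center, "data", l_center)),
                "L_celltype": float(getattr(l_celltype, "data", l_celltype)),
                "L_tissue": float(getattr(l_tissue, "data", l_tissue)),
                "L_total": float(
                    loss_total(
                        float(getattr(l_ppi, "data", l_ppi)),
                        float(getattr(l_center, "data", l_center)),
                        float(getattr(l_celltype, "data", l_celltype)),
                        float(getattr(l_tissue, "data", l_tissue)),
                        cfg.theta,
                        cfg.lam,
                    )
                ),
                "val_auroc": float(val_auroc),
                "ch_score": float(ch),
            }
        )
        if (val_auroc, ch) > best[:2]:
            best = (val_auroc, ch, epoch)
            best_params = {k: p.data.copy() for k, p in model.params.items()}

    for k, p in model.params.items():  # restore selected epoch
        p.data = best_params[k].copy()

    p_fin, mg_fin, _ = model.forward(train=False)  # full graphs for inference
    space = model.embedding_space(p_fin, mg_fin)

    # held-out test AUROC with the selected parameters (train-graph messages)
    p_ev, _, _ = model.forward(train=False, message_edges=split.train)
    scores, labels = [], []
    for c in model.contexts:
        lut = {p: i for i, p in enumerate(model.ctx_nodes[c])}
        pairs = sorted(split.test[c]) + eval_neg["test"][c]
        pe = p_ev[c].data
        _, pr = decode_edge(
            pe[[lut[u] for u, _ in pairs]],
            model.decoder_vector("PP").data,
            pe[[lut[v] for _, v in pairs]],
        )
        scores.extend(pr)
        labels.extend([1] * len(split.test[c]) + [0] * len(eval_neg["test"][c]))
    test_auroc = float(roc_auc_score(labels, scores))

    return PretrainResults(
        embedding_space=space,
        history=pd.DataFrame(history),
        best_epoch=best[2],
        val_auroc=float(best[0]),
        test_auroc=test_auroc,
        config=cfg,
        split=split,
        model=model,
    )


class MultiscaleEmbeddingModel:
    """Model-object interface over pretraining.

    Parameters
    ----------
    networks : list of CellTypePPINetwork
    metagraph : Metagraph
    config : TrainingConfig, optional

    ``fit(seed)`` trains the multiscale attention model and returns a
    :class:`PretrainResults` carrying the embedding space, the per-epoch
    loss/metric history and a ``summary()``.
    """

    def __init__(self, networks, metagraph, config: TrainingConfig | None = None):
        self.networks = networks
        self.metagraph = metagraph
        self.config = config or TrainingConfig()

    def fit(self, seed: int = 0) -> PretrainResults:
        return train(self.networks, self.metagraph, self.config, seed=seed)
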