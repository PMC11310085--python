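"""Context-specific therapeutic-target prioritization.

Protein-level binary labels are joined to the per-context embeddings to form
one record per (protein, context). Splitting is by protein identity (all of
a protein's contextual representations share one split, preventing leakage),
with greedy reassignment so every cell type keeps at least one positive per
split where feasible. A small MLP scores each record; model selection is by
validation AUPRC; contexts are ranked by APR@K of their held-out test
records, averaged over seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score

from ._autograd import Tensor

__all__ = [
    "FinetuneConfig",
    "FinetuneDataset",
    "build_finetune_dataset",
    "MLPClassifier",
    "train_mlp",
    "apr_at_k",
    "rank_contexts",
    "rank_proteins_for_context",
    "RankingResult",
    "TargetScoringModel",
    "FinetuneResults",
]


@dataclass
class FinetuneConfig:
    hidden: tuple[int, int] = (16, 16)
    dropout: float = 0.5
    layer_norm: bool = True
    lr: float = 0.01
    weight_decay: float = 1e-4
    epochs: int = 200


@dataclass
class FinetuneDataset:
    """One record per (protein, context) with label and split assignment."""

    records: pd.DataFrame  # protein, context, label, split
    embeddings: dict[tuple[str, str], np.ndarray]
    unscorable: list[str] = field(default_factory=list)

    def split_records(self, split: str) -> pd.DataFrame:
        return self.records[self.records["split"] == split]

    def matrix(self, df: pd.DataFrame) -> np.ndarray:
        return np.vstack(
            [self.embeddings[(p, c)] for p, c in zip(df["protein"], df["context"])]
        )

    def check_leakage(self) -> None:
        by_split = self.records.groupby("split")["protein"].apply(set)
        splits = list(by_split)
        for i in range(len(splits)):
            for j in range(i + 1, len(splits)):
                assert not (splits[i] & splits[j]), "protein identity crosses splits"


def build_finetune_dataset(
    labels: dict[str, int],
    space,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> FinetuneDataset:
    """Assemble leakage-safe (protein, context) records from labels.

    Proteins are split by identity at the given fractions; positives are
    then greedily reassigned so every context keeps >= 1 positive record in
    each split where feasible. Contexts with no positive protein at all are
    flagged unscorable (not an error).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    keys = sorted(space.protein)
    labeled = sorted({p for p, _ in keys} & set(labels))
    pos = [p for p in labeled if labels[p] == 1]
    neg = [p for p in labeled if labels[p] == 0]
    if not pos or not neg:
        raise ValueError("need at least one positive and one negative labeled protein")

    rng = np.random.default_rng(seed)
    split_of: dict[str, str] = {}
    for group in (pos, neg):  # stratified identity split
        perm = [group[i] for i in rng.permutation(len(group))]
        n = len(perm)
        n_val = int(round(fractions[1] * n))
        n_test = int(round(fractions[2] * n))
        n_train = n - n_val - n_test
        for p in perm[:n_train]:
            split_of[p] = "train"
        for p in perm[n_train : n_train + n_val]:
            split_of[p] = "val"
        for p in perm[n_train + n_val :]:
            split_of[p] = "test"

    contexts = sorted({c for _, c in keys})
    members: dict[str, list[str]] = {
        c: sorted({p for p, cc in keys if cc == c and p in split_of}) for c in contexts
    }
    unscorable = [
        c for c in contexts if not any(labels[p] == 1 for p in members[c])
    ]

    # greedy reassignment: every context needs a positive in every split
    def pos_by_split(c):
        out = {"train": [], "val": [], "test": []}
        for p in members[c]:
            if labels[p] == 1:
                out[split_of[p]].append(p)
        return out

    for c in contexts:
        if c in unscorable:
            continue
        for target_split in ("train", "val", "test"):
            tally = pos_by_split(c)
            if tally[target_split]:
                continue
            donors = sorted(
                (s for s in ("train", "val", "test") if len(tally[s]) >= 2),
                key=lambda s: -len(tally[s]),
            )
            if donors:
                mover = tally[donors[0]][0]
                split_of[mover] = target_split

    rows = [
        (p, c, labels[p], split_of[p])
        for p, c in keys
        if p in split_of
    ]
    records = pd.DataFrame(rows, columns=["protein", "context", "label", "split"])
    ds = FinetuneDataset(
        records=records,
        embeddings={k: np.asarray(space.protein[k], float) for k in keys},
        unscorable=unscorable,
    )
    ds.check_leakage()
    return ds


class MLPClassifier:
    """Input -> hidden -> hidden -> sigmoid scorer with dropout and
    layer-norm between the input and hidden layers."""

    def __init__(self, in_dim: int, config: FinetuneConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        h1, h2 = config.hidden
        self.config = config

        def glorot(din, dout):
            return Tensor(
                rng.normal(0, np.sqrt(2.0 / (din + dout)), size=(din, dout)),
                requires_grad=True,
            )

        self.params = {
            "W1": glorot(in_dim, h1),
            "b1": Tensor(np.zeros(h1), requires_grad=True),
            "W2": glorot(h1, h2),
            "b2": Tensor(np.zeros(h2), requires_grad=True),
            "W3": glorot(h2, 1),
            "b3": Tensor(np.zeros(1), requires_grad=True),
        }

    def _forward(self, x: np.ndarray, rng=None) -> Tensor:
        cfg = self.config
        h = (Tensor(x) @ self.params["W1"] + self.params["b1"]).relu()
        if cfg.layer_norm:
            mu = h.mean(axis=1, keepdims=True)
            var = ((h - mu) ** 2).mean(axis=1, keepdims=True)
            h = (h - mu) / (var + 1e-5).sqrt()
        if rng is not None and cfg.dropout > 0:
            keep = (rng.random(h.data.shape) >= cfg.dropout) / (1 - cfg.dropout)
            h = h * Tensor(keep)
        h = (h @ self.params["W2"] + self.params["b2"]).relu()
        logit = h @ self.params["W3"] + self.params["b3"]
        return logit.reshape(-1).sigmoid()

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self._forward(np.atleast_2d(x)).data


def train_mlp(
    dataset: FinetuneDataset,
    config: FinetuneConfig | None = None,
    seed: int = 0,
) -> MLPClassifier:
    """Fit the scorer on train records; keep the epoch with best validation
    AUPRC."""
    from .training import Adam

    cfg = config or FinetuneConfig()
    tr = dataset.split_records("train")
    if len(tr) == 0:
        raise ValueError("empty train split")
    va = dataset.split_records("val")
    x_tr, y_tr = dataset.matrix(tr), tr["label"].to_numpy(float)
    x_va = dataset.matrix(va) if len(va) else None
    y_va = va["label"].to_numpy(float) if len(va) else None

    rng = np.random.default_rng(seed)
    clf = MLPClassifier(x_tr.shape[1], cfg, seed=int(rng.integers(2**31 - 1)))
    opt = Adam(clf.params, lr=cfg.lr, weight_decay=cfg.weight_decay)
    best_auprc, best_params = -np.inf, None
    y_t = Tensor(y_tr)
    for _ in range(cfg.epochs):
        p = clf._forward(x_tr, rng=rng).clip(1e-12, 1 - 1e-12)
        loss = -(y_t * p.log() + (1 - y_t) * (1 - p).log()).mean()
        opt.zero_grad()
        loss.backward()
        opt.step()
        if x_va is not None and y_va.sum() > 0:
            auprc = average_precision_score(y_va, clf.predict_proba(x_va))
        else:
            auprc = -float(loss.data)
        if auprc > best_auprc:
            best_auprc = auprc
            best_params = {k: t.data.copy() for k, t in clf.params.items()}
    if best_params is not None:
        for k, t in clf.params.items():
            t.data = best_params[k].copy()
    clf.val_auprc_ = float(best_auprc)
    return clf


def apr_at_k(relevance, K: int) -> float:
    """Average Precision and Recall at K over a ranked binary relevance list.

    APR@K = (1/r) * sum_{k<=K} Precision@k * rel(k), where r is the number
    of relevant items among the top K; returns 0 when r = 0. K larger than
    the list is clamped.
    """
    rel = np.asarray(relevance)
    if rel.size and not np.isin(rel, (0, 1)).all():
        raise ValueError("relevance must be binary")
    if K < 1:
        raise ValueError("K must be >= 1")
    K = min(K, rel.size)
    top = rel[:K].astype(int)
    r = int(top.sum())
    if r == 0:
        return 0.0
    # exact rational accumulation: APR@K is a ratio of small integers
    from fractions import Fraction

    total = Fraction(0)
    hits = 0
    for k in range(1, K + 1):
        hits += int(top[k - 1])
        if top[k - 1]:
            total += Fraction(hits, k)
    return float(total / r)


@dataclass
class RankingResult:
    per_context: pd.DataFrame  # context, seed, apr_at_k
    context_ranking: list[str]  # by descending mean APR@K
    mean_apr: pd.Series
    K: int


def _score_test_records(clf: MLPClassifier, dataset: FinetuneDataset, context: str):
    te = dataset.split_records("test")
    te = te[te["context"] == context]
    if len(te) == 0:
        return None
    x = dataset.matrix(te)
    scores = clf.predict_proba(x)
    df = te.assign(score=scores).sort_values(
        ["score", "protein"], ascending=[False, True], kind="stable"
    )
    return df


def rank_contexts(
    dataset: FinetuneDataset,
    config: FinetuneConfig | None = None,
    K: int = 5,
    seeds: tuple[int, ...] = (0, 1, 2),
) -> RankingResult:
    """Train the scorer once per seed and rank contexts by mean APR@K of
    their held-out test records."""
    rows = []
    contexts = sorted(set(dataset.records["context"]))
    scorable = [c for c in contexts if c not in dataset.unscorable]
    if not scorable:
        raise ValueError("no scorable context")
    for seed in seeds:
        clf = train_mlp(dataset, config, seed=seed)
        for c in scorable:
            ranked = _score_test_records(clf, dataset, c)
            if ranked is None:
                continue
            rows.append((c, seed, apr_at_k(ranked["label"].to_numpy(), K)))
    df = pd.DataFrame(rows, columns=["context", "seed", "apr_at_k"])
    mean_apr = df.groupby("context")["apr_at_k"].mean().sort_values(ascending=False)
    return RankingResult(
        per_context=df,
        context_ranking=list(mean_apr.index),
        mean_apr=mean_apr,
        K=K,
    )


def rank_proteins_for_context(
    clf: MLPClassifier, dataset: FinetuneDataset, context: str
) -> pd.DataFrame:
    """All of a context's records scored and sorted (ties by protein id)."""
    recs = dataset.records[dataset.records["context"] == context]
    if len(recs) == 0:
        raise ValueError(f"unknown or empty context {context!r}")
    scores = clf.predict_proba(dataset.matrix(recs))
    return (
        recs.assign(score=scores)
        .sort_values(["score", "protein"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )


@dataclass
class FinetuneResults:
    ranking: RankingResult
    dataset: FinetuneDataset
    classifier: MLPClassifier

    def summary(self) -> str:
        lines = [
            "Context-specific target prioritization",
            "=" * 40,
            f"records:        {len(self.dataset.records)}",
            f"contexts:       {self.ranking.per_context['context'].nunique()}",
            f"K:              {self.ranking.K}",
            "mean APR@K by context:",
        ]
        for c, v in self.ranking.mean_apr.items():
            lines.append(f"  {c:<16s} {v:.3f}")
        return "\n".join(lines)


class TargetScoringModel:
    """Model-object interface: labels + embedding space in, ranking out."""

    def __init__(
        self,
        labels: dict[str, int],
        space,
        config: FinetuneConfig | None = None,
        K: int = 5,
    ):
        self.labels = labels
        self.space = space
        self.config = config or FinetuneConfig()
        self.K = K

    def fit(self, seed: int = 0, n_seeds: int = 3) -> FinetuneResults:
        dataset = build_finetune_dataset(self.labels, self.space, seed=seed)
        seeds = tuple(seed + i for i in range(n_seeds))
        ranking = rank_contexts(dataset, self.config, K=self.K, seeds=seeds)
        clf = train_mlp(dataset, self.config, seed=seed)
        return FinetuneResults(ranking=ranking, dataset=dataset, classifier=clf)
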