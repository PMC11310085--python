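"""End-to-end convenience: synthetic study -> networks -> metagraph -> fit.

``build_study`` runs activation testing, network construction, the
ligand-receptor permutation test and metagraph assembly with one seed;
``pretrain_study`` adds multiscale pretraining. Tests and the acceptance
script share this path so every stage runs under the same conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .networks import (
    CellTypePPINetwork,
    Metagraph,
    RejectedNetwork,
    build_celltype_network,
    build_metagraph,
    compute_gene_activation,
    lr_significance_test,
)
from .synthetic import Fixture
from .training import MultiscaleEmbeddingModel, PretrainResults, TrainingConfig, fixture_config

__all__ = ["Study", "build_study", "pretrain_study"]


@dataclass
class Study:
    fixture: Fixture
    networks: list[CellTypePPINetwork]
    metagraph: Metagraph
    activation: dict[str, set[str]]  # context -> activated genes


def build_study(
    fixture: Fixture,
    seed: int = 0,
    *,
    top_k: int | None = None,
    n_iterations: int = 10,
    retention: float = 0.9,
    min_size: int = 20,
    n_permutations: int = 1000,
    lr_alpha: float = 0.001,
) -> Study:
    """Construct all context networks and the metagraph for a fixture.

    ``top_k`` defaults to each context's planted marker count (the study is
    synthetic, so the number of activated genes is known by design).
    """
    fx = fixture
    rng = np.random.default_rng(seed)
    networks, activation = [], {}
    for ct in fx.atlas.cell_types:
        k = top_k if top_k is not None else len(fx.truth.marker_genes[ct])
        acts = compute_gene_activation(
            fx.atlas,
            ct,
            top_k=k,
            n_iterations=n_iterations,
            retention=retention,
            seed=int(rng.integers(2**31 - 1)),
        )
        activated = {a.gene for a in acts if a.activated}
        activation[ct] = activated
        net = build_celltype_network(
            activated,
            fx.reference_edges,
            min_size=min_size,
            context=ct,
            provenance={a.gene: a.retention_fraction for a in acts},
        )
        if not isinstance(net, RejectedNetwork):
            networks.append(net)
    lr = lr_significance_test(
        fx.atlas,
        fx.lr_pairs,
        n_permutations=n_permutations,
        alpha=lr_alpha,
        seed=int(rng.integers(2**31 - 1)),
    )
    metagraph = build_metagraph(networks, lr, fx.atlas, fx.ontology, alpha=lr_alpha)
    return Study(fixture=fx, networks=networks, metagraph=metagraph, activation=activation)


def pretrain_study(
    study: Study,
    seed: int = 0,
    config: TrainingConfig | None = None,
) -> PretrainResults:
    cfg = config or fixture_config()
    return MultiscaleEmbeddingModel(study.networks, study.metagraph, cfg).fit(seed=seed)
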