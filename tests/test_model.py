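"""Multiscale attention model: initialization, attention normalization,
hand-computed toys, decoder, equivariance and gradient flow."""

import numpy as np
import pytest

from contextppi._autograd import Tensor
from contextppi.model import (
    ModelConfig,
    MultiscaleGAT,
    decode_edge,
    init_embeddings,
)
from contextppi.networks import CellTypePPINetwork, Metagraph


def toy_networks_and_metagraph():
    net_a = CellTypePPINetwork(
        context="A", nodes=["p1", "p2", "p3"],
        edges={("p1", "p2"), ("p2", "p3")},
    )
    net_b = CellTypePPINetwork(
        context="B", nodes=["p2", "p3", "p4"],
        edges={("p2", "p3"), ("p3", "p4")},
    )
    mg = Metagraph(
        cell_types={"A", "B"},
        tissues={"leaf1", "leaf2", "root"},
        cc_edges={("A", "B")},
        ct_edges={("A", "leaf1"), ("B", "leaf2")},
        tt_edges={("leaf1", "root"), ("leaf2", "root")},
    )
    return [net_a, net_b], mg


def small_config(**kw):
    defaults = dict(feature_dim=8, out_dim=4, heads=2, dropout=0.0)
    defaults.update(kw)
    return ModelConfig(**defaults)


class TestInitEmbeddings:
    def test_shared_identity_across_contexts(self):
        nets, mg = toy_networks_and_metagraph()
        state = init_embeddings(nets, mg, dim=6, seed=0)
        assert np.array_equal(state.protein["A"]["p2"], state.protein["B"]["p2"])
        assert np.array_equal(state.protein["A"]["p3"], state.protein["B"]["p3"])

    def test_celltype_is_mean_of_proteins(self):
        nets, mg = toy_networks_and_metagraph()
        state = init_embeddings(nets, mg, dim=4, seed=1)
        expected = np.mean([state.protein["A"][p] for p in nets[0].nodes], axis=0)
        assert np.allclose(state.cell_type["A"], expected)

    def test_tissue_is_mean_of_neighbors(self):
        nets, mg = toy_networks_and_metagraph()
        state = init_embeddings(nets, mg, dim=4, seed=2)
        # leaf1 neighbors: cell type A and root
        assert np.allclose(
            state.tissue["leaf1"],
            np.mean([state.cell_type["A"], state.tissue["root"]], axis=0),
        ) or np.allclose(  # root initialized after leaves: then leaf1 = mean(A)
            state.tissue["leaf1"], state.cell_type["A"]
        )

    def test_deterministic(self):
        nets, mg = toy_networks_and_metagraph()
        a = init_embeddings(nets, mg, dim=5, seed=3)
        b = init_embeddings(nets, mg, dim=5, seed=3)
        assert np.array_equal(a.protein["A"]["p1"], b.protein["A"]["p1"])

    def test_empty_network_list_rejected(self):
        _, mg = toy_networks_and_metagraph()
        with pytest.raises(ValueError):
            init_embeddings([], mg, dim=4)


class TestAttentionNormalization:
    def test_all_weight_families_sum_to_one(self):
        nets, mg = toy_networks_and_metagraph()
        model = MultiscaleGAT(nets, mg, small_config(), seed=0)
        _, _, state = model.forward()
        for (layer, ctx), (src, dst, alpha) in state.alpha.items():
            sums = np.zeros((len(model.ctx_nodes[ctx]), alpha.shape[1]))
            np.add.at(sums, dst, alpha)
            assert np.allclose(sums, 1.0), (layer, ctx)
        for (layer, rel), (src, dst, alpha) in state.alpha_mg.items():
            targets = np.unique(dst)
            sums = np.zeros((len(model.mg_nodes), alpha.shape[1]))
            np.add.at(sums, dst, alpha)
            assert np.allclose(sums[targets], 1.0), (layer, rel)
        for layer in (0, 1):
            assert state.beta[(layer, "CC")] + state.beta[(layer, "CT")] == pytest.approx(1.0)
            assert state.beta[(layer, "TT")] + state.beta[(layer, "TC")] == pytest.approx(1.0)
        for (layer, ctx), gamma in state.gamma.items():
            assert gamma.sum() == pytest.approx(1.0)
            assert (gamma >= 0).all()

    def test_single_protein_context_gamma_is_one(self):
        net = CellTypePPINetwork(context="A", nodes=["p1"], edges=set())
        mg = Metagraph(
            cell_types={"A"}, tissues={"leaf1"}, cc_edges=set(),
            ct_edges={("A", "leaf1")}, tt_edges=set(),
        )
        model = MultiscaleGAT([net], mg, small_config(), seed=1)
        _, _, state = model.forward()
        for (layer, ctx), (src, dst, alpha) in state.alpha.items():
            assert np.allclose(alpha, 1.0)  # self-loop only
        for key, gamma in state.gamma.items():
            assert gamma.shape == (1,) and gamma[0] == pytest.approx(1.0)

    def test_identical_neighbors_share_attention(self):
        # p2's neighbors p1 and p3 have identical features -> equal weights
        net = CellTypePPINetwork(
            context="A", nodes=["p1", "p2", "p3"], edges={("p1", "p2"), ("p2", "p3")}
        )
        mg = Metagraph(
            cell_types={"A"}, tissues={"leaf1"}, cc_edges=set(),
            ct_edges={("A", "leaf1")}, tt_edges=set(),
        )
        model = MultiscaleGAT([net], mg, small_config(), seed=2)
        feats = model.params["features"].data
        feats[model.pidx["p3"]] = feats[model.pidx["p1"]]
        _, _, state = model.forward()
        src, dst, alpha = state.alpha[(0, "A")]
        i2 = net.nodes.index("p2")
        w = {s: alpha[k] for k, (s, d) in enumerate(zip(src, dst)) if d == i2}
        assert np.allclose(w[net.nodes.index("p1")], w[net.nodes.index("p3")])


class TestHandComputedToy:
    def test_two_node_single_head_matches_hand_calculation(self):
        """dim=1, one head, all weights 1: attention reduces to a softmax of
        LeakyReLU(h_u + h_v) and the update to alpha-weighted sums."""
        net = CellTypePPINetwork(context="A", nodes=["u", "v"], edges={("u", "v")})
        mg = Metagraph(
            cell_types={"A"}, tissues={"t"}, cc_edges=set(),
            ct_edges={("A", "t")}, tt_edges=set(),
        )
        cfg = ModelConfig(
            feature_dim=1, out_dim=1, heads=1, dropout=0.0,
            layer_norm=False, batch_norm=False,
        )
        model = MultiscaleGAT([net], mg, cfg, seed=0)
        for name, p in model.params.items():
            p.data = np.ones_like(p.data)
        x = np.array([2.0, 3.0])  # features for u, v
        model.params["features"].data = x.reshape(2, 1)

        # hand calculation, layer 1 (weights all 1, slope 0.2):
        # edges into u: from v (score LeakyReLU(2+3)=5) and self (LeakyReLU(2+2)=4)
        # alpha_v = e^5/(e^5+e^4), alpha_u = e^4/(e^5+e^4); message values Wr h = h
        au_v = np.exp(5) / (np.exp(5) + np.exp(4))
        au_u = 1 - au_v
        h_u = max(au_v * 3 + au_u * 2, 0.0)
        av_u = np.exp(5) / (np.exp(5) + np.exp(6))
        av_v = 1 - av_u
        h_v = max(av_u * 2 + av_v * 3, 0.0)

        out, alpha = model._gat(
            model.params["features"],
            *model._ctx_edges_full["A"],
            2,
            model.params["pp/A/l0/Wl"],
            model.params["pp/A/l0/Wr"],
            model.params["pp/A/l0/a"],
            1,
            True,
        )
        assert out.data.ravel() == pytest.approx([h_u, h_v])

    def test_permuting_metagraph_input_order_is_invariant(self):
        nets, mg = toy_networks_and_metagraph()
        model = MultiscaleGAT(nets, mg, small_config(), seed=5)
        _, mg_x1, _ = model.forward()
        _, mg_x2, _ = model.forward()
        assert np.array_equal(mg_x1.data, mg_x2.data)


class TestDecoder:
    def test_closed_forms(self):
        ones = np.ones(4)
        logit, prob = decode_edge(ones, ones, ones)
        assert logit == pytest.approx(4.0)
        assert prob == pytest.approx(1 / (1 + np.exp(-4.0)))
        _, prob0 = decode_edge(ones, np.zeros(4), ones)
        assert prob0 == pytest.approx(0.5)

    def test_symmetry(self, rng):
        u, r, v = rng.normal(size=(3, 6))
        assert decode_edge(u, r, v)[0] == pytest.approx(decode_edge(v, r, u)[0])

    def test_dim_mismatch_rejected(self):
        with pytest.raises(ValueError):
            decode_edge(np.ones(3), np.ones(3), np.ones(4))


class TestForwardContract:
    def test_deterministic_without_dropout(self):
        nets, mg = toy_networks_and_metagraph()
        m1 = MultiscaleGAT(nets, mg, small_config(), seed=4)
        m2 = MultiscaleGAT(nets, mg, small_config(), seed=4)
        p1, g1, _ = m1.forward()
        p2, g2, _ = m2.forward()
        for c in m1.contexts:
            assert np.array_equal(p1[c].data, p2[c].data)
        assert np.array_equal(g1.data, g2.data)

    def test_zero_parameters_give_zero_outputs(self):
        nets, mg = toy_networks_and_metagraph()
        cfg = small_config(layer_norm=False, batch_norm=False)
        model = MultiscaleGAT(nets, mg, cfg, seed=0)
        for p in model.params.values():
            p.data = np.zeros_like(p.data)
        p_emb, mg_x, _ = model.forward()
        for c in model.contexts:
            assert np.allclose(p_emb[c].data, 0.0)
        assert np.allclose(mg_x.data, 0.0)

    def test_one_embedding_per_protein_context(self):
        nets, mg = toy_networks_and_metagraph()
        model = MultiscaleGAT(nets, mg, small_config(), seed=0)
        space = model.embedding_space()
        expected = {(p, n.context) for n in nets for p in n.nodes}
        assert set(space.protein) == expected
        assert all(np.isfinite(v).all() for v in space.protein.values())

    def test_context_equivariance(self):
        """Identical networks with identical parameters embed identically."""
        shared_edges = {("p1", "p2"), ("p2", "p3")}
        nets = [
            CellTypePPINetwork(context=c, nodes=["p1", "p2", "p3"], edges=set(shared_edges))
            for c in ("A", "B")
        ]
        mg = Metagraph(
            cell_types={"A", "B"}, tissues={"leaf1", "root"}, cc_edges=set(),
            ct_edges={("A", "leaf1"), ("B", "leaf1")}, tt_edges={("leaf1", "root")},
        )
        model = MultiscaleGAT(nets, mg, small_config(), seed=0)
        for l in range(2):
            for suffix in ("Wl", "Wr", "a"):
                model.params[f"pp/B/l{l}/{suffix}"].data = model.params[
                    f"pp/A/l{l}/{suffix}"
                ].data.copy()
        p_emb, _, _ = model.forward()
        assert np.allclose(p_emb["A"].data, p_emb["B"].data)

    def test_gradient_reaches_every_parameter_group(self):
        nets, mg = toy_networks_and_metagraph()
        model = MultiscaleGAT(nets, mg, small_config(), seed=3)
        p_emb, mg_x, _ = model.forward()
        loss = None
        for c in model.contexts:  # touch PP decoder + embeddings
            idx = list(range(len(model.ctx_nodes[c])))
            z = p_emb[c].gather(idx)
            r = model.params["decoder/r_PP"].reshape(1, -1)
            _, prob = decode_edge(z, r, z)
            term = (prob.clip(1e-9, 1 - 1e-9).log() * -1.0).sum()
            loss = term if loss is None else loss + term
        for et, pairs in (
            ("CC", [("A", "B")]),
            ("CT", [("A", "leaf1")]),
            ("TC", [("leaf1", "A")]),
            ("TT", [("leaf1", "root")]),
        ):
            idx_u = [model.mg_idx[u] for u, _ in pairs]
            idx_v = [model.mg_idx[v] for _, v in pairs]
            r = model.params[f"decoder/r_{et}"].reshape(1, -1)
            _, prob = decode_edge(mg_x.gather(idx_u), r, mg_x.gather(idx_v))
            loss = loss + (prob.clip(1e-9, 1 - 1e-9).log() * -1.0).sum()
        loss.backward()
        for group, names in model.parameter_groups().items():
            got = any(
                model.params[n].grad is not None
                and np.abs(model.params[n].grad).max() > 0
                for n in names
            )
            assert got, f"no gradient reached parameter group {group}"
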