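"""Embedding-space analyses: ontology distances, correlation nulls, spatial
enrichment, patch reduction, the permutation test."""

import itertools

import numpy as np
import pytest

from contextppi.evaluation import (
    PatchMatrix,
    TissueOntologyView,
    contextualize_structure,
    cross_context_similarity,
    pairwise_cosine,
    reduce_patch_matrix,
    score_gap_permutation_test,
    spatial_enrichment,
    tissue_distance_correlation,
    tissue_ontology_distance,
)
from contextppi.model import EmbeddingSpace

TOY_TREE = {
    "a": "p1", "b": "p1",  # siblings under p1
    "c": "p2", "p1": "g", "p2": "g", "g": "root",
}


class TestOntologyDistance:
    def test_identity_is_zero(self):
        assert tissue_ontology_distance("a", "a", TOY_TREE) == 0

    def test_parent_child_is_one(self):
        assert tissue_ontology_distance("a", "p1", TOY_TREE) == 1

    def test_lca_asymmetric_depths(self):
        # a's LCA with p2 is g: a->g is 2, p2->g is 1
        assert tissue_ontology_distance("a", "p2", TOY_TREE) == 3

    def test_unknown_node_rejected(self):
        with pytest.raises(KeyError):
            tissue_ontology_distance("a", "zz", TOY_TREE)

    def test_cycle_detection(self):
        with pytest.raises(ValueError):
            TissueOntologyView({"a": "b", "b": "a", "c": "root"})


class TestPairwiseCosine:
    def test_known_values(self):
        v = np.array([[1.0, 1.0], [1.0, 0.0], [0.0, 1.0]])
        sim = pairwise_cosine(v)
        assert sim[0, 0] == 1.0
        assert sim[0, 1] == pytest.approx(1 / np.sqrt(2))
        assert sim[1, 2] == pytest.approx(0.0)
        assert np.allclose(sim, sim.T)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            pairwise_cosine(np.array([[1.0, 0.0], [0.0, 0.0]]))


class TestTissueCorrelation:
    @staticmethod
    def chain_ontology(n):
        return {f"t{i}": (f"t{i-1}" if i else "root") for i in range(n)}

    def test_monotone_construction_gives_rho_one(self):
        # embeddings on a 2-d arc: cosine distance increases with chain depth
        onto = self.chain_ontology(8)
        ang = np.linspace(0, np.pi / 2, 8)
        emb = {f"t{i}": np.array([np.cos(a), np.sin(a)]) for i, a in enumerate(ang)}
        emb["root"] = np.array([np.cos(-np.pi / 16), np.sin(-np.pi / 16)])
        res = tissue_distance_correlation(emb, onto, n_shuffles=5, seed=0)
        assert res.spearman_rho > 0.95

    def test_random_embeddings_uncorrelated(self):
        onto = self.chain_ontology(20)
        rng = np.random.default_rng(42)
        emb = {t: rng.standard_normal(16) for t in list(onto) + ["root"]}
        res = tissue_distance_correlation(emb, onto, n_shuffles=10, seed=1)
        assert abs(res.spearman_rho) < 0.2

    def test_shuffled_null_centered_near_zero(self):
        onto = self.chain_ontology(20)
        ang = np.linspace(0, np.pi / 2, 21)
        emb = {t: np.array([np.cos(a), np.sin(a)]) for t, a in zip(list(onto) + ["root"], ang)}
        res = tissue_distance_correlation(emb, onto, n_shuffles=10, seed=2)
        assert abs(np.mean(res.null_rhos)) < 0.15

    def test_too_few_tissues_rejected(self):
        with pytest.raises(ValueError):
            tissue_distance_correlation(
                {"a": np.ones(3), "b": np.ones(3)}, {"a": "b"}, seed=0
            )


def space_from(protein: dict, dim: int) -> EmbeddingSpace:
    return EmbeddingSpace(protein=protein, cell_type={}, tissue={}, dim=dim)


class TestCrossContextSimilarity:
    def test_identical_embeddings_similarity_one(self):
        v = np.array([1.0, 2.0])
        space = space_from(
            {("p", "A"): v, ("p", "B"): v, ("q", "A"): v, ("q", "B"): v, ("q", "C"): v},
            2,
        )
        df, rho, _ = cross_context_similarity(space)
        assert df["mean_similarity"].to_numpy() == pytest.approx(1.0)

    def test_single_context_proteins_excluded(self):
        space = space_from(
            {("p", "A"): np.ones(2), ("p", "B"): np.ones(2), ("solo", "A"): np.ones(2)},
            2,
        )
        df, _, _ = cross_context_similarity(space)
        assert set(df["protein"]) == {"p"}

    def test_constructed_inverse_relation_gives_rho_minus_one(self):
        # vectors v_i = sqrt(1-1/k) e_i + sqrt(1/k) e_shared have pairwise
        # cosine exactly 1/k, so mean similarity decreases with context count
        protein = {}
        for k in (2, 3, 4):
            for c in range(k):
                v = np.zeros(6)
                v[c] = np.sqrt(1 - 1 / k)
                v[5] = np.sqrt(1 / k)
                protein[(f"p{k}", f"ctx{c}")] = v
        space = space_from(protein, 6)
        df, rho, _ = cross_context_similarity(space)
        assert df.sort_values("n_contexts")["mean_similarity"].to_numpy() == pytest.approx(
            [1 / 2, 1 / 3, 1 / 4]
        )
        assert rho == pytest.approx(-1.0)

    def test_no_multicontext_protein_rejected(self):
        with pytest.raises(ValueError):
            cross_context_similarity(space_from({("p", "A"): np.ones(2)}, 2))


class TestSpatialEnrichment:
    @staticmethod
    def clustered_space(rng, n_ctx=4, per_ctx=20, sep=6.0):
        protein = {}
        for c in range(n_ctx):
            center = np.zeros(6)
            center[c] = sep
            for i in range(per_ctx):
                protein[(f"p{c}_{i}", f"ctx{c}")] = center + rng.normal(0, 0.4, 6)
        return space_from(protein, 6)

    def test_planted_cluster_is_enriched(self, rng):
        space = self.clustered_space(rng)
        rep = spatial_enrichment(
            space, "ctx0", threshold=0.05, sample_sizes=(15, 15), seed=0
        )
        assert rep.n_enriched >= 1
        assert rep.max_nes == pytest.approx(1.0, abs=0.7)

    def test_random_labels_not_enriched(self, rng):
        space = self.clustered_space(rng)
        labels = {k: int(rng.random() < 0.25) for k in space.protein}
        rep = spatial_enrichment(
            space, "ctx0", threshold=0.05, sample_sizes=(15, 15), seed=0, labels=labels
        )
        assert rep.n_enriched == 0

    def test_all_focal_labels_degenerate(self, rng):
        space = self.clustered_space(rng)
        labels = dict.fromkeys(space.protein, 1)
        rep = spatial_enrichment(
            space, "ctx0", threshold=0.05, sample_sizes=(15, 15), seed=0, labels=labels
        )
        assert rep.n_enriched == 0
        assert np.allclose(rep.neighborhood_pvalues, 1.0)

    def test_relabeling_nodes_is_invariant(self, rng):
        space = self.clustered_space(rng)
        renamed = space_from(
            {(f"x{p}", c): v for (p, c), v in space.protein.items()}, 6
        )
        a = spatial_enrichment(space, "ctx0", threshold=0.05, sample_sizes=(15, 15), seed=0)
        b = spatial_enrichment(renamed, "ctx0", threshold=0.05, sample_sizes=(15, 15), seed=0)
        assert a.n_enriched == b.n_enriched
        assert a.mean_nes == pytest.approx(b.mean_nes)

    def test_bh_adjustment_is_monotone(self, rng):
        space = self.clustered_space(rng)
        rep = spatial_enrichment(space, "ctx0", threshold=0.05, sample_sizes=(15, 15), seed=0)
        # adjusted p-values sorted by raw p order must be nondecreasing
        order = np.argsort(rep.neighborhood_pvalues, kind="stable")
        adj = rep.neighborhood_pvalues[order]
        assert (np.diff(adj) >= -1e-12).all()

    def test_bad_threshold_rejected(self, rng):
        with pytest.raises(ValueError):
            spatial_enrichment(self.clustered_space(rng), "ctx0", threshold=1.5)


class TestPatchReduction:
    def test_default_k_is_200(self):
        import inspect

        sig = inspect.signature(reduce_patch_matrix)
        assert sig.parameters["k"].default == 200

    def test_hand_medians(self):
        patch = PatchMatrix(
            "p",
            np.array([[1, 2, 3, 4], [0, 0, 10, 10], [-1, 1, -1, 1]], dtype=float),
            binding_scores=np.array([3.0, 2.0, 1.0]),
        )
        out = reduce_patch_matrix(patch, k=3)
        assert out == pytest.approx([2.5, 5.0, 0.0])

    def test_single_dim_returns_score_ordered_column(self):
        patch = PatchMatrix("p", np.array([[3.0], [1.0], [2.0]]))
        out = reduce_patch_matrix(patch, k=2)
        assert out == pytest.approx([3.0, 2.0])

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            reduce_patch_matrix(PatchMatrix("p", np.ones((3, 2))), k=5)


class TestContextualizeStructure:
    def test_lengths_and_context_free_mean(self):
        struct = np.array([1.0, 2.0])
        ctx = {"A": np.array([1.0, 0.0]), "B": np.array([0.0, 1.0])}
        per, free = contextualize_structure(struct, ctx)
        assert all(len(v) == 4 for v in per.values())
        assert free == pytest.approx([1.0, 2.0, 0.5, 0.5])

    def test_single_context_equals_context_free(self):
        per, free = contextualize_structure(np.ones(3), {"A": np.arange(2.0)})
        assert free == pytest.approx(per["A"])

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            contextualize_structure(np.array([]), {"A": np.ones(2)})


class TestScoreGapPermutation:
    def test_exchangeable_groups_average_to_half(self):
        """Under exchangeability the one-sided p of a single draw is uniform;
        its Monte-Carlo average over draws calibrates to 1/2."""
        rng = np.random.default_rng(1)
        ps = []
        for i in range(40):
            a = rng.normal(size=50)
            b = rng.normal(size=50)
            _, p = score_gap_permutation_test(a, b, n_iter=400, seed=i)
            ps.append(p)
        assert abs(np.mean(ps) - 0.5) < 0.1

    def test_matches_exhaustive_enumeration_two_vs_two(self):
        binding = [3.0, 2.0]
        nonbinding = [1.0, 2.5]
        observed = np.mean(binding) - np.mean(nonbinding)
        pooled = binding + nonbinding
        exact = np.mean(
            [
                np.mean([pooled[i], pooled[j]])
                - np.mean([pooled[k] for k in range(4) if k not in (i, j)])
                >= observed
                for i, j in itertools.combinations(range(4), 2)
            ]
        )
        _, p = score_gap_permutation_test(binding, nonbinding, n_iter=100_000, seed=3)
        assert abs(p - exact) < 0.01

    def test_perfect_separation_gives_minimal_p(self):
        # groups large enough that re-drawing the original split is rare
        binding = list(10.0 + np.arange(10))
        nonbinding = list(np.arange(10) / 10.0)
        _, p = score_gap_permutation_test(binding, nonbinding, n_iter=2000, seed=0)
        assert p <= 1 / 2000 + 0.01

    def test_convergence_toward_exhaustive_value(self):
        binding, nonbinding = [3.0, 2.0], [1.0, 2.5]
        _, p_small = score_gap_permutation_test(binding, nonbinding, n_iter=500, seed=1)
        _, p_large = score_gap_permutation_test(binding, nonbinding, n_iter=50_000, seed=1)
        exact = 1 / 3  # from the enumeration above: 2 of 6 splits reach the gap
        assert abs(p_large - exact) <= abs(p_small - exact) + 0.02

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            score_gap_permutation_test([], [1.0], n_iter=10)
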