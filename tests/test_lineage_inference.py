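"""Distances, lineage graphs, PCA and progression embeddings."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

import thymotrace as tt
from thymotrace.lineage_inference import _classical_mds


def prufer_minimum_spanning_tree(matrix: np.ndarray) -> tuple[float, set]:
    """Exhaustive MST oracle: minimize over all labeled trees (Prüfer)."""
    n = matrix.shape[0]
    best_w, best_edges = np.inf, None
    for seq in itertools.product(range(n), repeat=n - 2):
        edges = _tree_from_prufer(list(seq), n)
        w = sum(matrix[u, v] for u, v in edges)
        if w < best_w:
            best_w, best_edges = w, edges
    return best_w, best_edges


def _tree_from_prufer(seq: list, n: int) -> set:
    degree = [1] * n
    for node in seq:
        degree[node] += 1
    edges = set()
    leaves = sorted(i for i in range(n) if degree[i] == 1)
    for node in seq:
        leaf = leaves.pop(0)
        edges.add(frozenset((leaf, node)))
        degree[node] -= 1
        if degree[node] == 1:
            import bisect

            bisect.insort(leaves, node)
    edges.add(frozenset(leaves))
    return {tuple(sorted(e)) for e in edges}


def random_distance_matrix(rng: np.random.Generator, n: int = 7) -> tt.DistanceMatrix:
    pts = rng.normal(size=(n, 3))
    return tt.DistanceMatrix(
        [chr(ord("A") + i) for i in range(n)], squareform(pdist(pts))
    )


class TestDistanceMatrix:
    def test_identical_profiles_zero_distance(self):
        values = pd.DataFrame(
            np.ones((10, 4)),
            index=[f"g{i}" for i in range(10)],
            columns=["s1", "s2", "s3", "s4"],
        )
        meta = pd.DataFrame(
            {"stage": ["A", "A", "B", "B"]}, index=values.columns
        )
        dm = tt.distance_matrix(tt.ExpressionMatrix(values, meta))
        assert dm.matrix[0, 1] == 0.0

    def test_three_four_five(self):
        values = pd.DataFrame(
            {"s1": [0.0, 3.0], "s2": [4.0, 0.0]}, index=["g1", "g2"]
        )
        meta = pd.DataFrame({"stage": ["A", "B"]}, index=values.columns)
        dm = tt.distance_matrix(tt.ExpressionMatrix(values, meta))
        assert dm.matrix[0, 1] == pytest.approx(5.0)

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(
            rng.normal(5, 2, size=(500, 7)),
            index=[f"g{i}" for i in range(500)],
            columns=list(tt.STAGES),
        )
        meta = pd.DataFrame({"stage": list(tt.STAGES)}, index=values.columns)
        dm = tt.distance_matrix(tt.ExpressionMatrix(values, meta))
        X = values.to_numpy().T
        for i in range(7):
            for j in range(7):
                expected = np.sqrt(((X[i] - X[j]) ** 2).sum())
                assert abs(dm.matrix[i, j] - expected) < 1e-9

    def test_invariant_to_sample_and_gene_order(self, default_expression):
        expr, _ = default_expression
        dm = tt.distance_matrix(expr, subset="Vg1.1")
        rng = np.random.default_rng(3)
        gene_perm = rng.permutation(expr.values.index)
        col_perm = rng.permutation(expr.values.columns)
        shuffled = tt.ExpressionMatrix(
            expr.values.loc[gene_perm, col_perm], expr.sample_meta.loc[col_perm]
        )
        dm2 = tt.distance_matrix(shuffled, subset="Vg1.1")
        assert dm.labels == dm2.labels
        np.testing.assert_allclose(dm.matrix, dm2.matrix, atol=1e-9)

    def test_exclusion_list_removed_first(self):
        values = pd.DataFrame(
            {"s1": [0.0, 3.0], "s2": [0.0, 0.0]}, index=["bad", "g2"]
        )
        meta = pd.DataFrame({"stage": ["A", "B"]}, index=values.columns)
        dm = tt.distance_matrix(
            tt.ExpressionMatrix(values, meta), exclude_genes=["bad"]
        )
        assert dm.matrix[0, 1] == pytest.approx(3.0)


class TestLineageGraph:
    def test_three_node_brute_force(self):
        dm = tt.DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0.0, 1.0, 3.0], [1.0, 0.0, 2.0], [3.0, 2.0, 0.0]]),
        )
        graph = tt.build_lineage_graph(dm, method="mst")
        assert graph.edge_set() == {frozenset("AB"), frozenset("BC")}
        assert graph.total_weight() == pytest.approx(3.0)

    def test_chain_distances_give_path_graph(self):
        pos = np.arange(5, dtype=float)[:, None]
        dm = tt.DistanceMatrix(
            list("ABCDE"), squareform(pdist(pos))
        )
        graph = tt.build_lineage_graph(dm, method="mst")
        assert len(graph.leaves) == 2
        assert graph.branch_points == []

    @pytest.mark.parametrize("seed", range(5))
    def test_mst_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        dm = random_distance_matrix(rng, n=7)
        graph = tt.build_lineage_graph(dm, method="mst")
        best_w, best_edges = prufer_minimum_spanning_tree(dm.matrix)
        assert graph.total_weight() == pytest.approx(best_w, abs=1e-9)
        idx = {lbl: i for i, lbl in enumerate(dm.labels)}
        ours = {tuple(sorted((idx[u], idx[v]))) for u, v in graph.graph.edges()}
        assert ours == best_edges

    def test_recovers_designed_topology(self, default_expression):
        expr, truth = default_expression
        dm = tt.distance_matrix(expr, subset="Vg1.1")
        graph = tt.build_lineage_graph(dm, method="mst")
        assert graph.edge_set() == {frozenset(e) for e in truth.topology}
        assert graph.branch_points == ["D"]

    def test_knn_graph_symmetrized(self):
        rng = np.random.default_rng(1)
        dm = random_distance_matrix(rng, n=7)
        graph = tt.build_lineage_graph(dm, method="knn", k=2)
        assert graph.graph.number_of_edges() >= 7  # symmetrized union

    def test_non_finite_distance_rejected(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = np.inf
        dm = tt.DistanceMatrix.__new__(tt.DistanceMatrix)
        dm.labels, dm.matrix, dm.metric = ["A", "B", "C"], m, "euclidean"
        with pytest.raises(ValueError, match="finite"):
            tt.build_lineage_graph(dm)


class TestPcaPopulations:
    def test_collinear_data_explained_by_pc1(self):
        t = np.linspace(0, 1, 6)
        values = pd.DataFrame(
            np.outer(np.ones(20), t) * np.arange(1, 21)[:, None],
            columns=[f"s{i}" for i in range(6)],
        )
        scores, var = tt.pca_populations(tt.ExpressionMatrix(values), 2)
        assert var[0] == pytest.approx(1.0, abs=1e-9)

    def test_scores_centered(self, default_expression):
        expr, _ = default_expression
        scores, _ = tt.pca_populations(expr, 3)
        np.testing.assert_allclose(scores.mean(axis=0).to_numpy(), 0.0, atol=1e-8)

    def test_full_reconstruction(self):
        rng = np.random.default_rng(2)
        values = pd.DataFrame(rng.normal(size=(30, 8)))
        expr = tt.ExpressionMatrix(values)
        X = values.to_numpy().T
        Xc = X - X.mean(axis=0)
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        np.testing.assert_allclose((U * s) @ Vt, Xc, atol=1e-8)
        scores, var = tt.pca_populations(expr, 8)
        np.testing.assert_allclose(
            np.abs(scores.to_numpy()), np.abs(U * s), atol=1e-8
        )

    def test_constant_matrix_rejected(self):
        values = pd.DataFrame(np.ones((10, 5)))
        with pytest.raises(ValueError, match="constant"):
            tt.pca_populations(tt.ExpressionMatrix(values), 2)


class TestIsomap:
    def test_recovers_planted_pseudotime(self, curve_events):
        events, t = curve_events
        coords, _ = tt.isomap_progression(events, 100, k_neighbors=10, seed=0)
        rho = spearmanr(coords[:, 0], t).statistic
        assert abs(rho) >= 0.99

    def test_complete_graph_equals_classical_mds(self, curve_events):
        events, _t = curve_events
        sub = events.subset_rows(np.arange(100))
        coords, _ = tt.isomap_progression(sub, 100, k_neighbors=99, seed=0)
        D = squareform(pdist(sub.intensities.to_numpy()))
        np.testing.assert_allclose(coords, _classical_mds(D, 2), atol=1e-6)

    def test_row_count_respects_downsampling(self, curve_events):
        events, _t = curve_events
        coords, kept = tt.isomap_progression(events, 40, k_neighbors=10, seed=0)
        assert coords.shape == (7 * 40, 2)
        assert len(kept) == 7 * 40

    def test_disconnected_graph_raises(self):
        X = np.vstack([np.zeros((30, 6)), np.full((30, 6), 100.0)])
        X += np.random.default_rng(0).normal(0, 0.01, X.shape)
        events = tt.EventMatrix(
            pd.DataFrame(X, columns=list(tt.REQUIRED_MARKERS)),
            pd.DataFrame({"true_stage": ["A"] * 30 + ["B"] * 30}),
            transformed=True,
        )
        with pytest.raises(ValueError, match="disconnected"):
            tt.isomap_progression(events, 30, k_neighbors=5, seed=0)


class TestDiffusionMap:
    def test_markov_spectrum(self, curve_events):
        events, _t = curve_events
        _coords, vals, _ = tt.diffusion_progression(events, 50, seed=0)
        assert vals[0] == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.abs(vals) <= 1.0 + 1e-9)

    def test_recovers_planted_pseudotime(self, curve_events):
        events, t = curve_events
        coords, _vals, _ = tt.diffusion_progression(events, 100, seed=0)
        rho = spearmanr(coords[:, 0], t).statistic
        assert abs(rho) >= 0.95

    def test_two_blobs_have_unit_second_eigenvalue(self):
        rng = np.random.default_rng(4)
        X = np.vstack(
            [rng.normal(0, 0.1, (40, 6)), rng.normal(200, 0.1, (40, 6))]
        )
        events = tt.EventMatrix(
            pd.DataFrame(X, columns=list(tt.REQUIRED_MARKERS)),
            pd.DataFrame({"true_stage": ["A"] * 40 + ["B"] * 40}),
            transformed=True,
        )
        _c, vals, _ = tt.diffusion_progression(events, 40, sigma=1.0, seed=0)
        assert vals[1] == pytest.approx(1.0, abs=1e-9)

    def test_nonpositive_sigma_rejected(self, curve_events):
        events, _t = curve_events
        with pytest.raises(ValueError, match="sigma"):
            tt.diffusion_progression(events, 50, sigma=0.0, seed=0)
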