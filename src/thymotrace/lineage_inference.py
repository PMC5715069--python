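"""Developmental-relationship inference between thymocyte populations.

Transcriptional similarity is used as a proxy for developmental
relatedness: two populations with a small whole-transcriptome Euclidean
distance are more likely adjacent in development than two distant ones.
The module builds the population-level models (pairwise distance matrix,
minimum-spanning lineage graph, population PCA) and the single-cell
progression embeddings (Isomap and diffusion map) on per-population
downsampled cytometry events.

The lineage graph formalizes "connect the least different populations" as
the minimum spanning tree of the distance matrix: the unique minimal-weight
connected acyclic realization. Leaves are candidate terminal (thymic
export) populations; nodes of degree >= 3 are branch points. A k-nearest-
neighbor graph is available as an alternative connection rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path
from scipy.spatial.distance import pdist, squareform

from .cytometry_staging import EventMatrix
from .transcriptome_screen import ExpressionMatrix


@dataclass
class DistanceMatrix:
    """Symmetric population x population distance matrix."""

    labels: list[str]
    matrix: np.ndarray
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if (m < 0).any():
            raise ValueError("distances must be non-negative")
        self.matrix = m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


@dataclass
class PopulationGraph:
    """Populations as nodes, transcriptional distances as edge weights."""

    graph: nx.Graph
    method: str
    leaves: list[str] = field(init=False)
    branch_points: list[str] = field(init=False)

    def __post_init__(self) -> None:
        deg = dict(self.graph.degree())
        self.leaves = sorted(n for n, d in deg.items() if d == 1)
        self.branch_points = sorted(n for n, d in deg.items() if d >= 3)
        if not nx.is_connected(self.graph):
            raise ValueError("population graph must be connected")
        if self.method == "mst" and self.graph.number_of_edges() != len(deg) - 1:
            raise ValueError("MST must have exactly n - 1 edges")

    def edge_set(self) -> set[frozenset]:
        return {frozenset((u, v)) for u, v in self.graph.edges()}

    def total_weight(self) -> float:
        return float(sum(d["weight"] for _, _, d in self.graph.edges(data=True)))

    def to_edge_list(self) -> pd.DataFrame:
        rows = [
            {"node1": min(u, v), "node2": max(u, v), "weight": d["weight"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows).sort_values(["node1", "node2"]).reset_index(drop=True)


def distance_matrix(
    expr: ExpressionMatrix,
    subset: str | None = None,
    aggregate: str = "replicate_mean",
    exclude_genes: list[str] | None = None,
    by: str = "stage",
) -> DistanceMatrix:
    """Pairwise Euclidean distances between population mean transcriptomes.

    Biological replicates are averaged per population first (the
    conservative representation of each population); an optional exclusion
    list (e.g. erythrocyte-contamination transcripts) is removed before
    distances are computed over all remaining genes.
    """
    if aggregate != "replicate_mean":
        raise ValueError("only replicate_mean aggregation is supported")
    values = expr.values
    meta = expr.sample_meta
    if subset is not None:
        keep = meta["subset"] == subset
        if not keep.any():
            raise ValueError(f"no samples for subset {subset!r}")
        values = values.loc[:, keep.to_numpy()]
        meta = meta[keep]
    if exclude_genes:
        values = values.drop(index=[g for g in exclude_genes if g in values.index])
    pops = meta[by]
    sizes = pops.value_counts()
    if (sizes == 0).any():
        raise ValueError("population with zero samples")
    means = values.T.groupby(pops.to_numpy()).mean()
    if len(means) < 2:
        raise ValueError("need at least two populations")
    labels = sorted(means.index)
    dm = squareform(pdist(means.loc[labels].to_numpy(), metric="euclidean"))
    return DistanceMatrix(list(labels), dm)


def build_lineage_graph(
    dm: DistanceMatrix,
    method: str = "mst",
    k: int | None = None,
) -> PopulationGraph:
    """Connect populations by MST (default) or symmetrized k-NN.

    MST ties are broken lexicographically by edge labels (Kruskal with a
    stable pre-sort), so the result is deterministic.
    """
    if not np.all(np.isfinite(dm.matrix)):
        raise ValueError("non-finite distances")
    n = len(dm.labels)
    g = nx.Graph()
    g.add_nodes_from(dm.labels)
    if method == "mst":
        edges = sorted(
            (
                (dm.matrix[i, j], dm.labels[i], dm.labels[j])
                for i in range(n)
                for j in range(i + 1, n)
            ),
            key=lambda e: (e[0], e[1], e[2]),
        )
        # Kruskal with union-find over the pre-sorted edge list
        parent = {lbl: lbl for lbl in dm.labels}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for w, u, v in edges:
            ru, rv = find(u), find(v)
            if ru != rv:
                parent[ru] = rv
                g.add_edge(u, v, weight=float(w))
            if g.number_of_edges() == n - 1:
                break
    elif method == "knn":
        if k is None or not 1 <= k < n:
            raise ValueError("knn method requires 1 <= k < n")
        order = np.argsort(dm.matrix, axis=1, kind="stable")
        for i in range(n):
            neighbors = [j for j in order[i] if j != i][:k]
            for j in neighbors:
                g.add_edge(dm.labels[i], dm.labels[j], weight=float(dm.matrix[i, j]))
    else:
        raise ValueError(f"unknown method {method!r}")
    return PopulationGraph(g, method)


def pca_populations(
    expr: ExpressionMatrix, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Column-centered SVD scores of samples in gene space.

    Returns (scores, explained-variance fractions); fractions are
    non-increasing and sum to at most one.
    """
    X = expr.values.to_numpy(dtype=float).T  # samples x genes
    if X.shape[0] < n_components:
        raise ValueError("need at least n_components samples")
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0.0):
        raise ValueError("expression matrix is constant; no variance to decompose")
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / np.sum(s**2)
    scores = pd.DataFrame(
        (U * s)[:, :n_components],
        index=expr.samples,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return scores, var[:n_components]


# ---------------------------------------------------------------------------
# Single-cell progression
# ---------------------------------------------------------------------------

def _downsample_per_population(
    events: EventMatrix,
    labels: pd.Series | None,
    n_per_population: int,
    rng: np.random.Generator,
    markers: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded uniform downsample to n cells per population (all if fewer)."""
    if labels is None:
        if "true_stage" not in events.annotations.columns:
            raise ValueError("no population labels: pass labels= or true_stage")
        labels = events.annotations["true_stage"]
    labels = pd.Series(np.asarray(labels))
    cols = markers or events.marker_names
    X = events.intensities[cols].to_numpy(dtype=float)
    picked: list[np.ndarray] = []
    for pop in sorted(labels.unique()):
        idx = np.flatnonzero(labels.to_numpy() == pop)
        if len(idx) > n_per_population:
            idx = rng.choice(idx, size=n_per_population, replace=False)
        picked.append(np.sort(idx))
    sel = np.concatenate(picked)
    return X[sel], labels.to_numpy()[sel]


def _classical_mds(D: np.ndarray, n_components: int, tol: float = 1e-9) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    B = (B + B.T) / 2
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vals = np.where(vals < tol, 0.0, vals)
    coords = vecs[:, :n_components] * np.sqrt(vals[:n_components])
    # deterministic sign convention: largest-magnitude loading positive
    for c in range(coords.shape[1]):
        col = coords[:, c]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            coords[:, c] = -col
    return coords


def _knn_geodesics(X: np.ndarray, k: int) -> np.ndarray:
    D = squareform(pdist(X))
    n = D.shape[0]
    if not 1 <= k < n:
        raise ValueError("k_neighbors must satisfy 1 <= k < n_cells")
    W = np.full((n, n), np.inf)
    order = np.argsort(D, axis=1, kind="stable")
    rows = np.repeat(np.arange(n), k)
    cols = order[:, 1 : k + 1].ravel()
    W[rows, cols] = D[rows, cols]
    W = np.minimum(W, W.T)  # symmetrize
    W[~np.isfinite(W)] = 0.0
    geo = shortest_path(W, method="D", directed=False, unweighted=False)
    if not np.all(np.isfinite(geo)):
        raise ValueError("k-NN graph is disconnected; increase k_neighbors")
    return geo


def isomap_progression(
    events: EventMatrix,
    n_per_population: int = 100,
    k_neighbors: int = 10,
    n_components: int = 2,
    seed: int = 0,
    labels: pd.Series | None = None,
    markers: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Isomap embedding of per-population downsampled cells.

    Geodesic distances along the symmetrized k-NN graph are embedded by
    classical MDS; with a complete graph (k = n - 1) this reduces exactly
    to MDS of the raw Euclidean distances. Returns (coordinates,
    population label per retained cell).
    """
    rng = np.random.default_rng(seed)
    X, kept = _downsample_per_population(events, labels, n_per_population, rng, markers)
    geo = _knn_geodesics(X, k_neighbors)
    return _classical_mds(geo, n_components), kept


def diffusion_progression(
    events: EventMatrix,
    n_per_population: int = 100,
    sigma: float | None = None,
    n_components: int = 2,
    seed: int = 0,
    labels: pd.Series | None = None,
    markers: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Diffusion-map embedding with density normalization (alpha = 1).

    Gaussian kernel W_ij = exp(-d_ij^2 / (2 sigma^2)) with the median
    pairwise distance as the default bandwidth; the anisotropic (alpha = 1)
    normalization removes sampling-density effects before the Markov
    matrix is formed. Returns (coordinates, eigenvalues incl. the trivial
    lambda_1 = 1, population label per retained cell); coordinate i is the
    (i+1)-th right eigenvector scaled by its eigenvalue.
    """
    rng = np.random.default_rng(seed)
    X, kept = _downsample_per_population(events, labels, n_per_population, rng, markers)
    D = squareform(pdist(X))
    if sigma is None:
        off = D[np.triu_indices_from(D, k=1)]
        sigma = float(np.median(off))
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    W = np.exp(-(D**2) / (2.0 * sigma**2))
    q = W.sum(axis=1)
    W_alpha = W / np.outer(q, q)  # alpha = 1 density normalization
    d = W_alpha.sum(axis=1)
    # symmetric conjugate of the row-stochastic Markov matrix
    S = W_alpha / np.sqrt(np.outer(d, d))
    vals, vecs = np.linalg.eigh((S + S.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    psi = vecs / np.sqrt(d)[:, None]  # right eigenvectors of the Markov matrix
    psi = psi / np.linalg.norm(psi, axis=0)
    coords = psi[:, 1 : n_components + 1] * vals[1 : n_components + 1]
    for c in range(coords.shape[1]):
        col = coords[:, c]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            coords[:, c] = -col
    return coords, vals, kept
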