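"""Unsupervised rediscovery of thymocyte populations.

A batch-trained self-organizing map (SOM) quantizes the six-marker event
cloud onto a small grid; average-linkage hierarchical metaclustering of
the grid codebook, cut at k = 7, merges grid nodes into candidate
populations (the FlowSOM strategy). Cluster mean-expression profiles are
then matched against the A-G stage signatures, and a t-SNE embedding of a
downsampled event set provides the 2-D map used for visual annotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist
from sklearn.manifold import TSNE

from .cytometry_staging import (
    REQUIRED_MARKERS,
    EventMatrix,
    PositivityThresholds,
    StageSignatureTable,
)


@dataclass
class SOMModel:
    """Trained SOM: grid geometry plus codebook vectors per node."""

    grid_rows: int
    grid_cols: int
    codebook: np.ndarray  # (grid_rows * grid_cols) x markers
    marker_names: list[str]
    epochs: int
    seed: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.codebook)):
            raise ValueError("codebook must be finite")
        if self.codebook.shape[0] != self.grid_rows * self.grid_cols:
            raise ValueError("codebook size does not match grid")

    @property
    def n_nodes(self) -> int:
        return self.grid_rows * self.grid_cols


def _grid_coordinates(rows: int, cols: int) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()]).astype(float)


def best_matching_units(model: SOMModel, X: np.ndarray) -> np.ndarray:
    """Index of the nearest codebook node per event; ties -> lowest index."""
    d = cdist(X, model.codebook)
    return np.argmin(d, axis=1)  # argmin returns the first (lowest) index


def quantization_error(model: SOMModel, X: np.ndarray) -> float:
    d = cdist(X, model.codebook)
    return float(d.min(axis=1).mean())


def train_som(
    events: EventMatrix,
    grid_rows: int = 10,
    grid_cols: int = 10,
    epochs: int = 20,
    seed: int = 0,
    markers: list[str] | None = None,
) -> SOMModel:
    """Batch-train a SOM on the six staging markers.

    Initialization samples random events; each epoch reassigns
    best-matching units and replaces every codebook vector by the
    neighborhood-weighted mean of its events, with a Gaussian neighborhood
    whose radius shrinks linearly from half the grid diameter to 0.5.
    Deterministic given the seed.
    """
    if grid_rows < 1 or grid_cols < 1 or epochs < 1:
        raise ValueError("grid dimensions and epochs must be positive")
    markers = markers or [m for m in REQUIRED_MARKERS if m in events.marker_names]
    X = events.intensities[markers].to_numpy(dtype=float)
    n_nodes = grid_rows * grid_cols
    rng = np.random.default_rng(seed)
    init_idx = rng.choice(len(X), size=n_nodes, replace=len(X) < n_nodes)
    codebook = X[init_idx].copy()
    grid = _grid_coordinates(grid_rows, grid_cols)
    grid_d2 = cdist(grid, grid) ** 2
    sigma0 = max(grid_rows, grid_cols) / 2.0
    for epoch in range(epochs):
        frac = epoch / max(1, epochs - 1)
        sigma = sigma0 + frac * (0.5 - sigma0)  # linear shrink to 0.5
        bmu = np.argmin(cdist(X, codebook), axis=1)
        H = np.exp(-grid_d2 / (2.0 * sigma**2))  # node x node neighborhood
        A = H[bmu]  # event x node weights
        weights = A.sum(axis=0)
        numer = A.T @ X
        nonzero = weights > 0
        codebook[nonzero] = numer[nonzero] / weights[nonzero, None]
    return SOMModel(grid_rows, grid_cols, codebook, list(markers), epochs, seed)


def metacluster(model: SOMModel, k: int) -> np.ndarray:
    """Average-linkage hierarchical merge of codebook nodes into k clusters.

    Returns a 0-based cluster label per grid node. Deterministic: the
    dendrogram is cut at exactly k clusters.
    """
    if not 1 <= k <= model.n_nodes:
        raise ValueError(f"k must be in [1, {model.n_nodes}]")
    if k == model.n_nodes:
        return np.arange(model.n_nodes)
    Z = linkage(model.codebook, method="average", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust") - 1
    return labels


def cluster_events(
    model: SOMModel, events: EventMatrix, node_labels: np.ndarray
) -> np.ndarray:
    """Event-level cluster labels inherited through best-matching units."""
    X = events.intensities[model.marker_names].to_numpy(dtype=float)
    return node_labels[best_matching_units(model, X)]


@dataclass
class ClusterProfile:
    """Per-cluster mean marker expression and cluster sizes."""

    means: pd.DataFrame  # clusters x markers
    sizes: pd.Series

    def __post_init__(self) -> None:
        if not self.means.index.equals(self.sizes.index):
            raise ValueError("means and sizes must share an index")


def cluster_profile(
    events: EventMatrix,
    event_cluster_labels: np.ndarray,
    n_clusters: int | None = None,
    markers: list[str] | None = None,
) -> ClusterProfile:
    """Mean transformed intensity of each marker within each cluster.

    Clusters with no events (possible when ``n_clusters`` names them
    explicitly) get a NaN profile row and a warning.
    """
    labels = np.asarray(event_cluster_labels)
    if len(labels) != events.n_events:
        raise ValueError("labels must align with events")
    cols = markers or events.marker_names
    df = events.intensities[cols]
    means = df.groupby(labels).mean()
    sizes = pd.Series(labels).value_counts().sort_index()
    if n_clusters is not None:
        idx = pd.RangeIndex(n_clusters)
        if len(means) < n_clusters:
            warnings.warn("empty cluster(s): profile rows set to NaN")
        means = means.reindex(idx)
        sizes = sizes.reindex(idx, fill_value=0)
    return ClusterProfile(means, sizes)


def match_clusters_to_stages(
    profile: ClusterProfile,
    thresholds: PositivityThresholds,
    signatures: StageSignatureTable | None = None,
) -> dict:
    """Map each cluster to the stage whose signature its mean profile meets.

    The thresholded mean profile is tested against stage signatures in
    gating-order priority; clusters satisfying no signature are labeled
    ``"unassigned"``. Two clusters mapping to the same stage are both kept
    and the collision is warned about.
    """
    signatures = signatures or StageSignatureTable()
    stage_priority = [stage for stage, _ in signatures.gating_order]
    mapping: dict = {}
    for cluster, row in profile.means.iterrows():
        if row.isna().any():
            mapping[cluster] = "unassigned"
            continue
        pattern = {
            m: bool(row[m] > thresholds[m])
            for m in row.index
            if m in thresholds.thresholds
        }
        assigned = "unassigned"
        for stage in stage_priority:
            if signatures.satisfied_by(pattern, stage):
                assigned = stage
                break
        mapping[cluster] = assigned
    seen: dict = {}
    for cluster, stage in mapping.items():
        if stage != "unassigned" and stage in seen:
            warnings.warn(f"clusters {seen[stage]} and {cluster} both map to {stage}")
        seen.setdefault(stage, cluster)
    return mapping


def embed_2d(
    events: EventMatrix,
    n_cells: int = 10_000,
    perplexity: float = 30.0,
    seed: int = 0,
    markers: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """t-SNE map of a uniform seeded downsample of the events.

    Returns (n_cells x 2 coordinates, indices of the sampled events).
    Deterministic given the seed (PCA initialization, fixed random state).
    """
    if n_cells > events.n_events:
        raise ValueError("n_cells exceeds the number of events")
    if perplexity >= n_cells / 3:
        raise ValueError("perplexity must be < n_cells / 3")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(events.n_events, size=n_cells, replace=False))
    cols = markers or [m for m in REQUIRED_MARKERS if m in events.marker_names]
    X = events.intensities[cols].to_numpy(dtype=float)[idx]
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        init="pca",
        random_state=seed,
    )
    coords = tsne.fit_transform(X)
    return coords, idx
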