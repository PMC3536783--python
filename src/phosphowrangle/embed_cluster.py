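"""Embedding of dissimilarity feature vectors and MST cluster extraction.

The filled dissimilarity matrix is used in two distinct ways:

* **distance representation** — classical multidimensional scaling tries
  to preserve the distances themselves;
* **dissimilarity representation** — each gene's row of dissimilarities to
  all genes is treated as its feature vector, and t-SNE (or k-means) runs
  on those vectors with no attempt to preserve the distances.  Sparse data
  resolves far better this way.

Clusters are read off an embedding by single-linkage on the minimum
spanning tree: either cut every MST edge longer than a radius (components
of the radius graph) or cut the k-1 longest MST edges for exactly k groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree
from scipy.spatial.distance import squareform, pdist
from sklearn.decomposition import PCA
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE

from .dissimilarity import DissimilarityMatrix

__all__ = [
    "EmbeddingConfig",
    "Embedding",
    "ClusterSet",
    "classical_mds",
    "tsne_embed",
    "mst_cluster",
    "kmeans_cluster",
    "fuzzy_select",
]

UNASSIGNED = 0  # cluster id for genes outside every cluster


@dataclass(frozen=True)
class EmbeddingConfig:
    """Parameters of an embedding run (recorded as provenance).

    Defaults follow the established t-SNE setup for these data: 2-3 output
    dimensions, perplexity 30, 30 whitened input dimensions, 1000
    iterations run to completion (no early stopping on cost).
    """

    method: str = "tsne"
    k: int = 2
    perplexity: float = 30.0
    initial_dims: int = 30
    max_iter: int = 1000
    min_cost: float = 0.0
    whiten: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in {"mds", "tsne"}:
            raise ValueError("method must be 'mds' or 'tsne'")
        if self.method == "tsne" and self.k not in (2, 3):
            raise ValueError("k must be 2 or 3 for t-SNE maps")


@dataclass(frozen=True)
class Embedding:
    """n x k coordinates with aligned gene labels and provenance."""

    coords: pd.DataFrame = field(repr=False)
    config: EmbeddingConfig | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.coords.to_numpy()).all():
            raise ValueError("embedding coordinates must be finite")

    @property
    def genes(self) -> list[str]:
        return list(self.coords.index)

    def values(self) -> np.ndarray:
        return self.coords.to_numpy()


@dataclass(frozen=True)
class ClusterSet:
    """A gene -> cluster assignment.

    Cluster ids are contiguous integers from 1 (in order of first
    appearance in the gene list); 0 marks unassigned genes.
    """

    assignments: pd.Series = field(repr=False)
    method: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = sorted(set(int(c) for c in self.assignments) - {UNASSIGNED})
        if ids and ids != list(range(1, len(ids) + 1)):
            raise ValueError("cluster ids must be contiguous from 1")
        object.__setattr__(self, "assignments", self.assignments.astype(int))

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignments) - {UNASSIGNED})

    @property
    def genes(self) -> list[str]:
        return list(self.assignments.index)

    def members(self, cluster_id: int) -> list[str]:
        mask = self.assignments == cluster_id
        return list(self.assignments.index[mask])

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for cid in sorted(set(self.assignments) - {UNASSIGNED}):
            out[cid] = self.members(cid)
        return out

    def labels(self) -> np.ndarray:
        return self.assignments.to_numpy()


def _relabel_first_appearance(raw: np.ndarray, index: pd.Index) -> pd.Series:
    """Map arbitrary component labels to contiguous ids by first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty(len(raw), dtype=int)
    nxt = 1
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = nxt
            nxt += 1
        out[i] = mapping[lab]
    return pd.Series(out, index=index)


# ---------------------------------------------------------------------------
# embeddings


def classical_mds(D: DissimilarityMatrix | pd.DataFrame, k: int = 2) -> Embedding:
    """Classical (Torgerson) multidimensional scaling.

    Double-centers the squared distance matrix, takes the top-k
    eigenvectors scaled by the square roots of their eigenvalues.
    Deterministic up to sign/rotation.  If fewer than k eigenvalues are
    positive the remaining coordinates are zero-padded with a warning.
    """
    if isinstance(D, DissimilarityMatrix):
        if not D.filled:
            raise ValueError("fill the dissimilarity matrix before embedding")
        df = D.data
    else:
        df = D
    labels = df.index
    d = df.to_numpy(dtype=float)
    n = d.shape[0]
    if not 1 <= k <= n:
        raise ValueError("k must be between 1 and the number of points")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d * d) @ J
    B = (B + B.T) / 2.0
    vals, vecs = eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    n_pos = int((vals > 1e-10).sum())
    if n_pos < k:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; padding {k - n_pos} dimension(s) with zeros"
        )
    coords = np.zeros((n, k))
    kk = min(k, n_pos)
    coords[:, :kk] = vecs[:, :kk] * np.sqrt(vals[:kk])
    cfg = EmbeddingConfig(method="mds", k=k if k in (2, 3) else 2)
    out = pd.DataFrame(coords, index=labels, columns=[f"dim{i+1}" for i in range(k)])
    return Embedding(out, config=cfg if k in (2, 3) else None)


def whiten_features(X: np.ndarray, initial_dims: int, seed: int = 0) -> np.ndarray:
    """Center + PCA-project to ``initial_dims`` with unit component variance."""
    n_comp = min(initial_dims, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_comp, whiten=True, random_state=seed)
    return pca.fit_transform(X)


def tsne_embed(
    features: DissimilarityMatrix | pd.DataFrame,
    config: EmbeddingConfig | None = None,
) -> Embedding:
    """t-SNE on dissimilarity rows used as feature vectors.

    The filled dissimilarity matrix is treated row-wise as a feature
    matrix (no attempt to preserve the distances themselves).  With
    ``whiten`` the features are centered and PCA-projected to
    ``initial_dims`` components with variance normalisation first.
    Stochastic but reproducible for a fixed seed.
    """
    config = config or EmbeddingConfig()
    if isinstance(features, DissimilarityMatrix):
        if not features.filled:
            raise ValueError("fill before embedding: missing entries present")
        df = features.data
    else:
        if np.isnan(features.to_numpy()).any():
            raise ValueError("fill before embedding: missing entries present")
        df = features
    n = df.shape[0]
    if config.perplexity >= n / 3:
        raise ValueError(f"perplexity {config.perplexity} too large for {n} points")
    X = df.to_numpy(dtype=float)
    if config.whiten:
        X = whiten_features(X, config.initial_dims, seed=config.seed)
    tsne = TSNE(
        n_components=config.k,
        perplexity=config.perplexity,
        max_iter=config.max_iter,
        min_grad_norm=config.min_cost,  # 0 -> run to max_iter, no early stop
        init="random",
        random_state=config.seed,
    )
    coords = tsne.fit_transform(X)
    out = pd.DataFrame(
        coords, index=df.index, columns=[f"dim{i+1}" for i in range(config.k)]
    )
    return Embedding(out, config=config)


# ---------------------------------------------------------------------------
# cluster extraction


def _distance_matrix(points) -> tuple[np.ndarray, pd.Index]:
    """Accept an Embedding, coordinate frame, or explicit distance matrix."""
    if isinstance(points, Embedding):
        d = squareform(pdist(points.values()))
        return d, points.coords.index
    if isinstance(points, DissimilarityMatrix):
        if not points.filled:
            raise ValueError("distance matrix has missing entries; fill first")
        return points.values(), points.data.index
    df = pd.DataFrame(points)
    arr = df.to_numpy(dtype=float)
    if arr.shape[0] == arr.shape[1] and np.allclose(arr, arr.T) and np.allclose(np.diag(arr), 0):
        return arr, df.index
    return squareform(pdist(arr)), df.index


def _mst_edges(d: np.ndarray) -> list[tuple[float, int, int]]:
    # shift all off-diagonal weights by +1 so zero-length edges (identical
    # points) are not dropped by the sparse representation; a constant shift
    # changes neither the MST nor the edge-length ordering
    n = d.shape[0]
    dd = d + 1.0 - np.eye(n)
    mst = minimum_spanning_tree(csr_matrix(dd)).tocoo()
    return [
        (float(w) - 1.0, int(i), int(j))
        for w, i, j in zip(mst.data, mst.row, mst.col)
    ]


def mst_cluster(
    points,
    mode: str = "radius",
    *,
    radius: float = 3.5,
    target_k: int | None = None,
    method: str = "mst",
) -> ClusterSet:
    """Single-linkage cluster extraction on the minimum spanning tree.

    ``radius`` mode: connected components of the graph joining all point
    pairs at distance <= radius (equivalently, cut every MST edge longer
    than the radius).  The default radius 3.5 is the similarity scale of a
    t-SNE map; for other embeddings pass an explicit radius or use
    ``target_k``.

    ``target_k`` mode: cut the ``target_k - 1`` longest MST edges, giving
    exactly ``target_k`` components — identical to cutting the
    single-linkage dendrogram.  Equal-length edges are cut in a stable
    order (descending weight, then lexicographic endpoint labels).
    """
    d, index = _distance_matrix(points)
    n = d.shape[0]
    if mode == "radius":
        adj = csr_matrix((d <= radius) & ~np.eye(n, dtype=bool))
        _, labels = connected_components(adj, directed=False)
    elif mode == "target_k":
        if target_k is None:
            raise ValueError("target_k mode requires target_k")
        if not 1 <= target_k <= n:
            raise ValueError(f"target_k must be in [1, {n}]")
        edges = _mst_edges(d)
        lab = [str(g) for g in index]
        edges.sort(
            key=lambda e: (-e[0], *sorted((lab[e[1]], lab[e[2]])))
        )
        keep = edges[target_k - 1:]
        rows = [i for _, i, j in keep]
        cols = [j for _, i, j in keep]
        adj = csr_matrix((np.ones(len(keep)), (rows, cols)), shape=(n, n))
        _, labels = connected_components(adj, directed=False)
    else:
        raise ValueError("mode must be 'radius' or 'target_k'")
    assign = _relabel_first_appearance(labels, index)
    params = {"mode": mode, "radius": radius if mode == "radius" else None,
              "target_k": target_k}
    return ClusterSet(assign, method=method, params=params)


def kmeans_cluster(
    features: DissimilarityMatrix | pd.DataFrame,
    k: int = 100,
    *,
    seed: int = 0,
    n_restarts: int = 10,
) -> ClusterSet:
    """k-means on dissimilarity rows as feature vectors (comparison method)."""
    if isinstance(features, DissimilarityMatrix):
        if not features.filled:
            raise ValueError("fill before clustering")
        df = features.data
    else:
        df = features
    n = df.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of genes ({n})")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(df.to_numpy(dtype=float))
    assign = _relabel_first_appearance(raw, df.index)
    return ClusterSet(assign, method="kmeans", params={"k": k, "seed": seed})


def fuzzy_select(scores: pd.DataFrame, n_sd: float = 2.5):
    """Select cluster members from fuzzy membership scores.

    A gene belongs to cluster *c* iff its score exceeds that cluster's
    mean score plus ``n_sd`` sample standard deviations (over genes).
    Genes may match zero or several clusters.  A degenerate cluster with
    zero score spread selects nobody (warned).

    Returns
    -------
    membership : DataFrame of bool, genes x clusters
    counts : Series, members per cluster
    """
    scores = pd.DataFrame(scores).astype(float)
    membership = pd.DataFrame(False, index=scores.index, columns=scores.columns)
    for col in scores.columns:
        s = scores[col]
        sd = float(s.std(ddof=1)) if len(s) > 1 else 0.0
        if sd == 0.0:
            warnings.warn(f"cluster {col!r}: zero score spread, no members selected")
            continue
        membership[col] = s > s.mean() + n_sd * sd
    counts = membership.sum(axis=0)
    return membership, counts
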