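"""Engineered feature profiles for one side of the bipartite network.

Two profiles are built per side (miRNAs from SM and the association rows,
diseases from SD and the association columns):

* the statistical profile (18 features): the entity's association count and
  summary statistics of its similarity row — mean, s.d., min, quartiles,
  median, max — plus a 10-bin histogram of the row expressed as proportions;
* the graph-theoretical profile (51 features): degree in the thresholded
  unweighted similarity graph, the k largest similarities (k = 10,
  zero-padded), plain and similarity-weighted means of the 18 statistical
  features over the k nearest neighbours, and betweenness / closeness /
  eigenvector centralities and PageRank in the unweighted graph.

After assembly every feature is min-max scaled to [0,1] across entities so
count-scale and proportion-scale features are commensurate in the model's
subspace regression; constant features map to 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import networkx as nx
import numpy as np

from .core_io import AssociationMatrix, SimilarityMatrix

__all__ = [
    "FeatureMatrix",
    "statistical_profile",
    "unweighted_graph",
    "graph_theoretical_profile",
    "minmax_scale_features",
    "extract_features",
    "STAT_FEATURE_NAMES",
]

N_BINS = 10
K_NEIGHBORS = 10
PAGERANK_DAMPING = 0.85

STAT_FEATURE_NAMES: tuple[str, ...] = (
    "n.obs", "ave.sim", "s.d.sim", "min.sim",
    "first.q.sim", "median.sim", "third.q.sim", "max.sim",
    *[f"hist.sim.{b + 1}" for b in range(N_BINS)],
)


@dataclass
class FeatureMatrix:
    """d_p x n real matrix of features (rows) by entities (columns)."""

    values: np.ndarray
    feature_names: tuple[str, ...]
    side: Literal["mirna", "disease"]
    profile_id: int  # 1 statistical, 2 graph-theoretical

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.feature_names):
            raise ValueError("feature count does not match feature_names")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_entities(self) -> int:
        return self.values.shape[1]


def _similarity_rows(sim: SimilarityMatrix) -> np.ndarray:
    if not sim.fully_known:
        raise ValueError("feature extraction requires a fully defined similarity")
    return sim.values


def statistical_profile(
    sim: SimilarityMatrix,
    assoc: AssociationMatrix,
    side: Literal["mirna", "disease"],
    bins: int = N_BINS,
) -> FeatureMatrix:
    """18 summary-statistic features per entity (unscaled).

    Similarity statistics run over the entity's row with the diagonal
    excluded (self-similarity of 1 is uninformative). The histogram uses
    ``bins`` equal bins on [0,1], right-open except the last, and reports
    proportions (each entity's histogram block sums to 1).
    """
    S = _similarity_rows(sim)
    n = S.shape[0]
    if n < 2:
        raise ValueError("need at least 2 entities for similarity statistics")
    if side == "mirna":
        if sim.index.names != assoc.mirnas.names:
            raise ValueError("similarity index does not match association miRNAs")
        n_obs = assoc.values.sum(axis=1)
    elif side == "disease":
        if sim.index.names != assoc.diseases.names:
            raise ValueError("similarity index does not match association diseases")
        n_obs = assoc.values.sum(axis=0)
    else:
        raise ValueError(f"unknown side {side!r}")

    off = S[~np.eye(n, dtype=bool)].reshape(n, n - 1)
    q1, med, q3 = np.quantile(off, [0.25, 0.5, 0.75], axis=1)
    # right-open bins except the last; interior edges as exact decimal
    # doubles so a value like 0.3 lands in [0.3, 0.4)
    edges = np.arange(1, bins) / bins
    bin_of = np.digitize(off, edges, right=False)
    hist = np.stack(
        [(bin_of == b).sum(axis=1) / (n - 1) for b in range(bins)]
    )
    values = np.vstack([
        n_obs,
        off.mean(axis=1),
        off.std(axis=1, ddof=0),
        off.min(axis=1),
        q1, med, q3,
        off.max(axis=1),
        hist,
    ])
    names = STAT_FEATURE_NAMES if bins == N_BINS else (
        *STAT_FEATURE_NAMES[:8], *[f"hist.sim.{b + 1}" for b in range(bins)]
    )
    return FeatureMatrix(values, tuple(names), side, profile_id=1)


def unweighted_graph(sim: SimilarityMatrix) -> np.ndarray:
    """Threshold the similarity into a binary graph.

    An undirected edge joins i and j (i != j) when sim(i,j) strictly exceeds
    the mean of all n^2 entries of the similarity matrix.
    """
    S = _similarity_rows(sim)
    thresh = S.mean()
    adj = (S > thresh).astype(float)
    np.fill_diagonal(adj, 0.0)
    return np.maximum(adj, adj.T)


def _knn_by_similarity(S: np.ndarray, k: int) -> list[np.ndarray]:
    """Indices of each entity's k most similar other entities, descending,
    ties broken by ascending index."""
    n = S.shape[0]
    out = []
    for i in range(n):
        others = np.array([j for j in range(n) if j != i])
        order = others[np.lexsort((others, -S[i, others]))]
        out.append(order[:k])
    return out


def _eigenvector_centrality(adj: np.ndarray) -> np.ndarray:
    """Perron eigenvector of the full adjacency; zero where it vanishes."""
    if not adj.any():
        return np.zeros(adj.shape[0])
    w, v = np.linalg.eigh(adj)
    vec = v[:, np.argmax(w)]
    if vec.sum() < 0:
        vec = -vec
    vec = np.clip(vec, 0.0, None)
    norm = np.linalg.norm(vec)
    return vec / norm if norm > 0 else vec


def graph_theoretical_profile(
    sim: SimilarityMatrix,
    stat: FeatureMatrix,
    k: int = K_NEIGHBORS,
) -> FeatureMatrix:
    """51 graph features per entity (unscaled), built on the thresholded graph.

    Neighbour features (k.sim, k.ave.feat, k.w.ave.feat) use the k nearest
    neighbours *by similarity value*; centralities use the unweighted graph.
    Betweenness is the raw shortest-path pair count; closeness is classical,
    computed within each connected component.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    S = _similarity_rows(sim)
    n = S.shape[0]
    if stat.n_entities != n:
        raise ValueError("statistical profile does not match similarity entities")
    adj = unweighted_graph(sim)
    G = nx.from_numpy_array(adj)

    num_nb = adj.sum(axis=1)
    neighbors = _knn_by_similarity(S, k)
    k_sim = np.zeros((k, n))
    k_ave = np.zeros((18, n))
    k_wave = np.zeros((18, n))
    n_stat = stat.values.shape[0]
    if n_stat != 18:
        k_ave = np.zeros((n_stat, n))
        k_wave = np.zeros((n_stat, n))
    for i in range(n):
        nb = neighbors[i]
        sims = S[i, nb]
        k_sim[: len(nb), i] = sims
        if len(nb):
            k_ave[:, i] = stat.values[:, nb].mean(axis=1)
            total = sims.sum()
            w = sims / total if total > 0 else np.full(len(nb), 1.0 / len(nb))
            k_wave[:, i] = stat.values[:, nb] @ w

    bt_map = nx.betweenness_centrality(G, normalized=False)
    cl_map = nx.closeness_centrality(G, wf_improved=False)
    pr_map = nx.pagerank(G, alpha=PAGERANK_DAMPING)
    bt = np.array([bt_map[i] for i in range(n)])
    cl = np.array([cl_map[i] for i in range(n)])
    ev = _eigenvector_centrality(adj)
    pr = np.array([pr_map[i] for i in range(n)])

    values = np.vstack([num_nb, k_sim, k_ave, k_wave, bt, cl, ev, pr])
    names = (
        "num.nb",
        *[f"k.sim.{j + 1}" for j in range(k)],
        *[f"k.ave.{f}" for f in stat.feature_names],
        *[f"k.w.ave.{f}" for f in stat.feature_names],
        "bt", "cl", "ev", "pr",
    )
    return FeatureMatrix(values, names, stat.side, profile_id=2)


def minmax_scale_features(fm: FeatureMatrix) -> FeatureMatrix:
    """Scale each feature row to [0,1] across entities; constant rows -> 0."""
    v = fm.values
    lo = v.min(axis=1, keepdims=True)
    rng = v.max(axis=1, keepdims=True) - lo
    scaled = np.where(rng > 0, (v - lo) / np.where(rng > 0, rng, 1.0), 0.0)
    return FeatureMatrix(scaled, fm.feature_names, fm.side, fm.profile_id)


def extract_features(
    sim: SimilarityMatrix,
    assoc: AssociationMatrix,
    side: Literal["mirna", "disease"],
    k: int = K_NEIGHBORS,
    bins: int = N_BINS,
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Both scaled profiles (X1 statistical, X2 graph-theoretical) for a side."""
    stat = statistical_profile(sim, assoc, side, bins=bins)
    graph = graph_theoretical_profile(sim, stat, k=k)
    return minmax_scale_features(stat), minmax_scale_features(graph)
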