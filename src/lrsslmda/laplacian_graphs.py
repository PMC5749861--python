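"""k-nearest-neighbour graphs and their (combinatorial) graph Laplacians.

Two kinds of graphs feed the model's smoothness terms:

* a profile graph per feature matrix, where closeness between entities is
  the cosine similarity of their feature vectors;
* an association graph, where closeness between two entities (restricted to
  those with at least one known association) is the maximum integrated
  similarity between their associated partner groups.

The directed top-k relation is symmetrized by logical OR so that the
Laplacian L = D - S is symmetric positive semidefinite; ties in the
neighbour ranking break by ascending entity index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .core_io import AssociationMatrix, SimilarityMatrix
from .feature_extraction import FeatureMatrix

__all__ = ["GraphLaplacian", "knn_profile_graph", "knn_association_graph"]


@dataclass
class GraphLaplacian:
    S: np.ndarray  # binary symmetric adjacency
    D: np.ndarray  # diagonal degree matrix
    L: np.ndarray  # D - S

    @classmethod
    def from_adjacency(cls, S: np.ndarray) -> "GraphLaplacian":
        S = np.asarray(S, dtype=float)
        if not np.array_equal(S, S.T):
            raise ValueError("adjacency must be symmetric")
        D = np.diag(S.sum(axis=1))
        return cls(S=S, D=D, L=D - S)


def _topk_adjacency(closeness: np.ndarray, k: int, active: np.ndarray) -> np.ndarray:
    """OR-symmetrized top-k adjacency from a closeness matrix.

    Only ``active`` entities participate; inactive rows/columns stay zero.
    Ties break by ascending index (stable lexsort on (-closeness, index)).
    """
    n = closeness.shape[0]
    S = np.zeros((n, n))
    idx = np.flatnonzero(active)
    for i in idx:
        others = idx[idx != i]
        if others.size == 0:
            continue
        order = others[np.lexsort((others, -closeness[i, others]))]
        for j in order[:k]:
            S[i, j] = 1.0
            S[j, i] = 1.0
    return S


def knn_profile_graph(X: FeatureMatrix, k: int = 10) -> GraphLaplacian:
    """kNN graph over entities by cosine similarity of feature columns."""
    V = X.values
    n = V.shape[1]
    if k >= n:
        k = n - 1
    if k < 1:
        raise ValueError("k must leave at least one neighbour")
    norms = np.linalg.norm(V, axis=0)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValueError(
            f"entity {zero[0]} has an all-zero feature vector; cosine undefined"
        )
    U = V / norms
    cos = U.T @ U
    S = _topk_adjacency(cos, k, np.ones(n, dtype=bool))
    return GraphLaplacian.from_adjacency(S)


def knn_association_graph(
    assoc: AssociationMatrix,
    other_side_sim: SimilarityMatrix,
    side: Literal["mirna", "disease"],
    k: int = 10,
) -> GraphLaplacian:
    """kNN graph over association profiles.

    closeness(i, j) = max over (a in partners(i), b in partners(j)) of
    other_side_sim(a, b). Entities with no known association are isolated
    (zero row and column in S).
    """
    if side == "mirna":
        Y = assoc.values
        if other_side_sim.index.names != assoc.diseases.names:
            raise ValueError("similarity index does not match association diseases")
    elif side == "disease":
        Y = assoc.values.T
        if other_side_sim.index.names != assoc.mirnas.names:
            raise ValueError("similarity index does not match association miRNAs")
    else:
        raise ValueError(f"unknown side {side!r}")
    n = Y.shape[0]
    active = Y.sum(axis=1) > 0
    closeness = np.full((n, n), -np.inf)
    sim = other_side_sim.values
    partner_lists = [np.flatnonzero(Y[i]) for i in range(n)]
    act = np.flatnonzero(active)
    for ai, i in enumerate(act):
        pi = partner_lists[i]
        for j in act[ai:]:
            c = sim[np.ix_(pi, partner_lists[j])].max()
            closeness[i, j] = closeness[j, i] = c
    S = _topk_adjacency(closeness, k, active)
    return GraphLaplacian.from_adjacency(S)
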