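"""Disease semantic similarity, Gaussian interaction-profile kernels, and
the integrated miRNA/disease similarity matrices SM and SD.

Semantic similarity scores two diseases by the overlap of their ancestor
DAGs: each term contributes ``-log(membership / n_diseases)`` (a rarer term
is more informative), a disease's semantic value DV is the sum over its
DAG, and the pairwise score is the shared contribution mass normalized by
the two DVs. The Gaussian interaction-profile kernel scores two entities by
the distance between their binary association profiles, with the bandwidth
scaled so that the mean squared profile norm maps to gamma_prime.
Integration takes the curated similarity where the source defines a pair
and falls back to the kernel elsewhere.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .core_io import DiseaseDAG, NameIndex, SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "KernelParams",
    "dag_membership",
    "semantic_value",
    "semantic_similarity",
    "gaussian_profile_kernel",
    "integrate_similarity",
]


@dataclass(frozen=True)
class KernelParams:
    """Bandwidth of the interaction-profile kernel.

    ``gamma`` is ``gamma_prime`` divided by the mean squared profile norm,
    so gamma_prime = 1 normalizes the kernel to the dataset's density.
    """

    gamma_prime: float
    gamma: float

    def __post_init__(self) -> None:
        if not (self.gamma_prime > 0 and math.isfinite(self.gamma) and self.gamma > 0):
            raise ValueError("kernel bandwidth must be positive and finite")


def dag_membership(dags: list[DiseaseDAG]) -> dict[str, int]:
    """Number of supplied DAGs containing each term."""
    counts: dict[str, int] = {}
    for dag in dags:
        for term in dag.nodes:
            counts[term] = counts.get(term, 0) + 1
    return counts


def semantic_value(
    dag: DiseaseDAG, n_diseases_total: int, membership: dict[str, int]
) -> tuple[dict[str, float], float]:
    """Per-term contributions and the semantic value DV of one disease.

    contribution(t) = -ln(membership(t) / n_total); DV = sum over the DAG.
    A term present in every DAG contributes 0.
    """
    if n_diseases_total < 1:
        raise ValueError("need at least one disease")
    contributions: dict[str, float] = {}
    for term in dag.nodes:
        count = membership.get(term)
        if count is None or count < 1:
            raise ValueError(f"term {term!r} missing from DAG membership counts")
        if count > n_diseases_total:
            raise ValueError(
                f"term {term!r} appears in {count} DAGs but only "
                f"{n_diseases_total} diseases exist"
            )
        contributions[term] = -math.log(count / n_diseases_total)
    return contributions, sum(contributions.values())


def semantic_similarity(dags: list[DiseaseDAG]) -> SimilarityMatrix:
    """Pairwise semantic similarity over a list of disease DAGs.

    SS(i,j) = sum over shared terms of (contrib_i + contrib_j) / (DV_i + DV_j).
    The score is invariant to the logarithm base. A disease whose every term
    is ubiquitous has DV = 0; its row/column is flagged undefined.
    """
    if not dags:
        raise ValueError("need at least one DAG")
    names = [dag.disease for dag in dags]
    index = NameIndex.from_names(names)
    n = len(dags)
    membership = dag_membership(dags)
    contribs: list[dict[str, float]] = []
    dvs: list[float] = []
    for dag in dags:
        c, dv = semantic_value(dag, n, membership)
        contribs.append(c)
        dvs.append(dv)
    values = np.zeros((n, n))
    mask = np.ones((n, n), dtype=bool)
    for i in range(n):
        if dvs[i] == 0.0:
            logger.warning(
                "disease %r has semantic value 0 (all terms ubiquitous); "
                "its semantic similarities are undefined", names[i],
            )
            mask[i, :] = False
            mask[:, i] = False
    for i in range(n):
        if dvs[i] == 0.0:
            continue
        for j in range(i, n):
            if dvs[j] == 0.0:
                continue
            shared = dags[i].nodes & dags[j].nodes
            num = sum(contribs[i][t] + contribs[j][t] for t in shared)
            values[i, j] = values[j, i] = num / (dvs[i] + dvs[j])
    return SimilarityMatrix(values, index, mask)


def gaussian_profile_kernel(
    profiles: np.ndarray,
    gamma_prime: float = 1.0,
    index: NameIndex | None = None,
) -> tuple[SimilarityMatrix, KernelParams]:
    """Gaussian kernel on binary interaction profiles (rows of ``profiles``).

    K(i,j) = exp(-gamma * ||IP_i - IP_j||^2) with
    gamma = gamma_prime / mean_i ||IP_i||^2. The miRNA kernel KM uses the
    rows of the association matrix as profiles; the disease kernel KD uses
    its columns (transposed in by the caller).
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2:
        raise ValueError("profiles must be a 2-D matrix")
    n = profiles.shape[0]
    mean_sq_norm = float((profiles ** 2).sum() / n)
    if mean_sq_norm == 0.0:
        raise ValueError("kernel bandwidth undefined: all interaction profiles are zero")
    params = KernelParams(gamma_prime=gamma_prime, gamma=gamma_prime / mean_sq_norm)
    # ||a-b||^2 = ||a||^2 + ||b||^2 - 2 a.b
    sq = (profiles ** 2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * profiles @ profiles.T
    np.maximum(d2, 0.0, out=d2)
    values = np.exp(-params.gamma * d2)
    np.fill_diagonal(values, 1.0)
    values = (values + values.T) / 2.0
    if index is None:
        index = NameIndex.from_names(f"e{i}" for i in range(n))
    return SimilarityMatrix.fully_defined(values, index), params


def integrate_similarity(
    primary: SimilarityMatrix, fallback: SimilarityMatrix
) -> SimilarityMatrix:
    """Casewise integration: the curated score where defined, else the kernel.

    SM(i,j) = FS(i,j) if (i,j) has a functional-similarity entry else KM(i,j);
    SD is formed the same way from SS and KD.
    """
    if primary.index.names != fallback.index.names:
        raise ValueError("primary and fallback similarity indices differ")
    if not fallback.fully_known:
        raise ValueError("fallback similarity must be fully defined")
    values = np.where(primary.known_mask, primary.values, fallback.values)
    return SimilarityMatrix.fully_defined(values, primary.index)
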