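"""End-to-end training pipeline: similarities -> features -> graphs -> fit
-> scores, for a given (possibly masked) association matrix.

Everything that depends on the association matrix — the interaction-profile
kernels, the integrated similarities, both feature profiles, all kNN graphs
— is recomputed from the supplied matrix, so cross-validation rounds that
mask entries never leak the held-out labels. The external similarity
sources (functional similarity, disease DAGs) do not depend on the
associations and are reused across rounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_io import AssociationMatrix, DiseaseDAG, SimilarityMatrix
from .feature_extraction import extract_features
from .laplacian_graphs import knn_association_graph, knn_profile_graph
from .predictor import ScoreMatrix, final_scores, perspective_scores
from .similarity import gaussian_profile_kernel, integrate_similarity, semantic_similarity
from .ssl_optimizer import Hyperparams, ModelState, fit

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "Dataset", "align_similarity",
           "build_integrated_similarities", "train_and_score"]


def align_similarity(sim: SimilarityMatrix, target) -> SimilarityMatrix:
    """Reindex a similarity matrix onto a target NameIndex by exact names.

    Entities missing from the source get fully undefined rows (the kernel
    fallback covers them); source names absent from the target are dropped.
    Both directions are logged so name-matching losses are visible.
    """
    if sim.index.names == tuple(target.names):
        return sim
    n = len(target)
    values = np.zeros((n, n))
    mask = np.zeros((n, n), dtype=bool)
    present = [i for i, name in enumerate(target.names) if name in sim.index]
    src = [sim.index[target.names[i]] for i in present]
    values[np.ix_(present, present)] = sim.values[np.ix_(src, src)]
    mask[np.ix_(present, present)] = sim.known_mask[np.ix_(src, src)]
    unmatched_target = len(target) - len(present)
    unmatched_source = len(sim.index) - len(present)
    if unmatched_target or unmatched_source:
        logger.info(
            "similarity alignment: %d target entities lack a source entry, "
            "%d source entries unused", unmatched_target, unmatched_source,
        )
    return SimilarityMatrix(values, target, mask)


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of the full pipeline in one place."""

    mu: float = 1.0
    lam: float = 1.0
    gamma_exp: float = 2.0
    gamma_prime: float = 1.0
    k_graph: int = 10
    k_features: int = 10
    bins: int = 10
    max_iter: int = 1000
    tol: float = 1e-6
    seed: int = 0
    renormalize_alpha: bool = False

    def hyperparams(self) -> Hyperparams:
        return Hyperparams(
            mu=self.mu, lam=self.lam, gamma_exp=self.gamma_exp,
            max_iter=self.max_iter, tol=self.tol, seed=self.seed,
        )


@dataclass
class Dataset:
    """Model inputs: associations plus optional external similarity sources."""

    assoc: AssociationMatrix
    fs: SimilarityMatrix | None = None  # miRNA functional similarity (partial)
    dags: list[DiseaseDAG] | None = None  # disease ancestor graphs

    def semantic(self) -> SimilarityMatrix | None:
        """Disease semantic similarity aligned to the association's disease
        index; diseases without a DAG get undefined rows (kernel fallback)."""
        if not self.dags:
            return None
        return align_similarity(semantic_similarity(self.dags), self.assoc.diseases)


def build_integrated_similarities(
    dataset: Dataset,
    assoc_values: np.ndarray | None = None,
    gamma_prime: float = 1.0,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Integrated miRNA (SM) and disease (SD) similarities.

    Kernels are computed from ``assoc_values`` (defaults to the dataset's
    matrix; cross-validation passes the masked training matrix). miRNA
    interaction profiles are the association rows, disease profiles the
    columns.
    """
    assoc = dataset.assoc
    A = dataset.assoc.values if assoc_values is None else assoc_values
    km, _ = gaussian_profile_kernel(A, gamma_prime, index=assoc.mirnas)
    kd, _ = gaussian_profile_kernel(A.T, gamma_prime, index=assoc.diseases)
    if dataset.fs is not None:
        fs = align_similarity(dataset.fs, assoc.mirnas)
        sm = integrate_similarity(fs, km)
    else:
        sm = km
    ss = dataset.semantic()
    sd = integrate_similarity(ss, kd) if ss is not None else kd
    return sm, sd


@dataclass
class TrainedModel:
    scores: ScoreMatrix
    mirna_scores: ScoreMatrix
    disease_scores: ScoreMatrix
    mirna_state: ModelState
    disease_state: ModelState
    sm: SimilarityMatrix = field(repr=False, default=None)
    sd: SimilarityMatrix = field(repr=False, default=None)


def train_and_score(
    dataset: Dataset,
    config: PipelineConfig | None = None,
    assoc_values: np.ndarray | None = None,
    profiles: tuple[int, ...] = (1, 2),
) -> TrainedModel:
    """Fit both perspectives on (masked) associations and score all pairs.

    ``profiles`` selects which feature profiles enter the model (both by
    default; a single profile reproduces the profile-ablation setting).
    """
    config = config or PipelineConfig()
    assoc = dataset.assoc
    A = assoc.values if assoc_values is None else np.asarray(assoc_values, dtype=float)
    train = AssociationMatrix(A, assoc.mirnas, assoc.diseases)
    sm, sd = build_integrated_similarities(dataset, A, config.gamma_prime)

    states: dict[str, ModelState] = {}
    persp: dict[str, ScoreMatrix] = {}
    for side, sim, other_sim, Y in (
        ("mirna", sm, sd, train.values),
        ("disease", sd, sm, train.values.T),
    ):
        x1, x2 = extract_features(sim, train, side, k=config.k_features, bins=config.bins)
        X = [x for x, pid in ((x1, 1), (x2, 2)) if pid in profiles]
        if not X:
            raise ValueError("profiles must select at least one of (1, 2)")
        L_p = [knn_profile_graph(x, k=config.k_graph) for x in X]
        L_MDA = knn_association_graph(train, other_sim, side, k=config.k_graph)
        state = fit(X, Y, L_p, L_MDA, config.hyperparams())
        states[side] = state
        persp[side] = perspective_scores(
            state, X, side, assoc.mirnas, assoc.diseases,
            renormalize_alpha=config.renormalize_alpha,
        )
    return TrainedModel(
        scores=final_scores(persp["mirna"], persp["disease"], train),
        mirna_scores=persp["mirna"],
        disease_scores=persp["disease"],
        mirna_state=states["mirna"],
        disease_state=states["disease"],
        sm=sm,
        sd=sd,
    )
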