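"""Turn fitted per-side models into association scores and ranked candidates.

Each side's prediction is the alpha-weighted sum of its row-normalized
subspace reconstructions X_p^T G_p (Laplacian weights alpha_MDA excluded,
so a perspective's rows carry total weight alpha_1 + alpha_2 < 1; no
renormalization by default, faithful to the published combination rule).
The final score for a pair follows three scenarios: a miRNA with no known
associated disease is scored from the miRNA perspective alone, a disease
with no known associated miRNA from the disease perspective alone, and
every other pair by the average of the two perspectives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .core_io import AssociationMatrix, NameIndex
from .feature_extraction import FeatureMatrix
from .ssl_optimizer import ModelState

logger = logging.getLogger(__name__)

__all__ = ["ScoreMatrix", "perspective_scores", "final_scores", "rank_candidates"]


@dataclass
class ScoreMatrix:
    """Real nm x nd predicted association scores, miRNA rows x disease cols."""

    values: np.ndarray
    mirnas: NameIndex
    diseases: NameIndex
    provenance: Literal["mirna-perspective", "disease-perspective", "final"]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.mirnas), len(self.diseases)):
            raise ValueError("score shape does not match name indices")
        if not np.isfinite(self.values).all():
            raise ValueError("scores contain non-finite values")


def _rownormalize(M: np.ndarray) -> np.ndarray:
    sums = M.sum(axis=1, keepdims=True)
    out = np.divide(M, sums, out=np.zeros_like(M), where=sums != 0)
    return out


def perspective_scores(
    state: ModelState,
    X: list[FeatureMatrix],
    side: Literal["mirna", "disease"],
    mirnas: NameIndex,
    diseases: NameIndex,
    renormalize_alpha: bool = False,
) -> ScoreMatrix:
    """sum_p alpha_p * rownormalize(X_p^T G_p) for one side.

    The disease-side result is transposed back into miRNA x disease
    orientation. Rows summing to zero stay zero.
    """
    pred = None
    for p, (Xp, Gp) in enumerate(zip(X, state.G)):
        R = Xp.values.T @ Gp
        if (R < -1e-12).any():
            raise AssertionError("negative subspace reconstruction from nonneg factors")
        term = state.alpha[p] * _rownormalize(np.clip(R, 0.0, None))
        pred = term if pred is None else pred + term
    if renormalize_alpha:
        profile_mass = state.alpha[:-1].sum()
        if profile_mass > 0:
            pred = pred / profile_mass
    if side == "disease":
        pred = pred.T
        provenance = "disease-perspective"
    else:
        provenance = "mirna-perspective"
    return ScoreMatrix(pred, mirnas, diseases, provenance)


def final_scores(
    mirna_side: ScoreMatrix,
    disease_side: ScoreMatrix,
    assoc: AssociationMatrix,
) -> ScoreMatrix:
    """Combine the two perspectives under the three-scenario rule.

    New miRNA (all-zero association row) -> miRNA-perspective score; new
    disease (all-zero column) -> disease-perspective score; otherwise the
    average. A pair where both entities are new takes the miRNA-perspective
    clause (first matching case); a warning is logged when that happens.
    """
    if (
        mirna_side.mirnas.names != disease_side.mirnas.names
        or mirna_side.diseases.names != disease_side.diseases.names
        or mirna_side.mirnas.names != assoc.mirnas.names
        or mirna_side.diseases.names != assoc.diseases.names
    ):
        raise ValueError("score matrices and association matrix indices differ")
    new_mirna = assoc.values.sum(axis=1) == 0  # (nm,)
    new_disease = assoc.values.sum(axis=0) == 0  # (nd,)
    both_new = np.outer(new_mirna, new_disease)
    if both_new.any():
        logger.warning(
            "%d pairs have neither side with known associations; "
            "using the miRNA-perspective score for them", int(both_new.sum()),
        )
    avg = (mirna_side.values + disease_side.values) / 2.0
    out = np.where(
        new_mirna[:, None], mirna_side.values,
        np.where(new_disease[None, :], disease_side.values, avg),
    )
    return ScoreMatrix(out, assoc.mirnas, assoc.diseases, "final")


def rank_candidates(
    scores: ScoreMatrix,
    assoc: AssociationMatrix,
    disease: str,
    top: int | None = 50,
) -> list[tuple[int, str, float]]:
    """Rank a disease's candidate miRNAs (unconfirmed pairs) by score.

    Returns (rank, miRNA name, score) tuples, descending score, ties broken
    by ascending miRNA index; at most ``top`` entries.
    """
    if disease not in scores.diseases:
        raise KeyError(f"unknown disease {disease!r}")
    j = scores.diseases[disease]
    candidates = np.flatnonzero(assoc.values[:, j] == 0)
    col = scores.values[:, j]
    order = candidates[np.lexsort((candidates, -col[candidates]))]
    if top is not None:
        order = order[:top]
    return [
        (rank, scores.mirnas.names[i], float(col[i]))
        for rank, i in enumerate(order, start=1)
    ]
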