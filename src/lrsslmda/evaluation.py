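"""Cross-validation protocols and the rank-threshold ROC/AUC.

The evaluation treats link prediction as a ranking problem: each held-out
known association ("test sample") receives a rank against a candidate set
of unconfirmed pairs, and the ROC sweeps a rank threshold — sensitivity is
the fraction of test samples ranked at or above the threshold, the false
positive rate the fraction of candidates ranked above it. Three schemes:

* global LOOCV: each known pair is left out in turn, the model refit on the
  rest, and the pair ranked against every pair never labelled 1;
* local LOOCV: the held-out pair is ranked only against the unconfirmed
  miRNAs of its own disease;
* repeated k-fold: the known pairs are partitioned into k near-equal folds,
  each fold masked and its pairs ranked against the global candidates, and
  the per-repeat AUC averaged across seeded repeats.

Every round refits the full pipeline from the masked matrix, so kernels,
features and graphs never see the held-out labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .pipeline import Dataset, PipelineConfig, train_and_score

logger = logging.getLogger(__name__)

__all__ = ["CVResult", "rank_against", "roc_auc", "global_loocv", "local_loocv", "kfold_cv"]


@dataclass
class CVResult:
    scheme: str
    ranks: list[tuple[tuple[int, int], float, int]]  # (pair, rank, n candidates)
    auc: float
    roc: np.ndarray = field(repr=False)  # (points, 2): FPR, TPR
    auc_sd: float | None = None
    rounds: int = 0
    per_round_auc: list[float] | None = None


def rank_against(test_score: float, candidate_scores: np.ndarray) -> float:
    """Rank of the test sample among candidates (1 = best).

    Strict greater-than counting; ties with candidates contribute half a
    position (mid-rank), since the AUC is tie-sensitive.
    """
    c = np.asarray(candidate_scores, dtype=float)
    return 1.0 + float((c > test_score).sum()) + 0.5 * float((c == test_score).sum())


def roc_auc(test_ranks: list[tuple[float, int]]) -> tuple[np.ndarray, float]:
    """ROC polyline and AUC from pooled (rank, candidate count) rounds.

    Sweeps every achievable rank threshold t: a test sample with rank r is a
    true positive when r <= t; the candidates occupying the remaining
    positions up to t count as false positives, normalized by the pooled
    candidate total. For a single round with rank r among n candidates this
    reduces to AUC = 1 - (r - 1)/n.
    """
    if not test_ranks:
        raise ValueError("need at least one test rank")
    ranks = np.array([r for r, _ in test_ranks], dtype=float)
    counts = np.array([n for _, n in test_ranks], dtype=float)
    if (counts < 1).any():
        raise ValueError("every round needs at least one candidate")
    max_t = counts.max() + 1.0
    thresholds = np.unique(np.concatenate([[0.0], ranks, np.arange(1.0, max_t + 1.0)]))
    n_tests = len(ranks)
    total_candidates = counts.sum()
    tpr = np.empty(len(thresholds))
    fpr = np.empty(len(thresholds))
    for k, t in enumerate(thresholds):
        hit = ranks <= t
        tpr[k] = hit.mean()
        # candidates above threshold in each round: positions 1..t minus the
        # test sample when it beat the threshold, capped by the round's size
        fp = np.clip(np.minimum(t, counts + 1.0) - hit, 0.0, counts)
        fpr[k] = fp.sum() / total_candidates
    order = np.argsort(fpr, kind="stable")
    fpr, tpr = fpr[order], tpr[order]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def _masked(dataset: Dataset, drop: list[tuple[int, int]]) -> np.ndarray:
    A = dataset.assoc.values.copy()
    for i, j in drop:
        A[i, j] = 0.0
    return A


def global_loocv(
    dataset: Dataset,
    config: PipelineConfig | None = None,
    budget: int | None = None,
    budget_seed: int = 0,
) -> CVResult:
    """Leave-one-association-out, ranked against all never-known pairs.

    ``budget`` subsamples the rounds (an approximation for smoke runs; the
    full protocol runs every known pair).
    """
    config = config or PipelineConfig()
    pairs = dataset.assoc.pairs()
    if len(pairs) < 2:
        raise ValueError("need at least two known associations")
    candidates = np.argwhere(dataset.assoc.values == 0.0)
    rounds = _subsample(pairs, budget, budget_seed)
    ranks: list[tuple[tuple[int, int], float, int]] = []
    for i, j in rounds:
        A = _masked(dataset, [(i, j)])
        model = train_and_score(dataset, config, assoc_values=A)
        scores = model.scores.values
        cand_scores = scores[candidates[:, 0], candidates[:, 1]]
        r = rank_against(scores[i, j], cand_scores)
        ranks.append(((i, j), r, len(cand_scores)))
    roc, auc = roc_auc([(r, n) for _, r, n in ranks])
    return CVResult("global-loocv", ranks, auc, roc, rounds=len(ranks))


def local_loocv(
    dataset: Dataset,
    config: PipelineConfig | None = None,
    budget: int | None = None,
    budget_seed: int = 0,
) -> CVResult:
    """Leave-one-out ranked against the same disease's unconfirmed miRNAs."""
    config = config or PipelineConfig()
    pairs = dataset.assoc.pairs()
    if len(pairs) < 2:
        raise ValueError("need at least two known associations")
    rounds = _subsample(pairs, budget, budget_seed)
    ranks: list[tuple[tuple[int, int], float, int]] = []
    for i, j in rounds:
        cand = np.flatnonzero(dataset.assoc.values[:, j] == 0.0)
        if cand.size == 0:
            logger.warning("disease %d has no candidate miRNAs; round skipped", j)
            continue
        A = _masked(dataset, [(i, j)])
        model = train_and_score(dataset, config, assoc_values=A)
        col = model.scores.values[:, j]
        r = rank_against(col[i], col[cand])
        ranks.append(((i, j), r, cand.size))
    roc, auc = roc_auc([(r, n) for _, r, n in ranks])
    result = CVResult("local-loocv", ranks, auc, roc, rounds=len(ranks))
    # per-disease mean AUC reported alongside the pooled curve
    by_disease: dict[int, list[tuple[float, int]]] = {}
    for (_, j), r, n in ranks:
        by_disease.setdefault(j, []).append((r, n))
    result.per_round_auc = [roc_auc(v)[1] for v in by_disease.values()]
    return result


def _subsample(pairs, budget, seed):
    if budget is None or budget >= len(pairs):
        return list(pairs)
    rng = np.random.default_rng(seed)
    keep = rng.choice(len(pairs), size=budget, replace=False)
    return [pairs[k] for k in sorted(keep)]


def partition_folds(n_items: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random partition into k folds whose sizes differ by at most one."""
    if k < 2:
        raise ValueError("k must be >= 2")
    perm = rng.permutation(n_items)
    return [np.sort(perm[f::k]) for f in range(k)]


def kfold_cv(
    dataset: Dataset,
    config: PipelineConfig | None = None,
    k: int = 5,
    repeats: int = 100,
    seed: int = 0,
) -> CVResult:
    """Repeated k-fold over the known pairs; per-repeat AUC mean and sd."""
    config = config or PipelineConfig()
    pairs = dataset.assoc.pairs()
    if len(pairs) < k:
        raise ValueError("need at least k known associations")
    candidates = np.argwhere(dataset.assoc.values == 0.0)
    rng = np.random.default_rng(seed)
    per_repeat: list[float] = []
    all_ranks: list[tuple[tuple[int, int], float, int]] = []
    last_roc = None
    for _ in range(repeats):
        folds = partition_folds(len(pairs), k, rng)
        ranks: list[tuple[float, int]] = []
        for fold in folds:
            test_pairs = [pairs[t] for t in fold]
            A = _masked(dataset, test_pairs)
            model = train_and_score(dataset, config, assoc_values=A)
            scores = model.scores.values
            cand_scores = scores[candidates[:, 0], candidates[:, 1]]
            for i, j in test_pairs:
                r = rank_against(scores[i, j], cand_scores)
                ranks.append((r, len(cand_scores)))
                all_ranks.append(((i, j), r, len(cand_scores)))
        last_roc, auc = roc_auc(ranks)
        per_repeat.append(auc)
    mean_auc = float(np.mean(per_repeat))
    sd = float(np.std(per_repeat, ddof=1)) if repeats > 1 else 0.0
    return CVResult(
        "kfold", all_ranks, mean_auc, last_roc, auc_sd=sd,
        rounds=repeats, per_round_auc=per_repeat,
    )
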