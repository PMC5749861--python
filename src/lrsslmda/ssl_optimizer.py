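"""Alternating minimization of the sparse-subspace objective for one side.

For one side of the bipartite network (miRNAs or diseases), with Y the
association matrix oriented entities x targets, X_p the two feature
profiles (d_p x n) and Laplacians L_1, L_2 (feature graphs) and L_MDA
(association graph), the objective is

    min_{F, G_p >= 0}  ||F - Y||_F^2 + Tr(F^T L F)
                       + mu * sum_p ||X_p^T G_p - F||_F^2
                       + lam * sum_p sum_j ||G_p(:,j)||_1^2

with L = sum_p alpha_p^gamma L_p + alpha_MDA^gamma L_MDA and the alpha
weights on the probability simplex. One outer iteration performs, in
order: a multiplicative update of each G_p on the F-eliminated objective
(an auxiliary-function step, so it can only decrease it), the closed-form
F update F = P (Y + mu sum_p X_p^T G_p) with P = (L + (1+m*mu) I)^{-1}
(the stationary point in F), and the closed-form simplex update of alpha.
Each step is a block minimization, so the objective recorded at the end of
every iteration is non-increasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .feature_extraction import FeatureMatrix
from .laplacian_graphs import GraphLaplacian

logger = logging.getLogger(__name__)

__all__ = ["Hyperparams", "LaplacianBundle", "ModelState", "objective",
           "update_F", "update_G", "update_alpha", "fit"]

_EPS = 1e-12


@dataclass(frozen=True)
class Hyperparams:
    """Model hyperparameters.

    mu balances the subspace regression, lam the squared-L1 sparsity of the
    projection columns, gamma_exp (> 1) the spread of the Laplacian weights.
    """

    mu: float = 1.0
    lam: float = 1.0
    gamma_exp: float = 2.0
    max_iter: int = 1000
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.lam < 0 or self.gamma_exp <= 1:
            raise ValueError("require mu > 0, lam >= 0, gamma_exp > 1")


@dataclass
class LaplacianBundle:
    """Per-graph Laplacians and their alpha-weighted combination."""

    L_p: list[GraphLaplacian]
    L_MDA: GraphLaplacian

    def combined(self, alpha: np.ndarray, gamma_exp: float) -> np.ndarray:
        L = (alpha[-1] ** gamma_exp) * self.L_MDA.L
        for a, lap in zip(alpha[:-1], self.L_p):
            L = L + (a ** gamma_exp) * lap.L
        return L

    def traces(self, F: np.ndarray) -> np.ndarray:
        """Tr(F^T L_q F) for q = 1..m, MDA (clipped at 0 against roundoff)."""
        ts = [float(np.einsum("it,ij,jt->", F, lap.L, F)) for lap in self.L_p]
        ts.append(float(np.einsum("it,ij,jt->", F, self.L_MDA.L, F)))
        return np.clip(np.array(ts), 0.0, None)


@dataclass
class ModelState:
    F: np.ndarray
    G: list[np.ndarray]
    alpha: np.ndarray
    P: np.ndarray
    objective_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


def _check_finite(name: str, arr: np.ndarray) -> None:
    if not np.isfinite(arr).all():
        raise FloatingPointError(f"non-finite values in {name}")


def objective(
    state: ModelState,
    X: list[FeatureMatrix],
    Y: np.ndarray,
    bundle: LaplacianBundle,
    hp: Hyperparams,
) -> float:
    """Value of the full objective at the current state."""
    L = bundle.combined(state.alpha, hp.gamma_exp)
    F = state.F
    val = float(((F - Y) ** 2).sum())
    val += float(np.einsum("it,ij,jt->", F, L, F))
    for Xp, Gp in zip(X, state.G):
        val += hp.mu * float(((Xp.values.T @ Gp - F) ** 2).sum())
        val += hp.lam * float((np.abs(Gp).sum(axis=0) ** 2).sum())
    if not np.isfinite(val):
        raise FloatingPointError("objective is non-finite")
    return val


def _P_matrix(L: np.ndarray, m: int, mu: float) -> np.ndarray:
    n = L.shape[0]
    M = L + (1.0 + m * mu) * np.eye(n)
    P = np.linalg.solve(M, np.eye(n))
    return (P + P.T) / 2.0


def update_F(
    state: ModelState, X: list[FeatureMatrix], Y: np.ndarray, hp: Hyperparams
) -> np.ndarray:
    """Closed-form stationary point of the objective in F."""
    rhs = Y.copy()
    for Xp, Gp in zip(X, state.G):
        rhs += hp.mu * (Xp.values.T @ Gp)
    F = state.P @ rhs
    _check_finite("F", F)
    return F


def update_G(
    state: ModelState,
    p: int,
    X: list[FeatureMatrix],
    Y: np.ndarray,
    hp: Hyperparams,
) -> np.ndarray:
    """Multiplicative auxiliary-function step for the p-th projection matrix.

    With A_p = X_p (mu I - mu^2 P) X_p^T + lam * 1 1^T and
    B_p = mu X_p P Y + mu^2 sum_{q != p} X_p P X_q^T G_q, the rule

        G <- G * sqrt((A^- G + B^+) / (A^+ G + B^- + eps))

    (M^+/M^- the positive/negative parts) decreases the F-eliminated
    objective and preserves entrywise nonnegativity.
    """
    Gp = state.G[p]
    if (Gp < 0).any():
        raise ValueError("G_p must be entrywise nonnegative")
    mu, lam = hp.mu, hp.lam
    P = state.P
    Xp = X[p].values
    d_p = Xp.shape[0]
    XpP = Xp @ P
    A = mu * (Xp @ Xp.T) - mu ** 2 * (XpP @ Xp.T) + lam * np.ones((d_p, d_p))
    B = mu * (XpP @ Y)
    for q, (Xq, Gq) in enumerate(zip(X, state.G)):
        if q == p:
            continue
        B += mu ** 2 * (XpP @ Xq.values.T @ Gq)
    A_pos = (np.abs(A) + A) / 2.0
    A_neg = (np.abs(A) - A) / 2.0
    B_pos = (np.abs(B) + B) / 2.0
    B_neg = (np.abs(B) - B) / 2.0
    num = A_neg @ Gp + B_pos
    den = A_pos @ Gp + B_neg + _EPS
    G_new = Gp * np.sqrt(num / den)
    _check_finite("G_p", G_new)
    return G_new


def update_alpha(
    state: ModelState, bundle: LaplacianBundle, hp: Hyperparams
) -> np.ndarray:
    """Closed-form simplex minimizer of sum_q alpha_q^gamma Tr(F^T L_q F).

    alpha_q is proportional to (1 / Tr(F^T L_q F))^(1/(gamma-1)); if some
    trace is zero, all mass goes to the zero-trace terms, split uniformly.
    """
    traces = bundle.traces(state.F)
    zero = traces <= _EPS
    alpha = np.zeros_like(traces)
    if zero.any():
        alpha[zero] = 1.0 / zero.sum()
        return alpha
    w = (1.0 / traces) ** (1.0 / (hp.gamma_exp - 1.0))
    return w / w.sum()


def fit(
    X: list[FeatureMatrix],
    Y: np.ndarray,
    L_p: list[GraphLaplacian],
    L_MDA: GraphLaplacian,
    hp: Hyperparams | None = None,
) -> ModelState:
    """Run the alternating optimization to convergence for one side.

    Stops when the relative objective change drops below ``hp.tol`` or
    after ``hp.max_iter`` iterations. Deterministic given ``hp.seed``.
    """
    hp = hp or Hyperparams()
    m = len(X)
    if m not in (1, 2):
        raise ValueError(f"expected 1 or 2 feature profiles, got {m}")
    Y = np.asarray(Y, dtype=float)
    n, t = Y.shape
    bundle = LaplacianBundle(L_p=list(L_p), L_MDA=L_MDA)
    rng = np.random.default_rng(hp.seed)
    alpha = np.full(m + 1, 1.0 / (m + 1))
    G = [rng.uniform(0.0, 1.0, size=(Xp.values.shape[0], t)) for Xp in X]
    state = ModelState(F=Y.copy(), G=G, alpha=alpha, P=np.eye(n))
    state.objective_trace.append(objective(state, X, Y, bundle, hp))

    for it in range(hp.max_iter):
        L = bundle.combined(state.alpha, hp.gamma_exp)
        state.P = _P_matrix(L, m, hp.mu)
        for p in range(m):
            state.G[p] = update_G(state, p, X, Y, hp)
        state.F = update_F(state, X, Y, hp)
        state.alpha = update_alpha(state, bundle, hp)
        obj = objective(state, X, Y, bundle, hp)
        state.objective_trace.append(obj)
        state.n_iter = it + 1
        prev = state.objective_trace[-2]
        rel = abs(prev - obj) / max(abs(prev), _EPS)
        if rel < hp.tol:
            state.converged = True
            break
    logger.debug(
        "fit finished after %d iterations (converged=%s, objective=%.6g)",
        state.n_iter, state.converged, state.objective_trace[-1],
    )
    return state
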