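import numpy as np
import pytest

from lrsslmda.feature_extraction import FeatureMatrix
from lrsslmda.laplacian_graphs import GraphLaplacian
from lrsslmda.ssl_optimizer import (
    Hyperparams,
    LaplacianBundle,
    ModelState,
    fit,
    objective,
    update_F,
    update_G,
    update_alpha,
)


def fm(values):
    values = np.asarray(values, dtype=float)
    return FeatureMatrix(values, tuple(f"f{i}" for i in range(values.shape[0])), "mirna", 1)


def random_laplacian(rng, n):
    S = (rng.random((n, n)) < 0.4).astype(float)
    S = np.triu(S, 1)
    S = S + S.T
    return GraphLaplacian.from_adjacency(S)


def random_problem(rng, n=8, t=6, d=(5, 7)):
    X = [fm(rng.random((dp, n))) for dp in d]
    Y = (rng.random((n, t)) < 0.3).astype(float)
    bundle = LaplacianBundle(
        L_p=[random_laplacian(rng, n) for _ in d], L_MDA=random_laplacian(rng, n)
    )
    return X, Y, bundle


def make_state(rng, X, Y, bundle, hp):
    n, t = Y.shape
    L = bundle.combined(np.full(len(X) + 1, 1 / (len(X) + 1)), hp.gamma_exp)
    M = L + (1 + len(X) * hp.mu) * np.eye(n)
    return ModelState(
        F=rng.random((n, t)),
        G=[rng.random((x.values.shape[0], t)) for x in X],
        alpha=np.full(len(X) + 1, 1 / (len(X) + 1)),
        P=np.linalg.inv(M),
    )


def eliminated_objective(G, X, Y, bundle, alpha, hp):
    """Full objective with F set to its closed form given G (independent
    evaluation used as the descent oracle)."""
    L = bundle.combined(alpha, hp.gamma_exp)
    n = Y.shape[0]
    M = L + (1 + len(X) * hp.mu) * np.eye(n)
    rhs = Y + hp.mu * sum(x.values.T @ g for x, g in zip(X, G))
    F = np.linalg.solve(M, rhs)
    val = ((F - Y) ** 2).sum() + np.einsum("it,ij,jt->", F, L, F)
    for x, g in zip(X, G):
        val += hp.mu * ((x.values.T @ g - F) ** 2).sum()
        val += hp.lam * ((np.abs(g).sum(axis=0) ** 2).sum())
    return float(val)


class TestObjective:
    def test_term_by_term_value_at_f_equals_y(self, rng):
        X, Y, bundle = random_problem(rng)
        hp = Hyperparams()
        state = make_state(rng, X, Y, bundle, hp)
        state.F = Y.copy()
        state.G = [np.zeros_like(g) for g in state.G]
        L = bundle.combined(state.alpha, hp.gamma_exp)
        expected = np.einsum("it,ij,jt->", Y, L, Y) + hp.mu * 2 * (Y ** 2).sum()
        assert objective(state, X, Y, bundle, hp) == pytest.approx(expected)

    def test_zero_everything_gives_zero(self, rng):
        X, Y, bundle = random_problem(rng)
        Y = np.zeros_like(Y)
        hp = Hyperparams()
        state = make_state(rng, X, Y, bundle, hp)
        state.F = np.zeros_like(Y)
        state.G = [np.zeros_like(g) for g in state.G]
        assert objective(state, X, Y, bundle, hp) == 0.0

    def test_l1_term_strictly_increases_with_g(self, rng):
        X, Y, bundle = random_problem(rng)
        hp = Hyperparams(lam=1.0)
        state = make_state(rng, X, Y, bundle, hp)
        before = objective(state, X, Y, bundle, hp)
        state.G[0][0, 0] += 1.0
        assert objective(state, X, Y, bundle, hp) > before


class TestUpdateF:
    def test_identity_laplacian_free_case(self, rng):
        # L = 0, G = 0, m = 2, mu = 1: F = (1 + 2)^-1 Y = Y/3
        n, t = 5, 4
        Y = (rng.random((n, t)) < 0.5).astype(float)
        X = [fm(rng.random((3, n))), fm(rng.random((4, n)))]
        hp = Hyperparams()
        state = ModelState(
            F=np.zeros((n, t)),
            G=[np.zeros((3, t)), np.zeros((4, t))],
            alpha=np.full(3, 1 / 3),
            P=np.linalg.inv(3 * np.eye(n)),
        )
        assert np.allclose(update_F(state, X, Y, hp), Y / 3.0)

    def test_zero_inputs_give_zero(self, rng):
        n, t = 4, 3
        X = [fm(rng.random((3, n))), fm(rng.random((2, n)))]
        hp = Hyperparams()
        state = ModelState(
            F=np.ones((n, t)),
            G=[np.zeros((3, t)), np.zeros((2, t))],
            alpha=np.full(3, 1 / 3),
            P=np.linalg.inv(3 * np.eye(n)),
        )
        assert np.allclose(update_F(state, X, np.zeros((n, t)), hp), 0.0)

    def test_stationarity_by_finite_differences(self, rng):
        X, Y, bundle = random_problem(rng, n=6, t=4)
        hp = Hyperparams()
        state = make_state(rng, X, Y, bundle, hp)
        state.F = update_F(state, X, Y, hp)
        base = objective(state, X, Y, bundle, hp)
        eps = 1e-6
        grad = np.zeros_like(state.F)
        for i in range(state.F.shape[0]):
            for t_ in range(state.F.shape[1]):
                state.F[i, t_] += eps
                up = objective(state, X, Y, bundle, hp)
                state.F[i, t_] -= 2 * eps
                down = objective(state, X, Y, bundle, hp)
                state.F[i, t_] += eps
                grad[i, t_] = (up - down) / (2 * eps)
        assert np.abs(grad).max() < 1e-5 * (1 + abs(base))


class TestUpdateG:
    def test_zero_g_is_a_fixed_point(self, rng):
        X, Y, bundle = random_problem(rng)
        hp = Hyperparams()
        state = make_state(rng, X, Y, bundle, hp)
        state.G[0] = np.zeros_like(state.G[0])
        assert np.array_equal(update_G(state, 0, X, Y, hp), state.G[0])

    def test_negative_g_rejected(self, rng):
        X, Y, bundle = random_problem(rng)
        hp = Hyperparams()
        state = make_state(rng, X, Y, bundle, hp)
        state.G[0][0, 0] = -0.5
        with pytest.raises(ValueError):
            update_G(state, 0, X, Y, hp)

    def test_descent_of_the_eliminated_objective_over_100_trials(self):
        # the multiplicative rule targets the objective with F eliminated in
        # closed form; each step must not increase it
        hp = Hyperparams()
        for trial in range(100):
            rng = np.random.default_rng(trial)
            X, Y, bundle = random_problem(rng, n=int(rng.integers(4, 9)),
                                          t=int(rng.integers(3, 7)))
            state = make_state(rng, X, Y, bundle, hp)
            L = bundle.combined(state.alpha, hp.gamma_exp)
            state.P = np.linalg.inv(L + 3 * np.eye(Y.shape[0]))
            for p in range(2):
                before = eliminated_objective(state.G, X, Y, bundle, state.alpha, hp)
                state.G[p] = update_G(state, p, X, Y, hp)
                after = eliminated_objective(state.G, X, Y, bundle, state.alpha, hp)
                assert after <= before + 1e-8 * max(1.0, abs(before))
                assert (state.G[p] >= 0).all()


class TestUpdateAlpha:
    def _state_with_traces(self, traces):
        # diag Laplacians scaled so Tr(F^T L_q F) equals the requested traces
        n = 3
        F = np.eye(n)
        bundles = [GraphLaplacian(S=np.zeros((n, n)), D=t * np.eye(n), L=t * np.eye(n))
                   for t in traces]
        bundle = LaplacianBundle(L_p=bundles[:-1], L_MDA=bundles[-1])
        state = ModelState(F=F, G=[], alpha=np.full(3, 1 / 3), P=np.eye(n))
        return state, bundle

    def test_equal_traces_give_uniform_weights(self):
        state, bundle = self._state_with_traces([1.0, 1.0, 1.0])
        assert np.allclose(update_alpha(state, bundle, Hyperparams()), 1 / 3)

    def test_hand_computed_weights(self):
        # gamma = 2, traces (1, 2, 2) -> alpha = (1/2, 1/4, 1/4)
        state, bundle = self._state_with_traces([1.0, 2.0, 2.0])
        assert np.allclose(update_alpha(state, bundle, Hyperparams()),
                           [0.5, 0.25, 0.25])

    def test_zero_trace_takes_all_mass(self):
        state, bundle = self._state_with_traces([0.0, 2.0, 3.0])
        assert np.allclose(update_alpha(state, bundle, Hyperparams()), [1.0, 0.0, 0.0])

    def test_profile_permutation_equivariance(self):
        state, bundle = self._state_with_traces([1.0, 4.0, 2.0])
        a = update_alpha(state, bundle, Hyperparams())
        state2, bundle2 = self._state_with_traces([4.0, 1.0, 2.0])
        a2 = update_alpha(state2, bundle2, Hyperparams())
        assert np.allclose(a2, a[[1, 0, 2]])

    def test_weights_sum_to_one_on_random_input(self, rng):
        state, bundle = self._state_with_traces(rng.random(3) + 0.1)
        assert update_alpha(state, bundle, Hyperparams()).sum() == pytest.approx(1.0)


class TestFit:
    def test_trace_non_increasing_on_synthetic_problem(self, rng):
        X, Y, bundle = random_problem(rng, n=10, t=8)
        state = fit(X, Y, bundle.L_p, bundle.L_MDA, Hyperparams(max_iter=50))
        tr = np.array(state.objective_trace)
        assert (np.diff(tr) <= 1e-8 * np.maximum(1.0, np.abs(tr[:-1]))).all()

    def test_same_seed_gives_bit_identical_result(self, rng):
        X, Y, bundle = random_problem(rng)
        hp = Hyperparams(max_iter=30, seed=42)
        s1 = fit(X, Y, bundle.L_p, bundle.L_MDA, hp)
        s2 = fit(X, Y, bundle.L_p, bundle.L_MDA, hp)
        assert np.array_equal(s1.F, s2.F)
        assert all(np.array_equal(a, b) for a, b in zip(s1.G, s2.G))

    def test_infinite_tolerance_stops_after_one_iteration(self, rng):
        X, Y, bundle = random_problem(rng)
        state = fit(X, Y, bundle.L_p, bundle.L_MDA,
                    Hyperparams(tol=float("inf"), max_iter=100))
        assert state.n_iter == 1

    def test_g_nonnegativity_preserved(self, rng):
        X, Y, bundle = random_problem(rng)
        state = fit(X, Y, bundle.L_p, bundle.L_MDA, Hyperparams(max_iter=40))
        assert all((g >= 0).all() for g in state.G)

    def test_alpha_on_simplex(self, rng):
        X, Y, bundle = random_problem(rng)
        state = fit(X, Y, bundle.L_p, bundle.L_MDA, Hyperparams(max_iter=40))
        assert state.alpha.sum() == pytest.approx(1.0, abs=1e-9)
        assert (state.alpha >= 0).all()
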