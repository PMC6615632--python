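"""Model likelihoods against scalar brute-force oracles.

The oracles below recompute every term of the two model likelihoods with
plain Python scalar arithmetic (no vectorization, no shared code with the
implementation) so the two routes are independent.
"""

import math

import numpy as np
import pytest

import dfemix as dx
from conftest import random_instance


def _log_normal(x, mean, var):
    return -0.5 * math.log(2.0 * math.pi * var) - (x - mean) ** 2 / (2.0 * var)


def _log_factorial(n):
    return math.lgamma(n + 1)


def oracle_multicat(data, state, shared, include_assign=True):
    n_c = len(state.e)
    v = [0] * n_c
    for mj in state.m:
        v[mj] += 1
    total = 0.0
    if include_assign:
        for mj in state.m:
            total += math.log(state.q[mj])
    coeff = _log_factorial(len(state.m))
    for k in range(n_c):
        coeff -= _log_factorial(v[k])
        coeff += v[k] * math.log(state.q[k])
    total += coeff
    for pk in shared.p:
        total += _log_normal(pk, 0.0, shared.V_p)
    for i in range(data.n_b):
        g = 0.0
        for j in range(data.n_m):
            g += state.e[state.m[j]] * data.M[i, j]
        ff = 0.0
        for j in range(data.n_f):
            ff += data.F[i, j] * shared.f[j]
        pe = shared.p[data.plate[i]] if data.n_p else 0.0
        resid = data.y[i] - g - ff - pe
        total += _log_normal(resid, shared.ybar[data.line[i]], shared.V_e)
    return total


def oracle_gamma(data, state, shared, include_assign=True):
    n_m = len(state.mu)
    total = 0.0
    v0 = 0
    for j in range(n_m):
        s = state.mu[j]
        x = state.E[s, j]
        rate, shape = state.rate[s], state.shape[s]
        total += (
            shape * math.log(rate)
            - math.lgamma(shape)
            + (shape - 1.0) * math.log(x)
            - rate * x
        )
        total += math.log(state.q[s]) if include_assign else 0.0
        v0 += 1 if s == 0 else 0
    total += (
        _log_factorial(n_m)
        - _log_factorial(v0)
        - _log_factorial(n_m - v0)
        + v0 * math.log(state.q[0])
        + (n_m - v0) * math.log(state.q[1])
    )
    for pk in shared.p:
        total += _log_normal(pk, 0.0, shared.V_p)
    for i in range(data.n_b):
        g = 0.0
        for j in range(n_m):
            sign = -1.0 if state.mu[j] == 0 else 1.0
            g += state.E[state.mu[j], j] * sign * data.M[i, j]
        ff = 0.0
        for j in range(data.n_f):
            ff += data.F[i, j] * shared.f[j]
        pe = shared.p[data.plate[i]] if data.n_p else 0.0
        resid = data.y[i] - g - ff - pe
        total += _log_normal(resid, shared.ybar[data.line[i]], shared.V_e)
    return total


def random_multicat_state(rng, n_m, n_c=3):
    e = np.concatenate([[0.0], rng.normal(0, 0.2, n_c - 1)])
    q = rng.dirichlet(np.ones(n_c))
    return dx.MulticategoryState(m=rng.integers(0, n_c, n_m), e=e, q=q)


def random_gamma_state(rng, n_m):
    q0 = rng.uniform(0.2, 0.8)
    return dx.GammaState(
        mu=rng.integers(0, 2, n_m),
        E=rng.gamma(1.0, 0.1, size=(2, n_m)) + 1e-6,
        q=np.array([q0, 1 - q0]),
        rate=rng.uniform(0.5, 20.0, 2),
        shape=rng.uniform(0.2, 5.0, 2),
    )


def random_shared(rng, data):
    return dx.SharedState(
        f=rng.normal(0, 0.2, data.n_f),
        p=rng.normal(0, 0.2, data.n_p),
        V_p=rng.uniform(0.05, 0.5),
        ybar=rng.normal(0, 0.3, max(data.n_lines, 1)),
        V_e=rng.uniform(0.5, 2.0),
    )


class TestGenotypicValues:
    def test_no_mutations_carried(self):
        g = dx.genotypic_values_multicat(np.zeros((3, 4)), [1, 0, 2, 1], [0, 0.1, -0.2])
        assert (g == 0).all()

    def test_carried_in_zero_category(self):
        g = dx.genotypic_values_multicat(np.ones((2, 3)), [0, 0, 0], [0, 0.5])
        assert (g == 0).all()

    def test_hand_example_multicat(self):
        g = dx.genotypic_values_multicat(
            np.array([[1, 0, 1]]), [1, 0, 2], [0.0, -0.03, 0.02]
        )
        assert g[0] == pytest.approx(-0.01)

    def test_sign_convention_gamma(self):
        g = dx.genotypic_values_gamma(
            np.array([[1]]), [0], np.array([[0.02], [0.5]])
        )
        assert g[0] == pytest.approx(-0.02)

    def test_hand_example_gamma(self):
        g = dx.genotypic_values_gamma(
            np.array([[1, 1]]), [0, 1], np.array([[0.03, 0.9], [0.7, 0.01]])
        )
        assert g[0] == pytest.approx(-0.02)


class TestOracleEquivalence:
    """Vectorized likelihoods equal scalar brute force at 1e-10 relative
    tolerance on 100 random small instances (n_b <= 20, n_m <= 5)."""

    @pytest.mark.parametrize("include_assign", [True, False])
    def test_multicat(self, include_assign):
        rng = np.random.default_rng(10)
        for _ in range(100):
            data = random_instance(rng)
            state = random_multicat_state(rng, data.n_m)
            shared = random_shared(rng, data)
            got = dx.loglik_multicat(data, state, shared, include_assign)
            want = oracle_multicat(data, state, shared, include_assign)
            assert got == pytest.approx(want, rel=1e-10)

    @pytest.mark.parametrize("include_assign", [True, False])
    def test_gamma(self, include_assign):
        rng = np.random.default_rng(11)
        for _ in range(100):
            data = random_instance(rng)
            state = random_gamma_state(rng, data.n_m)
            shared = random_shared(rng, data)
            got = dx.loglik_gamma(data, state, shared, include_assign)
            want = oracle_gamma(data, state, shared, include_assign)
            assert got == pytest.approx(want, rel=1e-10)


class TestReductions:
    def test_single_category_null_model(self):
        """With one category, no fixed effects and no plates, the likelihood
        reduces to independent normal densities around the line mean."""
        rng = np.random.default_rng(12)
        data = random_instance(rng, n_b=15, n_m=4, n_f=0, n_p=0)
        state = dx.MulticategoryState(m=np.zeros(4, dtype=int), e=[0.0], q=[1.0])
        shared = dx.SharedState(f=[], p=[], V_p=1.0, ybar=[0.3], V_e=1.2)
        got = dx.loglik_multicat(data, state, shared)
        want = sum(_log_normal(yi, 0.3, 1.2) for yi in data.y)
        assert got == pytest.approx(want, rel=1e-12)

    def test_gamma_no_mutations(self):
        rng = np.random.default_rng(13)
        data = random_instance(rng, n_b=10, n_m=0, n_f=0, n_p=0)
        state = dx.GammaState(
            mu=np.zeros(0, dtype=int), E=np.zeros((2, 0)),
            q=[0.5, 0.5], rate=[1.0, 1.0], shape=[1.0, 1.0],
        )
        shared = dx.SharedState(f=[], p=[], V_p=1.0, ybar=[0.0], V_e=1.0)
        got = dx.loglik_gamma(data, state, shared)
        want = sum(_log_normal(yi, 0.0, 1.0) for yi in data.y)
        assert got == pytest.approx(want, rel=1e-12)

    def test_occupied_zero_frequency_is_minus_inf(self):
        data = random_instance(np.random.default_rng(14), n_b=5, n_m=2)
        state = dx.MulticategoryState(m=[1, 1], e=[0.0, 0.1], q=[1.0, 0.0])
        shared = dx.SharedState(f=[], p=[], V_p=1.0, ybar=[0.0], V_e=1.0)
        assert dx.loglik_multicat(data, state, shared) == -np.inf


class TestTermIsolation:
    def test_multicat_category_move_changes_count_terms_only(self):
        """With a zero effect in the target category, reassigning one
        mutation changes the likelihood by the assignment and multinomial
        deltas only (computed analytically)."""
        rng = np.random.default_rng(15)
        data = random_instance(rng, n_b=12, n_m=3, n_f=0, n_p=0)
        shared = dx.SharedState(f=[], p=[], V_p=1.0, ybar=[0.0], V_e=1.0)
        q = np.array([0.5, 0.5])
        before = dx.loglik_multicat(
            data, dx.MulticategoryState(m=[0, 0, 0], e=[0.0, 0.0], q=q), shared
        )
        after = dx.loglik_multicat(
            data, dx.MulticategoryState(m=[1, 0, 0], e=[0.0, 0.0], q=q), shared
        )
        # assignment: log q1 - log q0 = 0; multinomial: counts (3,0)->(2,1)
        expected = (math.log(3) - math.log(1)) * 0 + (
            (-_log_factorial(2) - _log_factorial(1))
            - (-_log_factorial(3) - _log_factorial(0))
        )
        assert after - before == pytest.approx(expected, abs=1e-12)

    def test_gamma_side_flip_delta_decomposition(self):
        """Flipping one side indicator changes the likelihood by the gamma
        density, side-probability, binomial-count and observation deltas."""
        rng = np.random.default_rng(16)
        data = random_instance(rng, n_b=10, n_m=2, n_f=0, n_p=0)
        shared = random_shared(rng, data)
        state = random_gamma_state(rng, 2)
        flipped = dx.GammaState(
            mu=state.mu.copy(), E=state.E, q=state.q,
            rate=state.rate, shape=state.shape,
        )
        flipped.mu = state.mu.copy()
        flipped.mu[0] = 1 - flipped.mu[0]
        delta = dx.loglik_gamma(data, flipped, shared) - dx.loglik_gamma(
            data, state, shared
        )
        s, t = state.mu[0], 1 - state.mu[0]

        def lgpdf(x, side):
            return (
                state.shape[side] * math.log(state.rate[side])
                - math.lgamma(state.shape[side])
                + (state.shape[side] - 1.0) * math.log(x)
                - state.rate[side] * x
            )

        expected = lgpdf(state.E[t, 0], t) - lgpdf(state.E[s, 0], s)
        # side probability appears in the assignment term and in the binomial
        # q-part, hence twice
        expected += 2.0 * (math.log(state.q[t]) - math.log(state.q[s]))
        v0 = int((state.mu == 0).sum())
        v0_new = int((flipped.mu == 0).sum())
        expected += (-_log_factorial(v0_new) - _log_factorial(2 - v0_new)) - (
            -_log_factorial(v0) - _log_factorial(2 - v0)
        )
        d_old = -1.0 if s == 0 else 1.0
        d_new = -1.0 if t == 0 else 1.0
        g_shift = d_new * state.E[t, 0] - d_old * state.E[s, 0]
        for i in range(data.n_b):
            if data.M[i, 0]:
                r_old = data.y[i] - (
                    d_old * state.E[s, 0] * data.M[i, 0]
                    + (-1.0 if state.mu[1] == 0 else 1.0)
                    * state.E[state.mu[1], 1]
                    * data.M[i, 1]
                )
                r_new = r_old - g_shift
                expected += _log_normal(r_new, shared.ybar[0], shared.V_e) - _log_normal(
                    r_old, shared.ybar[0], shared.V_e
                )
        assert delta == pytest.approx(expected, rel=1e-10)
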