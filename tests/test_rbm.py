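"""RBM conditionals, Gibbs sampling and CD updates against enumeration oracles.

The oracle used throughout enumerates the 2^(V+H) joint states of the
Boltzmann distribution with explicit Python loops — an implementation
deliberately independent of the vectorized code under test.
"""

import itertools
import math

import numpy as np
import pytest

from dbnscreen import (
    RBMParameters,
    TrainConfig,
    cd_update,
    exact_moments,
    gibbs_chain,
    hidden_conditional,
    sigmoid,
    visible_conditional,
)


def boltzmann_table(params):
    """{(v, h): probability} by explicit enumeration (oracle)."""
    V, H = params.n_visible, params.n_hidden
    weights = {}
    for v in itertools.product((0, 1), repeat=V):
        for h in itertools.product((0, 1), repeat=H):
            energy = -sum(params.a[i] * v[i] for i in range(V))
            energy -= sum(params.b[j] * h[j] for j in range(H))
            energy -= sum(params.W[i][j] * v[i] * h[j]
                          for i in range(V) for j in range(H))
            weights[(v, h)] = math.exp(-energy)
    z = sum(weights.values())
    return {k: w / z for k, w in weights.items()}


def oracle_hidden_conditional(v, params):
    table = boltzmann_table(params)
    H = params.n_hidden
    v = tuple(int(x) for x in v)
    pv = sum(p for (vv, _), p in table.items() if vv == v)
    out = []
    for j in range(H):
        pj = sum(p for (vv, hh), p in table.items() if vv == v and hh[j] == 1)
        out.append(pj / pv)
    return np.array(out)


def random_tiny_params(rng, V=3, H=2):
    return RBMParameters(
        rng.normal(scale=0.8, size=(V, H)),
        rng.normal(scale=0.5, size=V),
        rng.normal(scale=0.5, size=H),
    )


class TestSigmoid:
    def test_values(self):
        assert sigmoid(0) == 0.5
        assert sigmoid(2) == pytest.approx(0.8807970779778823, abs=1e-12)

    def test_symmetry_and_saturation(self):
        for x in (-700.0, -3.2, 0.1, 5.0, 700.0):
            assert sigmoid(x) + sigmoid(-x) == pytest.approx(1.0)
            assert 0.0 <= sigmoid(x) <= 1.0


class TestConditionals:
    def test_zero_parameters_give_half(self):
        p = RBMParameters(np.zeros((3, 2)), np.zeros(3), np.zeros(2))
        np.testing.assert_allclose(hidden_conditional([1, 0, 1], p), 0.5)
        np.testing.assert_allclose(visible_conditional([1, 0], p), 0.5)

    def test_zero_input_gives_bias_sigmoid(self):
        rng = np.random.default_rng(0)
        p = random_tiny_params(rng)
        np.testing.assert_allclose(
            hidden_conditional(np.zeros(3), p), sigmoid(p.b))
        np.testing.assert_allclose(
            visible_conditional(np.zeros(2), p), sigmoid(p.a))

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_boltzmann_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        p = random_tiny_params(rng)
        for v in itertools.product((0, 1), repeat=3):
            np.testing.assert_allclose(
                hidden_conditional(np.array(v, float), p),
                oracle_hidden_conditional(v, p),
                atol=1e-12,
            )

    def test_dimension_mismatch(self):
        p = RBMParameters(np.zeros((3, 2)), np.zeros(3), np.zeros(2))
        with pytest.raises(ValueError):
            hidden_conditional(np.zeros(4), p)
        with pytest.raises(ValueError):
            visible_conditional(np.zeros(3), p)


class TestExactMoments:
    def test_uniform_at_zero_parameters(self):
        p = RBMParameters(np.zeros((2, 2)), np.zeros(2), np.zeros(2))
        vh, pv, ph = exact_moments(p)
        np.testing.assert_allclose(vh, 0.25)
        np.testing.assert_allclose(pv, 0.5)
        np.testing.assert_allclose(ph, 0.5)

    @pytest.mark.parametrize("w", [-2.0, -0.5, 0.0, 1.0, 3.0])
    def test_one_by_one_closed_form(self, w):
        # four states: Z = 3 + e^w, <vh> = e^w / (3 + e^w)
        p = RBMParameters(np.array([[w]]), np.zeros(1), np.zeros(1))
        vh, _, _ = exact_moments(p)
        assert vh[0, 0] == pytest.approx(math.exp(w) / (3 + math.exp(w)),
                                         rel=1e-12)

    @pytest.mark.parametrize("seed", [4, 5])
    def test_agrees_with_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = random_tiny_params(rng)
        table = boltzmann_table(p)
        vh_o = np.zeros((3, 2))
        pv_o = np.zeros(3)
        ph_o = np.zeros(2)
        for (v, h), prob in table.items():
            for i in range(3):
                pv_o[i] += prob * v[i]
                for j in range(2):
                    vh_o[i, j] += prob * v[i] * h[j]
            for j in range(2):
                ph_o[j] += prob * h[j]
        vh, pv, ph = exact_moments(p)
        np.testing.assert_allclose(vh, vh_o, atol=1e-12)
        np.testing.assert_allclose(pv, pv_o, atol=1e-12)
        np.testing.assert_allclose(ph, ph_o, atol=1e-12)

    def test_factorization_of_conditionals(self):
        # p(h|v) from enumeration equals the product of per-unit conditionals
        rng = np.random.default_rng(6)
        p = random_tiny_params(rng)
        table = boltzmann_table(p)
        v = (1, 0, 1)
        pv = sum(prob for (vv, _), prob in table.items() if vv == v)
        cond = hidden_conditional(np.array(v, float), p)
        for h in itertools.product((0, 1), repeat=2):
            joint = table[(v, h)] / pv
            factored = np.prod([cond[j] if h[j] else 1 - cond[j]
                                for j in range(2)])
            assert joint == pytest.approx(factored, abs=1e-12)

    def test_rejects_large_models(self):
        p = RBMParameters(np.zeros((15, 10)), np.zeros(15), np.zeros(10))
        with pytest.raises(ValueError, match="too large"):
            exact_moments(p)


class TestGibbs:
    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(3)
        p = random_tiny_params(rng)
        v0 = np.array([1.0, 0.0, 1.0])
        out1 = gibbs_chain(v0, p, 5, np.random.default_rng(99))
        out2 = gibbs_chain(v0, p, 5, np.random.default_rng(99))
        for a, b in zip(out1, out2):
            np.testing.assert_array_equal(a, b)

    def test_fair_coin_limit_at_zero_parameters(self):
        p = RBMParameters(np.zeros((2, 2)), np.zeros(2), np.zeros(2))
        rng = np.random.default_rng(0)
        n = 10_000
        v = np.zeros(2)
        total = np.zeros(2)
        for _ in range(n):
            v, _, _, _ = gibbs_chain(v, p, 1, rng)
            total += v
        se = math.sqrt(0.25 / n)
        assert np.all(np.abs(total / n - 0.5) <= 3 * se)

    def test_positive_weight_correlates_units(self):
        # e^w/(3+e^w) > 0.25 for w > 0; check empirical joint frequency
        w = 3.0
        p = RBMParameters(np.array([[w]]), np.zeros(1), np.zeros(1))
        rng = np.random.default_rng(1)
        n = 4000
        hits = 0
        v = np.ones(1)
        for _ in range(n):
            v, h, _, _ = gibbs_chain(v, p, 1, rng)
            hits += int(v[0] == 1 and h[0] == 1)
        # exact expectation e^3/(3+e^3) ~ 0.87
        assert hits / n > 0.25


class TestCDUpdate:
    def test_zero_learning_rate_is_identity(self):
        rng = np.random.default_rng(2)
        p = random_tiny_params(rng)
        # learning_rate must be positive in config; emulate eps->0 via tiny eps
        cfg = TrainConfig(learning_rate=1e-300, epochs=1, batch_size=4,
                          gibbs_steps=1, seed=0)
        batch = np.array([[1, 0, 1], [0, 1, 0]], float)
        out = cd_update(batch, p, cfg, np.random.default_rng(0))
        np.testing.assert_allclose(out.W, p.W, atol=1e-290)
        np.testing.assert_allclose(out.a, p.a, atol=1e-290)

    def test_empty_batch_rejected(self):
        p = RBMParameters(np.zeros((2, 2)), np.zeros(2), np.zeros(2))
        cfg = TrainConfig(seed=0)
        with pytest.raises(ValueError, match="empty"):
            cd_update(np.empty((0, 2)), p, cfg, np.random.default_rng(0))

    def test_all_ones_batch_moves_visible_bias_up(self):
        # hand-computed: da = eps * (1 - <v>_model); model near uniform so
        # the update must be positive for every visible unit
        p = RBMParameters(np.zeros((3, 2)), np.zeros(3), np.zeros(2))
        cfg = TrainConfig(learning_rate=0.5, epochs=1, batch_size=8,
                          gibbs_steps=1, seed=0)
        batch = np.ones((8, 3))
        out = cd_update(batch, p, cfg, np.random.default_rng(5))
        assert np.all(out.a > p.a)
        assert np.all(out.a - p.a <= 0.5)   # bounded by eps * 1

    def test_fixed_point_when_data_matches_model_moments(self):
        # draw a large sample from the model itself; expected update ~ 0
        rng = np.random.default_rng(8)
        p = random_tiny_params(rng, V=2, H=2)
        vh, pv, ph = exact_moments(p)
        # sample exact model visible marginal by enumeration of p(v)
        states = list(itertools.product((0, 1), repeat=2))
        table = boltzmann_table(p)
        probs = [sum(t for (vv, _), t in table.items() if vv == s)
                 for s in states]
        n = 6000
        idx = rng.choice(len(states), size=n, p=probs)
        batch = np.array([states[i] for i in idx], float)
        cfg = TrainConfig(learning_rate=1.0, epochs=1, batch_size=n,
                          gibbs_steps=25, seed=0)
        out = cd_update(batch, p, cfg, rng)
        # Monte-Carlo s.e. of a Bernoulli moment at n samples
        se = 3.0 / math.sqrt(n)
        assert np.abs(out.W - p.W).max() < se
        assert np.abs(out.a - p.a).max() < se
        assert np.abs(out.b - p.b).max() < se

    def test_cd_with_exact_moments_increases_likelihood(self):
        # CD-infinity oracle: substituting exact model moments must ascend
        # the data log-likelihood for small learning rates
        rng = np.random.default_rng(9)
        p = random_tiny_params(rng, V=2, H=2)
        data = np.array([[1, 1], [1, 1], [1, 0], [0, 1]], float)

        def loglik(params):
            table = boltzmann_table(params)
            out = 0.0
            for row in data:
                v = tuple(int(x) for x in row)
                out += math.log(sum(t for (vv, _), t in table.items()
                                    if vv == v))
            return out

        eps = 0.05
        ph_data = hidden_conditional(data, p)
        vh_data = data.T @ ph_data / len(data)
        vh_m, pv_m, ph_m = exact_moments(p)
        stepped = RBMParameters(
            p.W + eps * (vh_data - vh_m),
            p.a + eps * (data.mean(axis=0) - pv_m),
            p.b + eps * (ph_data.mean(axis=0) - ph_m),
        )
        assert loglik(stepped) > loglik(p)
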