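"""Rate computations and the joint log density against independent oracles."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm, poisson

from prrr import (
    CountMatrix,
    FactorPair,
    PriorConfig,
    SizeFactors,
    log_joint,
    nnprrr_rates,
    prrr_rates,
)


def loop_rates_prrr(X, U, V):
    """Entrywise triple-loop oracle for exp(X U V^T)."""
    n, p = X.shape
    q, r = V.shape
    out = np.empty((n, q))
    for i in range(n):
        for j in range(q):
            acc = 0.0
            for k in range(r):
                acc += sum(X[i, a] * U[a, k] for a in range(p)) * V[j, k]
            out[i, j] = np.exp(acc)
    return out


def loop_rates_nnprrr(X, U, V, s):
    n, p = X.shape
    q, r = V.shape
    out = np.empty((n, q))
    for i in range(n):
        for j in range(q):
            acc = 0.0
            for k in range(r):
                acc += sum(X[i, a] * U[a, k] for a in range(p)) * V[j, k]
            out[i, j] = s[i] * acc + 1e-8
    return out


dims = st.integers(min_value=1, max_value=5)


class TestLogLinkRates:
    def test_zero_factors_give_unit_rates(self, rng):
        F = FactorPair(np.zeros((4, 2)), np.zeros((6, 2)))
        np.testing.assert_array_equal(prrr_rates(rng.normal(size=(3, 4)), F), np.ones((3, 6)))

    def test_scalar_link(self):
        F = FactorPair(np.array([[0.5]]), np.array([[1.0]]))
        rate = prrr_rates(np.array([[2.0]]), F)
        np.testing.assert_allclose(rate, [[np.exp(1.0)]])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(n=dims, p=dims, q=dims, r=dims, seed=st.integers(0, 1000))
    def test_matches_triple_loop(self, n, p, q, r, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        U, V = rng.normal(size=(p, r)), rng.normal(size=(q, r))
        np.testing.assert_allclose(
            prrr_rates(X, FactorPair(U, V)), loop_rates_prrr(X, U, V), atol=1e-10, rtol=1e-10
        )

    def test_clipping_keeps_rates_finite(self):
        F = FactorPair(np.array([[100.0]]), np.array([[100.0]]))
        rate = prrr_rates(np.array([[10.0]]), F)
        assert np.isfinite(rate).all() and rate[0, 0] == np.exp(30.0)

    def test_dimension_mismatch_message(self):
        F = FactorPair(np.ones((4, 1)), np.ones((2, 1)))
        with pytest.raises(ValueError, match="4"):
            prrr_rates(np.ones((3, 5)), F)


class TestIdentityLinkRates:
    def test_hand_arithmetic(self):
        F = FactorPair(np.array([[1.0], [1.0]]), np.array([[0.5]]))
        rate = nnprrr_rates(np.array([[1.0, 1.0]]), F, SizeFactors([10.0]))
        np.testing.assert_allclose(rate, [[10.0]], atol=1e-7)

    def test_zero_covariate_row_hits_floor(self):
        F = FactorPair(np.ones((2, 1)), np.ones((3, 1)))
        X = np.array([[0.0, 0.0], [1.0, 0.0]])
        rate = nnprrr_rates(X, F, SizeFactors([5.0, 5.0]))
        np.testing.assert_allclose(rate[0], 1e-8)
        assert (rate[1] > 1.0).all()

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(n=dims, p=dims, q=dims, r=dims, seed=st.integers(0, 1000))
    def test_matches_triple_loop(self, n, p, q, r, seed):
        rng = np.random.default_rng(seed)
        X = rng.uniform(0, 2, size=(n, p))
        U, V = rng.gamma(2.0, 1.0, size=(p, r)), rng.gamma(2.0, 1.0, size=(q, r))
        s = rng.uniform(1, 10, size=n)
        np.testing.assert_allclose(
            nnprrr_rates(X, FactorPair(U, V), SizeFactors(s)),
            loop_rates_nnprrr(X, U, V, s),
            atol=1e-10,
            rtol=1e-9,
        )

    def test_negative_inputs_rejected(self):
        F = FactorPair(np.ones((2, 1)), np.ones((2, 1)))
        with pytest.raises(ValueError):
            nnprrr_rates(np.array([[-1.0, 0.0]]), F, SizeFactors([1.0]))
        with pytest.raises(ValueError):
            nnprrr_rates(np.ones((1, 2)), FactorPair(-np.ones((2, 1)), np.ones((2, 1))), SizeFactors([1.0]))

    def test_scaling_invariance_of_rates(self, rng):
        """(U*c, V/c) leaves the rates unchanged — B is what is identified."""
        U, V = rng.gamma(2, 1, size=(3, 2)), rng.gamma(2, 1, size=(4, 2))
        X = rng.uniform(0, 2, size=(5, 3))
        s = SizeFactors(rng.uniform(1, 5, size=5))
        for c in (0.1, 3.7):
            np.testing.assert_allclose(
                nnprrr_rates(X, FactorPair(U, V), s),
                nnprrr_rates(X, FactorPair(U * c, V / c), s),
                rtol=1e-10,
            )


class TestLogJoint:
    def test_poisson_term_at_unit_rate(self):
        """U = 0 forces rate 1; with a flat prior the data term is log e^-1."""
        F = FactorPair(np.zeros((1, 1)), np.zeros((1, 1)))
        prior = PriorConfig(sigma2_u=1e6, sigma2_v=1e6)
        lj = log_joint(np.ones((1, 1)), CountMatrix(np.zeros((1, 1))), F, prior, "prrr")
        prior_term = 2 * norm.logpdf(0.0, scale=1e3)
        np.testing.assert_allclose(lj - prior_term, -1.0, atol=1e-10)

    def test_per_term_oracle(self, rng):
        """Joint equals independently computed prior + Poisson log-pmf sums."""
        X = rng.normal(size=(3, 2))
        U, V = rng.normal(size=(2, 1)) * 0.5, rng.normal(size=(2, 1)) * 0.5
        F = FactorPair(U, V)
        rates = np.exp(X @ U @ V.T)
        Y = rng.poisson(rates)
        prior = PriorConfig(sigma2_u=2.0, sigma2_v=0.5)
        expected = (
            norm.logpdf(U, scale=np.sqrt(2.0)).sum()
            + norm.logpdf(V, scale=np.sqrt(0.5)).sum()
            + poisson.logpmf(Y, rates).sum()
        )
        lj = log_joint(X, CountMatrix(Y), F, prior, "prrr")
        np.testing.assert_allclose(lj, expected, atol=1e-8)

    def test_gamma_per_term_oracle(self, rng):
        from scipy.stats import gamma as gamma_dist

        X = rng.uniform(0, 2, size=(4, 3))
        U, V = rng.gamma(2, 1, size=(3, 2)), rng.gamma(2, 1, size=(2, 2))
        F = FactorPair(U, V)
        Y = CountMatrix(rng.poisson(5.0, size=(4, 2)))
        s = Y.values.sum(axis=1).astype(float)
        rates = s[:, None] * (X @ U @ V.T) + 1e-8
        prior = PriorConfig.for_model("nnprrr")
        expected = (
            gamma_dist.logpdf(U, a=2.0, scale=1.0).sum()
            + gamma_dist.logpdf(V, a=2.0, scale=1.0).sum()
            + poisson.logpmf(Y.values, rates).sum()
        )
        np.testing.assert_allclose(log_joint(X, Y, F, prior, "nnprrr"), expected, atol=1e-8)

    def test_doubling_data_doubles_likelihood_term(self, rng):
        X = rng.normal(size=(4, 3))
        Y = rng.poisson(2.0, size=(4, 5))
        F = FactorPair(rng.normal(size=(3, 2)) * 0.3, rng.normal(size=(5, 2)) * 0.3)
        prior = PriorConfig()
        prior_term = (
            norm.logpdf(F.U).sum() + norm.logpdf(F.V).sum()
        )
        lj1 = log_joint(X, CountMatrix(Y), F, prior, "prrr")
        lj2 = log_joint(
            np.vstack([X, X]), CountMatrix(np.vstack([Y, Y])), F, prior, "prrr"
        )
        np.testing.assert_allclose(lj2 - prior_term, 2 * (lj1 - prior_term), rtol=1e-12)

    def test_monotone_in_excess_counts(self):
        """Counts far above the rate strictly decrease the joint."""
        X = np.ones((1, 1))
        F = FactorPair(np.zeros((1, 1)), np.zeros((1, 1)))
        prior = PriorConfig()
        vals = [
            log_joint(X, CountMatrix(np.array([[y]])), F, prior, "prrr")
            for y in (5, 10, 20)
        ]
        assert vals[0] > vals[1] > vals[2]

    def test_family_model_mismatch(self):
        F = FactorPair(np.ones((1, 1)), np.ones((1, 1)))
        with pytest.raises(ValueError, match="family"):
            log_joint(np.ones((1, 1)), CountMatrix(np.ones((1, 1))), F, PriorConfig(), "nnprrr")
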