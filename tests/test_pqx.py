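"""Unit and property tests for the PQX distribution layer."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.special import logsumexp

from pqxinar import pqx
from pqxinar.exceptions import DomainError, ParameterError
from pqxinar.pqx import (
    MeanPQXParams,
    NBParams,
    PQXParams,
    classify_modality,
    nb_reference,
)

from conftest import support_window, truncated_moments

param_strategy = st.tuples(
    st.floats(0.0, 30.0), st.floats(0.05, 10.0)
).map(lambda at: PQXParams(*at))


class TestPmfCdf:
    def test_known_values(self):
        # alpha=0 is NB(3, 1/2): pmf(0) = (1/2)^3
        assert pqx.pmf(0, PQXParams(0.0, 1.0)) == pytest.approx(0.125, abs=1e-15)
        # direct arithmetic: (2*3*1.5*6.25 + 3.375*2) / (2*4*2.5^3) = 63/125
        assert pqx.pmf(0, PQXParams(3.0, 1.5)) == pytest.approx(0.504, abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(param_strategy)
    def test_normalization(self, params):
        x = support_window(params)
        assert np.sum(pqx.pmf(x, params)) == pytest.approx(1.0, abs=1e-12)

    def test_cdf_increments_equal_pmf(self, random_params):
        for params in random_params[:10]:
            x = np.arange(1, 40)
            inc = pqx.cdf(x, params) - pqx.cdf(x - 1, params)
            np.testing.assert_allclose(inc, pqx.pmf(x, params), atol=1e-12)
            assert pqx.cdf(0, params) == pytest.approx(pqx.pmf(0, params), abs=1e-14)

    def test_sf_matches_log_space_summation(self):
        # tail cross-check down to ~1e-13: closed form vs summed pmf
        params = PQXParams(3.0, 1.5)
        for x in (0, 5, 10, 15, 20):
            upper = np.arange(x + 1, 400)
            summed = logsumexp(pqx.logpmf(upper, params))
            assert pqx.logsf(x, params) == pytest.approx(summed, abs=1e-10)

    def test_tail_monotone_positive(self, random_params):
        for params in random_params[:10]:
            x = support_window(params, tail=1e-12)
            s = pqx.sf(x, params)
            assert np.all(s > 0)
            assert np.all(np.diff(s) < 0)

    def test_printed_tail_cells(self):
        # mean-parametrized spot cells from the tail-comparison table
        p = MeanPQXParams(mu=1.0, theta=1.5).to_pqx()
        assert p.alpha == pytest.approx(3.0)
        assert pqx.sf(5, p) == pytest.approx(0.01552, abs=5e-6)
        p2 = MeanPQXParams(mu=0.5, theta=3.0).to_pqx()
        assert pqx.sf(10, p2) == pytest.approx(2.943e-6, rel=5e-4)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            pqx.pmf(-1, PQXParams(1.0, 1.0))
        with pytest.raises(DomainError):
            pqx.pmf(1.5, PQXParams(1.0, 1.0))
        with pytest.raises(ParameterError):
            PQXParams(-0.5, 1.0)
        with pytest.raises(ParameterError):
            PQXParams(1.0, 0.0)


class TestMoments:
    def test_factorial_moments(self):
        p = PQXParams(0.5, 1.5)
        assert pqx.factorial_moment(1, p) == pytest.approx(3.5 / 2.25, rel=1e-12)
        assert pqx.factorial_moment(1, PQXParams(0.0, 1.0)) == pytest.approx(3.0)
        # second factorial moment vs direct sum of x(x-1) pmf(x)
        x = support_window(p)
        direct = float(np.sum(x * (x - 1) * pqx.pmf(x, p)))
        assert pqx.factorial_moment(2, p) == pytest.approx(direct, rel=1e-10)
        assert pqx.factorial_moment(2, p) == pytest.approx(3.85185, abs=1e-5)
        with pytest.raises(DomainError):
            pqx.factorial_moment(0, p)

    def test_closed_forms_match_truncated_sums(self, random_params):
        for params in random_params[:12]:
            oracle = truncated_moments(params)
            closed = pqx.moments(params)
            for key in oracle:
                assert closed[key] == pytest.approx(oracle[key], rel=1e-8), key

    def test_dispersion_index_value(self):
        # 1 + (0.5*8.5 + 3)/(1.5*3.5*1.5); oracle = Var/E of the truncated pmf
        p = PQXParams(0.5, 1.5)
        assert pqx.dispersion_index(p) == pytest.approx(1.0 + 7.25 / 7.875, rel=1e-12)
        assert pqx.dispersion_index(p) == pytest.approx(
            truncated_moments(p)["dispersion_index"], rel=1e-9
        )

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(1e-6, 1e3), st.floats(1e-3, 1e3))
    def test_overdispersed_everywhere(self, alpha, theta):
        assert pqx.dispersion_index(PQXParams(alpha, theta)) > 1.0

    def test_geometric_limit_mean(self):
        # alpha -> infinity at theta=1 tends to geometric(1/2) with mean 1
        assert pqx.mean(PQXParams(1e6, 1.0)) == pytest.approx(1.0, abs=1e-4)


class TestReductions:
    @pytest.mark.parametrize("theta", [0.5, 1.0, 2.5])
    def test_alpha_zero_is_nb3(self, theta):
        x = np.arange(60)
        ours = pqx.pmf(x, PQXParams(0.0, theta))
        nb = stats.nbinom(3, theta / (theta + 1.0)).pmf(x)
        np.testing.assert_allclose(ours, nb, rtol=1e-12, atol=1e-300)

    def test_alpha_large_is_geometric(self):
        theta = 1.2
        x = np.arange(200)
        ours = pqx.pmf(x, PQXParams(1e6, theta))
        geom = stats.nbinom(1, theta / (theta + 1.0)).pmf(x)
        assert 0.5 * np.sum(np.abs(ours - geom)) < 1e-4  # total variation


class TestGeneratingFunctions:
    def test_pgf_identities(self):
        p = PQXParams(0.7, 1.3)
        assert pqx.pgf(1.0, p) == pytest.approx(1.0, abs=1e-12)
        assert pqx.pgf(0.0, p) == pytest.approx(pqx.pmf(0, p), abs=1e-12)
        h = 1e-6
        deriv = (pqx.pgf(1.0, p) - pqx.pgf(1.0 - h, p)) / h
        assert deriv == pytest.approx(pqx.mean(p), rel=1e-4)

    def test_pgf_matches_series(self):
        p = PQXParams(2.0, 0.9)
        s = 0.6
        x = support_window(p)
        assert pqx.pgf(s, p) == pytest.approx(float(np.sum(s**x * pqx.pmf(x, p))), rel=1e-10)

    def test_mgf_divergence(self):
        p = PQXParams(1.0, 1.0)
        assert pqx.mgf(0.0, p) == pytest.approx(1.0)
        with pytest.raises(DomainError):
            pqx.mgf(math.log(2.0) + 0.01, p)  # e^t >= theta+1 = 2

    def test_pgf_domain(self):
        with pytest.raises(DomainError):
            pqx.pgf(1.5, PQXParams(1.0, 1.0))


class TestMeanParametrization:
    def test_substitution_identity(self):
        mp = MeanPQXParams(mu=1.0, theta=1.5)
        x = np.arange(30)
        np.testing.assert_allclose(
            pqx.mean_parametrized_pmf(x, mp),
            pqx.pmf(x, PQXParams(3.0, 1.5)),
            rtol=1e-12,
        )

    @pytest.mark.parametrize("mu,theta", [(0.5, 4.0), (1.0, 2.0), (2.0, 1.2)])
    def test_mean_contract(self, mu, theta):
        assert pqx.mean(MeanPQXParams(mu, theta).to_pqx()) == pytest.approx(mu, rel=1e-12)

    def test_domain(self):
        with pytest.raises(ParameterError):
            MeanPQXParams(mu=1.0, theta=3.01)
        with pytest.raises(ParameterError):
            MeanPQXParams(mu=1.0, theta=0.9)


class TestNBReference:
    def test_printed_tail_cells(self):
        nb = nb_reference(NBParams.from_mean(mu=1.0, size=1.5))
        assert nb.sf(5) == pytest.approx(0.00973, abs=5e-6)
        nb2 = nb_reference(NBParams.from_mean(mu=1.0, size=2.0))
        assert nb2.sf(10) == pytest.approx(4.704e-5, rel=1e-3)

    def test_moment_formulas(self):
        nb = nb_reference(NBParams(size=0.5, prob=0.5))
        assert nb.skewness == pytest.approx(3.0, rel=1e-12)
        assert nb.mean == pytest.approx(0.5, rel=1e-12)
        assert nb.kurtosis == pytest.approx(3.0 + 12.0 + 0.25 / 0.25, rel=1e-12)
        with pytest.raises(ParameterError):
            NBParams(size=1.0, prob=1.0)


def brute_force_modes(params: PQXParams) -> set:
    """Local maxima of the pmf over a generous window (independent oracle)."""
    n = max(60, int(10 * pqx.mean(params)))
    lp = pqx.logpmf(np.arange(n), params)
    modes = set()
    for i in range(n - 1):
        left_ok = i == 0 or lp[i] >= lp[i - 1] - 1e-12
        right_ok = lp[i] >= lp[i + 1] - 1e-12
        if left_ok and right_ok:
            modes.add(i)
    return modes


class TestModality:
    @pytest.mark.parametrize(
        "alpha,theta,category,modes",
        [
            (1.0, 2.5, "unimodal-at-zero", {0}),
            (0.5, 1.0, "unimodal-at-zero", {0}),
            (0.25, 1.0, "mode-at-one", {0, 1}),  # alpha = theta(2-theta)/(1+theta)^2
            (0.1, 1.0, "unimodal-interior", None),
            (0.3, 0.2, "bimodal", {0, 7}),
            # nominally in the bimodal strip, but no integer falls in the
            # ratio>1 interval so the pmf is strictly decreasing
            (0.34, 0.5, "unimodal-at-zero", {0}),
        ],
    )
    def test_classification(self, alpha, theta, category, modes):
        result = classify_modality(PQXParams(alpha, theta))
        assert result.category == category
        if modes is not None:
            assert set(result.modes) == modes

    def test_agrees_with_brute_force(self, rng):
        # structured + random grid covering all four regions
        grid = [(1.0, 2.5), (2.0, 0.5), (0.5, 1.0), (0.1, 1.0), (0.05, 0.3),
                (0.3, 0.2), (0.3, 0.25), (0.34, 0.5), (0.2, 1.5)]
        grid += [(float(a), float(t))
                 for a, t in zip(rng.uniform(0.01, 3, 40), rng.uniform(0.05, 3, 40))]
        for alpha, theta in grid:
            params = PQXParams(alpha, theta)
            declared = classify_modality(params)
            brute = brute_force_modes(params)
            lp = pqx.logpmf(np.arange(max(60, int(10 * pqx.mean(params)))), params)
            argmax = int(np.argmax(lp))
            assert argmax in declared.modes, (alpha, theta, declared, argmax)
            assert set(declared.modes) <= brute, (alpha, theta, declared, brute)
            if declared.category == "bimodal":
                assert 0 in declared.modes and len(declared.modes) >= 2


class TestSampling:
    def test_deterministic_under_seed(self):
        p = PQXParams(3.0, 1.5)
        a = pqx.rvs(1000, p, seed=42)
        b = pqx.rvs(1000, p, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_mean_within_three_se(self):
        p = PQXParams(0.5, 1.5)
        draws = pqx.rvs(100_000, p, seed=7)
        se = math.sqrt(pqx.variance(p) / draws.size)
        assert abs(draws.mean() - 3.5 / 2.25) < 3 * se

    def test_chi_square_gof(self):
        p = PQXParams(3.0, 1.5)
        draws = pqx.rvs(100_000, p, seed=11)
        kmax = 12
        observed = np.bincount(np.minimum(draws, kmax), minlength=kmax + 1)
        probs = pqx.pmf(np.arange(kmax), p)
        probs = np.append(probs, pqx.sf(kmax - 1, p))
        stat, pval = stats.chisquare(observed, probs * draws.size)
        assert pval > 0.01

    def test_invalid_size(self):
        with pytest.raises(DomainError):
            pqx.rvs(0, PQXParams(1.0, 1.0), seed=1)
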