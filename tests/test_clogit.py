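import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import comb

from rfjem import clogit
from rfjem.errors import DataError, NotConvergedError


def brute_force_loglik(eta, case):
    """Exhaustive enumeration over all case subsets of the observed size."""
    eta = np.asarray(eta, float)
    case = np.asarray(case, bool)
    d, n = int(case.sum()), len(eta)
    num = eta[case].sum()
    den = np.logaddexp.reduce(
        [eta[list(S)].sum() for S in itertools.combinations(range(n), d)]
    )
    return float(num - den)


@st.composite
def stratum(draw, max_n=10):
    n = draw(st.integers(2, max_n))
    d = draw(st.integers(1, n - 1))
    eta = draw(st.lists(st.floats(-4, 4), min_size=n, max_size=n))
    case = np.zeros(n, bool)
    case[draw(st.permutations(range(n)))[:d]] = True
    return np.array(eta), case


class TestStratumLoglik:
    def test_equal_predictors_give_combinatorial_value(self):
        for n, d in [(5, 2), (8, 3), (12, 6)]:
            eta = np.full(n, 1.7)
            case = np.zeros(n, bool)
            case[:d] = True
            ll, _ = clogit.stratum_loglik(eta, case)
            assert ll == pytest.approx(-np.log(comb(n, d, exact=True)), abs=1e-12)

    def test_matched_pair_closed_form(self):
        for beta in (-2.0, 0.0, 0.5, 3.0):
            ll, _ = clogit.stratum_loglik([beta, 0.0], [True, False])
            assert ll == pytest.approx(beta - np.log1p(np.exp(beta)), abs=1e-12)

    def test_non_informative_stratum_contributes_zero(self):
        ll, grad = clogit.stratum_loglik([1.0, 2.0], [True, True])
        assert ll == 0.0 and np.all(grad == 0)

    @given(stratum())
    @settings(max_examples=150, deadline=None)
    def test_matches_exhaustive_enumeration(self, s):
        eta, case = s
        ll, grad = clogit.stratum_loglik(eta, case)
        assert ll == pytest.approx(brute_force_loglik(eta, case), abs=1e-10)

    @given(stratum(), st.floats(-30, 30))
    @settings(max_examples=100, deadline=None)
    def test_shift_invariance(self, s, shift):
        eta, case = s
        ll, _ = clogit.stratum_loglik(eta, case)
        ll2, _ = clogit.stratum_loglik(eta + shift, case)
        assert ll2 == pytest.approx(ll, abs=1e-8)

    def test_large_stratum_is_stable(self):
        rng = np.random.default_rng(5)
        eta = rng.normal(0, 3, 500)
        case = np.zeros(500, bool)
        case[:200] = True
        ll, grad = clogit.stratum_loglik(eta, case)
        assert np.isfinite(ll) and ll < 0
        assert np.all(np.isfinite(grad))


@pytest.fixture(scope="module")
def simulated_design():
    rng = np.random.default_rng(17)
    n = 600
    strata = rng.integers(0, 60, n)
    X = rng.normal(0, 1, (n, 3))
    beta = np.array([0.8, 0.0, -0.5])
    eta = X @ beta + 0.3 * rng.standard_normal(60)[strata]
    y = rng.random(n) < 1 / (1 + np.exp(-eta))
    return X, y, strata


class TestFit:
    def test_null_design_gives_closed_form_loglik(self, simulated_design):
        X, y, strata = simulated_design
        fit = clogit.fit_clogit(np.empty((len(y), 0)), y, strata)
        assert fit.loglik == pytest.approx(clogit.null_loglik(y, strata), abs=1e-12)
        assert fit.converged

    def test_all_zero_covariates_return_null_fit(self, simulated_design):
        X, y, strata = simulated_design
        fit = clogit.fit_clogit(np.zeros((len(y), 2)), y, strata)
        assert np.allclose(fit.beta, 0.0)
        assert fit.loglik == pytest.approx(clogit.null_loglik(y, strata))

    def test_matches_independent_implementation(self, simulated_design):
        from statsmodels.discrete.conditional_models import ConditionalLogit

        X, y, strata = simulated_design
        fit = clogit.fit_clogit(X, y, strata)
        sm = ConditionalLogit(y.astype(int), X, groups=strata).fit(disp=0)
        assert np.max(np.abs(fit.beta - sm.params)) < 1e-4
        assert np.max(np.abs(fit.se - sm.bse)) < 1e-4
        assert fit.loglik == pytest.approx(sm.llf, abs=1e-5)

    def test_order_invariance(self, simulated_design):
        X, y, strata = simulated_design
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(y))
        fit = clogit.fit_clogit(X, y, strata)
        fit_p = clogit.fit_clogit(X[perm], y[perm], strata[perm])
        assert np.allclose(fit.beta, fit_p.beta, atol=1e-9)
        assert fit.loglik == pytest.approx(fit_p.loglik, abs=1e-9)

    def test_breslow_equals_exact_for_matched_pairs(self):
        rng = np.random.default_rng(11)
        n_pairs = 150
        strata = np.repeat(np.arange(n_pairs), 2)
        X = rng.normal(0, 1, (2 * n_pairs, 1))
        y = np.tile([True, False], n_pairs)
        exact = clogit.fit_clogit(X, y, strata, method="exact")
        bres = clogit.fit_clogit(X, y, strata, method="breslow")
        # with one case per stratum the Breslow denominator is the exact one
        assert np.allclose(exact.beta, bres.beta, atol=1e-6)

    def test_separation_is_flagged_not_silent(self):
        # case always has the larger covariate: monotone likelihood
        strata = np.repeat(np.arange(30), 2)
        X = np.tile([1.0, 0.0], 30)[:, None]
        y = np.tile([True, False], 30)
        fit = clogit.fit_clogit(X, y, strata)
        assert not fit.converged
        assert fit.monotone_likelihood
        with pytest.raises(NotConvergedError):
            clogit.odds_ratios(fit)

    def test_non_informative_strata_dropped_and_counted(self):
        strata = np.array([1, 1, 2, 2, 3, 3])
        y = np.array([True, False, True, True, False, False])
        X = np.zeros((6, 0))
        fit = clogit.fit_clogit(X, y, strata)
        assert fit.n_informative_strata == 1
        assert fit.n_dropped_strata == 2

    def test_no_informative_strata_is_error(self):
        with pytest.raises(DataError):
            clogit.fit_clogit(np.zeros((4, 1)),
                              np.array([True, True, False, False]),
                              np.array([1, 1, 2, 2]))


class TestOddsRatios:
    def test_wald_interval_formula(self):
        fit = clogit.ClogitFit(
            beta=np.array([0.0, np.log(1.36)]),
            cov=np.diag([0.1 ** 2, 0.05 ** 2]),
            loglik=-10.0, n_informative_strata=5, n_dropped_strata=0,
            converged=True, iterations=3, names=["a", "b"],
        )
        table = clogit.odds_ratios(fit)
        assert table.loc[0, "OR"] == pytest.approx(1.0)
        assert table.loc[0, "CI_low"] == pytest.approx(0.82, abs=0.005)
        assert table.loc[0, "CI_high"] == pytest.approx(1.22, abs=0.005)
        assert table.loc[1, "OR"] == pytest.approx(1.36)
        assert (table["CI_low"] <= table["OR"]).all()
        assert (table["OR"] <= table["CI_high"]).all()


class TestTrend:
    def test_constant_score_gives_p_one(self):
        strata = np.repeat(np.arange(20), 3)
        y = np.tile([True, False, False], 20)
        score = np.ones(60)
        t = clogit.trend_test(score, y, strata)
        assert t.p_value == 1.0
        assert t.beta == 0.0

    def test_monotone_effect_detected(self):
        rng = np.random.default_rng(23)
        n = 900
        strata = rng.integers(0, 45, n)
        score = rng.integers(0, 5, n).astype(float)
        eta = 0.4 * score
        y = rng.random(n) < 1 / (1 + np.exp(-(eta - 1.0)))
        t = clogit.trend_test(score, y, strata)
        assert t.beta > 0
        assert t.p_value < 0.01
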