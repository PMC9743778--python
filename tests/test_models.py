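"""Likelihoods and ML fits for the eight count-regression families."""

import numpy as np
import pytest
from scipy import optimize, special, stats

from prrtest import FAMILIES, CountTable, CountTableError, fit_ml, get_family, log_likelihood

from conftest import random_counts


def oracle_loglik(family, params, y, X, Z, s):
    """Independent log-likelihood built from scipy.stats pmfs (never from the
    package's own density code)."""
    kx = X.shape[1]
    kz = Z.shape[1] if family.zero_inflated else 0
    alpha = params[:kx]
    beta = params[kx : kx + kz]
    aux = params[kx + kz] if family.overdispersed else None
    if family.binomial_type:
        p = special.expit(X @ alpha)
        if family.base == "binomial":
            base = stats.binom.logpmf(y, s.astype(int), p)
        else:
            rho = special.expit(aux)
            gam = (1 - rho) / rho
            base = stats.betabinom.logpmf(y, s.astype(int), p * gam, (1 - p) * gam)
    else:
        mu = np.exp(X @ alpha) * s
        if family.base == "poisson":
            base = stats.poisson.logpmf(y, mu)
        else:
            theta = np.exp(aux)
            base = stats.nbinom.logpmf(y, theta, theta / (theta + mu))
    if not family.zero_inflated:
        return float(np.sum(base))
    pi = special.expit(Z @ beta)
    f = np.where(y == 0, pi + (1 - pi) * np.exp(base), (1 - pi) * np.exp(base))
    return float(np.sum(np.log(f)))


class TestLogLikelihood:
    def test_poisson_unit_example(self):
        # intercept 0, s=1 (zero offset), y=1: log f = -1 exactly
        ll = log_likelihood("Poisson", [0.0], [1], [[1.0]], s=[1.0])
        assert ll == pytest.approx(-1.0, abs=1e-12)

    def test_zero_inflation_vanishes_at_negative_infinity_intercept(self):
        # pi -> 0 makes the mixture collapse onto the plain Poisson
        y = np.array([0, 1, 3, 0, 2])
        X = np.ones((5, 1))
        s = np.full(5, 2.0)
        plain = log_likelihood("Poisson", [0.3], y, X, s=s)
        mixed = log_likelihood("ZIPoisson", [0.3, -40.0], y, X, Z=X, s=s)
        assert mixed == pytest.approx(plain, abs=1e-8)

    def test_negbin_poisson_limit_matches_independent_pmf(self):
        # huge size parameter: NB(mean 1, theta -> inf) -> Poisson(1)
        y = np.array([0, 1, 2])
        s = np.ones(3)
        ours = log_likelihood(
            "NegativeBinomial", [0.0, 11.9], y, np.ones((3, 1)), s=s
        )
        oracle = float(stats.poisson.logpmf(y, 1.0).sum())
        assert ours == pytest.approx(oracle, abs=1e-4)

    @pytest.mark.parametrize("name", list(FAMILIES))
    def test_matches_scipy_density_at_arbitrary_params(self, name):
        family = FAMILIES[name]
        rng = np.random.default_rng(3)
        n = 40
        s = rng.integers(50, 200, n).astype(float)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        Z = X if family.zero_inflated else np.empty((n, 0))
        y = random_counts(rng, n, family, s)
        params = rng.normal(0, 0.5, 2 + Z.shape[1] + family.n_aux)
        params[0] = -3.0
        ours = log_likelihood(family, params, y, X, Z if family.zero_inflated else None, s)
        assert ours == pytest.approx(oracle_loglik(family, params, y, X, Z, s), abs=1e-6)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="non-negative integers"):
            log_likelihood("Poisson", [0.0], [-1], [[1.0]], s=[1.0])
        with pytest.raises(ValueError, match="non-negative integers"):
            log_likelihood("Poisson", [0.0], [1.5], [[1.0]], s=[1.0])
        # counts above the trial size are impossible, not an exception
        assert log_likelihood("Binomial", [0.0], [5], [[1.0]], s=[2.0]) == -np.inf


class TestFitClosedForms:
    def test_poisson_intercept_is_log_rate(self):
        rng = np.random.default_rng(0)
        s = rng.integers(100, 1000, 50).astype(float)
        y = rng.poisson(0.02 * s)
        fr = fit_ml("Poisson", y, np.ones((50, 1)), s=s)
        assert fr.converged
        assert fr.alpha[0] == pytest.approx(np.log(y.sum() / s.sum()), abs=1e-8)

    def test_binomial_intercept_is_logit_proportion(self):
        rng = np.random.default_rng(1)
        s = rng.integers(100, 1000, 50).astype(float)
        y = rng.binomial(s.astype(int), 0.03)
        fr = fit_ml("Binomial", y, np.ones((50, 1)), s=s)
        assert fr.converged
        assert fr.alpha[0] == pytest.approx(
            special.logit(y.sum() / s.sum()), abs=1e-8
        )

    @pytest.mark.parametrize("name", list(FAMILIES))
    def test_intercept_only_mean_matches_closed_form_on_equal_exposure(self, name):
        """With equal library sizes every family's fitted mean-component
        intercept reproduces the closed-form rate / proportion."""
        family = FAMILIES[name]
        rng = np.random.default_rng(5)
        n = 300
        s = np.full(n, 500.0)
        y = rng.poisson(12.0, n)  # no zero excess, no overdispersion signal
        Z = np.ones((n, 1)) if family.zero_inflated else None
        fr = fit_ml(family, y, np.ones((n, 1)), Z, s=s)
        rate = y.sum() / s.sum()
        expected = special.logit(rate) if family.binomial_type else np.log(rate)
        # ZI families may explain a sliver of mass via the zero component
        tol = 1e-6 if not family.zero_inflated else 5e-3
        assert fr.alpha[0] == pytest.approx(expected, abs=tol)


class TestFitProperties:
    @pytest.mark.parametrize("pair", [
        ("Poisson", "ZIPoisson"),
        ("Poisson", "NegativeBinomial"),
        ("Binomial", "ZIBinomial"),
        ("Binomial", "BetaBinomial"),
        ("NegativeBinomial", "ZINegativeBinomial"),
        ("BetaBinomial", "ZIBetaBinomial"),
    ])
    def test_nested_family_never_fits_worse(self, pair):
        base_name, bigger_name = pair
        rng = np.random.default_rng(11)
        n = 80
        s = rng.integers(100, 500, n).astype(float)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = random_counts(rng, n, get_family(bigger_name), s)
        Zb = X if get_family(bigger_name).zero_inflated else None
        Zs = X if get_family(base_name).zero_inflated else None
        small = fit_ml(base_name, y, X, Zs, s=s)
        big = fit_ml(bigger_name, y, X, Zb, s=s)
        assert big.loglik >= small.loglik - 1e-6

    @pytest.mark.parametrize("name", ["Poisson", "NegativeBinomial",
                                      "ZIPoisson", "ZINegativeBinomial"])
    def test_doubling_exposure_shifts_only_the_intercept(self, name):
        family = get_family(name)
        rng = np.random.default_rng(13)
        n = 150
        s = rng.integers(100, 500, n).astype(float)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = random_counts(rng, n, family, s)
        Z = X if family.zero_inflated else None
        f1 = fit_ml(family, y, X, Z, s=s)
        f2 = fit_ml(family, y, X, Z, s=2 * s)
        assert f2.alpha[0] == pytest.approx(f1.alpha[0] - np.log(2), abs=1e-6)
        assert f2.alpha[1] == pytest.approx(f1.alpha[1], abs=1e-6)

    @pytest.mark.parametrize("name", list(FAMILIES))
    def test_optimizer_beats_generic_oracle(self, name):
        """On 20 random small instances per family a converged fit is at
        least as good as a Nelder-Mead oracle on the independent scipy-built
        likelihood (up to 1e-3).  The covariate is a binary group indicator,
        as in the differential-abundance designs the fitter serves; a
        continuous zero-component covariate could quasi-separate the zeros
        in its tail, in which case no finite maximizer exists at all.  Fits
        reporting non-convergence are excluded but must stay rare."""
        family = FAMILIES[name]
        rng = np.random.default_rng(17)
        n = 100
        n_converged = 0
        for _ in range(20):
            s = rng.integers(50, 300, n).astype(float)
            X = np.column_stack([np.ones(n), (rng.random(n) < 0.5).astype(float)])
            Z = X if family.zero_inflated else np.empty((n, 0))
            y = random_counts(rng, n, family, s)
            fr = fit_ml(family, y, X, Z if family.zero_inflated else None, s=s)
            if not fr.converged:
                continue
            n_converged += 1

            def neg(params):
                with np.errstate(all="ignore"):
                    v = oracle_loglik(family, params, y, X, Z, s)
                # a sum of discrete log-pmfs is never positive; anything else
                # means scipy was driven outside its parameter domain
                return -v if np.isfinite(v) and v <= 1e-9 else 1e12

            k = 2 + Z.shape[1] + family.n_aux
            best = -np.inf
            for start in (fr.params, np.zeros(k), rng.normal(0, 0.5, k)):
                res = optimize.minimize(neg, start, method="Nelder-Mead",
                                        options={"maxiter": 2000, "fatol": 1e-10})
                best = max(best, -res.fun)
            assert fr.loglik >= best - 1e-3
        assert n_converged >= 15

    def test_poisson_glm_matches_statsmodels(self):
        """Cross-check the offset Poisson regression against an established
        GLM implementation (coefficients and maximized log-likelihood)."""
        import statsmodels.api as sm

        rng = np.random.default_rng(29)
        n = 200
        s = rng.integers(200, 5000, n).astype(float)
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        y = rng.poisson(np.exp(-4.0 + 0.4 * x) * s)
        ours = fit_ml("Poisson", y, X, s=s)
        ref = sm.GLM(y, X, family=sm.families.Poisson(), offset=np.log(s)).fit()
        assert np.allclose(ours.alpha, ref.params, atol=1e-6)
        assert ours.loglik == pytest.approx(ref.llf, abs=1e-6)

    def test_negbin_matches_statsmodels(self):
        """Cross-check the negative binomial ML fit (mean coefficients,
        dispersion, log-likelihood) against statsmodels' NegativeBinomial."""
        import statsmodels.api as sm

        rng = np.random.default_rng(31)
        n = 300
        s = rng.integers(200, 5000, n).astype(float)
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        mu = np.exp(-4.0 + 0.5 * x) * s
        theta = 1.5
        y = rng.negative_binomial(theta, theta / (theta + mu))
        ours = fit_ml("NegativeBinomial", y, X, s=s)
        ref = sm.NegativeBinomial(y, X, offset=np.log(s)).fit(disp=0)
        assert np.allclose(ours.alpha, ref.params[:2], atol=1e-4)
        # statsmodels parameterizes alpha = 1/theta
        assert ours.aux_natural(get_family("NegativeBinomial"))[
            "theta"
        ] == pytest.approx(1.0 / ref.params[-1], rel=1e-3)
        assert ours.loglik == pytest.approx(ref.llf, abs=1e-4)

    def test_rank_deficient_design_raises(self):
        y = np.arange(10)
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(np.linalg.LinAlgError, match="rank deficient"):
            fit_ml("Poisson", y, X, s=np.full(10, 10.0))

    def test_all_zero_counts_do_not_crash(self):
        y = np.zeros(20, dtype=int)
        fr = fit_ml("Poisson", y, np.ones((20, 1)), s=np.full(20, 100.0))
        assert np.isfinite(fr.loglik)

    def test_deterministic_given_data(self, diet_design):
        rng = np.random.default_rng(23)
        n = 80
        s = rng.integers(100, 500, n).astype(float)
        y = random_counts(rng, n, get_family("ZINegativeBinomial"), s)
        X = np.hstack([diet_design.X_interest, diet_design.X_nuisance])
        f1 = fit_ml("ZINegativeBinomial", y, X, X, s=s)
        f2 = fit_ml("ZINegativeBinomial", y, X, X, s=s)
        assert f1.loglik == f2.loglik
        assert np.array_equal(f1.params, f2.params)


class TestCountTable:
    def test_library_sizes_are_row_sums(self):
        t = CountTable([[1, 2], [3, 4]], ["a", "b"], ["t1", "t2"])
        assert list(t.library_sizes) == [3, 7]

    def test_rejects_negative_and_fractional_counts(self):
        with pytest.raises(CountTableError, match="negative"):
            CountTable([[1, -2]], ["a"], ["t1", "t2"])
        with pytest.raises(CountTableError, match="non-integral"):
            CountTable([[1.5, 2]], ["a"], ["t1", "t2"])

    def test_subset_library_sizes_must_dominate_row_sums(self):
        t = CountTable([[1, 2]], ["a"], ["t1", "t2"], library_sizes=[10])
        assert t.library_sizes[0] == 10
        with pytest.raises(CountTableError, match="dominate"):
            CountTable([[5, 6]], ["a"], ["t1", "t2"], library_sizes=[7])
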