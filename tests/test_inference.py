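import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import tempdiv as td
from tempdiv.inference import (
    LmmFit,
    fit_lmm,
    ols_with_covariate,
    orth_poly,
    select_degree,
    welch_t,
)


def _lmm_data(n_res=4, n_frag=4, n_samples=9, sigma_b=1.0, sigma_e=1.0,
              treat_effect=0.0, trend=(0.0, 0.0, 0.0), seed=0):
    """Balanced random-intercept data with a known polynomial date trend."""
    rng = np.random.default_rng(seed)
    rows = []
    dates = np.linspace(91, 240, n_samples)
    for i in range(n_res + n_frag):
        treatment = "reserve" if i < n_res else "fragment"
        b = rng.normal(0, sigma_b)
        for dte in dates:
            x = (dte - dates.mean()) / dates.std()
            mu = (treat_effect * (treatment == "fragment") + b
                  + trend[0] * x + trend[1] * x**2 + trend[2] * x**3)
            rows.append({"plot_id": f"p{i}", "treatment": treatment,
                         "julian_date": dte,
                         "y": mu + rng.normal(0, sigma_e)})
    return pd.DataFrame(rows)


class TestWelch:
    def test_identical_groups(self):
        w = welch_t([1.0, 2, 3], [1.0, 2, 3])
        assert w.t == 0.0
        assert w.p_two_sided == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # x=[1,2,3], y=[2,3,4]: s^2=1 each, t = -1/sqrt(2/3), df = 4
        w = welch_t([1, 2, 3], [2, 3, 4])
        assert w.t == pytest.approx(-np.sqrt(3 / 2), abs=1e-9)
        assert w.df == pytest.approx(4.0)

    def test_antisymmetry(self):
        x, y = [1.2, 3.1, 0.5, 2.2], [0.9, 4.4, 2.0]
        a, b = welch_t(x, y), welch_t(y, x)
        assert a.t == pytest.approx(-b.t)
        assert a.p_two_sided == pytest.approx(b.p_two_sided)

    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=9), rng.normal(1, 2, size=14)
        w = welch_t(x, y)
        ref = stats.ttest_ind(x, y, equal_var=False)
        assert w.t == pytest.approx(ref.statistic)
        assert w.p_two_sided == pytest.approx(ref.pvalue)

    def test_equals_pooled_t_in_balanced_equal_variance_limit(self):
        # with n1 = n2 the Welch statistic equals the pooled-variance t
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=6), rng.normal(size=6)
        w = welch_t(x, y)
        pooled = stats.ttest_ind(x, y, equal_var=True)
        assert w.t == pytest.approx(pooled.statistic)

    def test_null_pvalues_uniform(self):
        """p-values under exchangeable Gaussian groups are uniform
        (KS distance < 0.02 at 10,000 replicates, vectorised Welch)."""
        rng = np.random.default_rng(7)
        reps, n = 10_000, 8
        x = rng.normal(size=(reps, n))
        y = rng.normal(size=(reps, n))
        vx, vy = x.var(1, ddof=1), y.var(1, ddof=1)
        se2 = vx / n + vy / n
        t = (x.mean(1) - y.mean(1)) / np.sqrt(se2)
        df = se2**2 / ((vx / n) ** 2 / (n - 1) + (vy / n) ** 2 / (n - 1))
        p = 2 * stats.t.sf(np.abs(t), df)
        # spot-check the vectorised formulas against welch_t itself
        w0 = welch_t(x[0], y[0])
        assert w0.p_two_sided == pytest.approx(p[0])
        ks = stats.kstest(p, "uniform").statistic
        assert ks < 0.02

    def test_zero_variance_fails(self):
        with pytest.raises(ValueError):
            welch_t([1.0, 1.0], [1.0, 1.0])


class TestOrthPoly:
    def test_degree_one_example(self):
        cols = orth_poly(np.array([1.0, 2.0, 3.0]), 1)
        assert np.allclose(cols[:, 0], np.array([-1, 0, 1]) / np.sqrt(2))

    def test_gram_matrix_identity(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 200, size=40)
        for deg in (1, 2, 3):
            q = orth_poly(x, deg)
            assert np.allclose(q.T @ q, np.eye(deg), atol=1e-10)
            assert np.allclose(q.sum(axis=0), 0.0, atol=1e-10)

    def test_quadratic_even_on_symmetric_grid(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        q = orth_poly(x, 2)
        assert np.allclose(q[:, 1], q[::-1, 1])  # even function of centered x
        assert np.allclose(q[:, 0], -q[::-1, 0])  # odd

    def test_prediction_invariant_to_basis(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(size=30)
        y = rng.normal(size=30)
        raw = np.column_stack([np.ones(30), x, x**2, x**3])
        orth = np.column_stack([np.ones(30), orth_poly(x, 3)])
        yhat_raw = raw @ np.linalg.lstsq(raw, y, rcond=None)[0]
        yhat_orth = orth @ np.linalg.lstsq(orth, y, rcond=None)[0]
        assert np.allclose(yhat_raw, yhat_orth, atol=1e-8)

    def test_too_few_distinct_values(self):
        with pytest.raises(ValueError, match="distinct"):
            orth_poly(np.array([1.0, 1.0, 2.0]), 2)


class TestLmmFit:
    def test_agrees_with_statsmodels_mixedlm(self):
        """Fixed effects, variance components and ML log-likelihood match
        the general-purpose (statsmodels) mixed-model fitter."""
        import statsmodels.formula.api as smf

        data = _lmm_data(sigma_b=1.3, treat_effect=1.0, trend=(2, 1, 0), seed=3)
        fit = fit_lmm(data, "y", degree=2)
        d = data.copy()
        d["treat"] = (d.treatment == "fragment").astype(float)
        q = orth_poly(d.julian_date.to_numpy(), 2)
        d["p1"], d["p2"] = q[:, 0], q[:, 1]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ml = smf.mixedlm("y ~ treat + p1 + p2 + treat:p1 + treat:p2", d,
                             groups=d.plot_id).fit(reml=False)
            reml = smf.mixedlm("y ~ treat + p1 + p2 + treat:p1 + treat:p2", d,
                               groups=d.plot_id).fit(reml=True)
        assert fit.llf_ml == pytest.approx(ml.llf, abs=1e-4)
        assert fit.params["treatment"] == pytest.approx(reml.params["treat"], abs=1e-5)
        assert fit.sigma2_e == pytest.approx(reml.scale, rel=1e-4)
        assert fit.sigma2_b == pytest.approx(float(reml.cov_re.iloc[0, 0]), rel=1e-3)
        assert fit.bse["treatment"] == pytest.approx(reml.bse["treat"], rel=1e-3)

    def test_profile_likelihood_matches_dense_gaussian(self):
        """The profiled likelihood equals the dense multivariate-normal
        log-density at the fitted parameters (independent oracle)."""
        data = _lmm_data(n_res=3, n_frag=3, n_samples=4, sigma_b=0.8, seed=9)
        fit = fit_lmm(data, "y", degree=1)
        d = data.sort_values(["plot_id", "julian_date"], kind="stable")
        codes, _ = pd.factorize(d.plot_id)
        n = len(d)
        z = np.zeros((n, codes.max() + 1))
        z[np.arange(n), codes] = 1
        x = np.column_stack([np.ones(n), (d.treatment == "fragment").astype(float),
                             orth_poly(d.julian_date.to_numpy(), 1)[:, 0]])
        x = np.column_stack([x, x[:, 1] * x[:, 2]])
        v = fit.sigma2_e * np.eye(n) + fit.sigma2_b * z @ z.T
        resid = d.y.to_numpy() - x @ fit.params.to_numpy()
        llf = stats.multivariate_normal.logpdf(resid, mean=np.zeros(n), cov=v)
        # REML adds the fixed-effect correction; compare the ML variant
        lam = fit.sigma2_b / fit.sigma2_e if fit.sigma2_e else 0.0
        from tempdiv.inference import _profile_loglik
        starts = np.flatnonzero(np.r_[1, np.diff(codes)])
        sizes = np.diff(np.r_[starts, n]).astype(float)
        prof = _profile_loglik(lam, d.y.to_numpy(), x, sizes, starts, reml=False)
        assert prof[0] == pytest.approx(
            stats.multivariate_normal.logpdf(d.y.to_numpy(), mean=x @ prof[1],
                                             cov=prof[2] / fit.sigma2_e * v
                                             if fit.sigma2_e else v),
            abs=1e-6,
        )
        assert llf == pytest.approx(prof[0], abs=0.5)  # params near ML optimum

    def test_between_within_df_pattern(self):
        """4+4 plots x 9 samples with one observation dropped: treatment
        tested on 6 df, the date terms on 61 df in the linear model."""
        data = _lmm_data(seed=1).iloc[:-1]  # 71 observations
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_lmm(data, "y", degree=1)
        an = fit.anova.set_index("term")
        assert an.loc["treatment", "ddf"] == 6.0
        assert an.loc["date^1", "ddf"] == 61.0
        assert an.loc["treatment:date^1", "ddf"] == 61.0
        assert (an["ndf"] == 1).all()

    def test_zero_variance_limit_equals_ols(self):
        """With no between-plot variance the fit reduces to OLS."""
        data = _lmm_data(sigma_b=0.0, trend=(1, 0, 0), seed=1)
        with pytest.warns(UserWarning, match="singular"):
            fit = fit_lmm(data, "y", degree=1)
        import statsmodels.api as sm

        d = data.sort_values(["plot_id", "julian_date"], kind="stable")
        x = np.column_stack([np.ones(len(d)),
                             (d.treatment == "fragment").astype(float),
                             orth_poly(d.julian_date.to_numpy(), 1)[:, 0]])
        x = np.column_stack([x, x[:, 1] * x[:, 2]])
        ols = sm.OLS(d.y.to_numpy(), x).fit()
        assert fit.sigma2_b == 0.0
        assert np.allclose(fit.params.to_numpy(), ols.params, atol=1e-6)

    def test_parameter_recovery(self):
        """Estimates fall within 2 SE of the truth in most replicates.

        Uses a 10+10-plot design so the normal 2-SE band is a fair
        reference; with very few plots the t quantile would be needed."""
        hits, total = 0, 0
        for seed in range(40):
            data = _lmm_data(n_res=10, n_frag=10, n_samples=8, sigma_b=1.0,
                             treat_effect=2.0, trend=(3, 0, 0), seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_lmm(data, "y", degree=1)
            est, se = fit.params["treatment"], fit.bse["treatment"]
            hits += abs(est - 2.0) < 2 * se
            total += 1
        assert hits / total >= 0.90

    def test_requires_two_plots_per_treatment(self):
        data = _lmm_data(n_res=1, n_frag=4, seed=0)
        with pytest.raises(ValueError, match="at least 2 plots"):
            fit_lmm(data, "y", degree=1)

    def test_marginal_tests_available(self):
        data = _lmm_data(treat_effect=1.0, trend=(2, 0, 0), seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            seq = fit_lmm(data, "y", degree=1, tests="sequential")
            marg = fit_lmm(data, "y", degree=1, tests="marginal")
        assert set(seq.anova.term) == set(marg.anova.term)
        # interaction term (last entered) has equal sequential/marginal F
        a = seq.anova.set_index("term").loc["treatment:date^1", "F"]
        b = marg.anova.set_index("term").loc["treatment:date^1", "F"]
        assert a == pytest.approx(b, rel=1e-6)


class TestSelectDegree:
    def _dummy(self, degree, aic, rows=(1, 2, 3)):
        return LmmFit(response="y", degree=degree, params=pd.Series(dtype=float),
                      bse=pd.Series(dtype=float), sigma2_b=0, sigma2_e=1,
                      llf_ml=0, llf_reml=0, aic=aic, anova=pd.DataFrame(),
                      n_obs=3, n_groups=2, rows=tuple(rows))

    def test_all_equivalent_lowest_degree_wins(self):
        fits = [self._dummy(1, 100.5), self._dummy(2, 100.0), self._dummy(3, 99.9)]
        assert select_degree(fits).degree == 1

    def test_clear_winner(self):
        fits = [self._dummy(1, 110.0), self._dummy(2, 100.0), self._dummy(3, 101.5)]
        assert select_degree(fits).degree == 2

    def test_differing_rows_fail(self):
        fits = [self._dummy(1, 100, rows=(1, 2)), self._dummy(2, 99, rows=(1, 3))]
        with pytest.raises(ValueError, match="differing observation sets"):
            select_degree(fits)

    def test_recovers_strong_cubic_signal(self):
        hits = 0
        for seed in range(30):
            data = _lmm_data(sigma_b=0.5, trend=(2.0, 0.0, 1.5), seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fits = {d: fit_lmm(data, "y", d) for d in (1, 2, 3)}
            hits += select_degree(fits).degree == 3
        assert hits / 30 >= 0.8


class TestOlsWithCovariate:
    def test_noise_covariate_not_favored_on_average(self):
        rng = np.random.default_rng(0)
        deltas = []
        for _ in range(60):
            tab = pd.DataFrame({
                "treatment": ["reserve"] * 5 + ["fragment"] * 5,
                "resp": np.r_[rng.normal(1, 1, 5), rng.normal(0, 1, 5)],
                "cov": rng.normal(size=10),
            })
            deltas.append(ols_with_covariate(tab, "resp", "cov")["delta_aic"])
        assert np.mean(deltas) > 0  # the simpler model wins on average

    def test_duplicate_covariate_warns(self):
        rng = np.random.default_rng(1)
        resp = rng.normal(size=12)
        tab = pd.DataFrame({"treatment": ["reserve", "fragment"] * 6,
                            "resp": resp, "cov": resp})
        with pytest.warns(UserWarning, match="near-perfect"):
            ols_with_covariate(tab, "resp", "cov")

    def test_zero_variance_covariate_fails(self):
        tab = pd.DataFrame({"treatment": ["reserve", "fragment"] * 3,
                            "resp": np.arange(6.0), "cov": np.ones(6)})
        with pytest.raises(ValueError, match="collinear"):
            ols_with_covariate(tab, "resp", "cov")
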