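"""Statistical comparisons: Welch tests, OLS/AIC, and mixed-model trends.

The seasonal-trend model for the per-sample (temporal alpha) tables is a
Gaussian random-intercept linear mixed model,

    y_ij = beta0 + treatment_i + f(date_ij) + treatment_i : f(date_ij)
           [+ covariate] + b_i + e_ij,

with plot-level random intercepts b_i ~ N(0, sigma_b^2) and f an
orthogonal polynomial in the Julian sampling date of degree 1-3. The
degree is chosen by ML-based AIC with equivalent models (delta AIC < 2)
resolved toward the lowest degree. Reported per-term F tests use the
REML fit, sequential (type-I) sums of squares, and the classic
"between-within" denominator degrees of freedom: plot-level terms are
tested against the number of plots, within-plot terms against the
residual observations.

The random-intercept likelihood is profiled analytically over the fixed
effects and residual variance, leaving a one-dimensional optimisation
over the variance ratio; fits are exact and fast, and agree with
general-purpose mixed-model software (cross-checked in the test suite
against statsmodels' MixedLM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "WelchResult",
    "LmmFit",
    "welch_t",
    "orth_poly",
    "fit_lmm",
    "select_degree",
    "ols_with_covariate",
]


# ---------------------------------------------------------------------------
# Welch's t-test


@dataclass
class WelchResult:
    t: float
    df: float
    p_two_sided: float
    mean_x: float
    mean_y: float
    var_x: float
    var_y: float
    n_x: int
    n_y: int


def welch_t(x, y) -> WelchResult:
    """Welch's two-sample t-test (unequal variances, Satterthwaite df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 finite observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("zero variance in both groups; Welch test undefined")
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(p), float(x.mean()), float(y.mean()),
                       float(vx), float(vy), nx, ny)


# ---------------------------------------------------------------------------
# Orthogonal polynomial basis


def orth_poly(x, degree: int) -> np.ndarray:
    """Orthonormal polynomial basis of the given degree (no constant column).

    Columns span the same space as the centered raw powers x..x^degree,
    are mutually orthonormal, orthogonal to the constant vector, and use
    the sign convention that each column's leading raw-power coefficient
    is positive. x is centered and scaled first for conditioning; the
    span (and any regression fit through the basis) is unaffected.
    """
    x = np.asarray(x, dtype=float)
    if degree not in (1, 2, 3):
        raise ValueError("degree must be 1, 2 or 3")
    if len(np.unique(x)) < degree + 1:
        raise ValueError(
            f"need at least {degree + 1} distinct x values for degree {degree}"
        )
    xs = (x - x.mean())
    scale = xs.std()
    if scale > 0:
        xs = xs / scale
    v = np.vander(xs, degree + 1, increasing=True)  # [1, x, x^2, ...]
    q, r = np.linalg.qr(v)
    # flip signs so diag(R) > 0: leading raw-power coefficient positive
    signs = np.sign(np.diag(r))
    signs[signs == 0] = 1.0
    q = q * signs
    return q[:, 1:]


# ---------------------------------------------------------------------------
# Random-intercept linear mixed model


@dataclass
class LmmFit:
    """A fitted random-intercept mixed model for one response and degree."""

    response: str
    degree: int
    params: pd.Series  # REML fixed effects
    bse: pd.Series  # REML standard errors
    sigma2_b: float  # between-plot (random intercept) variance, REML
    sigma2_e: float  # residual variance, REML
    llf_ml: float
    llf_reml: float
    aic: float  # -2 llf_ml + 2 (n fixed + 2)
    anova: pd.DataFrame  # term, F, ndf, ddf, p
    n_obs: int
    n_groups: int
    rows: tuple  # index of the observations used (for like-for-like AIC)
    terms: dict = field(default_factory=dict)
    test_type: str = "sequential"


def _profile_loglik(lam: float, y, x, group_sizes, starts, reml: bool):
    """Profile log-likelihood over lambda = sigma_b^2 / sigma_e^2.

    For fixed lambda, V0 = I + lambda Z Z' is block diagonal with blocks
    I + lambda J; GLS beta and the scaled variance are closed form. Both
    ML and REML profiles are returned up to their usual constants.
    """
    n, p = x.shape
    # V0^{-1} block: I - (lam / (1 + lam n_i)) J  -> apply via group sums
    shrink = lam / (1.0 + lam * group_sizes)
    ysum = np.add.reduceat(y, starts)
    xsum = np.add.reduceat(x, starts, axis=0)
    xtvx = x.T @ x - (xsum * shrink[:, None]).T @ xsum
    xtvy = x.T @ y - (xsum * shrink[:, None]).T @ ysum
    ytvy = y @ y - shrink @ ysum**2
    beta = np.linalg.solve(xtvx, xtvy)
    rss = ytvy - beta @ xtvy  # r' V0^{-1} r via projection identity
    rss = max(rss, 1e-300)
    logdet_v = np.log1p(lam * group_sizes).sum()
    if reml:
        sigma2 = rss / (n - p)
        sign, logdet_x = np.linalg.slogdet(xtvx)
        llf = -0.5 * (
            (n - p) * np.log(2 * np.pi * sigma2) + logdet_v + logdet_x + (n - p)
        )
    else:
        sigma2 = rss / n
        llf = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet_v + n)
    return llf, beta, sigma2, xtvx


def _fit_variance_ratio(y, x, group_sizes, starts, reml: bool):
    """Maximise the profiled likelihood over lambda >= 0 (1-D search)."""

    def neg(loglam):
        return -_profile_loglik(np.exp(loglam), y, x, group_sizes, starts, reml)[0]

    res = optimize.minimize_scalar(neg, bounds=(-14.0, 14.0), method="bounded",
                                   options={"xatol": 1e-9})
    lam = float(np.exp(res.x))
    llf_interior = -res.fun
    llf_zero = _profile_loglik(0.0, y, x, group_sizes, starts, reml)[0]
    if llf_zero >= llf_interior or lam < 1e-6:
        lam = 0.0  # boundary (singular) solution: no between-plot variance
    llf, beta, sigma2, xtvx = _profile_loglik(lam, y, x, group_sizes, starts, reml)
    return lam, llf, beta, sigma2, xtvx


def _build_design(table: pd.DataFrame, degree: int, covariate: str | None,
                  date_col: str, treatment_col: str):
    """Design matrix columns grouped by model term, in entry order."""
    treat = (table[treatment_col] == "fragment").to_numpy(dtype=float)
    if len(np.unique(treat)) < 2:
        raise ValueError("both treatments must be present")
    poly = orth_poly(table[date_col].to_numpy(dtype=float), degree)
    cols = [np.ones(len(table)), treat]
    names = ["Intercept", "treatment"]
    terms = {"Intercept": [0], "treatment": [1]}
    j = 2
    for d in range(degree):
        cols.append(poly[:, d])
        names.append(f"date^{d+1}")
        terms[f"date^{d+1}"] = [j]
        j += 1
    for d in range(degree):
        cols.append(treat * poly[:, d])
        names.append(f"treatment:date^{d+1}")
        terms[f"treatment:date^{d+1}"] = [j]
        j += 1
    if covariate is not None:
        cols.append(table[covariate].to_numpy(dtype=float))
        names.append(covariate)
        terms[covariate] = [j]
    return np.column_stack(cols), names, terms


def _between_within_ddf(term: str, table, group_col, covariate, n_obs, n_groups,
                        n_params) -> float:
    """Between-within denominator df for one fixed-effect term.

    Terms constant within a plot (treatment; a plot-level covariate) are
    tested at the plot stratum: ddf = n_plots - n plot-level parameters
    (intercept included). Terms varying within plots use
    ddf = N - n_plots - n within-plot parameters.
    """
    plot_level = {"Intercept", "treatment"}
    if covariate is not None:
        nuniq = table.groupby(group_col)[covariate].nunique()
        if (nuniq <= 1).all():
            plot_level.add(covariate)
    n_plot_params = sum(n_params[t] for t in n_params if t in plot_level)
    n_within_params = sum(n_params[t] for t in n_params if t not in plot_level)
    if term in plot_level:
        return float(n_groups - n_plot_params)
    return float(n_obs - n_groups - n_within_params)


def fit_lmm(table: pd.DataFrame, response: str, degree: int,
            covariate: str | None = None, date_col: str = "julian_date",
            group_col: str = "plot_id", treatment_col: str = "treatment",
            tests: str = "sequential") -> LmmFit:
    """Fit the random-intercept seasonal-trend model for one response.

    Rows with a missing response are dropped (rarefaction exclusions
    surface here as missing values). The model is fitted twice: by ML
    for AIC-based degree selection and by REML for the reported
    estimates and F tests. A fit with zero between-plot variance is
    retained (with a warning) rather than rejected — small designs
    produce them routinely.

    ``tests`` chooses sequential (type-I, terms in entry order) or
    marginal (each term adjusted for all others) F statistics; both use
    between-within denominator df.
    """
    if tests not in ("sequential", "marginal"):
        raise ValueError("tests must be 'sequential' or 'marginal'")
    need = [response, date_col, group_col, treatment_col]
    if covariate is not None:
        need.append(covariate)
    data = table.loc[:, need].dropna(subset=[response]).copy()
    data = data.sort_values([group_col, date_col], kind="stable")
    if data[group_col].nunique() < 2:
        raise ValueError("need at least 2 plots")
    for trt in ("reserve", "fragment"):
        if data.loc[data[treatment_col] == trt, group_col].nunique() < 2:
            raise ValueError(f"need at least 2 plots in treatment {trt!r}")

    x, names, terms = _build_design(data, degree, covariate, date_col, treatment_col)
    y = data[response].to_numpy(dtype=float)
    codes, _ = pd.factorize(data[group_col], sort=False)
    starts = np.flatnonzero(np.r_[1, np.diff(codes)])
    group_sizes = np.diff(np.r_[starts, len(codes)]).astype(float)
    n_obs, p = x.shape
    n_groups = len(starts)

    lam_ml, llf_ml, *_ = _fit_variance_ratio(y, x, group_sizes, starts, reml=False)
    lam, llf_reml, beta, sigma2_e, xtvx = _fit_variance_ratio(
        y, x, group_sizes, starts, reml=True
    )
    sigma2_b = lam * sigma2_e
    if lam == 0.0:
        warnings.warn("singular fit: between-plot variance estimated at 0",
                      stacklevel=2)
    cov_beta = sigma2_e * np.linalg.inv(xtvx)
    bse = np.sqrt(np.diag(cov_beta))

    # whiten by V0^{-1/2} (block: I - c J with (1 - c n_i)^2 = 1/(1 + lam n_i))
    c = (1.0 - 1.0 / np.sqrt(1.0 + lam * group_sizes)) / group_sizes
    ystar = y - np.repeat(c * np.add.reduceat(y, starts), group_sizes.astype(int))
    xstar = x - np.repeat(c[:, None] * np.add.reduceat(x, starts, axis=0),
                          group_sizes.astype(int), axis=0)

    q, r = np.linalg.qr(xstar)
    effects = q.T @ ystar
    rss = float(ystar @ ystar - effects @ effects)
    s2 = rss / (n_obs - p)

    n_params = {t: len(ix) for t, ix in terms.items()}
    rows = []
    for term, ix in terms.items():
        if term == "Intercept":
            continue
        ndf = len(ix)
        if tests == "sequential":
            ss = float((effects[ix] ** 2).sum())
            f = (ss / ndf) / s2
        else:
            l_beta = beta[ix]
            l_cov = cov_beta[np.ix_(ix, ix)]
            f = float(l_beta @ np.linalg.solve(l_cov, l_beta)) / ndf
        ddf = _between_within_ddf(term, data, group_col, covariate, n_obs,
                                  n_groups, n_params)
        pval = float(stats.f.sf(f, ndf, ddf)) if ddf > 0 else np.nan
        rows.append({"term": term, "F": float(f), "ndf": ndf, "ddf": ddf, "p": pval})

    return LmmFit(
        response=response,
        degree=degree,
        params=pd.Series(beta, index=names),
        bse=pd.Series(bse, index=names),
        sigma2_b=float(sigma2_b),
        sigma2_e=float(sigma2_e),
        llf_ml=float(llf_ml),
        llf_reml=float(llf_reml),
        aic=float(-2 * llf_ml + 2 * (p + 2)),
        anova=pd.DataFrame(rows),
        n_obs=n_obs,
        n_groups=n_groups,
        rows=tuple(data.index),
        terms=terms,
        test_type=tests,
    )


def select_degree(fits: dict[int, LmmFit] | list[LmmFit]) -> LmmFit:
    """AIC degree selection with the delta-AIC < 2 simplicity rule.

    Among fits whose ML AIC lies within 2 of the minimum, the lowest
    polynomial degree wins. All candidate fits must have been computed
    on the identical set of observations, otherwise their likelihoods
    are not comparable and a hard failure is raised.
    """
    fits = list(fits.values()) if isinstance(fits, dict) else list(fits)
    if not fits:
        raise ValueError("no fits supplied")
    row_sets = {f.rows for f in fits}
    if len(row_sets) > 1:
        raise ValueError("fits were computed on differing observation sets; "
                         "AIC values are not comparable")
    best_aic = min(f.aic for f in fits)
    candidates = [f for f in fits if f.aic - best_aic < 2.0]
    return min(candidates, key=lambda f: f.degree)


# ---------------------------------------------------------------------------
# Plot-level OLS with an added covariate


def ols_with_covariate(table: pd.DataFrame, response: str, covariate: str,
                       treatment_col: str = "treatment"):
    """OLS of a plot-level response on treatment, with and without a covariate.

    Returns a dict with both fitted models (statsmodels results) and
    their AICs on the identical rows, for judging whether the covariate
    earns its place. A covariate collinear with the design fails hard; a
    near-perfect fit (R^2 > 0.999) warns, since it usually means the
    covariate duplicates the response.
    """
    import statsmodels.api as sm

    data = table.loc[:, [response, covariate, treatment_col]].dropna()
    if len(data) < 4:
        raise ValueError("need at least 4 complete rows")
    treat = (data[treatment_col] == "fragment").astype(float)
    x_base = sm.add_constant(pd.DataFrame({"treatment": treat}))
    x_full = x_base.copy()
    x_full[covariate] = data[covariate].to_numpy(dtype=float)
    if np.linalg.matrix_rank(x_full.to_numpy()) < x_full.shape[1]:
        raise ValueError(f"covariate {covariate!r} is collinear with the design")
    y = data[response].to_numpy(dtype=float)
    base = sm.OLS(y, x_base).fit()
    full = sm.OLS(y, x_full).fit()
    if full.rsquared > 0.999:
        warnings.warn("covariate yields a near-perfect fit; it may duplicate "
                      "the response", stacklevel=2)
    return {
        "base": base,
        "full": full,
        "aic_base": float(base.aic),
        "aic_full": float(full.aic),
        "delta_aic": float(full.aic - base.aic),
    }
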