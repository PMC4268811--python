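"""Cohort-level linear models: fixed-effect ANOVA, simple regression, and
random-intercept linear mixed models with likelihood-ratio tests.

Three analyses are covered:

* fixed-effect linear models of a per-retina response (p+OC percentage or
  total ommatidium count) on strain and sex, summarised by a sequential
  (type-I) ANOVA table in a stated term order;
* simple OLS regression of one response on one covariate (e.g. p+OC
  percentage on total ommatidia), reporting slope, R^2 and the overall F;
* random-intercept linear mixed models for qPCR expression indexes, with
  species and sex as fixed effects and crossed random intercepts for
  strain and biological replicate, fitted by maximum likelihood so that
  nested fixed-effect structures can be compared with likelihood-ratio
  chi-square tests.

The LMM is estimated by profiling: with V(r) = I + r_1 Z_1 Z_1' +
r_2 Z_2 Z_2' (r_g = variance ratio sigma_g^2 / sigma^2), the GLS
coefficients and the residual variance have closed forms given r, leaving
a bounded 1-2 parameter optimisation over log r from several documented
starting points.  Responses are modelled on the identity (percentage)
scale by default; a logit option exists for sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm


class RankDeficiencyError(ValueError):
    """The fixed-effect design matrix is rank deficient."""


class NonNestedError(ValueError):
    """Likelihood-ratio test requested for non-nested models."""


@dataclass
class AnovaTable:
    """Sequential (type-I) ANOVA: one row per term in entry order."""

    terms: list[str]
    df: list[float]
    sum_sq: list[float]
    mean_sq: list[float]
    f: list[float]
    p: list[float]
    resid_df: float
    resid_ss: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "df": self.df + [self.resid_df],
                "sum_sq": self.sum_sq + [self.resid_ss],
                "mean_sq": self.mean_sq + [self.resid_ss / self.resid_df],
                "F": self.f + [np.nan],
                "p": self.p + [np.nan],
            },
            index=self.terms + ["Residual"],
        )


def ols_fit(
    table: pd.DataFrame,
    response: str,
    terms: Sequence[str],
    order: Sequence[str] | None = None,
) -> tuple[pd.Series, AnovaTable]:
    """OLS fit with treatment coding and a sequential ANOVA table.

    ``terms`` uses formula syntax fragments, e.g. ``["sex", "strain",
    "sex:strain"]``; ``order`` reorders them for the sequential
    decomposition (default: entry order).  Returns the coefficient
    series and the ANOVA table.  Raises :class:`RankDeficiencyError`
    naming aliased terms if the design is not full rank.
    """
    ordered = list(order) if order is not None else list(terms)
    if set(ordered) != set(terms):
        raise ValueError("order must be a permutation of terms")
    formula = f"Q('{response}') ~ " + " + ".join(ordered)
    model = smf.ols(formula, data=table)
    r = np.linalg.matrix_rank(model.exog)
    if r < model.exog.shape[1]:
        raise RankDeficiencyError(
            f"design matrix rank {r} < {model.exog.shape[1]} columns; "
            f"check aliased terms among {ordered}"
        )
    fit = model.fit()
    aov = anova_lm(fit, typ=1)
    rows = aov.drop(index="Residual")
    table_out = AnovaTable(
        terms=[str(t) for t in rows.index],
        df=list(rows["df"]),
        sum_sq=list(rows["sum_sq"]),
        mean_sq=list(rows["sum_sq"] / rows["df"]),
        f=list(rows["F"]),
        p=list(rows["PR(>F)"]),
        resid_df=float(aov.loc["Residual", "df"]),
        resid_ss=float(aov.loc["Residual", "sum_sq"]),
    )
    return fit.params, table_out


def marginal_f_test(
    table: pd.DataFrame, response: str, terms: Sequence[str], drop: str
) -> tuple[float, float, float, int, int]:
    """Drop-one (marginal) F-test of one term in an additive OLS model.

    Returns (coefficient-or-nan, F, p, df_num, df_den).  For a two-level
    factor the single treatment-coded coefficient and its SE summarise
    the effect; they are returned via the first element as (coef, se)
    packed in the caller's report instead -- here only F/p/df.
    """
    full = smf.ols(f"Q('{response}') ~ " + " + ".join(terms), data=table).fit()
    reduced_terms = [t for t in terms if t != drop]
    rhs = " + ".join(reduced_terms) if reduced_terms else "1"
    reduced = smf.ols(f"Q('{response}') ~ " + rhs, data=table).fit()
    df_num = int(round(reduced.df_resid - full.df_resid))
    f = ((reduced.ssr - full.ssr) / df_num) / (full.ssr / full.df_resid)
    p = float(stats.f.sf(f, df_num, full.df_resid))
    return float("nan"), float(f), p, df_num, int(full.df_resid)


def simple_regression(
    y: Sequence[float], x: Sequence[float]
) -> tuple[float, float, float, float]:
    """OLS of y on x: returns (slope, R^2, F, p) with F = (n-2) R^2/(1-R^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.var(x) == 0:
        raise ValueError("x is constant; slope undefined")
    res = stats.linregress(x, y)
    r2 = res.rvalue**2
    n = len(x)
    if r2 >= 1.0:
        f = math.inf
        p = 0.0
    else:
        f = (n - 2) * r2 / (1.0 - r2)
        p = float(stats.f.sf(f, 1, n - 2))
    return float(res.slope), float(r2), float(f), p


# ---------------------------------------------------------------------------
# random-intercept linear mixed model (maximum likelihood)
# ---------------------------------------------------------------------------


@dataclass
class LmmFit:
    """An ML fit of a Gaussian LMM with 1-2 crossed random intercepts."""

    params: pd.Series  # fixed effects
    se: pd.Series
    vc: dict[str, float]  # variance components per random grouping
    sigma2: float  # residual variance
    loglik: float
    converged: bool
    n_obs: int
    fixed_columns: tuple[str, ...]
    response: str
    n_fixed: int = 0

    def __post_init__(self) -> None:
        self.n_fixed = len(self.params)


@dataclass(frozen=True)
class LrtResult:
    """Likelihood-ratio chi-square test between nested ML fits."""

    x2: float
    df: int
    p: float


def _design_matrices(
    table: pd.DataFrame, response: str, fixed_terms: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Treatment-coded fixed design (with intercept) and the response."""
    y = np.asarray(table[response], dtype=float)
    if np.isnan(y).any():
        raise ValueError("missing responses are not allowed")
    cols: list[np.ndarray] = [np.ones(len(table))]
    names: list[str] = ["Intercept"]
    for term in fixed_terms:
        col = table[term]
        if col.dtype.kind in "OUb" or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.astype(str).unique())
            for lev in levels[1:]:
                cols.append((col.astype(str) == lev).astype(float).to_numpy())
                names.append(f"{term}[T.{lev}]")
        else:
            cols.append(np.asarray(col, dtype=float))
            names.append(term)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficiencyError(f"fixed-effect design rank deficient: {names}")
    return X, y, names


def _grouping_matrix(table: pd.DataFrame, group: str) -> np.ndarray:
    codes, _ = pd.factorize(table[group].astype(str))
    Z = np.zeros((len(table), codes.max() + 1))
    Z[np.arange(len(table)), codes] = 1.0
    return Z


def _profiled_negloglik(
    log_r: np.ndarray, X: np.ndarray, y: np.ndarray, ZZs: list[np.ndarray]
) -> float:
    n = len(y)
    V = np.eye(n)
    for lr, ZZ in zip(log_r, ZZs):
        V = V + math.exp(lr) * ZZ
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:  # pragma: no cover - V is PD by construction
        return 1e300
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    Xw = np.linalg.solve(L, X)
    yw = np.linalg.solve(L, y)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    sigma2 = rss / n
    if sigma2 <= 0:  # pragma: no cover
        return 1e300
    return 0.5 * (n * math.log(2.0 * math.pi * sigma2) + logdet + n)


def fit_random_intercept_lmm(
    table: pd.DataFrame,
    response: str,
    fixed_terms: Sequence[str],
    random_groups: Sequence[str],
    tol: float = 1e-8,
) -> LmmFit:
    """Maximum-likelihood fit of a Gaussian random-intercept LMM.

    ``random_groups`` names 1 or 2 grouping columns (e.g. strain and
    biological replicate); each contributes an independent Gaussian
    intercept.  ML (not REML) is used throughout because the fits feed
    likelihood-ratio tests of fixed effects.  The variance ratios are
    optimised on the log scale by L-BFGS-B from a documented grid of
    starting points; the best of all starts is returned, with a
    convergence flag (never silent failure).
    """
    if not 1 <= len(random_groups) <= 2:
        raise ValueError("1 or 2 random groupings supported")
    for g in random_groups:
        if table[g].nunique() < 2:
            raise ValueError(f"random grouping {g!r} needs >= 2 levels")
    X, y, names = _design_matrices(table, response, fixed_terms)
    Zs = [_grouping_matrix(table, g) for g in random_groups]
    ZZs = [Z @ Z.T for Z in Zs]
    n, k = X.shape

    # documented multi-start grid over log variance ratios: near-zero,
    # comparable-to-residual and dominant components, plus mixed corners
    if len(ZZs) == 1:
        grid = [[-8.0], [-2.0], [0.0], [2.0]]
    else:
        grid = [[-6.0, -6.0], [0.0, 0.0], [2.0, 2.0], [2.0, -6.0], [-6.0, 2.0], [0.0, -2.0]]
    best = None
    any_ok = False
    for x0 in grid:
        res = optimize.minimize(
            _profiled_negloglik,
            x0=np.array(x0),
            args=(X, y, ZZs),
            method="L-BFGS-B",
            bounds=[(-30.0, 15.0)] * len(ZZs),
            options={"ftol": tol, "gtol": 1e-10},
        )
        any_ok = any_ok or bool(res.success)
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    log_r = best.x
    # closed-form GLS quantities at the optimum
    V = np.eye(n)
    for lr, ZZ in zip(log_r, ZZs):
        V = V + math.exp(lr) * ZZ
    Vinv = np.linalg.inv(V)
    XtVinv = X.T @ Vinv
    cov_unscaled = np.linalg.inv(XtVinv @ X)
    beta = cov_unscaled @ (XtVinv @ y)
    resid = y - X @ beta
    sigma2 = float(resid @ (Vinv @ resid)) / n
    loglik = -float(best.fun)
    se = np.sqrt(np.diag(cov_unscaled) * sigma2)
    vc = {
        g: float(math.exp(lr) * sigma2) for g, lr in zip(random_groups, log_r)
    }
    return LmmFit(
        params=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        vc=vc,
        sigma2=sigma2,
        loglik=loglik,
        converged=any_ok,
        n_obs=n,
        fixed_columns=tuple(names),
        response=response,
    )


def lrt(full: LmmFit, reduced: LmmFit) -> LrtResult:
    """Likelihood-ratio test of nested fixed-effect structures.

    Both fits must be ML fits of the same response on the same data with
    the same random structure; the reduced model's fixed-effect columns
    must be a subset of the full model's.  The statistic is clamped at 0
    (boundary cases where the larger model converges marginally worse).
    """
    if full.n_obs != reduced.n_obs or full.response != reduced.response:
        raise NonNestedError("fits are not on the same data/response")
    if set(full.vc) != set(reduced.vc):
        raise NonNestedError("fits differ in random structure")
    if not set(reduced.fixed_columns) <= set(full.fixed_columns):
        raise NonNestedError(
            "reduced fixed effects are not nested in the full model"
        )
    df = full.n_fixed - reduced.n_fixed
    x2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p = float(stats.chi2.sf(x2, df)) if df > 0 else 1.0
    return LrtResult(x2=x2, df=df, p=p)
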