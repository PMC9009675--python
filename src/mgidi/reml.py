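"""Per-trait linear mixed models for multi-environment trials.

Model (one trait at a time):

    y = X beta + Z_g a + Z_ge u + e

where beta holds the fixed environment and block-within-environment effects,
a ~ N(0, sigma2_g I) the genotype main effects, u ~ N(0, sigma2_ge I) the
genotype-by-environment effects and e ~ N(0, sigma2_e I) the plot residuals.
Blocks are fixed.

Variance components are estimated by REML: the residual variance is profiled
out analytically and the restricted log-likelihood is maximized over the
non-negative variance ratios (gamma_g, gamma_ge) = (sigma2_g, sigma2_ge) /
sigma2_e with a bounded quasi-Newton search (L-BFGS-B, zero lower bounds, so
boundary estimates are exact zeros).  BLUPs are the conditional means of the
random effects at the optimum; fixed effects are GLS estimates.

Random effects are tested by REML likelihood-ratio against the model without
the term, referred to chi-square with 1 df (conservative at the boundary:
the exact reference is a 50:50 mixture of chi2_0 and chi2_1).  The fixed
environment effect is tested by a maximum-likelihood ratio with e-1 df,
since restricted likelihoods are not comparable across fixed structures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .trial import DesignSummary, TrialData, summarize_design

__all__ = [
    "TraitFit",
    "LRTResult",
    "ConvergenceError",
    "fit_reml",
    "blup_means",
    "lrt_random",
    "test_fixed_effects",
    "fit_all_traits",
    "genotype_blup_matrix",
    "genotype_environment_blup_matrix",
]

_LOGLIK_TOL = 1e-8
_MAX_ITER = 500


class ConvergenceError(RuntimeError):
    """REML/ML optimization failed to converge; carries the optimizer trace."""


@dataclass
class LRTResult:
    term: str
    statistic: float
    df: int
    p_value: float


@dataclass
class TraitFit:
    """One trait's fitted mixed model."""

    trait: str
    design: DesignSummary
    grand_mean: float
    fixed_effects: pd.Series  # named coefficients of the fixed design
    env_effects: pd.Series  # per-environment deviation from the grand mean
    var_g: float
    var_ge: float
    var_e: float
    blup_g: pd.Series  # genotype main effects alpha_hat
    blup_ge: pd.Series  # MultiIndex (genotype, environment)
    restricted_loglik: float
    ml_loglik: float
    n_used: int
    converged: bool = True

    @property
    def varcomp(self) -> tuple[float, float, float]:
        return (self.var_g, self.var_ge, self.var_e)


# ---------------------------------------------------------------------------
# design construction


def _design(tab: pd.DataFrame):
    """Fixed and random design matrices for one trait's non-missing rows.

    Fixed part: intercept, treatment-coded environment columns (e-1), and
    block-within-environment sum-to-zero contrasts (e*(b-1)) — the latter are
    orthogonal to the environment indicators, so dropping the environment
    columns is a clean rank-(e-1) reduction for the fixed-effect test.
    """
    genotypes = sorted(tab["genotype"].unique())
    envs = sorted(tab["environment"].unique())
    n = len(tab)
    g, e = len(genotypes), len(envs)

    gi = tab["genotype"].map({v: i for i, v in enumerate(genotypes)}).to_numpy()
    ei = tab["environment"].map({v: j for j, v in enumerate(envs)}).to_numpy()

    cols = [np.ones(n)]
    names = ["intercept"]
    env_cols = []
    for j in range(1, e):
        cols.append((ei == j).astype(float))
        names.append(f"env[{envs[j]}]")
        env_cols.append(len(cols) - 1)
    for j, env in enumerate(envs):
        blocks = sorted(tab.loc[tab["environment"] == env, "block"].unique())
        bmap = {v: k for k, v in enumerate(blocks)}
        bi = tab["block"].map(bmap)
        for k in range(len(blocks) - 1):
            col = np.zeros(n)
            mask_env = ei == j
            col[mask_env & (bi == k).to_numpy()] = 1.0
            col[mask_env & (bi == len(blocks) - 1).to_numpy()] = -1.0
            cols.append(col)
            names.append(f"block[{env}:{blocks[k]}]")
    X = np.column_stack(cols)

    Zg = np.zeros((n, g))
    Zg[np.arange(n), gi] = 1.0
    Zge = np.zeros((n, g * e))
    Zge[np.arange(n), gi * e + ei] = 1.0
    return X, names, env_cols, Zg, Zge, genotypes, envs


def _profile(y, X, Zg, Zge, gamma, *, reml: bool):
    """Profiled (restricted) log-likelihood and GLS pieces at gamma.

    Uses the Woodbury identity on H = I + gamma_g Zg Zg' + gamma_ge Zge Zge'
    so the factorization is of an m x m matrix (m = g + g*e random effects)
    rather than n x n.
    """
    n, p = X.shape
    blocks = []
    if gamma[0] > 0:
        blocks.append(np.sqrt(gamma[0]) * Zg)
    if gamma[1] > 0:
        blocks.append(np.sqrt(gamma[1]) * Zge)
    if blocks:
        Z = np.hstack(blocks)
        M = np.eye(Z.shape[1]) + Z.T @ Z
        c, low = cho_factor(M, lower=True)
        logdetH = 2.0 * np.log(np.diag(c)).sum()

        def hsolve(v):
            return v - Z @ cho_solve((c, low), Z.T @ v)

    else:
        logdetH = 0.0

        def hsolve(v):
            return v

    HiX = hsolve(X)
    Hiy = hsolve(y)
    XtHiX = X.T @ HiX
    beta = np.linalg.solve(XtHiX, X.T @ Hiy)
    r = y - X @ beta
    Hir = Hiy - HiX @ beta
    quad = float(r @ Hir)
    quad = max(quad, 1e-300)
    if reml:
        dof = n - p
        s2 = quad / dof
        sign, logdetXtHiX = np.linalg.slogdet(XtHiX)
        ll = -0.5 * (dof * (math.log(2 * math.pi * s2) + 1.0) + logdetH + logdetXtHiX)
    else:
        s2 = quad / n
        ll = -0.5 * (n * (math.log(2 * math.pi * s2) + 1.0) + logdetH)
    return ll, s2, beta, Hir


class _Suff:
    """Sufficient statistics for the profiled likelihood.

    Everything the likelihood needs at a new gamma reduces to fixed
    cross-products plus one m x m Cholesky, so optimizer iterations never
    touch the n-dimensional data again.
    """

    def __init__(self, y, X, Zg, Zge):
        self.n, self.p = X.shape
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.ZgtX = Zg.T @ X
        self.ZgetX = Zge.T @ X
        self.Zgty = Zg.T @ y
        self.Zgety = Zge.T @ y
        self.dg = Zg.sum(axis=0)
        self.dge = Zge.sum(axis=0)
        self.G12 = Zg.T @ Zge

    def loglik(self, gamma, *, reml: bool) -> float:
        g0, g1 = gamma
        use0, use1 = g0 > 0, g1 > 0
        if not (use0 or use1):
            XtHiX, XtHiy, yHiy, logdetH = self.XtX, self.Xty, self.yty, 0.0
        else:
            ZtX_parts, Zty_parts, Mrows = [], [], []
            if use0:
                ZtX_parts.append(np.sqrt(g0) * self.ZgtX)
                Zty_parts.append(np.sqrt(g0) * self.Zgty)
            if use1:
                ZtX_parts.append(np.sqrt(g1) * self.ZgetX)
                Zty_parts.append(np.sqrt(g1) * self.Zgety)
            ZtX = np.vstack(ZtX_parts)
            Zty = np.concatenate(Zty_parts)
            if use0 and use1:
                c = np.sqrt(g0 * g1)
                M = np.block(
                    [
                        [np.diag(1.0 + g0 * self.dg), c * self.G12],
                        [c * self.G12.T, np.diag(1.0 + g1 * self.dge)],
                    ]
                )
            elif use0:
                M = np.diag(1.0 + g0 * self.dg)
            else:
                M = np.diag(1.0 + g1 * self.dge)
            cf = cho_factor(M, lower=True)
            logdetH = 2.0 * np.log(np.diag(cf[0])).sum()
            MiZtX = cho_solve(cf, ZtX)
            MiZty = cho_solve(cf, Zty)
            XtHiX = self.XtX - ZtX.T @ MiZtX
            XtHiy = self.Xty - ZtX.T @ MiZty
            yHiy = self.yty - float(Zty @ MiZty)
        beta = np.linalg.solve(XtHiX, XtHiy)
        quad = max(yHiy - float(beta @ XtHiy), 1e-300)
        if reml:
            dof = self.n - self.p
            s2 = quad / dof
            _, logdetXtHiX = np.linalg.slogdet(XtHiX)
            return -0.5 * (
                dof * (math.log(2 * math.pi * s2) + 1.0) + logdetH + logdetXtHiX
            )
        s2 = quad / self.n
        return -0.5 * (self.n * (math.log(2 * math.pi * s2) + 1.0) + logdetH)


def _optimize_gamma(y, X, Zg, Zge, *, reml: bool, free=(True, True)):
    """Maximize the (restricted) likelihood over the free variance ratios."""
    suff = _Suff(y, X, Zg, Zge)

    def pack(theta):
        gamma = np.zeros(2)
        it = iter(theta)
        for i, f in enumerate(free):
            gamma[i] = next(it) if f else 0.0
        return gamma

    def negll(theta):
        try:
            return -suff.loglik(pack(theta), reml=reml)
        except np.linalg.LinAlgError:
            return 1e12

    k = sum(free)
    if k == 0:
        ll, s2, beta, Hir = _profile(y, X, Zg, Zge, np.zeros(2), reml=reml)
        return np.zeros(2), ll, s2, beta, Hir
    starts = [np.full(k, 0.1), np.full(k, 1.5)]
    best = None
    trace = []
    for x0 in starts:
        res = optimize.minimize(
            negll,
            x0,
            method="L-BFGS-B",
            bounds=[(0.0, 1e8)] * k,
            options={"ftol": 1e-12, "gtol": 1e-9, "maxiter": _MAX_ITER},
        )
        trace.append(res)
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError(f"variance-ratio optimization failed: {trace}")
    # simplex polish for the last digits (the quasi-Newton step size floors
    # out near the optimum with a forward-difference gradient)
    res = optimize.minimize(
        negll,
        best.x,
        method="Nelder-Mead",
        options={"fatol": _LOGLIK_TOL * 1e-2, "xatol": 1e-9, "maxiter": 400},
    )
    if np.isfinite(res.fun) and res.fun <= best.fun:
        best = res
    if not np.isfinite(best.fun):
        raise ConvergenceError(f"REML did not converge: {trace + [res]}")
    gamma = pack(np.clip(best.x, 0.0, None))
    ll, s2, beta, Hir = _profile(y, X, Zg, Zge, gamma, reml=reml)
    return gamma, ll, s2, beta, Hir


# ---------------------------------------------------------------------------
# public fitting API


def _prepare(data: TrialData, trait: str):
    data.spec(trait)
    tab = data.table.loc[data.table[trait].notna()].reset_index(drop=True)
    if tab["genotype"].nunique() < 2:
        raise ValueError("mixed model needs at least two genotypes")
    g = tab["genotype"].nunique()
    if len(tab) < g + 2:
        raise ValueError(
            f"trait {trait!r}: needs at least g+2={g + 2} non-missing observations"
        )
    return tab


def fit_reml(data: TrialData, trait: str, *, ml: bool = False) -> TraitFit:
    """Fit the genotype + genotype-by-environment mixed model by REML.

    Convergence criterion: successive restricted log-likelihoods within
    1e-8 (optimizer function tolerance); variance ratios are constrained
    non-negative, so boundary solutions report exact zeros.  ``ml=True``
    additionally runs the maximum-likelihood fit and fills ``ml_loglik``
    (needed for fixed-effect comparisons; NaN otherwise).
    """
    tab = _prepare(data, trait)
    y = tab[trait].to_numpy(dtype=float)
    X, names, env_cols, Zg, Zge, genotypes, envs = _design(tab)
    design = summarize_design(TrialData(table=tab, trait_specs=[data.spec(trait)]))

    scale = float(np.var(y))
    if scale <= 1e-28 * (1.0 + float(np.mean(y)) ** 2):
        # degenerate: constant response, all variance at zero
        return _degenerate_fit(trait, design, tab, names, genotypes, envs, float(y.mean()))

    # with a single environment the interaction is confounded with genotype
    free = (True, len(envs) > 1)
    gamma, ll, s2, beta, Hir = _optimize_gamma(y, X, Zg, Zge, reml=True, free=free)
    ml_ll = math.nan
    if ml:
        _, ml_ll, *_ = _optimize_gamma(y, X, Zg, Zge, reml=False, free=free)

    blup_g = gamma[0] * (Zg.T @ Hir)
    blup_ge = gamma[1] * (Zge.T @ Hir)

    grand_mean, env_dev = _fixed_summaries(tab, names, env_cols, beta, envs)
    e = len(envs)
    return TraitFit(
        trait=trait,
        design=design,
        grand_mean=grand_mean,
        fixed_effects=pd.Series(beta, index=names),
        env_effects=env_dev,
        var_g=float(gamma[0] * s2),
        var_ge=float(gamma[1] * s2),
        var_e=float(s2),
        blup_g=pd.Series(blup_g, index=pd.Index(genotypes, name="genotype")),
        blup_ge=pd.Series(
            blup_ge,
            index=pd.MultiIndex.from_product(
                [genotypes, envs], names=["genotype", "environment"]
            ),
        ),
        restricted_loglik=float(ll),
        ml_loglik=float(ml_ll),
        n_used=len(y),
    )


def _fixed_summaries(tab, names, env_cols, beta, envs):
    """Grand mean and per-environment deviations implied by the fixed part.

    Evaluated on the complete environment x block grid, so block contrasts
    (sum-to-zero) drop out and the grand mean is the equally-weighted mean
    over environments.
    """
    e = len(envs)
    env_means = {}
    for j, env in enumerate(envs):
        mean_row = np.zeros(len(names))
        mean_row[0] = 1.0
        if j >= 1:
            mean_row[env_cols[j - 1]] = 1.0
        env_means[env] = float(mean_row @ beta)
    grand = float(np.mean(list(env_means.values())))
    dev = pd.Series({env: m - grand for env, m in env_means.items()}, name="env_effect")
    dev.index.name = "environment"
    return grand, dev


def _degenerate_fit(trait, design, tab, names, genotypes, envs, c):
    beta = np.zeros(len(names))
    beta[0] = c
    return TraitFit(
        trait=trait,
        design=design,
        grand_mean=c,
        fixed_effects=pd.Series(beta, index=names),
        env_effects=pd.Series(0.0, index=pd.Index(envs, name="environment")),
        var_g=0.0,
        var_ge=0.0,
        var_e=0.0,
        blup_g=pd.Series(0.0, index=pd.Index(genotypes, name="genotype")),
        blup_ge=pd.Series(
            0.0,
            index=pd.MultiIndex.from_product(
                [genotypes, envs], names=["genotype", "environment"]
            ),
        ),
        restricted_loglik=math.inf,
        ml_loglik=math.inf,
        n_used=len(tab),
    )


def blup_means(
    fit: TraitFit, level: Literal["genotype", "genotype-environment"] = "genotype"
) -> pd.DataFrame:
    """Predicted means from a fitted model.

    ``genotype``: grand mean + genotype BLUP (performance across both
    environments).  ``genotype-environment``: adds the environment deviation
    and the interaction BLUP (cell-level prediction).
    """
    if level == "genotype":
        out = (fit.grand_mean + fit.blup_g).rename("predicted").reset_index()
        return out
    if level == "genotype-environment":
        idx = fit.blup_ge.index
        env_dev = fit.env_effects.reindex(idx.get_level_values("environment")).to_numpy()
        alpha = fit.blup_g.reindex(idx.get_level_values("genotype")).to_numpy()
        pred = fit.grand_mean + env_dev + alpha + fit.blup_ge.to_numpy()
        return pd.DataFrame(
            {
                "genotype": idx.get_level_values("genotype"),
                "environment": idx.get_level_values("environment"),
                "predicted": pred,
            }
        )
    raise ValueError(f"unknown level {level!r}")


def lrt_random(
    data: TrialData,
    trait: str,
    term: Literal["genotype", "genotype-environment"],
) -> LRTResult:
    """REML likelihood-ratio test of a random term (chi-square, 1 df).

    The statistic is twice the gain in restricted log-likelihood from adding
    the term, clamped at zero.  The plain chi2(1) reference is conservative
    for a variance component on the boundary.
    """
    tab = _prepare(data, trait)
    y = tab[trait].to_numpy(dtype=float)
    X, *_rest = _design(tab)
    names, env_cols, Zg, Zge = _rest[0], _rest[1], _rest[2], _rest[3]
    free_full = (True, True)
    if term == "genotype":
        free_red = (False, True)
    elif term == "genotype-environment":
        free_red = (True, False)
    else:
        raise ValueError(f"unknown random term {term!r}")
    _, ll_full, *_ = _optimize_gamma(y, X, Zg, Zge, reml=True, free=free_full)
    _, ll_red, *_ = _optimize_gamma(y, X, Zg, Zge, reml=True, free=free_red)
    stat = max(2.0 * (ll_full - ll_red), 0.0)
    return LRTResult(
        term=term, statistic=stat, df=1, p_value=float(stats.chi2.sf(stat, 1))
    )


def test_fixed_effects(data: TrialData, trait: str) -> LRTResult:
    """ML likelihood-ratio test of the fixed environment effect (df = e-1)."""
    tab = _prepare(data, trait)
    envs = sorted(tab["environment"].unique())
    if len(envs) < 2:
        raise ValueError("environment test needs at least two environments")
    y = tab[trait].to_numpy(dtype=float)
    X, names, env_cols, Zg, Zge, *_ = _design(tab)
    keep = [i for i in range(X.shape[1]) if i not in env_cols]
    X_red = X[:, keep]
    _, ll_full, *_ = _optimize_gamma(y, X, Zg, Zge, reml=False)
    _, ll_red, *_ = _optimize_gamma(y, X_red, Zg, Zge, reml=False)
    stat = max(2.0 * (ll_full - ll_red), 0.0)
    df = len(envs) - 1
    return LRTResult(
        term="environment", statistic=stat, df=df, p_value=float(stats.chi2.sf(stat, df))
    )


# ---------------------------------------------------------------------------
# convenience: all traits at once


def fit_all_traits(data: TrialData) -> dict[str, TraitFit]:
    return {spec.name: fit_reml(data, spec.name) for spec in data.trait_specs}


def genotype_blup_matrix(fits: dict[str, TraitFit]) -> pd.DataFrame:
    """Genotype x trait matrix of predicted genotype means (MGIDI input)."""
    cols = {}
    for trait, fit in fits.items():
        cols[trait] = fit.grand_mean + fit.blup_g
    return pd.DataFrame(cols)


def genotype_environment_blup_matrix(fits: dict[str, TraitFit]) -> pd.DataFrame:
    """(genotype, environment) x trait matrix of predicted cell means."""
    cols = {}
    for trait, fit in fits.items():
        bm = blup_means(fit, "genotype-environment")
        cols[trait] = bm.set_index(["genotype", "environment"])["predicted"]
    return pd.DataFrame(cols)
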