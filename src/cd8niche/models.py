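"""Association models: Kendall correlation, zero-inflated negative binomial
regression by EM, quadratic-vs-linear model comparison, and a rank-based
differential-expression utility.

The ZINB model is a two-part mixture: with probability pi an observation is
a structural zero, otherwise it is NB2 with mean mu = exp(x beta) and
dispersion theta (variance mu + mu^2/theta). Fitting is
expectation-maximization with the zero-membership posterior as the latent
variable and a warm-started quasi-Newton inner step for (beta, log theta);
a guard keeps the observed log-likelihood non-decreasing across iterations.
Covariate effects are tested by likelihood ratio against the
intercept-only model.

``rank_de`` is a plain two-sided Mann–Whitney screen per gene with BH
correction — a deliberately simple rank-based utility for contrasting cell
groups (e.g. lymphoid-aggregate cells vs surrounding immune cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator, RegressorMixin
from statsmodels.stats.multitest import multipletests

__all__ = [
    "kendall_tau",
    "ZINBFit",
    "ZINBRegressor",
    "fit_zinb",
    "quadratic_vs_linear",
    "ModelComparison",
    "rank_de",
]


# --------------------------------------------------------------------------
# Kendall tau

def kendall_tau(x: Sequence[float], y: Sequence[float]) -> dict:
    """Kendall tau-b with tie correction.

    p-value by exact enumeration for n <= 8 without ties, normal
    approximation otherwise. Zero variance in either input returns
    ``computable=False``.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size != yv.size:
        raise ValueError("x and y must have equal length")
    if xv.size < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(xv).size < 2 or np.unique(yv).size < 2:
        return {"computable": False, "reason": "zero variance"}
    no_ties = (np.unique(xv).size == xv.size) and (np.unique(yv).size == yv.size)
    method = "exact" if (xv.size <= 8 and no_ties) else "asymptotic"
    res = stats.kendalltau(xv, yv, variant="b", method=method)
    return {"computable": True, "tau": float(res.statistic),
            "p": float(res.pvalue), "method": method}


# --------------------------------------------------------------------------
# Zero-inflated negative binomial (EM)

@dataclass
class ZINBFit:
    """Fitted ZINB: mixing weight pi, log-link mean coefficients, dispersion."""

    pi: float
    beta: np.ndarray
    theta: float
    loglik: float
    converged: bool
    n_iter: int
    loglik_trace: np.ndarray
    lrt_stat: Optional[float] = None
    lrt_df: Optional[int] = None
    lrt_p: Optional[float] = None

    @property
    def mu_intercept(self) -> float:
        return float(np.exp(self.beta[0]))


def _nb_logpmf(y: np.ndarray, mu: np.ndarray, theta: float) -> np.ndarray:
    return (special.gammaln(y + theta) - special.gammaln(theta)
            - special.gammaln(y + 1)
            + theta * (np.log(theta) - np.log(theta + mu))
            + y * (np.log(mu) - np.log(theta + mu)))


def _zinb_loglik(y: np.ndarray, mu: np.ndarray, theta: float, pi: float) -> float:
    ll_nb = _nb_logpmf(y, mu, theta)
    zero = y == 0
    out = np.empty_like(mu)
    # log(pi + (1-pi) * NB(0)) via logaddexp for stability
    out[zero] = np.logaddexp(np.log(pi) if pi > 0 else -np.inf,
                             np.log1p(-pi) + ll_nb[zero])
    out[~zero] = np.log1p(-pi) + ll_nb[~zero]
    return float(out.sum())


def _weighted_nb_obj(params: np.ndarray, X: np.ndarray, y: np.ndarray,
                     w: np.ndarray) -> float:
    beta, logtheta = params[:-1], params[-1]
    theta = np.exp(np.clip(logtheta, -10, 10))
    eta = np.clip(X @ beta, -25, 25)
    mu = np.exp(eta)
    return -float((w * _nb_logpmf(y, mu, theta)).sum())


def fit_zinb(counts: Sequence[int], design: Optional[np.ndarray] = None,
             max_iter: int = 500, tol: float = 1e-6,
             test_covariates: bool = True) -> ZINBFit:
    """Fit a ZINB model by EM; optionally LRT the covariate slopes.

    ``design`` is the covariate matrix *without* intercept (one is
    prepended); None fits an intercept-only model. The LRT compares the
    full model to the intercept-only null with df = number of covariate
    columns (chi-square reference).
    """
    y = np.asarray(counts, dtype=float)
    if y.size == 0 or (y < 0).any() or not np.allclose(y, np.round(y)):
        raise ValueError("counts must be nonnegative integers")
    if not (y > 0).any():
        raise ValueError("all counts are zero; ZINB not identifiable")
    if design is None:
        X = np.ones((y.size, 1))
    else:
        D = np.asarray(design, dtype=float)
        if D.ndim == 1:
            D = D[:, None]
        X = np.column_stack([np.ones(y.size), D])
    n_params = X.shape[1] + 2
    if y.size < 10 * n_params:
        raise ValueError(f"need n >= {10 * n_params} observations "
                         f"for {n_params} parameters")

    # initialization
    pos_mean = y[y > 0].mean()
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(pos_mean)
    logtheta = 0.0
    pi = min(0.9, 0.5 * float((y == 0).mean()))
    params = np.concatenate([beta, [logtheta]])

    zero = y == 0
    ll_trace = []
    theta = np.exp(logtheta)
    mu = np.exp(np.clip(X @ beta, -25, 25))
    ll = _zinb_loglik(y, mu, theta, pi)
    converged = False
    for it in range(max_iter):
        # E-step: posterior that a zero is structural
        nb0 = np.exp(_nb_logpmf(np.zeros(zero.sum()), mu[zero], theta))
        w_struct = np.zeros(y.size)
        if pi > 0:
            w_struct[zero] = pi / (pi + (1 - pi) * nb0)
        # M-step
        pi_new = float(np.clip(w_struct.mean(), 0.0, 1 - 1e-12))
        w_nb = 1.0 - w_struct
        res = optimize.minimize(_weighted_nb_obj, params, args=(X, y, w_nb),
                                method="L-BFGS-B",
                                options={"maxiter": 30, "ftol": 1e-10})
        cand = res.x if res.fun <= _weighted_nb_obj(params, X, y, w_nb) else params
        beta_new, logtheta_new = cand[:-1], cand[-1]
        theta_new = np.exp(np.clip(logtheta_new, -10, 10))
        mu_new = np.exp(np.clip(X @ beta_new, -25, 25))
        ll_new = _zinb_loglik(y, mu_new, theta_new, pi_new)
        if ll_new + 1e-9 < ll:
            # guard: generalized EM must not decrease the objective
            break
        params, pi, mu, theta, ll = cand, pi_new, mu_new, theta_new, ll_new
        ll_trace.append(ll)
        if it > 0 and len(ll_trace) >= 2 and abs(ll_trace[-1] - ll_trace[-2]) < tol:
            converged = True
            break

    fit = ZINBFit(pi=pi, beta=params[:-1].copy(), theta=float(theta),
                  loglik=ll, converged=converged, n_iter=len(ll_trace),
                  loglik_trace=np.array(ll_trace))
    if test_covariates and X.shape[1] > 1:
        null = fit_zinb(counts, design=None, max_iter=max_iter, tol=tol,
                        test_covariates=False)
        stat = max(0.0, 2.0 * (fit.loglik - null.loglik))
        df = X.shape[1] - 1
        fit.lrt_stat = stat
        fit.lrt_df = df
        fit.lrt_p = float(stats.chi2.sf(stat, df))
    return fit


class ZINBRegressor(BaseEstimator, RegressorMixin):
    """sklearn-style wrapper for ZINB regression of counts on covariates.

    ``fit(X, y)`` fits counts ``y`` on covariates ``X`` (intercept added).
    Fitted attributes: ``pi_``, ``beta_``, ``theta_``, ``loglik_``,
    ``converged_``, ``lrt_p_``. ``predict(X)`` returns the marginal mean
    (1 − pi) · exp(x beta).
    """

    def __init__(self, max_iter: int = 500, tol: float = 1e-6):
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        res = fit_zinb(y, design=np.asarray(X, dtype=float),
                       max_iter=self.max_iter, tol=self.tol)
        self.pi_ = res.pi
        self.beta_ = res.beta
        self.theta_ = res.theta
        self.loglik_ = res.loglik
        self.converged_ = res.converged
        self.lrt_p_ = res.lrt_p
        self.result_ = res
        return self

    def predict(self, X):
        D = np.asarray(X, dtype=float)
        if D.ndim == 1:
            D = D[:, None]
        Xd = np.column_stack([np.ones(len(D)), D])
        return (1 - self.pi_) * np.exp(Xd @ self.beta_)


# --------------------------------------------------------------------------
# Quadratic vs linear model comparison

@dataclass
class ModelComparison:
    r2_linear: float
    r2_quadratic: float
    lrt_stat: float
    df: int
    p: float
    coef_linear: np.ndarray = field(default_factory=lambda: np.array([]))
    coef_quadratic: np.ndarray = field(default_factory=lambda: np.array([]))


def quadratic_vs_linear(x: Sequence[float], y: Sequence[float]) -> ModelComparison:
    """OLS fits of y~x and y~x+x² with an LRT for the quadratic term.

    LRT = n·log(RSS_linear / RSS_quadratic), df = 1, chi-square reference.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size != yv.size or xv.size < 4:
        raise ValueError("need equal-length x, y with n >= 4")
    if np.unique(xv).size < 3:
        raise ValueError("x is degenerate (fewer than 3 distinct values)")
    X1 = np.column_stack([np.ones_like(xv), xv])
    X2 = np.column_stack([np.ones_like(xv), xv, xv ** 2])
    b1, *_ = np.linalg.lstsq(X1, yv, rcond=None)
    b2, *_ = np.linalg.lstsq(X2, yv, rcond=None)
    rss1 = float(((yv - X1 @ b1) ** 2).sum())
    rss2 = float(((yv - X2 @ b2) ** 2).sum())
    tss = float(((yv - yv.mean()) ** 2).sum())
    if tss == 0:
        raise ValueError("y is constant")
    r2_1 = 1.0 - rss1 / tss
    r2_2 = 1.0 - rss2 / tss
    n = xv.size
    eps = np.finfo(float).tiny
    lrt = max(0.0, n * np.log(max(rss1, eps) / max(rss2, eps)))
    p = float(stats.chi2.sf(lrt, 1))
    return ModelComparison(r2_1, r2_2, lrt, 1, p, b1, b2)


# --------------------------------------------------------------------------
# Rank-based differential expression

def rank_de(group_a: pd.DataFrame, group_b: pd.DataFrame) -> pd.DataFrame:
    """Per-gene two-sided Mann–Whitney screen between two cell groups.

    Returns a gene table with the U statistic, p, BH FDR, and the log2
    fold change of group means (pseudocount 1). Genes constant across both
    groups get p = 1.
    """
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("both groups need at least 3 cells")
    genes = [g for g in group_a.columns if g in set(group_b.columns)]
    rows = []
    for g in genes:
        a = group_a[g].to_numpy(dtype=float)
        b = group_b[g].to_numpy(dtype=float)
        if np.unique(np.concatenate([a, b])).size < 2:
            u, p = a.size * b.size / 2.0, 1.0
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="asymptotic")
            u, p = float(res.statistic), float(res.pvalue)
        lfc = float(np.log2((a.mean() + 1.0) / (b.mean() + 1.0)))
        rows.append((g, u, p, lfc))
    df = pd.DataFrame(rows, columns=["gene", "U", "p", "log2_fc"])
    df["fdr"] = multipletests(df["p"], method="fdr_bh")[1]
    return df.sort_values(["p", "gene"]).reset_index(drop=True)
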