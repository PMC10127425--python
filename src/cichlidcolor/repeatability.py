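"""Variance-component repeatability (intraclass correlation) with
parametric-bootstrap confidence intervals and a likelihood-ratio p-value.

The model is the Gaussian random-intercept model

    value_ij = mu + u_i + e_ij,   u_i ~ N(0, sigma2_between),
                                  e_ij ~ N(0, sigma2_within)

and repeatability is R = sigma2_between / (sigma2_between + sigma2_within):
the fraction of variance attributable to consistent differences among
individuals. Variances are estimated by REML; the one-way structure lets
the profiled REML criterion be optimized over the single variance ratio
theta = sigma2_between / sigma2_within, which makes bootstrap refits cheap.

The p-value tests sigma2_between = 0 by a likelihood-ratio statistic (ML
fits) referred to the boundary mixture 0.5*chi2_0 + 0.5*chi2_1; a label
permutation test is available as a cross-check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import chi2

logger = logging.getLogger(__name__)

_LOG_THETA_BOUNDS = (-14.0, 18.0)


@dataclass(frozen=True)
class RepeatabilityResult:
    R: float
    SE: float
    CI: tuple[float, float]
    p: float
    n_groups: int
    n_obs: int
    sigma2_between: float = np.nan
    sigma2_within: float = np.nan


# ---------------------------------------------------------------------------
# Sufficient statistics and profiled criteria
# ---------------------------------------------------------------------------

def _suffstats(values, group_ids):
    """Group sizes, group means, within-group SS and N for one-way data."""
    y = np.asarray(values, dtype=float)
    _, idx = np.unique(np.asarray(group_ids), return_inverse=True)
    G = idx.max() + 1
    n_i = np.bincount(idx, minlength=G).astype(float)
    sums = np.bincount(idx, weights=y, minlength=G)
    ybar = sums / n_i
    ssw = float(np.sum((y - ybar[idx]) ** 2))
    return n_i, ybar, ssw, y.size


def _profile_crit(theta, n_i, ybar, ssw, N, reml):
    """Profiled -2 log-likelihood (up to a constant) at variance ratio theta."""
    w = 1.0 / (1.0 + n_i * theta)
    nw = n_i * w
    mu = np.dot(nw, ybar) / nw.sum()
    Q = ssw + np.dot(nw, (ybar - mu) ** 2)
    crit = np.sum(np.log1p(n_i * theta))
    if reml:
        return (N - 1) * np.log(Q) + crit + np.log(nw.sum())
    return N * np.log(Q) + crit


def _fit_theta(n_i, ybar, ssw, N, reml=True):
    """Minimize the profiled criterion over theta >= 0.

    Optimizes over log(theta) and compares against the theta = 0 boundary;
    a negative between-group variance is thereby clamped at zero.
    """
    obj = lambda u: _profile_crit(np.exp(u), n_i, ybar, ssw, N, reml)
    res = optimize.minimize_scalar(
        obj, bounds=_LOG_THETA_BOUNDS, method="bounded",
        options={"xatol": 1e-11},
    )
    crit0 = _profile_crit(0.0, n_i, ybar, ssw, N, reml)
    if crit0 <= res.fun:
        return 0.0, crit0
    return float(np.exp(res.x)), float(res.fun)


def fit_variance_components(values, group_ids):
    """REML estimates (sigma2_between, sigma2_within, loglik) for the
    random-intercept model. Negative between-group estimates are clamped
    at the boundary (theta = 0) and logged."""
    n_i, ybar, ssw, N = _suffstats(values, group_ids)
    if n_i.size < 2:
        raise ValueError("need at least 2 groups")
    if not np.any(n_i >= 2):
        raise ValueError("all groups are singletons: within-group variance undefined")
    if ssw == 0.0 and np.ptp(ybar) > 0:
        # degenerate: replicates identical within every individual
        s2b = float(np.dot(n_i, (ybar - np.average(ybar, weights=n_i)) ** 2) / (N - 1))
        return s2b, 0.0, np.inf
    theta, crit = _fit_theta(n_i, ybar, ssw, N, reml=True)
    if theta == 0.0:
        logger.debug("between-group variance estimated at the zero boundary")
    w = 1.0 / (1.0 + n_i * theta)
    nw = n_i * w
    mu = np.dot(nw, ybar) / nw.sum()
    Q = ssw + np.dot(nw, (ybar - mu) ** 2)
    s2w = Q / (N - 1)
    loglik = -0.5 * (crit - (N - 1) * np.log(Q) + (N - 1) * (np.log(s2w) + 1)
                     + (N - 1) * np.log(2 * np.pi))
    return float(theta * s2w), float(s2w), float(loglik)


def repeatability(sigma2_between: float, sigma2_within: float) -> float:
    """R = sigma2_between / (sigma2_between + sigma2_within)."""
    if sigma2_between < 0 or sigma2_within < 0:
        raise ValueError("variances must be non-negative")
    total = sigma2_between + sigma2_within
    if total == 0:
        raise ValueError("both variance components are zero: R undefined")
    return sigma2_between / total


def _fit_R(n_i, ybar, ssw, N):
    if ssw == 0.0:
        return 1.0
    theta, _ = _fit_theta(n_i, ybar, ssw, N, reml=True)
    return theta / (1.0 + theta)


def estimate_R(values, group_ids) -> float:
    """Point estimate of repeatability from raw grouped data."""
    n_i, ybar, ssw, N = _suffstats(values, group_ids)
    return float(_fit_R(n_i, ybar, ssw, N))


# ---------------------------------------------------------------------------
# Likelihood-ratio p-value
# ---------------------------------------------------------------------------

def lrt_statistic(values, group_ids) -> float:
    """LR statistic for sigma2_between = 0 (ML fits, >= 0 by construction)."""
    n_i, ybar, ssw, N = _suffstats(values, group_ids)
    if ssw == 0.0:
        return np.inf if np.ptp(ybar) > 0 else 0.0
    theta, _ = _fit_theta(n_i, ybar, ssw, N, reml=False)
    w = 1.0 / (1.0 + n_i * theta)
    nw = n_i * w
    mu = np.dot(nw, ybar) / nw.sum()
    Q = ssw + np.dot(nw, (ybar - mu) ** 2)
    neg2_full = N * np.log(Q) + np.sum(np.log1p(n_i * theta))
    # null: iid Gaussian, sigma2 = SST / N
    grand = (np.dot(n_i, ybar)) / N
    sst = ssw + np.dot(n_i, (ybar - grand) ** 2)
    neg2_null = N * np.log(sst)
    return float(max(0.0, neg2_null - neg2_full))


def lrt_pvalue(values, group_ids) -> float:
    """Boundary-mixture p-value: P = 0.5*chi2_1.sf(LR) for LR > 0, 1 at 0."""
    lr = lrt_statistic(values, group_ids)
    if lr <= 0:
        return 1.0
    return float(0.5 * chi2.sf(lr, df=1))


def permutation_pvalue(values, group_ids, n_perm: int = 1000, seed: int = 0) -> float:
    """Permutation test of R = 0: shuffle values across groups."""
    y = np.asarray(values, dtype=float)
    g = np.asarray(group_ids)
    r_obs = estimate_R(y, g)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if estimate_R(rng.permutation(y), g) >= r_obs:
            count += 1
    return (1 + count) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Parametric bootstrap
# ---------------------------------------------------------------------------

def bootstrap_repeatability(values, group_ids, n_boot: int = 1000, seed: int = 0):
    """Parametric-bootstrap SE and 95% CI for R.

    Datasets are simulated from the fitted random-intercept model on the
    observed group structure, each refit by REML; SE is the SD of the
    bootstrap replicates and the CI their 2.5/97.5 percentiles. Refit
    failures are counted and reported if they exceed 5%.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    n_i, ybar, ssw, N = _suffstats(values, group_ids)
    s2b, s2w, _ = fit_variance_components(values, group_ids)
    G = n_i.size
    idx = np.repeat(np.arange(G), n_i.astype(int))
    rng = np.random.default_rng(seed)

    u = rng.normal(0.0, np.sqrt(s2b), (n_boot, G))
    e = rng.normal(0.0, np.sqrt(s2w), (n_boot, N))
    r_star = np.empty(n_boot)
    n_fail = 0
    for b in range(n_boot):
        yb = u[b, idx] + e[b]
        sums = np.bincount(idx, weights=yb, minlength=G)
        yb_bar = sums / n_i
        ssw_b = float(np.sum((yb - yb_bar[idx]) ** 2))
        try:
            r_star[b] = _fit_R(n_i, yb_bar, ssw_b, N)
        except Exception:  # pragma: no cover - fit failures are pathological
            r_star[b] = np.nan
            n_fail += 1
    if n_fail > 0.05 * n_boot:
        logger.warning("%d of %d bootstrap refits failed", n_fail, n_boot)
    ok = r_star[np.isfinite(r_star)]
    se = float(ok.std(ddof=1))
    lo, hi = np.percentile(ok, [2.5, 97.5])
    return se, (float(lo), float(hi))


def repeatability_analysis(
    values, group_ids, n_boot: int = 1000, seed: int = 0, method: str = "lrt",
    n_perm: int = 1000,
) -> RepeatabilityResult:
    """Full repeatability workup: R, bootstrap SE/CI and a p-value."""
    s2b, s2w, _ = fit_variance_components(values, group_ids)
    R = repeatability(s2b, s2w)
    se, ci = bootstrap_repeatability(values, group_ids, n_boot=n_boot, seed=seed)
    if method == "lrt":
        p = lrt_pvalue(values, group_ids)
    elif method == "permutation":
        p = permutation_pvalue(values, group_ids, n_perm=n_perm, seed=seed)
    else:
        raise ValueError(f"unknown method {method!r}")
    n_i, _, _, N = _suffstats(values, group_ids)
    return RepeatabilityResult(
        R=float(R), SE=se, CI=ci, p=float(p), n_groups=int(n_i.size), n_obs=int(N),
        sigma2_between=s2b, sigma2_within=s2w,
    )
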