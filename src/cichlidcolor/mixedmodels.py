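"""Small mixed-model engine: Gaussian and binomial-logit models with
crossed random intercepts, sized for the datasets this package analyzes
(hundreds of observations, a handful of variance components).

Gaussian models profile the fixed effects and residual variance out of the
marginal likelihood and optimize only the variance ratios, using dense
Cholesky factorizations of the n x n marginal correlation matrix.
Binomial models use the Laplace approximation: the random effects (jointly
with the fixed effects) are found by penalized Newton iterations, and the
log-determinant correction is taken over the random-effect block.

Likelihood-ratio tests between nested fits use ML (never REML) log
likelihoods; that is what the model-reduction procedures in
:mod:`cichlidcolor.behavior_stats` rely on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit

logger = logging.getLogger(__name__)

_LOG_VAR_BOUNDS = (-12.0, 8.0)   # bounds on log(theta) / log(sigma)


def _factor_indices(labels) -> tuple[np.ndarray, int]:
    _, idx = np.unique(np.asarray(labels), return_inverse=True)
    return idx, int(idx.max()) + 1


@dataclass
class MixedFit:
    """Result of one mixed-model fit."""

    loglik: float
    beta: np.ndarray
    fixed_names: list[str]
    variance_components: dict[str, float]
    converged: bool = True
    separation: bool = False
    scale: float = np.nan  # residual variance (Gaussian only)

    def coef(self, name: str) -> float:
        return float(self.beta[self.fixed_names.index(name)])


# ---------------------------------------------------------------------------
# Gaussian LMM
# ---------------------------------------------------------------------------

def fit_lmm(
    y: np.ndarray,
    X: np.ndarray,
    fixed_names: list[str],
    random_factors: dict[str, np.ndarray],
) -> MixedFit:
    """ML fit of y = X beta + sum_k Z_k u_k + e with crossed intercepts.

    A random factor with fewer than two levels cannot support a variance
    component; it is dropped with a logged warning and the model degrades
    gracefully toward an ordinary linear model.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = y.size

    blocks = []  # (name, n x n incidence Gram matrix Z Z')
    for name, labels in random_factors.items():
        idx, q = _factor_indices(labels)
        if q < 2:
            logger.warning("random factor %r has %d level(s); dropped", name, q)
            continue
        Z = np.zeros((n, q))
        Z[np.arange(n), idx] = 1.0
        blocks.append((name, Z @ Z.T))
    k = len(blocks)

    def crit(log_theta: np.ndarray) -> float:
        R = np.eye(n)
        for (_, G), lt in zip(blocks, log_theta):
            R = R + np.exp(lt) * G
        c, low = cho_factor(R, lower=True)
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        Ri_X = cho_solve((c, low), X)
        Ri_y = cho_solve((c, low), y)
        XtRiX = X.T @ Ri_X
        beta = np.linalg.solve(XtRiX, X.T @ Ri_y)
        resid = y - X @ beta
        q = float(resid @ cho_solve((c, low), resid))
        return n * np.log(q / n) + logdet

    if k == 0:
        theta = np.empty(0)
    else:
        if k == 1:
            res = optimize.minimize_scalar(
                lambda u: crit(np.array([u])), bounds=_LOG_VAR_BOUNDS,
                method="bounded", options={"xatol": 1e-8},
            )
            theta = np.array([res.x])
        else:
            res = optimize.minimize(
                crit, np.full(k, -1.0), method="Nelder-Mead",
                options={"xatol": 1e-5, "fatol": 1e-8, "maxfev": 400},
            )
            theta = np.clip(res.x, *_LOG_VAR_BOUNDS)

    # final pass at the optimum to extract estimates
    R = np.eye(n)
    for (_, G), lt in zip(blocks, theta):
        R = R + np.exp(lt) * G
    c, low = cho_factor(R, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    XtRiX = X.T @ cho_solve((c, low), X)
    beta = np.linalg.solve(XtRiX, X.T @ cho_solve((c, low), y))
    resid = y - X @ beta
    qform = float(resid @ cho_solve((c, low), resid))
    s2 = qform / n
    loglik = -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)
    vc = {name: float(np.exp(lt) * s2) for (name, _), lt in zip(blocks, theta)}
    return MixedFit(
        loglik=float(loglik), beta=beta, fixed_names=list(fixed_names),
        variance_components=vc, scale=s2,
    )


# ---------------------------------------------------------------------------
# Binomial GLMM (Laplace)
# ---------------------------------------------------------------------------

_SEPARATION_BETA = 15.0


def fit_glmm_binomial(
    y: np.ndarray,
    X: np.ndarray,
    fixed_names: list[str],
    random_factors: dict[str, np.ndarray],
    max_newton: int = 50,
) -> MixedFit:
    """Laplace-approximate ML fit of a binomial-logit mixed model.

    The variance parameters are optimized on the log-sigma scale by
    Nelder-Mead; at each candidate, fixed effects and random-effect modes
    are found jointly by penalized Newton iterations (the fixed effects are
    unpenalized), and the Laplace correction determinant is computed over
    the random-effect block only.

    Quasi-complete separation shows up as runaway coefficients; fits with
    any |beta| above 15 on the logit scale are flagged, not raised.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape

    Zs, names, qs = [], [], []
    for name, labels in random_factors.items():
        idx, q = _factor_indices(labels)
        if q < 2:
            logger.warning("random factor %r has %d level(s); dropped", name, q)
            continue
        Z = np.zeros((n, q))
        Z[np.arange(n), idx] = 1.0
        Zs.append(Z)
        names.append(name)
        qs.append(q)
    k = len(Zs)
    T = np.hstack([X] + Zs) if k else X
    qtot = sum(qs)
    state = {"v": np.zeros(p + qtot)}

    def laplace_negloglik(log_sigma: np.ndarray) -> float:
        sig2 = np.exp(2.0 * np.clip(log_sigma, *_LOG_VAR_BOUNDS))
        prec = np.concatenate(
            [np.zeros(p)] + [np.full(q, 1.0 / s2) for q, s2 in zip(qs, sig2)]
        )
        v = state["v"].copy()
        for _ in range(max_newton):
            eta = T @ v
            mu = expit(eta)
            w = mu * (1.0 - mu) + 1e-10
            grad = T.T @ (y - mu) - prec * v
            H = (T.T * w) @ T + np.diag(prec)
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                H = H + 1e-8 * np.eye(H.shape[0])
                step = np.linalg.solve(H, grad)
            # halve the step until the penalized objective does not worsen
            vnew = v + step
            if not np.all(np.isfinite(vnew)):
                break
            v = vnew
            if np.max(np.abs(grad)) < 1e-8:
                break
        state["v"] = v
        eta = T @ v
        mu = expit(eta)
        w = mu * (1.0 - mu) + 1e-10
        ll_cond = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        u = v[p:]
        penalty = 0.5 * float(np.sum(prec[p:] * u**2))
        # log det (I + D^{1/2} Z' W Z D^{1/2}) over the random-effect block
        if qtot:
            Zall = T[:, p:]
            d_half = np.concatenate(
                [np.full(q, np.sqrt(s2)) for q, s2 in zip(qs, sig2)]
            )
            M = (Zall.T * w) @ Zall * np.outer(d_half, d_half)
            M[np.diag_indices_from(M)] += 1.0
            sign, logdet = np.linalg.slogdet(M)
            if sign <= 0:
                return np.inf
        else:
            logdet = 0.0
        return -(ll_cond - penalty - 0.5 * logdet)

    if k == 0:
        nll = laplace_negloglik(np.empty(0))
        sig = np.empty(0)
    elif k == 1:
        res = optimize.minimize_scalar(
            lambda u: laplace_negloglik(np.array([u])),
            bounds=(-5.0, 3.0), method="bounded", options={"xatol": 1e-4},
        )
        sig = np.array([res.x])
        nll = res.fun
    else:
        res = optimize.minimize(
            laplace_negloglik, np.full(k, -0.7), method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-6, "maxfev": 300},
        )
        sig = res.x
        nll = res.fun

    nll = laplace_negloglik(sig)  # refresh state at the optimum
    beta = state["v"][:p]
    vc = {name: float(np.exp(2.0 * s)) for name, s in zip(names, sig)}
    separated = bool(np.any(np.abs(beta) > _SEPARATION_BETA))
    if separated:
        logger.warning("possible complete separation: max |beta| = %.1f", np.abs(beta).max())
    return MixedFit(
        loglik=float(-nll), beta=beta, fixed_names=list(fixed_names),
        variance_components=vc, separation=separated,
    )
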