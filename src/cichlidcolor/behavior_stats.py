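"""Statistics for the dyadic-contest analysis.

Covers the full statistical chain around the dominance experiment:
normality screening (Lilliefors-corrected Kolmogorov-Smirnov), Box-Cox
transformation toward normality, two-sample comparisons (Welch t, Wilcoxon
rank sum, paired t), the binomial mixed model for dominance with stepwise
single-term likelihood-ratio reduction, linear mixed models for the color
variables with a display x dominance interaction (plus subset models per
dominance status), and the method-switching correlation matrix (Pearson
where both variables pass normality, Spearman otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors as _sm_lilliefors

from .mixedmodels import MixedFit, fit_glmm_binomial, fit_lmm

DOMINANCE_PREDICTORS = ("display", "attacks", "SL", "LC_before", "RCA_before")


@dataclass(frozen=True)
class ModelTermResult:
    """Likelihood-ratio test of a single model term (df always 1)."""

    term: str
    chi_square: float
    df: int
    p: float
    estimate_sign: int  # sign of the fitted coefficient in the full model
    separation: bool = False


@dataclass(frozen=True)
class CorrelationCell:
    r: float
    p: float
    method: str  # "pearson" | "spearman" | "undefined"


# ---------------------------------------------------------------------------
# Distribution checks and transformations
# ---------------------------------------------------------------------------

def lilliefors_normality(x) -> tuple[float, float]:
    """Kolmogorov-Smirnov test against a normal with estimated moments,
    with the Lilliefors small-sample p-value approximation."""
    x = np.asarray(x, dtype=float)
    if x.size < 5:
        raise ValueError("Lilliefors test needs at least 5 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant vector: normality test undefined")
    stat, p = _sm_lilliefors(x, dist="norm", pvalmethod="approx")
    return float(stat), float(p)


def box_cox(x) -> tuple[float, np.ndarray]:
    """Box-Cox power transform with lambda chosen by maximum likelihood.

    Returns ``(lambda, transformed)`` where the transform is
    (x^lambda - 1)/lambda, or log(x) at lambda = 0.
    """
    x = np.asarray(x, dtype=float)
    n_bad = int(np.sum(x <= 0))
    if n_bad:
        raise ValueError(f"Box-Cox requires positive values; {n_bad} are <= 0")
    transformed, lam = stats.boxcox(x)
    return float(lam), transformed


def two_sample_tests(x, y, kind: str):
    """Welch t, Wilcoxon rank sum, or paired t; returns (statistic, df, p).

    The Wilcoxon test uses exact enumeration of the rank-sum distribution
    for small tie-free samples (n1 + n2 <= 50) and the tie-corrected normal
    approximation otherwise; df is None for it. Two-sided throughout.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per sample")
    if kind == "welch_t":
        res = stats.ttest_ind(x, y, equal_var=False)
        return float(res.statistic), float(res.df), float(res.pvalue)
    if kind == "paired_t":
        if x.size != y.size:
            raise ValueError("paired test requires equal lengths")
        res = stats.ttest_rel(x, y)
        return float(res.statistic), float(x.size - 1), float(res.pvalue)
    if kind == "wilcoxon":
        pooled = np.concatenate([x, y])
        has_ties = np.unique(pooled).size < pooled.size
        method = "exact" if (not has_ties and pooled.size <= 50) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        return float(res.statistic), None, float(res.pvalue)
    raise ValueError(f"unknown test kind {kind!r}")


# ---------------------------------------------------------------------------
# Mixed models with stepwise LRT reduction
# ---------------------------------------------------------------------------

def _standardize(col: np.ndarray) -> np.ndarray:
    sd = col.std()
    return (col - col.mean()) / sd if sd > 0 else col - col.mean()


def _design(df: pd.DataFrame, terms: list[str], standardize: bool = True) -> np.ndarray:
    cols = [np.ones(len(df))]
    for t in terms:
        if ":" in t:
            a, b = t.split(":")
            v = df[a].to_numpy(float) * df[b].to_numpy(float)
        else:
            v = df[t].to_numpy(float)
        cols.append(_standardize(v) if standardize else v)
    return np.column_stack(cols)


def _lrt(full: MixedFit, reduced: MixedFit, term: str) -> ModelTermResult:
    chi2_stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p = float(stats.chi2.sf(chi2_stat, df=1))
    sign = int(np.sign(full.coef(term)))
    return ModelTermResult(
        term=term, chi_square=float(chi2_stat), df=1, p=p, estimate_sign=sign,
        separation=full.separation or reduced.separation,
    )


def fit_dominance_glmm(
    df: pd.DataFrame, predictors=DOMINANCE_PREDICTORS
) -> list[ModelTermResult]:
    """Binomial GLMM for dominance with family and trial random intercepts.

    Each explanatory variable (display, attacks, SL, LC and RCA before the
    trial) is tested by a likelihood-ratio test against the model with that
    single term deleted; degrees of freedom therefore always differ by one.
    Predictors are standardized internally (the LRTs are invariant to this).
    Complete separation is flagged on the affected terms, never raised.
    """
    y = df["dominant"].to_numpy(float)
    if not np.all(np.isin(y, [0.0, 1.0])):
        raise ValueError("dominance response must be binary")
    random_factors = {
        "family": df["family"].to_numpy(),
        "trial": df["trial"].to_numpy(),
    }
    predictors = list(predictors)
    full = fit_glmm_binomial(
        y, _design(df, predictors), ["intercept"] + predictors, random_factors
    )
    results = []
    for term in predictors:
        rest = [t for t in predictors if t != term]
        reduced = fit_glmm_binomial(
            y, _design(df, rest), ["intercept"] + rest, random_factors
        )
        results.append(_lrt(full, reduced, term))
    return results


def fit_color_lmm(
    df: pd.DataFrame,
    response: str = "RCA_before",
    with_interaction: bool = True,
    subset: str = "all",
) -> list[ModelTermResult]:
    """Linear mixed models for a color variable (RCA or LC before trials).

    ``subset='all'``: response ~ display + dominance (+ display:dominance),
    random intercepts for family and trial. The interaction is tested by
    comparing the models with and without the product term (both containing
    the main effects); main effects are tested by single-term deletion from
    the additive model.

    ``subset='dominant'`` / ``'subordinate'``: display only, family as the
    sole random factor; the returned term carries the display slope's sign.
    """
    if subset == "all":
        data = df
        random_factors = {
            "family": data["family"].to_numpy(),
            "trial": data["trial"].to_numpy(),
        }
        terms_add = ["display", "dominant"]
        y = data[response].to_numpy(float)
        additive = fit_lmm(y, _design(data, terms_add), ["intercept"] + terms_add,
                           random_factors)
        results = []
        if with_interaction:
            terms_full = terms_add + ["display:dominant"]
            full = fit_lmm(y, _design(data, terms_full),
                           ["intercept"] + terms_full, random_factors)
            results.append(_lrt(full, additive, "display:dominant"))
        for term in terms_add:
            rest = [t for t in terms_add if t != term]
            reduced = fit_lmm(y, _design(data, rest), ["intercept"] + rest,
                              random_factors)
            results.append(_lrt(additive, reduced, term))
        return results

    if subset not in ("dominant", "subordinate"):
        raise ValueError(f"unknown subset {subset!r}")
    data = df[df["dominant"] == (1 if subset == "dominant" else 0)]
    if len(data) == 0:
        raise ValueError(f"subset {subset!r} is empty")
    y = data[response].to_numpy(float)
    random_factors = {"family": data["family"].to_numpy()}
    full = fit_lmm(y, _design(data, ["display"]), ["intercept", "display"],
                   random_factors)
    null = fit_lmm(y, _design(data, []), ["intercept"], random_factors)
    return [_lrt(full, null, "display")]


# ---------------------------------------------------------------------------
# Correlation matrix with per-cell method choice
# ---------------------------------------------------------------------------

def correlation_matrix(
    df: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Pairwise correlations: Pearson where both variables pass the
    Lilliefors normality screen at ``alpha``, Spearman otherwise.

    Returns a square DataFrame of :class:`CorrelationCell`; constant
    columns yield cells marked ``undefined``.
    """
    cols = list(df.columns)
    normal = {}
    for c in cols:
        x = df[c].dropna().to_numpy(float)
        try:
            _, p = lilliefors_normality(x)
            normal[c] = p > alpha
        except ValueError:
            normal[c] = None  # constant or too short
    out = pd.DataFrame(index=cols, columns=cols, dtype=object)
    for i, a in enumerate(cols):
        for b in cols[i:]:
            if a == b:
                cell = CorrelationCell(1.0, 0.0, "pearson")
            else:
                pair = df[[a, b]].dropna()
                if len(pair) < 3 or normal[a] is None or normal[b] is None:
                    cell = CorrelationCell(np.nan, np.nan, "undefined")
                elif normal[a] and normal[b]:
                    r, p = stats.pearsonr(pair[a], pair[b])
                    cell = CorrelationCell(float(r), float(p), "pearson")
                else:
                    r, p = stats.spearmanr(pair[a], pair[b])
                    cell = CorrelationCell(float(r), float(p), "spearman")
            out.loc[a, b] = cell
            out.loc[b, a] = cell
    return out
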