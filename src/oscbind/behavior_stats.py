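"""Behavioral and brain-behavior statistics.

Normality screening (Shapiro-Wilk), paired Wilcoxon signed-rank tests with
Rosenthal's effect size r = Z / sqrt(n), the binding effect (overlapping
minus non-overlapping), and multiple linear regression with backward
elimination (drop the weakest predictor while its partial-F removal p is
above the threshold, SPSS-style POUT = 0.10) with Durbin-Watson, VIF and
standardized-residual diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.stats.stattools import durbin_watson

EXACT_WILCOXON_MAX_N = 25


def shapiro_wilk(sample: np.ndarray) -> tuple[float, float]:
    x = np.asarray(sample, float)
    if not (3 <= len(x) <= 5000):
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float  # signed rank sum T = W+ - W-
    z: float
    p: float
    r: float
    n: int  # number of pairs entering the test


def _signed_rank_exact_sf(w_plus: float, ranks: np.ndarray) -> tuple[float, float]:
    """Exact P(W+ <= w) and P(W+ >= w) by convolution over sign patterns."""
    # distribution of W+ on a half-unit lattice (ties give .5 average ranks)
    scale = 2  # doubled ranks stay integer
    r2 = np.round(ranks * scale).astype(int)
    dist = np.zeros(r2.sum() + 1)
    dist[0] = 1.0
    for r in r2:
        nxt = dist.copy()
        if r > 0:
            nxt[r:] += dist[:-r]
        else:
            nxt += dist
        dist = nxt
    dist /= dist.sum()
    w2 = int(round(w_plus * scale))
    cdf = dist.cumsum()
    p_le = float(cdf[min(w2, len(dist) - 1)])
    p_ge = float(dist[w2:].sum()) if w2 < len(dist) else 0.0
    return p_le, p_ge


def wilcoxon_signed_rank(a: np.ndarray, b: np.ndarray) -> PairedTestResult:
    """Paired Wilcoxon signed-rank test.

    Zero differences are dropped.  Exact p by sign-pattern enumeration
    for n <= 25 (ties handled on the half-unit rank lattice); otherwise a
    continuity-corrected normal approximation.  z always carries the sign
    of (a - b)'s rank sum so that a deficit in ``a`` gives negative z, and
    r = z / sqrt(n) with n the number of non-zero pairs.
    """
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    w_minus = ranks[d < 0].sum()
    T = w_plus - w_minus
    mu = n * (n + 1) / 4.0
    # tie-corrected variance of W+
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / 48.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    if sigma == 0:
        raise ValueError("degenerate rank variance")
    cc = 0.5 if abs(w_plus - mu) > 0.5 else 0.0
    z = (w_plus - mu - np.sign(w_plus - mu) * cc) / sigma
    if n <= EXACT_WILCOXON_MAX_N:
        p_le, p_ge = _signed_rank_exact_sf(w_plus, ranks)
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        p = 2.0 * stats.norm.sf(abs(z))
    return PairedTestResult(
        statistic=float(T), z=float(z), p=float(p), r=float(z / np.sqrt(n)), n=n
    )


def effect_size_r(z: float, n: int) -> float:
    """Rosenthal's r = Z / sqrt(n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return z / np.sqrt(n)


def binding_effect(overlapping: float, non_overlapping: float) -> float:
    """The binding effect: overlapping minus non-overlapping."""
    return overlapping - non_overlapping


@dataclass
class EliminationStep:
    predictors: list
    adjusted_r2: float
    removed: Optional[str]
    removal_p: Optional[float]
    max_vif: float


@dataclass
class RegressionResult:
    predictors: list  # retained predictor names
    beta_standardized: dict
    p_values: dict
    adjusted_r2: float
    f_stat: float
    df: tuple[int, int]
    f_pvalue: float
    durbin_watson: float
    vif: dict
    std_residual_min: float
    std_residual_max: float
    steps: list = field(default_factory=list)


def _vifs(X: pd.DataFrame) -> dict:
    if X.shape[1] < 2:
        return {c: 1.0 for c in X.columns}
    exog = sm.add_constant(X).to_numpy()
    return {
        c: float(variance_inflation_factor(exog, i + 1))
        for i, c in enumerate(X.columns)
    }


def backward_elimination(
    y: np.ndarray,
    X: pd.DataFrame,
    removal_p: float = 0.10,
) -> RegressionResult:
    """Backward elimination multiple regression.

    Starting from the full model, repeatedly remove the predictor whose
    partial F-test for removal (equivalently its coefficient t-test) has
    the largest p, as long as that p is at or above ``removal_p``; stop
    when removing any remaining predictor would significantly decrease R².
    Reports standardized betas, adjusted R², the model F test,
    Durbin-Watson, per-predictor VIF and standardized residual extremes,
    plus the full elimination trace.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, float), columns=[f"x{i}" for i in range(np.asarray(X).shape[1])])
    y = np.asarray(y, float)
    n, k = X.shape
    if n <= k + 1:
        raise ValueError("need n subjects > n predictors + 1")
    if np.linalg.matrix_rank(X.to_numpy()) < k:
        # name an offending collinear pair via correlation
        corr = np.corrcoef(X.to_numpy(), rowvar=False)
        np.fill_diagonal(corr, 0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"collinear predictors: {X.columns[i]!r} and {X.columns[j]!r}"
        )

    cols = list(X.columns)
    steps: list[EliminationStep] = []
    while cols:
        model = sm.OLS(y, sm.add_constant(X[cols])).fit()
        pvals = model.pvalues.drop("const")
        vifs = _vifs(X[cols])
        worst = pvals.idxmax()
        if pvals[worst] >= removal_p and len(cols) >= 1:
            steps.append(
                EliminationStep(
                    predictors=list(cols),
                    adjusted_r2=float(model.rsquared_adj),
                    removed=str(worst),
                    removal_p=float(pvals[worst]),
                    max_vif=max(vifs.values()),
                )
            )
            cols.remove(worst)
        else:
            steps.append(
                EliminationStep(
                    predictors=list(cols),
                    adjusted_r2=float(model.rsquared_adj),
                    removed=None,
                    removal_p=None,
                    max_vif=max(vifs.values()),
                )
            )
            break

    if not cols:
        resid = y - y.mean()
        sd = resid.std(ddof=1)
        std_resid = resid / sd if sd > 0 else resid
        return RegressionResult(
            predictors=[],
            beta_standardized={},
            p_values={},
            adjusted_r2=0.0,
            f_stat=float("nan"),
            df=(0, n - 1),
            f_pvalue=float("nan"),
            durbin_watson=float(durbin_watson(resid)),
            vif={},
            std_residual_min=float(std_resid.min()),
            std_residual_max=float(std_resid.max()),
            steps=steps,
        )

    model = sm.OLS(y, sm.add_constant(X[cols])).fit()
    sy = y.std(ddof=1)
    beta_std = {
        c: float(model.params[c] * X[c].std(ddof=1) / sy) for c in cols
    }
    mse = model.mse_resid
    std_resid = model.resid / np.sqrt(mse)
    return RegressionResult(
        predictors=list(cols),
        beta_standardized=beta_std,
        p_values={c: float(model.pvalues[c]) for c in cols},
        adjusted_r2=float(model.rsquared_adj),
        f_stat=float(model.fvalue),
        df=(int(model.df_model), int(model.df_resid)),
        f_pvalue=float(model.f_pvalue),
        durbin_watson=float(durbin_watson(model.resid)),
        vif=_vifs(X[cols]),
        std_residual_min=float(std_resid.min()),
        std_residual_max=float(std_resid.max()),
        steps=steps,
    )
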