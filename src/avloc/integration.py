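"""Multisensory-integration metrics and observed-vs-predicted comparisons.

Redundancy gain (RG) quantifies the bimodal improvement over the best
unimodal condition as a relative dispersion reduction,

    RG = 100 * (VE_best - VE_VA) / VE_best   [%]

(positive = multisensory improvement; the printed variance-ratio form
sigma_VA^2 / sigma_V^2 * 100 is exposed separately as
``redundancy_gain_printed`` — it is a residual-variance percentage, not a
gain, and is inconsistent with the gain values it accompanies).  Inverse
effectiveness is the correlation of per-target RG with the dispersion of
the best unimodal estimate: the poorer the best single cue, the more is
gained by adding the second.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "RegressionStep",
    "FieldComparison",
    "redundancy_gain",
    "redundancy_gain_printed",
    "inverse_effectiveness",
    "hierarchical_regression",
    "compare_fields",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    defined: bool = True


@dataclass(frozen=True)
class RegressionStep:
    predictors: tuple[str, ...]
    r2: float
    adj_r2: float
    r2_change: float
    f_change: float
    p_change: float
    rank_deficient: bool = False


@dataclass(frozen=True)
class FieldComparison:
    mean_difference: float
    t: float
    p: float
    correlation: CorrelationResult
    n: int


def redundancy_gain(ve_best_unimodal, ve_bimodal):
    """Relative dispersion reduction of the bimodal condition, percent.

    Accepts scalars or arrays; the best-unimodal dispersion must be
    positive.
    """
    best = np.asarray(ve_best_unimodal, dtype=float)
    bim = np.asarray(ve_bimodal, dtype=float)
    if np.any(best <= 0):
        raise ValueError("best unimodal VE must be positive")
    out = 100.0 * (best - bim) / best
    return float(out) if out.ndim == 0 else out


def redundancy_gain_printed(var_bimodal, var_best_unimodal):
    """Residual-variance percentage 100 * sigma_VA^2 / sigma_best^2."""
    best = np.asarray(var_best_unimodal, dtype=float)
    if np.any(best <= 0):
        raise ValueError("best unimodal variance must be positive")
    out = 100.0 * np.asarray(var_bimodal, dtype=float) / best
    return float(out) if out.ndim == 0 else out


def inverse_effectiveness(rg_per_target, ve_best_per_target,
                          square: bool = False) -> CorrelationResult:
    """Pearson correlation of RG with best-unimodal dispersion (or variance).

    A zero-variance input makes the product-moment coefficient undefined;
    that case is flagged (``defined=False``) rather than propagating NaN.
    """
    rg = np.asarray(rg_per_target, dtype=float)
    ve = np.asarray(ve_best_per_target, dtype=float)
    if rg.shape != ve.shape or rg.ndim != 1:
        raise ValueError("inputs must be matched 1D sequences")
    if rg.size < 3:
        raise ValueError("need at least 3 targets")
    if square:
        ve = ve ** 2
    if np.std(rg) == 0 or np.std(ve) == 0:
        return CorrelationResult(np.nan, np.nan, rg.size, defined=False)
    r, p = stats.pearsonr(rg, ve)
    return CorrelationResult(float(r), float(p), rg.size)


def hierarchical_regression(response, ordered_predictors: pd.DataFrame):
    """Nested OLS fits, predictors entered in the given column order.

    Returns ``(steps, vif)``: one RegressionStep per nested model with the
    R^2 change of the newly entered predictor and its F/p, plus the
    variance inflation factor of every predictor in the full model.
    """
    import statsmodels.api as sm
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    y = np.asarray(response, dtype=float)
    x_all = ordered_predictors.astype(float)
    n, k = x_all.shape
    if n <= k + 1:
        raise ValueError("need more observations than predictors + 1")

    steps: list[RegressionStep] = []
    prev_r2, prev_df_resid = 0.0, n - 1
    for j in range(1, k + 1):
        cols = list(x_all.columns[:j])
        design = sm.add_constant(x_all[cols])
        fit = sm.OLS(y, design).fit()
        rank_deficient = np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]
        r2 = float(fit.rsquared)
        dr2 = r2 - prev_r2
        df_resid = float(fit.df_resid)
        if df_resid > 0 and r2 < 1.0 - 1e-12:
            f_change = dr2 / 1.0 / ((1.0 - r2) / df_resid)
            p_change = float(stats.f.sf(f_change, 1, df_resid))
        else:
            f_change, p_change = np.inf, 0.0
        steps.append(
            RegressionStep(
                predictors=tuple(cols),
                r2=r2,
                adj_r2=float(fit.rsquared_adj),
                r2_change=dr2,
                f_change=float(f_change),
                p_change=p_change,
                rank_deficient=rank_deficient,
            )
        )
        prev_r2 = r2

    full = sm.add_constant(x_all).to_numpy()
    vif = pd.Series(
        [variance_inflation_factor(full, i) for i in range(1, full.shape[1])],
        index=list(x_all.columns),
        name="vif",
    )
    return steps, vif


def compare_fields(observed, predicted) -> FieldComparison:
    """Paired comparison of an observed and a predicted per-target metric.

    Returns the mean difference (observed - predicted), the paired t
    statistic with its two-sided p value, and the across-target Pearson
    correlation.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be matched 1D sequences")
    if obs.size < 3:
        raise ValueError("need at least 3 targets")
    diff = obs - pred
    if np.std(diff) == 0:
        t, p = (0.0, 1.0) if np.allclose(diff, diff[0]) and diff[0] == 0 else (np.inf, 0.0)
        if diff[0] != 0:
            t = np.sign(diff[0]) * np.inf
    else:
        t, p = stats.ttest_rel(obs, pred)
    if np.std(obs) == 0 or np.std(pred) == 0:
        corr = CorrelationResult(np.nan, np.nan, obs.size, defined=False)
    else:
        r, pr = stats.pearsonr(obs, pred)
        corr = CorrelationResult(float(r), float(pr), obs.size)
    return FieldComparison(
        mean_difference=float(diff.mean()),
        t=float(t),
        p=float(p),
        correlation=corr,
        n=obs.size,
    )
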