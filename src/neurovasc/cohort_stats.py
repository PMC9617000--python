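"""Cohort-level statistics.

Robust linear correlations between physiology and cognition (iteratively
reweighted least squares with a Tukey bisquare loss), Benjamini-Hochberg
FDR correction at q = 0.05, forward stepwise covariate selection by
adjusted R^2, longitudinal intelligence-change scores, and the attrition
ledger.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RobustFitResult",
    "CorrelationRow",
    "AttritionLedger",
    "robust_fit",
    "fdr_adjust",
    "stepwise_select",
    "delta_iq",
    "attrition_accounting",
    "correlation_table",
]

TUKEY_C = 4.685


@dataclass
class RobustFitResult:
    beta: float
    intercept: float
    r_squared: float
    p_value: float
    n_used: int


@dataclass
class CorrelationRow:
    predictor: str
    outcome: str
    beta: float
    r_squared: float
    p: float
    p_fdr: float
    significant: bool
    n_used: int


@dataclass
class AttritionLedger:
    enrolled: int
    exclusions: dict[str, int]
    completed: int

    def reconciles(self) -> bool:
        return self.enrolled == self.completed + sum(self.exclusions.values())


def robust_fit(x, y) -> RobustFitResult:
    """Robust simple linear regression of y on x.

    Tukey-bisquare IRLS (c = 4.685) with a Huber scale estimate; the p
    value for the slope uses the normal approximation of the IRLS
    estimator.  R^2 is computed on the weighted fit.  A numerically
    perfect linear relation degenerates the scale estimate, so the exact
    OLS solution is returned in that case.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant")
    X = sm.add_constant(x)
    ols = sm.OLS(y, X).fit()
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0 or float(ols.ssr) <= 1e-12 * max(tss, 1.0):
        # perfect (or constant-response) fit: IRLS scale collapses
        r2 = 1.0 if tss > 0 else 0.0
        return RobustFitResult(
            beta=float(ols.params[1]),
            intercept=float(ols.params[0]),
            r_squared=r2,
            p_value=float(min(ols.pvalues[1], 1.0)) if tss > 0 else 1.0,
            n_used=n,
        )
    rlm = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(c=TUKEY_C)).fit(
        scale_est=sm.robust.scale.HuberScale()
    )
    w = rlm.weights
    fitted = rlm.fittedvalues
    ybar_w = float((w * y).sum() / w.sum())
    ss_res = float((w * (y - fitted) ** 2).sum())
    ss_tot = float((w * (y - ybar_w) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return RobustFitResult(
        beta=float(rlm.params[1]),
        intercept=float(rlm.params[0]),
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        p_value=float(rlm.pvalues[1]),
        n_used=n,
    )


def fdr_adjust(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns ``(adjusted_p, significant)`` where significance is tested at
    level ``q``.  Adjusted p values are monotone nondecreasing in rank.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p values supplied")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p values must lie in (0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def stepwise_select(
    candidates: pd.DataFrame, response, order: list[str] | None = None
) -> tuple[list[str], float]:
    """Forward stepwise OLS selection maximizing adjusted R^2.

    Covariates are added greedily while the adjusted R^2 improves; ties
    go to the earlier covariate in the declared order.  Returns
    ``(selected_names, adjusted_r2)``; an empty candidate set yields the
    intercept-only model.
    """
    y = np.asarray(response, dtype=float)
    names = list(order) if order is not None else list(candidates.columns)
    selected: list[str] = []
    best_adj = 0.0  # adjusted R^2 of the intercept-only model
    improved = True
    while improved and len(selected) < len(names):
        improved = False
        best_candidate = None
        for name in names:
            if name in selected:
                continue
            cols = selected + [name]
            X = sm.add_constant(candidates[cols].to_numpy(dtype=float))
            if len(y) <= X.shape[1] + 1:
                continue
            fit = sm.OLS(y, X).fit()
            adj = float(fit.rsquared_adj)
            if adj > best_adj + 1e-12:
                best_adj = adj
                best_candidate = name
                improved = True
        if best_candidate is not None:
            selected.append(best_candidate)
    return selected, best_adj


def delta_iq(score_late, score_early) -> np.ndarray:
    """Longitudinal intelligence change: z-score both measurements across
    the cohort, then subtract (later - earlier)."""
    a = np.asarray(score_late, dtype=float)
    b = np.asarray(score_early, dtype=float)
    if a.shape != b.shape:
        raise ValueError("score vectors must cover the same subjects")

    def z(v):
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValueError("zero variance in a score vector")
        return (v - v.mean()) / sd

    return z(a) - z(b)


def attrition_accounting(enrolled: int, exclusions: dict[str, int]) -> AttritionLedger:
    """Completed-n bookkeeping: enrolled minus the per-reason exclusions."""
    if enrolled < 0 or any(v < 0 for v in exclusions.values()):
        raise ValueError("counts must be nonnegative")
    completed = enrolled - sum(exclusions.values())
    if completed < 0:
        raise ValueError("exclusions exceed enrollment")
    return AttritionLedger(enrolled=enrolled, exclusions=dict(exclusions), completed=completed)


def correlation_table(
    cohort: pd.DataFrame,
    predictors: list[str],
    outcomes: list[str],
    q: float = 0.05,
) -> pd.DataFrame:
    """Robust correlation of every outcome with every predictor.

    One :func:`robust_fit` per (predictor, outcome) pair on complete
    cases; FDR correction is applied within each predictor family.
    """
    if cohort.empty:
        raise ValueError("cohort table is empty")
    rows: list[CorrelationRow] = []
    for pred in predictors:
        fam: list[CorrelationRow] = []
        for out in outcomes:
            res = robust_fit(cohort[pred], cohort[out])
            fam.append(
                CorrelationRow(
                    predictor=pred,
                    outcome=out,
                    beta=res.beta,
                    r_squared=res.r_squared,
                    p=res.p_value,
                    p_fdr=np.nan,
                    significant=False,
                    n_used=res.n_used,
                )
            )
        p_adj, rej = fdr_adjust([max(r.p, np.finfo(float).tiny) for r in fam], q=q)
        for r, pa, rj in zip(fam, p_adj, rej):
            r.p_fdr = float(pa)
            r.significant = bool(rj)
        rows.extend(fam)
    return pd.DataFrame([r.__dict__ for r in rows])
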