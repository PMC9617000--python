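"""Breath-hold cerebrovascular reactivity.

Sagittal-sinus blood flow (phase-contrast) and venous saturation
(susceptibility oximetry) are acquired simultaneously per dynamic during
a paradigm of two 36-s breath holds.  Per-dynamic A-V.O2 = SaO2 - SvO2(t)
and Fick CMRO2(t) = [Hgb] * flow(t) * A-V.O2(t) are derived; each series
is expressed as percent change from its own pre-first-hold baseline mean
and regressed on a cohort-mean regressor normalized to its largest
response, so the coefficient reads directly as the percent change at the
response peak (dCBF_BH, dA-V.O2, dCMRO2_BH).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core import BreathHoldParadigm

__all__ = [
    "BreathHoldSeries",
    "BreathHoldResult",
    "baseline_mask",
    "percent_change_series",
    "derive_series",
    "build_population_regressor",
    "fit_series_glm",
    "fit_breath_hold_glm",
]


@dataclass
class BreathHoldSeries:
    """Simultaneous per-dynamic sagittal-sinus flow and venous saturation.

    ``times`` are dynamic midpoints (s); ``flow`` in ml/min; ``svo2``
    fractional; ``sao2`` a scalar (pulse oximetry); ``hgb`` mmol/l.
    """

    times: np.ndarray
    flow: np.ndarray
    svo2: np.ndarray
    sao2: float
    hgb: float
    paradigm: BreathHoldParadigm

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        self.svo2 = np.asarray(self.svo2, dtype=float)
        if not len(self.times) == len(self.flow) == len(self.svo2):
            raise ValueError("time, flow and saturation series must align")
        if baseline_mask(self.times, self.paradigm).sum() < 3:
            raise ValueError("baseline window must contain at least 3 samples")


@dataclass
class BreathHoldResult:
    """Percent changes from baseline at the regressor peak."""

    dcbf_bh: float
    davo2_bh: float
    dcmro2_bh: float
    dcbf_p: float
    dcmro2_p: float


def baseline_mask(times: np.ndarray, paradigm: BreathHoldParadigm) -> np.ndarray:
    """Dynamics fully inside the pre-first-hold baseline window.

    A dynamic with midpoint t and spacing dt spans [t - dt/2, t + dt/2];
    it counts as baseline when the whole span precedes the first hold.
    """
    times = np.asarray(times, dtype=float)
    dt = np.median(np.diff(times)) if len(times) > 1 else 0.0
    return (times + dt / 2.0) <= paradigm.baseline + 1e-9


def percent_change_series(
    y: np.ndarray, times: np.ndarray, paradigm: BreathHoldParadigm
) -> np.ndarray:
    """Series as percent change from the pre-hold baseline mean."""
    y = np.asarray(y, dtype=float)
    base = y[baseline_mask(times, paradigm)]
    b = base.mean()
    if b == 0:
        raise ValueError("degenerate baseline (zero mean)")
    return 100.0 * (y / b - 1.0)


def derive_series(series: BreathHoldSeries) -> tuple[np.ndarray, np.ndarray]:
    """Per-dynamic A-V.O2 and Fick CMRO2 series.

    avo2(t) = SaO2 - SvO2(t); cmro2(t) = [Hgb] * flow(t) * avo2(t).
    Constants cancel in the percent-change analyses, but the Fick form is
    kept so the series have physiological units.
    """
    avo2 = series.sao2 - series.svo2
    if np.any(avo2 < 0):
        raise ValueError("negative arteriovenous saturation difference")
    cmro2 = series.hgb * series.flow * avo2
    return avo2, cmro2


def build_population_regressor(pct_series: Sequence[np.ndarray]) -> np.ndarray:
    """Cohort-mean response normalized to the largest response.

    ``pct_series`` are per-subject percent-change-from-baseline series on
    a common dynamic grid.  They are averaged per dynamic and divided by
    the maximum absolute value (responses may be negative, e.g. A-V.O2).
    """
    if len(pct_series) == 0:
        raise ValueError("need at least one subject")
    arr = np.asarray(pct_series, dtype=float)
    mean = arr.mean(axis=0)
    peak = np.max(np.abs(mean))
    if peak == 0:
        raise ValueError("flat cohort response: cannot normalize regressor")
    return mean / peak


def fit_series_glm(
    y: np.ndarray,
    times: np.ndarray,
    paradigm: BreathHoldParadigm,
    regressor: np.ndarray,
) -> tuple[float, float]:
    """OLS of the percent-change series on [intercept, regressor].

    With the regressor normalized to peak 1, the coefficient is the
    percent change from baseline at the response peak.  Returns
    ``(beta, p_value)``.
    """
    pct = percent_change_series(y, times, paradigm)
    x = np.asarray(regressor, dtype=float)
    if len(x) != len(pct):
        raise ValueError("regressor and series lengths differ")
    xc = x - x.mean()
    yc = pct - pct.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise ValueError("regressor has zero variance")
    beta = float(yc @ xc) / sxx
    resid = yc - beta * xc
    dof = len(yc) - 2
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(sigma2 / sxx)
    p = 0.0 if se == 0 else 2.0 * stats.t.sf(abs(beta) / se, dof)
    return beta, float(p)


def fit_breath_hold_glm(
    series: BreathHoldSeries,
    flow_regressor: np.ndarray,
    avo2_regressor: Optional[np.ndarray] = None,
    cmro2_regressor: Optional[np.ndarray] = None,
) -> BreathHoldResult:
    """Fit flow, A-V.O2 and CMRO2 percent-change series.

    Each quantity is fitted against its own cohort-mean regressor; if the
    A-V.O2 or CMRO2 regressors are omitted the flow regressor is reused
    (same response timing, possibly different sign captured by beta).

    The reported change is beta scaled by the regressor value at its
    largest absolute response (+/-1 after normalization), so a decrease
    — e.g. A-V.O2 during the hold — is reported with a negative sign
    even though its regressor peaks at -1.
    """

    def extreme(reg):
        reg = np.asarray(reg, dtype=float)
        return float(reg[np.argmax(np.abs(reg))])

    avo2, cmro2 = derive_series(series)
    if avo2_regressor is None:
        avo2_regressor = flow_regressor
    if cmro2_regressor is None:
        cmro2_regressor = flow_regressor
    dcbf, p_cbf = fit_series_glm(series.flow, series.times, series.paradigm, flow_regressor)
    davo2, _ = fit_series_glm(avo2, series.times, series.paradigm, avo2_regressor)
    dcmro2, p_cm = fit_series_glm(cmro2, series.times, series.paradigm, cmro2_regressor)
    return BreathHoldResult(
        dcbf_bh=dcbf * extreme(flow_regressor),
        davo2_bh=davo2 * extreme(avo2_regressor),
        dcmro2_bh=dcmro2 * extreme(cmro2_regressor),
        dcbf_p=p_cbf,
        dcmro2_p=p_cm,
    )
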