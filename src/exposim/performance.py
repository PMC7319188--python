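"""Aggregation of replicate fits into simulation performance measures."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .fitting import FitResult
from .outcomes import CRFSet

__all__ = ["HorizonSummary", "PerformanceSummary", "summarize"]

_Z95 = 1.96


@dataclass(frozen=True)
class HorizonSummary:
    """Performance measures for one exposure horizon (ST or LT).

    ``pct_bias`` is None when the true coefficient is zero; then
    ``abs_bias`` (mean estimate minus truth, per 10 ug/m3) is the
    reported bias measure and ``bias_is_absolute`` is set.
    """

    horizon: str
    true_value: float  # per 10 ug/m3
    mean_est: float
    mean_se: float
    pct_bias: Optional[float]
    abs_bias: float
    bias_is_absolute: bool
    coverage: float  # percent
    power: float  # percent
    t_stat: float
    t_pvalue: float


@dataclass(frozen=True)
class PerformanceSummary:
    st: HorizonSummary
    lt: HorizonSummary
    n_effective: int
    n_sims: int
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_effective > self.n_sims:
            raise ValueError("n_effective cannot exceed n_sims")


def _summarize_horizon(est: np.ndarray, se: np.ndarray, true10: float, name: str) -> HorizonSummary:
    mean_est = float(est.mean())
    mean_se = float(se.mean())
    abs_bias = mean_est - true10
    if true10 != 0.0:
        pct_bias: Optional[float] = 100.0 * abs_bias / true10
        is_abs = False
    else:
        pct_bias = None
        is_abs = True
    lo, hi = est - _Z95 * se, est + _Z95 * se
    coverage = 100.0 * float(np.mean((lo <= true10) & (true10 <= hi)))
    power = 100.0 * float(np.mean(np.abs(est / se) > _Z95))
    if est.size > 1 and est.std(ddof=1) > 0:
        t_stat, t_p = stats.ttest_1samp(est, true10)
    else:
        t_stat, t_p = (0.0, 1.0) if abs_bias == 0 else (np.inf, 0.0)
    return HorizonSummary(
        horizon=name,
        true_value=true10,
        mean_est=mean_est,
        mean_se=mean_se,
        pct_bias=pct_bias,
        abs_bias=float(abs_bias),
        bias_is_absolute=is_abs,
        coverage=coverage,
        power=power,
        t_stat=float(t_stat),
        t_pvalue=float(t_p),
    )


def summarize(
    fits: Sequence[FitResult],
    truth: CRFSet,
    labels: Optional[dict] = None,
) -> PerformanceSummary:
    """Summarize replicate fits against the true coefficients.

    Percent bias is ``100*(mean_est - 10*beta)/(10*beta)``, coverage the
    percentage of Wald 95% intervals containing ``10*beta``, power the
    percentage of replicates with ``|est/se| > 1.96``, and the t-test a
    one-sample t of the estimates against ``10*beta``.  Non-converged
    fits are excluded and counted via ``n_effective``.
    """
    fits = list(fits)
    good = [f for f in fits if f.converged]
    if len(good) < 2:
        raise ValueError("need at least 2 converged fits to summarize")
    est_st = np.array([f.est_ST for f in good])
    se_st = np.array([f.se_ST for f in good])
    est_lt = np.array([f.est_LT for f in good])
    se_lt = np.array([f.se_LT for f in good])
    return PerformanceSummary(
        st=_summarize_horizon(est_st, se_st, 10.0 * truth.beta_ST, "ST"),
        lt=_summarize_horizon(est_lt, se_lt, 10.0 * truth.beta_LT, "LT"),
        n_effective=len(good),
        n_sims=len(fits),
        labels=dict(labels or {}),
    )
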