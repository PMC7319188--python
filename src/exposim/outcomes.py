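"""Simulation of daily health-outcome counts from a truth field.

Counts follow a multilevel Poisson model with a log-population offset,
an area-level random intercept and separate short-term (daily deviation)
and long-term (period mean) concentration effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import Geography
from .truth import TruthField

__all__ = ["CRFSet", "OutcomePanel", "simulate_outcomes"]

#: reject rates beyond exp(LOG_RATE_CAP) events per cell as parameter errors
LOG_RATE_CAP = 25.0


@dataclass(frozen=True)
class CRFSet:
    """Prespecified outcome-model coefficients.

    ``beta0`` is the log baseline rate per person-day; ``beta_ST`` and
    ``beta_LT`` are the short- and long-term log-rate changes per
    1 ug/m3; ``sigma_u`` the sd of the area random intercepts.
    """

    beta0: float
    beta_ST: float
    beta_LT: float
    sigma_u: float = 0.05

    def __post_init__(self) -> None:
        if not np.isfinite(self.beta0):
            raise ValueError("beta0 must be finite")
        if self.sigma_u < 0:
            raise ValueError("sigma_u must be >= 0")


@dataclass
class OutcomePanel:
    """Daily counts per area with offsets, linked to the truth field."""

    counts: np.ndarray
    log_offsets: np.ndarray
    field: TruthField

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.shape != self.field.values.shape:
            raise ValueError("counts must match the field dimensions")

    @property
    def n_areas(self) -> int:
        return self.counts.shape[0]

    @property
    def n_days(self) -> int:
        return self.counts.shape[1]


def simulate_outcomes(
    field: TruthField,
    crf: CRFSet,
    geography: Geography,
    seed: int,
) -> OutcomePanel:
    """Draw Poisson counts from the truth field.

        Y[i,t] ~ Poisson(lambda_it)
        log lambda_it = log(pop_i) + beta0 + u_i
                        + beta_ST * D_it + beta_LT * Xbar_i

    Log-scale fields are exponentiated to the natural concentration
    scale before the decomposition into (Xbar_i, D_it).
    """
    if field.geography is not geography and field.n_areas != geography.n_areas:
        raise ValueError("field and geography dimensions disagree")
    natural = field.to_natural()
    rng = np.random.default_rng(seed)
    u = crf.sigma_u * rng.standard_normal(geography.n_areas)
    log_off = np.log(geography.populations.astype(float))
    log_rate = (
        log_off[:, None]
        + crf.beta0
        + u[:, None]
        + crf.beta_ST * natural.deviations
        + crf.beta_LT * natural.area_means[:, None]
    )
    worst = log_rate.max()
    if worst > LOG_RATE_CAP:
        i, t = np.unravel_index(np.argmax(log_rate), log_rate.shape)
        raise ValueError(
            f"log rate {worst:.1f} exceeds cap {LOG_RATE_CAP} at area {i}, day {t}; "
            f"check beta0/beta_ST/beta_LT against the concentration scale"
        )
    counts = rng.poisson(np.exp(log_rate))
    return OutcomePanel(counts=counts, log_offsets=log_off, field=natural)
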