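"""Injection of spatio-temporal measurement error into a truth field.

Given a truth field decomposed into per-area means and daily deviations,
a pseudo-modeled field is produced whose spatial and temporal components
have prespecified Pearson correlations (rho_S, rho_T) with, and variance
ratios (lambda_S, lambda_T) against, the corresponding truth components.
Additive error operates on the natural scale; proportional error expects
a log-scale field, with exponentiation at the downstream boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .truth import LOG, TruthField

__all__ = ["ErrorParams", "inject_error", "inject_components"]

ADDITIVE = "additive"
PROPORTIONAL = "proportional"

POLLUTION_MODELS = ("LUR", "dispersion", "hybrid1", "hybrid2", "custom")


@dataclass(frozen=True)
class ErrorParams:
    """Planted or estimated model-vs-truth error structure.

    ``rho_T``/``rho_S`` are temporal/spatial Pearson correlations between
    modeled and true components; ``lambda_T``/``lambda_S`` the matching
    variance ratios (model / true).  ``mean_offset`` shifts the
    pseudo-model mean and defaults to 0 (mean anchored to truth).
    """

    rho_T: float = 1.0
    rho_S: float = 1.0
    lambda_T: float = 1.0
    lambda_S: float = 1.0
    error_scale: str = ADDITIVE
    mean_offset: float = 0.0
    pollutant: str = "NO2"
    pollution_model: str = "custom"
    site_type: str = "background"

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho_T <= 1.0:
            raise ValueError("rho_T must be in [-1, 1]")
        if not -1.0 <= self.rho_S <= 1.0:
            raise ValueError("rho_S must be in [-1, 1]")
        if self.lambda_T <= 0:
            raise ValueError("lambda_T must be > 0")
        if self.lambda_S <= 0:
            raise ValueError("lambda_S must be > 0")
        if self.error_scale not in (ADDITIVE, PROPORTIONAL):
            raise ValueError("error_scale must be 'additive' or 'proportional'")
        if self.pollution_model not in POLLUTION_MODELS:
            raise ValueError(f"pollution_model must be one of {POLLUTION_MODELS}")


def inject_components(
    means: np.ndarray,
    deviations: np.ndarray,
    err: ErrorParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Apply the injection rule to an explicit (means, deviations) split.

    With m = mean(means), s2_S = var(means), s2_T = var(deviations)
    (sample moments of the realized truth):

        Zbar_i = m + rho_S*sqrt(lambda_S)*(Xbar_i - m)
                   + sqrt(lambda_S*s2_S*(1 - rho_S^2)) * eta_i
        E_it   = rho_T*sqrt(lambda_T)*D_it
                   + sqrt(lambda_T*s2_T*(1 - rho_T^2)) * nu_it

    and the pseudo-modeled matrix is Zbar_i + E_it (+ mean_offset).
    Realized sample moments are used so the variance-ratio calibration
    holds for the data actually fed downstream.
    """
    means = np.asarray(means, dtype=float)
    deviations = np.asarray(deviations, dtype=float)
    m = means.mean()
    s2_S = means.var(ddof=1) if means.size > 1 else 0.0
    s2_T = deviations.var(ddof=1)

    eta = rng.standard_normal(means.shape)
    nu = rng.standard_normal(deviations.shape)

    zbar = (
        m
        + err.mean_offset
        + err.rho_S * np.sqrt(err.lambda_S) * (means - m)
        + np.sqrt(err.lambda_S * s2_S * (1.0 - err.rho_S**2)) * eta
    )
    edev = (
        err.rho_T * np.sqrt(err.lambda_T) * deviations
        + np.sqrt(err.lambda_T * s2_T * (1.0 - err.rho_T**2)) * nu
    )
    return zbar[:, None] + edev if deviations.ndim == 2 else zbar + edev


def inject_error(field: TruthField, err: ErrorParams, seed: int) -> TruthField:
    """Generate a pseudo-modeled field from the truth.

    For proportional error the input field must be on the log scale;
    the returned field stays on the field's scale (use
    :meth:`TruthField.to_natural` before outcome fitting).
    """
    if err.error_scale == PROPORTIONAL and field.scale_flag != LOG:
        raise ValueError("proportional error requires a log-scale truth field")
    rng = np.random.default_rng(seed)
    z = inject_components(field.area_means, field.deviations, err, rng)
    return TruthField(field.geography, z, scale_flag=field.scale_flag)
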