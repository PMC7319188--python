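"""Simulation of "true" daily pollutant concentrations at area centroids.

The generating model is additive on the working scale (natural or log):

    X[i, t] = mu + a_i + g(t) + c_t + e_it

where ``a_i`` is a zero-mean Gaussian spatial field with exponential
covariance ``sigma_S**2 * exp(-d_ij / phi_km)``, ``g(t)`` is a cosine
seasonal cycle, ``c_t`` is a stationary AR(1) common daily shock and
``e_it`` is iid Gaussian noise.  The field decomposes exactly into
per-area long-term means and daily deviations, which is the split the
error-injection and fitting stages operate on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .synthetic import Geography

__all__ = ["TruthModelParams", "TruthField", "simulate_truth", "decompose"]

#: scale flags accepted by :class:`TruthModelParams`
NATURAL = "natural"
LOG = "log"


@dataclass(frozen=True)
class TruthModelParams:
    """Parameters of the spatio-temporal generating model.

    Attributes
    ----------
    mu : float
        Overall mean concentration (working scale).
    sigma_S : float
        Between-area (spatial) standard deviation.
    phi_km : float
        Range of the exponential spatial correlogram, in km.
    amp : float
        Amplitude of the cosine seasonal cycle.
    period_days : float
        Seasonal period in days.
    rho_AR : float
        Lag-1 autocorrelation of the common daily shock, ``|rho_AR| < 1``.
    sigma_C : float
        Stationary standard deviation of the common daily shock.
    sigma_E : float
        Standard deviation of the idiosyncratic daily noise.
    scale_flag : str
        ``"natural"`` or ``"log"``; on the log scale concentrations are
        exponentiated at the outcome/fitting boundary.
    """

    mu: float = 30.0
    sigma_S: float = 5.0
    phi_km: float = 10.0
    amp: float = 5.0
    period_days: float = 365.25
    rho_AR: float = 0.5
    sigma_C: float = 4.0
    sigma_E: float = 3.0
    scale_flag: str = NATURAL

    def __post_init__(self) -> None:
        for name in ("sigma_S", "sigma_C", "sigma_E"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.phi_km <= 0:
            raise ValueError("phi_km must be > 0")
        if not abs(self.rho_AR) < 1:
            raise ValueError("rho_AR must satisfy |rho_AR| < 1")
        if self.period_days <= 0:
            raise ValueError("period_days must be > 0")
        if self.scale_flag not in (NATURAL, LOG):
            raise ValueError("scale_flag must be 'natural' or 'log'")


@dataclass
class TruthField:
    """A realized concentration field over areas x days.

    ``values`` has shape ``(n_areas, n_days)``.  ``area_means`` and
    ``deviations`` form the exact decomposition
    ``values = area_means[:, None] + deviations``.
    """

    geography: Geography
    values: np.ndarray
    scale_flag: str = NATURAL
    area_means: np.ndarray = dc_field(init=False, repr=False)
    deviations: np.ndarray = dc_field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-d (areas x days) array")
        if self.values.shape[0] != self.geography.n_areas:
            raise ValueError("row count must equal the number of areas")
        self.area_means = self.values.mean(axis=1)
        self.deviations = self.values - self.area_means[:, None]

    @property
    def n_areas(self) -> int:
        return self.values.shape[0]

    @property
    def n_days(self) -> int:
        return self.values.shape[1]

    def to_natural(self) -> "TruthField":
        """Return the field on the natural concentration scale.

        Log-scale fields are exponentiated; natural-scale fields are
        returned unchanged.
        """
        if self.scale_flag == NATURAL:
            return self
        return TruthField(self.geography, np.exp(self.values), scale_flag=NATURAL)


def _spatial_effects(
    coords: np.ndarray,
    sigma_S: float,
    phi_km: float,
    rng: np.random.Generator,
    on_duplicates: str = "jitter",
) -> np.ndarray:
    """Draw a zero-mean Gaussian field with exponential covariance."""
    n = coords.shape[0]
    if sigma_S == 0:
        rng.standard_normal(n)  # keep the stream layout stable
        return np.zeros(n)
    dist = squareform(pdist(coords))
    off_diag = dist[~np.eye(n, dtype=bool)]
    if off_diag.size and off_diag.min() == 0.0:
        if on_duplicates == "reject":
            raise ValueError("duplicate centroids make the spatial covariance singular")
        warnings.warn(
            "duplicate centroids detected; jittering coordinates by 1e-6 km",
            RuntimeWarning,
            stacklevel=3,
        )
        jitter = 1e-6 * rng.standard_normal(coords.shape)
        dist = squareform(pdist(coords + jitter))
    cov = sigma_S**2 * np.exp(-dist / phi_km)
    # tiny nugget keeps the Cholesky stable for near-coincident sites
    cov[np.diag_indices(n)] += 1e-10 * sigma_S**2
    chol = np.linalg.cholesky(cov)
    return chol @ rng.standard_normal(n)


def _ar1(n_days: int, rho: float, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) path of length ``n_days`` with marginal sd ``sigma``."""
    z = rng.standard_normal(n_days)
    if sigma == 0:
        return np.zeros(n_days)
    c = np.empty(n_days)
    c[0] = sigma * z[0]
    innov_sd = sigma * np.sqrt(1.0 - rho**2)
    for t in range(1, n_days):
        c[t] = rho * c[t - 1] + innov_sd * z[t]
    return c


def simulate_truth(
    geography: Geography,
    params: TruthModelParams,
    n_days: int,
    seed: int,
    on_duplicates: str = "jitter",
) -> TruthField:
    """Simulate a "true" concentration field at the area centroids.

    Parameters
    ----------
    geography : Geography
        Area centroids and populations.
    params : TruthModelParams
        Generating-model parameters.
    n_days : int
        Number of days to simulate (>= 2).
    seed : int or numpy SeedSequence
        Seed; identical seeds give bit-identical fields.
    on_duplicates : str
        ``"jitter"`` (default) perturbs duplicate centroids with a warning;
        ``"reject"`` raises.

    Returns
    -------
    TruthField
    """
    if n_days < 2:
        raise ValueError("n_days must be >= 2")
    rng = np.random.default_rng(seed)
    a = _spatial_effects(geography.centroids, params.sigma_S, params.phi_km, rng, on_duplicates)
    t = np.arange(1, n_days + 1, dtype=float)
    g = params.amp * np.cos(2.0 * np.pi * t / params.period_days)
    c = _ar1(n_days, params.rho_AR, params.sigma_C, rng)
    e = params.sigma_E * rng.standard_normal((geography.n_areas, n_days))
    values = params.mu + a[:, None] + g[None, :] + c[None, :] + e
    return TruthField(geography, values, scale_flag=params.scale_flag)


def decompose(field: TruthField) -> tuple[np.ndarray, np.ndarray]:
    """Split a field into per-area means and daily deviations.

    Returns ``(area_means, deviations)`` with
    ``field.values == area_means[:, None] + deviations`` exactly and
    ``deviations.mean(axis=1) == 0`` per area.
    """
    return field.area_means.copy(), field.deviations.copy()
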