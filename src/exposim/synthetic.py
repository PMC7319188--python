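"""Synthetic geographies, monitor networks and validation fixtures.

Everything downstream (truth simulation, error injection, parameter
estimation) is exercised against data generated here, so no external
download is ever required.  Coordinates are planar km; distances are
Euclidean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Geography",
    "MonitorNetwork",
    "ValidationPair",
    "make_geography",
    "make_monitor_network",
    "make_validation_pairs",
    "geography_to_csv",
    "pairs_to_csv",
    "pairs_from_csv",
]

SITE_TYPES = ("background", "roadside")


@dataclass(frozen=True)
class Geography:
    """Small-area centroids with populations.

    Attributes
    ----------
    area_ids : tuple of str
        Unique area identifiers.
    centroids : ndarray, shape (n_areas, 2)
        Planar coordinates in km.
    populations : ndarray of int
        Person counts per area, all >= 1.
    """

    area_ids: tuple
    centroids: np.ndarray
    populations: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "centroids", np.asarray(self.centroids, dtype=float))
        object.__setattr__(self, "populations", np.asarray(self.populations, dtype=np.int64))
        if len(set(self.area_ids)) != len(self.area_ids):
            raise ValueError("area_ids must be unique")
        if self.centroids.shape != (len(self.area_ids), 2):
            raise ValueError("centroids must be (n_areas, 2)")
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("centroids must be finite")
        if np.any(self.populations < 1):
            raise ValueError("populations must be >= 1")

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)


@dataclass
class MonitorNetwork:
    """A network of monitoring sites with daily concentration series.

    ``daily_series`` maps site_id -> DataFrame with columns ``day`` (int)
    and ``value`` (float, ug/m3); days may be missing.
    """

    site_ids: tuple
    coords: np.ndarray
    site_types: tuple
    daily_series: dict

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if len(set(self.site_ids)) != len(self.site_ids):
            raise ValueError("site_ids must be unique")
        bad = set(self.site_types) - set(SITE_TYPES)
        if bad:
            raise ValueError(f"unknown site types: {sorted(bad)}")
        for sid in self.site_ids:
            vals = self.daily_series[sid]["value"].to_numpy()
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"non-finite concentrations at site {sid}")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def sites_of_type(self, site_type: str) -> list:
        return [s for s, t in zip(self.site_ids, self.site_types) if t == site_type]


@dataclass
class ValidationPair:
    """Paired monitor/model daily series at one site.

    ``records`` is a DataFrame with columns ``day``, ``monitor``,
    ``model`` (complete cases only).  ``instrument_error_variance`` is
    the known variance of the additive instrument noise, in (ug/m3)^2.
    """

    site_id: str
    site_type: str
    records: pd.DataFrame
    instrument_error_variance: float = 0.0

    def __post_init__(self) -> None:
        if self.instrument_error_variance < 0:
            raise ValueError("instrument_error_variance must be >= 0")
        req = {"day", "monitor", "model"}
        if not req.issubset(self.records.columns):
            raise ValueError(f"records must have columns {sorted(req)}")
        if self.records[["monitor", "model"]].isna().any().any():
            raise ValueError("records must be complete cases")

    @property
    def n_days(self) -> int:
        return len(self.records)


def make_geography(
    n_areas: int = 1000,
    extent_km: float = 40.0,
    population_mean: float = 1500.0,
    seed: int = 0,
) -> Geography:
    """Generate a square study region of small areas.

    Centroids are uniform on ``[0, extent_km]^2``; populations are Poisson
    around ``population_mean``, floored at 1.  Deterministic given ``seed``.
    """
    if n_areas < 2:
        raise ValueError("n_areas must be >= 2")
    if extent_km <= 0:
        raise ValueError("extent_km must be > 0")
    if population_mean <= 0:
        raise ValueError("population_mean must be > 0")
    rng = np.random.default_rng(seed)
    centroids = rng.uniform(0.0, extent_km, size=(n_areas, 2))
    populations = np.maximum(rng.poisson(population_mean, size=n_areas), 1)
    area_ids = tuple(f"A{i:05d}" for i in range(n_areas))
    return Geography(area_ids, centroids, populations)


def make_monitor_network(
    n_background: int = 47,
    n_roadside: int = 72,
    n_days: int = 1826,
    extent_km: float = 40.0,
    mean_background: float = 30.0,
    mean_roadside: float = 50.0,
    sigma_site: float = 5.0,
    amp: float = 5.0,
    rho_AR: float = 0.5,
    sigma_daily: float = 4.0,
    sigma_noise: float = 3.0,
    missing_frac: float = 0.0,
    seed: int = 0,
) -> MonitorNetwork:
    """Generate a two-type monitor network with daily series.

    Per-site series follow the same additive structure as the truth
    simulator (site effect + seasonal cycle + AR(1) common shock + iid
    noise) with a type-specific mean.  ``missing_frac`` deletes days
    completely at random.
    """
    if n_background < 1 or n_roadside < 1:
        raise ValueError("need at least one site of each type")
    if not 0 <= missing_frac < 1:
        raise ValueError("missing_frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_sites = n_background + n_roadside
    coords = rng.uniform(0.0, extent_km, size=(n_sites, 2))
    site_types = ("background",) * n_background + ("roadside",) * n_roadside
    site_ids = tuple(
        f"{'BG' if t == 'background' else 'RD'}{i:03d}" for i, t in enumerate(site_types)
    )
    means = np.where(np.array(site_types) == "background", mean_background, mean_roadside)
    alpha = sigma_site * rng.standard_normal(n_sites)
    t = np.arange(1, n_days + 1, dtype=float)
    g = amp * np.cos(2.0 * np.pi * t / 365.25)
    z = rng.standard_normal(n_days)
    c = np.empty(n_days)
    c[0] = sigma_daily * z[0]
    innov = sigma_daily * np.sqrt(1 - rho_AR**2)
    for k in range(1, n_days):
        c[k] = rho_AR * c[k - 1] + innov * z[k]
    series = {}
    for j, sid in enumerate(site_ids):
        vals = means[j] + alpha[j] + g + c + sigma_noise * rng.standard_normal(n_days)
        days = np.arange(1, n_days + 1)
        if missing_frac > 0:
            keep = rng.random(n_days) >= missing_frac
            days, vals = days[keep], vals[keep]
        series[sid] = pd.DataFrame({"day": days, "value": vals})
    return MonitorNetwork(site_ids, coords, site_types, series)


def make_validation_pairs(
    network: MonitorNetwork,
    planted,
    instrument_sd: float = 0.0,
    seed: int = 0,
) -> list:
    """Build validation pairs with a planted error structure.

    The network's series are treated as the latent truth.  The monitor
    series adds iid Gaussian instrument noise with sd ``instrument_sd``;
    the model series is constructed from the latent truth via the same
    component-wise injection rule as :func:`exposim.errors.inject_error`,
    so the latent (rho_T, rho_S, lambda_T, lambda_S) equal the planted
    values.

    Parameters
    ----------
    network : MonitorNetwork
    planted : ErrorParams
        The error structure to plant.
    instrument_sd : float
        Instrument-noise sd in ug/m3 (on the latent scale).
    seed : int

    Returns
    -------
    list of ValidationPair
    """
    from .errors import inject_components  # deferred: avoids import cycle

    if instrument_sd < 0:
        raise ValueError("instrument_sd must be >= 0")
    if network.n_sites < 2:
        raise ValueError("need >= 2 sites for spatial error components")
    rng = np.random.default_rng(seed)

    # Latent truth on a common day grid (complete cases across the network)
    ids = list(network.site_ids)
    frames = [network.daily_series[s].set_index("day")["value"] for s in ids]
    truth = pd.concat(frames, axis=1, keys=ids).dropna()
    days = truth.index.to_numpy()
    X = truth.to_numpy().T  # (n_sites, n_days)

    # error structure is site-type specific: inject within each type so the
    # planted (rho, lambda) hold for per-type estimation
    Z = np.empty_like(X)
    types = np.asarray(network.site_types, dtype=object)
    for st in SITE_TYPES:
        idx = np.flatnonzero(types == st)
        if idx.size == 0:
            continue
        Xg = X[idx]
        means = Xg.mean(axis=1)
        devs = Xg - means[:, None]
        Z[idx] = inject_components(means, devs, planted, rng)
    monitor = X + instrument_sd * rng.standard_normal(X.shape)

    pairs = []
    for j, sid in enumerate(ids):
        rec = pd.DataFrame({"day": days, "monitor": monitor[j], "model": Z[j]})
        pairs.append(
            ValidationPair(
                site_id=sid,
                site_type=network.site_types[j],
                records=rec,
                instrument_error_variance=instrument_sd**2,
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# CSV round-tripping


def geography_to_csv(geography: Geography, path) -> None:
    """Write a geography as (area_id, x_km, y_km, population)."""
    pd.DataFrame(
        {
            "area_id": geography.area_ids,
            "x_km": geography.centroids[:, 0],
            "y_km": geography.centroids[:, 1],
            "population": geography.populations,
        }
    ).to_csv(path, index=False)


def pairs_to_csv(pairs: Sequence[ValidationPair], path) -> None:
    """Write validation pairs in long format."""
    frames = []
    for p in pairs:
        df = p.records.copy()
        df.insert(0, "site_id", p.site_id)
        df.insert(1, "site_type", p.site_type)
        df["instrument_error_variance"] = p.instrument_error_variance
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def pairs_from_csv(path) -> list:
    """Read validation pairs written by :func:`pairs_to_csv`.

    Also accepts external files with at least (site_id, day, monitor,
    model); site_type defaults to "background" and instrument variance
    to 0 when absent.
    """
    df = pd.read_csv(path)
    req = {"site_id", "day", "monitor", "model"}
    missing = req - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    pairs = []
    for sid, grp in df.groupby("site_id", sort=True):
        stype = grp["site_type"].iloc[0] if "site_type" in grp else "background"
        ivar = (
            float(grp["instrument_error_variance"].iloc[0])
            if "instrument_error_variance" in grp
            else 0.0
        )
        rec = grp[["day", "monitor", "model"]].dropna().reset_index(drop=True)
        pairs.append(ValidationPair(str(sid), stype, rec, ivar))
    return pairs
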