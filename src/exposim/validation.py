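"""Estimation of error parameters and standard metrics from paired data.

Two jobs live here.  First, estimating the (rho_T, rho_S, lambda_T,
lambda_S) error structure of a pollution model from paired model-monitor
series, correcting for instrument noise in the monitors so the
comparison targets modeled-vs-true rather than modeled-vs-monitored.
The correction is the standard errors-in-variables disattenuation:
subtract the known instrument variance from the monitor variance and
rescale the correlation by the sd ratio; for the spatial (between-site)
components the instrument variance is first divided by the number of
observation days per site, since site means average the noise away.
Second, the standard per-site model-validation metrics (MB, NMB, NMGE,
RMSE, FAC2) with site-type averages.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ADDITIVE, PROPORTIONAL, ErrorParams
from .synthetic import MonitorNetwork, ValidationPair

__all__ = [
    "ValidationStats",
    "estimate_error_params",
    "standard_metrics",
    "leave_out_split",
]


@dataclass(frozen=True)
class ValidationStats:
    """Per-site validation metrics plus site-type averages.

    ``per_site`` columns: site_id, site_type, n_days, n_excluded, MB,
    NMB, NMGE, RMSE, FAC2.  ``by_type`` holds unweighted means of each
    metric over sites of a type.
    """

    per_site: pd.DataFrame
    by_type: pd.DataFrame


def _log_series(monitor: np.ndarray, model: np.ndarray, ivar: float):
    """Move a pair to the log scale; delta-method for instrument variance."""
    if np.any(monitor <= 0) or np.any(model <= 0):
        raise ValueError("proportional scale requires strictly positive series")
    ivar_log = ivar / float(np.mean(monitor)) ** 2
    return np.log(monitor), np.log(model), ivar_log


def estimate_error_params(
    pairs: Sequence[ValidationPair],
    site_type: str,
    scale: str = ADDITIVE,
    correct_instrument: bool = True,
    pooling: str = "pooled",
) -> ErrorParams:
    """Estimate (rho_T, rho_S, lambda_T, lambda_S) from validation pairs.

    Temporal components compare daily deviations (after per-site
    centering), pooled across sites of the given type by default
    (``pooling="per_site"`` averages per-site estimates instead).
    Spatial components compare site means across sites.  With
    ``correct_instrument`` the monitor variance is disattenuated using
    each pair's known ``instrument_error_variance``; set it to False for
    the naive modeled-vs-monitored quantities.

    Parameters
    ----------
    pairs : sequence of ValidationPair
    site_type : str
        Only pairs of this type enter the estimate.
    scale : {"additive", "proportional"}
        Proportional applies the identical algebra to log-transformed
        series (instrument variance mapped by the delta method).
    correct_instrument : bool
    pooling : {"pooled", "per_site"}

    Returns
    -------
    ErrorParams
        With the estimated coefficients and matching labels.
    """
    sel = [p for p in pairs if p.site_type == site_type]
    if len(sel) < 3:
        raise ValueError(f"need >= 3 sites of type {site_type!r} for spatial components")
    if scale not in (ADDITIVE, PROPORTIONAL):
        raise ValueError("scale must be 'additive' or 'proportional'")
    if pooling not in ("pooled", "per_site"):
        raise ValueError("pooling must be 'pooled' or 'per_site'")

    mon_dev, mod_dev, weights, site_ids = [], [], [], []
    mon_means, mod_means, ivar_means = [], [], []
    ivar_devs = []
    for p in sel:
        if p.n_days < 2:
            raise ValueError(f"site {p.site_id} has fewer than 2 paired days")
        mon = p.records["monitor"].to_numpy(dtype=float)
        mod = p.records["model"].to_numpy(dtype=float)
        ivar = p.instrument_error_variance
        if scale == PROPORTIONAL:
            mon, mod, ivar = _log_series(mon, mod, ivar)
        mon_dev.append(mon - mon.mean())
        mod_dev.append(mod - mod.mean())
        weights.append(len(mon))
        site_ids.append(p.site_id)
        mon_means.append(mon.mean())
        mod_means.append(mod.mean())
        ivar_devs.append(ivar)
        ivar_means.append(ivar / len(mon))

    # --- temporal (within sites) -------------------------------------
    if pooling == "pooled":
        dmon = np.concatenate(mon_dev)
        dmod = np.concatenate(mod_dev)
        dof = dmon.size - len(sel)  # one mean per site removed
        var_mon = float(dmon @ dmon) / dof
        var_mod = float(dmod @ dmod) / dof
        cov = float(dmon @ dmod) / dof
        ivar_t = float(np.average(ivar_devs, weights=weights))
        rho_T, lam_T = _corrected(var_mon, var_mod, cov, ivar_t, correct_instrument,
                                  what=f"temporal ({site_type})")
    else:
        rhos, lams = [], []
        for j, sid in enumerate(site_ids):
            n = weights[j]
            var_mon = float(mon_dev[j] @ mon_dev[j]) / (n - 1)
            var_mod = float(mod_dev[j] @ mod_dev[j]) / (n - 1)
            cov = float(mon_dev[j] @ mod_dev[j]) / (n - 1)
            r, l = _corrected(var_mon, var_mod, cov, ivar_devs[j], correct_instrument,
                              what=f"site {sid}")
            rhos.append(r)
            lams.append(l)
        rho_T, lam_T = float(np.mean(rhos)), float(np.mean(lams))

    # --- spatial (between sites) -------------------------------------
    mm = np.asarray(mon_means)
    dm = np.asarray(mod_means)
    var_mon_s = float(mm.var(ddof=1))
    var_mod_s = float(dm.var(ddof=1))
    cov_s = float(np.cov(mm, dm, ddof=1)[0, 1])
    ivar_s = float(np.mean(ivar_means))
    rho_S, lam_S = _corrected(var_mon_s, var_mod_s, cov_s, ivar_s, correct_instrument,
                              what=f"spatial ({site_type})")

    return ErrorParams(
        rho_T=float(np.clip(rho_T, -1.0, 1.0)),
        rho_S=float(np.clip(rho_S, -1.0, 1.0)),
        lambda_T=lam_T,
        lambda_S=lam_S,
        error_scale=scale,
        site_type=site_type,
    )


def _corrected(var_mon, var_mod, cov, ivar, correct, what):
    """Disattenuated (rho, lambda) from second moments."""
    true_var = var_mon - ivar if correct else var_mon
    if true_var <= 0:
        raise ValueError(
            f"corrected variance <= 0 for {what}: instrument variance {ivar:.4g} "
            f"exceeds monitor variance {var_mon:.4g}"
        )
    rho = cov / math.sqrt(var_mod * true_var)
    lam = var_mod / true_var
    return rho, lam


def standard_metrics(pairs: Sequence[ValidationPair]) -> ValidationStats:
    """Per-site MB, NMB, NMGE, RMSE and FAC2, with site-type averages.

    MB and RMSE use all paired days.  NMB, NMGE and FAC2 require
    positive monitor values; days with monitor <= 0 are excluded from
    those three metrics and counted in ``n_excluded`` (an all-nonpositive
    site gets NaN there, with a warning).
    """
    if not pairs:
        raise ValueError("no validation pairs supplied")
    rows = []
    for p in pairs:
        o = p.records["monitor"].to_numpy(dtype=float)
        m = p.records["model"].to_numpy(dtype=float)
        diff = m - o
        mb = float(diff.mean())
        rmse = float(np.sqrt((diff**2).mean()))
        pos = o > 0
        n_excl = int((~pos).sum())
        if pos.any():
            op, mp = o[pos], m[pos]
            nmb = float((mp - op).sum() / op.sum())
            nmge = float(np.abs(mp - op).sum() / op.sum())
            ratio = mp / op
            fac2 = float(np.mean((ratio >= 0.5) & (ratio <= 2.0)))
        else:
            warnings.warn(
                f"site {p.site_id}: no positive monitor values; "
                "normalized metrics undefined",
                RuntimeWarning,
                stacklevel=2,
            )
            nmb = nmge = fac2 = float("nan")
        rows.append(
            {
                "site_id": p.site_id,
                "site_type": p.site_type,
                "n_days": p.n_days,
                "n_excluded": n_excl,
                "MB": mb,
                "NMB": nmb,
                "NMGE": nmge,
                "RMSE": rmse,
                "FAC2": fac2,
            }
        )
    per_site = pd.DataFrame(rows)
    by_type = (
        per_site.groupby("site_type")[["MB", "NMB", "NMGE", "RMSE", "FAC2"]]
        .mean()
        .reset_index()
    )
    return ValidationStats(per_site=per_site, by_type=by_type)


def leave_out_split(network: MonitorNetwork, fraction: float, seed: int) -> list:
    """Partition sites into successive ~``fraction``-sized leave-out groups.

    Every site appears in exactly one group; groups are disjoint and
    cover the network.  Deterministic given ``seed``.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n = network.n_sites
    n_groups = int(round(1.0 / fraction))
    if n_groups > n:
        raise ValueError(
            f"fraction {fraction} yields {n_groups} groups for {n} sites "
            "(empty groups)"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    ids = np.asarray(network.site_ids, dtype=object)
    return [list(ids[chunk]) for chunk in np.array_split(order, n_groups)]
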