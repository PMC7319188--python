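"""Scenario orchestration: replicate loops, manifests and result tables.

A scenario bundles a truth model, an outcome model, an error structure
and study dimensions; running it executes, per replicate,

    simulate_truth -> simulate_outcomes -> inject_error -> fit

with seeds derived deterministically from (base_seed, scenario id,
replicate), so results are reproducible and independent of execution
order within a manifest.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import PROPORTIONAL, ErrorParams, inject_error
from .fitting import FitResult, fit_multilevel_poisson
from .outcomes import CRFSet, simulate_outcomes
from .performance import PerformanceSummary, summarize
from .synthetic import Geography, make_geography
from .truth import LOG, TruthModelParams, simulate_truth

__all__ = ["ScenarioSpec", "run_scenario", "run_manifest", "load_manifest", "results_to_frame"]

RESULT_COLUMNS = [
    "scenario",
    "pollutant",
    "outcome",
    "pollution_model",
    "site_type",
    "error_scale",
    "horizon",
    "true_value",
    "mean_est",
    "mean_se",
    "pct_bias",
    "abs_bias",
    "coverage",
    "power",
    "t_stat",
    "t_pvalue",
    "n_effective",
    "n_sims",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """One fully specified simulation scenario."""

    name: str
    error: ErrorParams
    crf: CRFSet
    truth: TruthModelParams
    n_areas: int = 100
    n_days: int = 365
    n_sims: int = 1000
    base_seed: int = 0
    pollutant: str = "NO2"
    outcome: str = "mortality"
    extent_km: float = 40.0
    population_mean: float = 1500.0
    max_failure_frac: float = 0.10

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if self.n_areas < 2 or self.n_days < 2:
            raise ValueError("need at least 2 areas and 2 days")
        if self.error.error_scale == PROPORTIONAL and self.truth.scale_flag != LOG:
            raise ValueError(
                "proportional-error scenarios must use a log-scale truth model "
                "(set truth.scale_flag='log')"
            )

    @property
    def scenario_id(self) -> int:
        """Stable integer id from the scenario labels (order-independent)."""
        key = json.dumps(
            [self.name, self.pollutant, self.outcome, self.error.pollution_model,
             self.error.site_type, self.error.error_scale],
        )
        return zlib.crc32(key.encode())

    def labels(self) -> dict:
        return {
            "scenario": self.name,
            "pollutant": self.pollutant,
            "outcome": self.outcome,
            "pollution_model": self.error.pollution_model,
            "site_type": self.error.site_type,
            "error_scale": self.error.error_scale,
        }


def replicate_seed_sequences(spec: ScenarioSpec, r: int) -> tuple:
    """Deterministic per-replicate seed sequences (truth, outcomes, error)."""
    root = np.random.SeedSequence([spec.base_seed, spec.scenario_id, r])
    return tuple(root.spawn(3))


def run_scenario(
    spec: ScenarioSpec,
    geography: Optional[Geography] = None,
    progress: bool = False,
) -> tuple[PerformanceSummary, pd.DataFrame]:
    """Run all replicates of one scenario and summarize.

    Returns the performance summary and a per-replicate table of fit
    results (one row per replicate, including non-converged ones).
    Per-replicate failures are recorded and skipped; the scenario aborts
    if more than ``spec.max_failure_frac`` of replicates fail.
    """
    if geography is None:
        geo_seed = np.random.SeedSequence([spec.base_seed, spec.scenario_id])
        geography = make_geography(
            spec.n_areas, spec.extent_km, spec.population_mean, seed=geo_seed
        )
    fits: list[FitResult] = []
    rows = []
    n_failed = 0
    for r in range(spec.n_sims):
        ss_truth, ss_out, ss_err = replicate_seed_sequences(spec, r)
        try:
            field_true = simulate_truth(geography, spec.truth, spec.n_days, seed=ss_truth)
            outcomes = simulate_outcomes(field_true, spec.crf, geography, seed=ss_out)
            field_model = inject_error(field_true, spec.error, seed=ss_err)
            fit = fit_multilevel_poisson(outcomes, field_model.to_natural(), geography)
        except Exception as exc:  # noqa: BLE001 - replicate isolation
            fit = FitResult(np.nan, np.nan, np.nan, np.nan, np.nan, False,
                            spec.n_areas * spec.n_days, f"error:{type(exc).__name__}")
        if not fit.converged:
            n_failed += 1
            if n_failed > spec.max_failure_frac * spec.n_sims:
                raise RuntimeError(
                    f"scenario {spec.name!r}: {n_failed} failed replicates "
                    f"exceed the {spec.max_failure_frac:.0%} limit"
                )
        fits.append(fit)
        rows.append(
            {
                "replicate": r,
                "est_ST": fit.est_ST,
                "se_ST": fit.se_ST,
                "est_LT": fit.est_LT,
                "se_LT": fit.se_LT,
                "sigma_u_hat": fit.sigma_u_hat,
                "converged": fit.converged,
                "method": fit.method,
            }
        )
        if progress and (r + 1) % 50 == 0:
            print(f"  {spec.name}: {r + 1}/{spec.n_sims} replicates")
    summary = summarize(fits, spec.crf, labels=spec.labels())
    return summary, pd.DataFrame(rows)


def results_to_frame(summaries: Sequence[PerformanceSummary]) -> pd.DataFrame:
    """Flatten summaries into one row per scenario x horizon."""
    rows = []
    for s in summaries:
        for h in (s.st, s.lt):
            rows.append(
                {
                    **s.labels,
                    "horizon": h.horizon,
                    "true_value": h.true_value,
                    "mean_est": h.mean_est,
                    "mean_se": h.mean_se,
                    "pct_bias": h.pct_bias,
                    "abs_bias": h.abs_bias,
                    "coverage": h.coverage,
                    "power": h.power,
                    "t_stat": h.t_stat,
                    "t_pvalue": h.t_pvalue,
                    "n_effective": s.n_effective,
                    "n_sims": s.n_sims,
                }
            )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def run_manifest(
    specs: Sequence[ScenarioSpec],
    out_dir=None,
    progress: bool = False,
) -> tuple[pd.DataFrame, list]:
    """Run every scenario in a manifest and collect the results table.

    Duplicate scenario label combinations are rejected.  When
    ``out_dir`` is given, writes ``results.csv``, per-scenario replicate
    tables and a plain-text run log there.
    """
    seen = set()
    for spec in specs:
        key = tuple(sorted(spec.labels().items()))
        if key in seen:
            raise ValueError(f"duplicate scenario labels: {dict(key)}")
        seen.add(key)

    summaries = []
    log: list[str] = []
    replicate_tables = {}
    for spec in specs:
        summary, table = run_scenario(spec, progress=progress)
        summaries.append(summary)
        replicate_tables[spec.name] = table
        n_bad = summary.n_sims - summary.n_effective
        log.append(
            f"scenario={spec.name} n_sims={summary.n_sims} "
            f"converged={summary.n_effective} failed={n_bad} "
            f"methods={table['method'].value_counts().to_dict()}"
        )
    results = results_to_frame(summaries)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        results.to_csv(out / "results.csv", index=False)
        for name, table in replicate_tables.items():
            table.to_csv(out / f"replicates_{name}.csv", index=False)
        (out / "run.log").write_text("\n".join(log) + "\n")
    return results, log


# ---------------------------------------------------------------------------
# YAML manifests


def _build_spec(entry: dict, defaults: dict, base_seed: int) -> ScenarioSpec:
    def merged(section: str) -> dict:
        d = dict(defaults.get(section, {}))
        d.update(entry.get(section, {}))
        return d

    labels = {**defaults.get("labels", {}), **entry.get("labels", {})}
    err_kwargs = merged("error")
    err_kwargs.setdefault("pollutant", labels.get("pollutant", "NO2"))
    err_kwargs.setdefault("pollution_model", labels.get("pollution_model", "custom"))
    err_kwargs.setdefault("site_type", labels.get("site_type", "background"))
    error = ErrorParams(**err_kwargs)

    truth_kwargs = merged("truth")
    if error.error_scale == PROPORTIONAL:
        truth_kwargs.setdefault("scale_flag", LOG)
    truth = TruthModelParams(**truth_kwargs)
    crf = CRFSet(**merged("crf"))
    dims = merged("dims")
    return ScenarioSpec(
        name=str(entry["name"]),
        error=error,
        crf=crf,
        truth=truth,
        n_areas=int(dims.get("n_areas", 100)),
        n_days=int(dims.get("n_days", 365)),
        n_sims=int(entry.get("n_sims", defaults.get("n_sims", 1000))),
        base_seed=int(entry.get("base_seed", base_seed)),
        pollutant=labels.get("pollutant", "NO2"),
        outcome=labels.get("outcome", "mortality"),
    )


def load_manifest(path, base_seed: Optional[int] = None) -> list:
    """Parse a YAML manifest into scenario specs.

    Schema: top-level ``base_seed``, optional ``defaults`` (sections
    ``labels``, ``error``, ``crf``, ``truth``, ``dims``, ``n_sims``) and
    a ``scenarios`` list of entries overriding any section.  A
    ``base_seed`` argument overrides the file's.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    seed = int(base_seed if base_seed is not None else doc.get("base_seed", 0))
    defaults = doc.get("defaults", {}) or {}
    entries = doc.get("scenarios", []) or []
    return [_build_spec(e, defaults, seed) for e in entries]


def scale_spec(spec: ScenarioSpec, n_areas=None, n_days=None, n_sims=None) -> ScenarioSpec:
    """Return a copy with overridden dimensions (desk-scale <-> full-scale)."""
    return replace(
        spec,
        n_areas=n_areas or spec.n_areas,
        n_days=n_days or spec.n_days,
        n_sims=n_sims or spec.n_sims,
    )
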