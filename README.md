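# exposim

Simulation toolkit for assessing how measurement error in modeled
air-pollution exposures biases health-effect estimates in a multilevel
Poisson analysis that jointly estimates short-term (daily) and long-term
(period-mean) effects.

The pipeline, per replicate:

1. **Truth simulation** — "true" daily concentrations at small-area
   centroids from a spatio-temporal model (spatial Gaussian field with
   exponential covariance, cosine seasonality, AR(1) common daily shock,
   iid noise), on the natural or log scale.
2. **Outcome simulation** — daily event counts per area from a
   multilevel Poisson model with a log-population offset, area random
   intercepts and prespecified short-/long-term concentration-response
   coefficients.
3. **Error injection** — pseudo-modeled concentrations with
   prespecified temporal/spatial Pearson correlations (ρT, ρS) and
   variance ratios (λT, λS) against the truth; additive error on the
   natural scale or proportional error on the log scale.
4. **Refitting** — a Laplace-approximate multilevel Poisson fit with a
   within/between exposure split, returning short- and long-term
   estimates and standard errors per 10 µg/m³.

Replicate fits are aggregated into mean estimate, mean SE, percent
bias, 95% coverage, power and a one-sample t-test. The validation side
estimates (ρT, ρS, λT, λS) from paired model–monitor series with
instrument-error correction, computes the standard model-validation
metrics (MB, NMB, NMGE, RMSE, FAC2), and provides leave-out site
splits. A synthetic-data module generates geographies, monitor networks
and validation pairs with known planted error structure, so everything
is testable offline.

## CLI

```sh
# synthetic fixtures (geography + validation pairs with planted error)
exposim synth --n-areas 100 --n-days 365 --out-dir fixtures/

# run every scenario in a YAML manifest (see examples/manifest.yaml)
exposim run examples/manifest.yaml --out-dir results/ --n-sims 200
exposim run examples/manifest.yaml --full     # 1000 areas x 1826 days x 1000 sims

# one scenario
exposim simulate examples/manifest.yaml --scenario hybrid2_background

# estimate error parameters + standard metrics from paired CSV
# (columns: site_id, day, monitor, model[, site_type, instrument_error_variance])
exposim validate fixtures/validation_pairs.csv --out-dir validation/
```

Manifests set a `base_seed`, shared `defaults` (truth model, CRFs,
dimensions) and a list of scenarios, each naming its pollution model,
site type and error parameters. Results are written as CSV (one row per
scenario × horizon) plus per-replicate tables and a run log. Runs are
fully reproducible: replicate seeds derive deterministically from
(base_seed, scenario labels, replicate index).

The coefficients in `examples/manifest.yaml` are illustrative
placeholders spanning the qualitative error regimes (high correlation +
low variance ratio → bias away from the null; low correlation + high
variance ratio → attenuation toward the null); replace them with values
estimated from your own validation data via `exposim validate`.

## Library use

```python
from exposim import (make_geography, TruthModelParams, simulate_truth,
                     CRFSet, simulate_outcomes, ErrorParams, inject_error,
                     fit_multilevel_poisson, summarize)

geo   = make_geography(n_areas=100, seed=1)
truth = simulate_truth(geo, TruthModelParams(), n_days=365, seed=2)
crf   = CRFSet(beta0=-6.2, beta_ST=0.003, beta_LT=0.02)
panel = simulate_outcomes(truth, crf, geo, seed=3)
model = inject_error(truth, ErrorParams(rho_S=0.7, lambda_S=2.0), seed=4)
fit   = fit_multilevel_poisson(panel, model.to_natural(), geo)
```
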