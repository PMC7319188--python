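# Template manifest: a 4-model x 2-site-type grid for one pollutant.
# The (rho, lambda) values are illustrative placeholders spanning the
# qualitative error regimes (high correlation + low variance ratio vs
# low correlation + high variance ratio); replace them with estimates
# from your own validation data (exposim validate ...).  CRF values are
# likewise illustrative, not estimates from any study.
base_seed: 20200513
defaults:
  labels: {pollutant: NO2, outcome: mortality}
  truth: {mu: 30.0, sigma_S: 5.0, phi_km: 10.0, amp: 5.0, rho_AR: 0.5, sigma_C: 4.0, sigma_E: 3.0}
  crf: {beta0: -7.6, beta_ST: 0.002, beta_LT: 0.02, sigma_u: 0.05}
  dims: {n_areas: 100, n_days: 365}
  n_sims: 200
scenarios:
  - name: lur_background
    labels: {pollution_model: LUR, site_type: background}
    error: {rho_T: 0.75, rho_S: 0.45, lambda_T: 1.3, lambda_S: 2.5}
  - name: lur_roadside
    labels: {pollution_model: LUR, site_type: roadside}
    error: {rho_T: 0.70, rho_S: 0.35, lambda_T: 1.5, lambda_S: 3.0}
  - name: dispersion_background
    labels: {pollution_model: dispersion, site_type: background}
    error: {rho_T: 0.80, rho_S: 0.70, lambda_T: 1.1, lambda_S: 1.5}
  - name: dispersion_roadside
    labels: {pollution_model: dispersion, site_type: roadside}
    error: {rho_T: 0.75, rho_S: 0.65, lambda_T: 1.2, lambda_S: 1.6}
  - name: hybrid1_background
    labels: {pollution_model: hybrid1, site_type: background}
    error: {rho_T: 0.82, rho_S: 0.72, lambda_T: 1.1, lambda_S: 1.4}
  - name: hybrid1_roadside
    labels: {pollution_model: hybrid1, site_type: roadside}
    error: {rho_T: 0.78, rho_S: 0.60, lambda_T: 1.2, lambda_S: 1.8}
  - name: hybrid2_background
    labels: {pollution_model: hybrid2, site_type: background}
    error: {rho_T: 0.90, rho_S: 0.90, lambda_T: 1.0, lambda_S: 1.1}
  - name: hybrid2_roadside
    labels: {pollution_model: hybrid2, site_type: roadside}
    error: {rho_T: 0.88, rho_S: 0.85, lambda_T: 1.05, lambda_S: 1.2}
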