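# Default run configuration: final population PK model estimates for
# meropenem in critically ill adults, and Monte Carlo simulation settings.
model:
  theta_cl: 6.37          # L/h, typical CL at the eGFR centering value
  theta_cov: 0.00925      # per mL/min/1.73 m^2
  ce_ref: 91.57           # mL/min/1.73 m^2 (cohort median CKD-EPI eGFR)
  vc: 9.07                # L
  q: 10.7                 # L/h
  vp: 7.91                # L
  omega_cl: 0.314         # SD of log-scale IIV on CL (31.4%)
  omega_vc: 0.436
  omega_vp: 0.366
  sigma_prop: 0.246       # residual SD (24.6% proportional at power=1)
  power: 0.865            # residual-variance exponent
  f_unbound: 0.98         # unbound fraction
seed: 1861
n_empirical: 10000        # virtual patients, empirical-therapy simulation
n_per_band: 1000          # virtual patients per renal band, dose-finding grids
egfr_median: 90.0         # mL/min/1.73 m^2, empirical-cohort eGFR median
egfr_sdlog: 0.5           # log-scale SD of the empirical-cohort eGFR
egfr_upper: 130.0         # mL/min/1.73 m^2, truncation bound
grid_step: 0.02           # h, profile evaluation grid
mic_table: null           # null -> packaged illustrative table
output_dir: meropopk_output
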