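# meropopk

Population pharmacokinetics of **meropenem in critically ill adults** (including
patients on ECMO), with Monte Carlo **probability of target attainment (PTA)**
simulation for renally banded dosing regimens.

Meropenem is a hydrophilic carbapenem whose efficacy tracks the fraction of the
dosing interval during which the *free* drug concentration stays above the
pathogen's MIC (*f*T<sub>&gt;MIC</sub>). In ICU patients, sepsis-driven volume
shifts and widely varying renal function make standard dosing unreliable. This
package implements the full analysis chain a pharmacometrician would run on such
a study:

* a **two-compartment IV-infusion model** with renal covariate on clearance,

  CL = θ₁ · (1 + θ₂ · (CE − 91.57))  [L/h],

  where CE is the CKD-EPI eGFR (mL/min/1.73 m²); parameters vary log-normally
  across subjects (θᵢ = θ·e^η, η ~ N(0, ω²)) and observations carry
  power-proportional residual error, Y = F + F^power · ε, ε ~ N(0, σ²).
  The packaged defaults are the final estimates of the source study:
  θ₁ = 6.37 L/h, θ₂ = 0.00925, V_C = 9.07 L, Q = 10.7 L/h, V_P = 7.91 L
  (so V_SS = V_C + V_P = 17.0 L), ω_CL = 31.4%, ω_VC = 43.6%, ω_VP = 36.6%,
  σ = 0.246, power = 0.865, unbound fraction f = 0.98;
* **nonlinear mixed-effects estimation** (Laplace approximation at the
  conditional η mode, with η-residual interaction), likelihood-ratio model
  comparison, covariate screening, nonparametric bootstrap, CWRES, η-shrinkage
  and a prediction-corrected visual predictive check;
* **renal function equations**: Cockcroft–Gault, MDRD-4 and 2009 CKD-EPI (race
  terms deliberately omitted — see `docs/methods.md`), Du Bois BSA and
  BSA-de-indexing;
* the **four Monte Carlo dosing simulations**: an empirical-therapy cohort
  (renally banded label regimen, MICs drawn from a user-supplied frequency
  table) and three dose-finding grids (0.5/1/2 g × q8/q12 h × 0.5/1/2/3 h
  infusions × six renal bands × nine MICs) for the 40%fT>MIC, 100%fT>MIC and
  100%fT>4×MIC targets, with regimens called adequate at PTA ≥ 90%;
* external-validation metrics (rPE, rBias, rRMSE) and a **synthetic study
  generator** that emulates the 26-patient ICU design (q8/q12 dosing, five
  first-dose samples, steady-state trough/peak, LLOQ 0.2 mg/L), so the entire
  pipeline is testable without patient data.

## Worked example

```python
import numpy as np
from meropopk import (PopulationModel, DosingRegimen, individual_from_eta,
                      steady_state_profile, ftmic, pta, RenalBand)
from meropopk.pta import FT40, uniform_band_sampler

model = PopulationModel()                       # packaged final estimates
ip = individual_from_eta(model, ce=91.57)       # typical patient
print(ip.cl, ip.vss)                            # 6.37 (L/h) 16.98 (L)

prof = steady_state_profile(ip, DosingRegimen(1000, 8, 0.5))
print(round(ftmic(prof, mic=4.0), 1))           # 96.9  (% of interval free conc > 4 mg/L)

value = pta(model, uniform_band_sampler(RenalBand(26, 50)),
            DosingRegimen(1000, 12, 0.5), mic=4.0, target=FT40,
            n=10_000, rng=np.random.default_rng(1))
print(round(value, 1))                          # 99.9  (PTA %, adequate: >= 90)
```

The typical patient clears 6.37 L/h with a 17 L steady-state volume; at 1 g
q8h (30-min infusion) the free concentration exceeds 4 mg/L for ~97% of the
interval (dipping below only near the trough), comfortably above the 40%
bactericidal threshold, and in the 26–50 mL/min renal band 1 g q12h attains
the 40%fT>MIC target at MIC 4 mg/L in >99% of simulated patients.

A command line mirrors the library:

```bash
meropopk simulate-study --seed 7 --n 26 --out study.csv
meropopk fit study.csv
meropopk pta --target FT100 --seed 1 --out grid.csv
meropopk run-paper --out-dir results/
```

`run-paper` executes all four simulations and writes long-format PTA CSVs, an
adequate-regimen summary per target, and a manifest (config hash + seeds) that
makes every output byte-reproducible. The packaged MIC table is an
illustrative synthetic distribution, **not** the EUCAST database; supply a real
frequency table (`mic_mg_per_L,frequency`) for inference about actual
pathogens.

## Dataset dialect

Long CSV, one row per event: `subject_id, time (h), event_type
(dose|observation), amount (mg), infusion_duration (h), concentration (mg/L),
below_lloq, role (build|validation), ce, age, sex, weight, height,
serum_creatinine, cystatin_c, albumin, ecmo_type (none|VA|VV), crrt`. Dose rows
carry an amount and no concentration; observation rows the reverse; times are
non-decreasing within subject. Observations below the 0.2 mg/L LLOQ are
flagged and excluded from the likelihood.

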