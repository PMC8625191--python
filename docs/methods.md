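# Methods

## Structural and statistical model

Meropenem disposition is modelled as a linear two-compartment system with
constant-rate (zero-order) infusion into the central compartment and
first-order elimination from it. With micro-constants k10 = CL/V_C,
k12 = Q/V_C, k21 = Q/V_P, the central concentration is the standard
bi-exponential in the hybrid rates α, β (α+β = k10+k12+k21, αβ = k10·k21).
Both the single-dose and the multiple-dose steady-state profiles are
evaluated in closed form; at steady state each post-infusion exponential
acquires the geometric accumulation factor 1/(1 − e^{−λτ}). β is computed as
k10·k21/α to avoid catastrophic cancellation when α ≫ β, and the hybrid
discriminant is strictly positive for any positive parameter set, so no
repeated-root branch is ever reached in practice (a floor guards the
degenerate limit anyway). The closed form is verified against a stiff-ODE
oracle to 1e−6 relative tolerance and against brute-force superposition of
30 consecutive doses.

Population clearance depends linearly on the CKD-EPI eGFR covariate (CE,
mL/min/1.73 m²), centred at the study-median 91.57:

    CL = θ₁ · (1 + θ₂ · (CE − 91.57)).

A linear covariate model can cross zero for extreme (CE, θ₂) pairs, e.g.
during bootstrap resampling; clearance is floored at 0.01 L/h and a warning
is logged. Inter-individual variability is log-normal on CL, V_C and V_P
(none on Q — the study resolved IIV only for those three), with independent
η's (no off-diagonal ω was estimated). Residual error follows
Y = F + F^power·ε with a single σ; power = 1 recovers a pure proportional
model, and the default power 0.865 makes the noise slightly
sub-proportional, stabilising the variance at high concentrations. The
default parameter values in `meropopk/data/default_config.yaml` are the
final published estimates of the source analysis; the unbound fraction is
fixed at 0.98.

One wording choice deserves note: infusion drug *input* is zero-order by
definition of an IV infusion; all *disposition* processes are first-order.
The model implements constant-rate input accordingly.

## Estimation

The per-subject marginal likelihood is approximated by a Laplace expansion
at the conditional mode η̂, with the residual variance evaluated at the
conditional prediction (η-residual interaction, the "FOCE-I in spirit"
approximation). The reported OFV is −2·log(approximate marginal likelihood)
with the additive 2π constants dropped, so nested-model ΔOFV values are
directly comparable to χ² thresholds (3.84/5.99 at p<0.05; 6.635 forward,
10.83 backward in covariate selection). This is deliberately *not* a NONMEM
re-implementation: printed OFVs of the original analysis are not
reproduction targets, and bit-exact FOCEI numerics are out of scope.

Numerics:

* The conditional-mode search runs as a single vectorised damped-Newton
  iteration across all subjects (finite-difference gradients/Hessians of the
  conditional objective, eigenvalue-clipped Newton steps, backtracking line
  search, η restarted at 0 for every outer iteration so the objective is
  deterministic). An independent per-subject scipy-BFGS path and a 64-node
  adaptive Gauss–Hermite quadrature of the marginal likelihood serve as
  oracles in the test suite.
* The outer problem minimises total OFV by L-BFGS-B on a transformed scale:
  log for strictly positive parameters, identity (×100) for the covariate
  slope θ₂, which may be negative. Before optimisation the variables are
  rescaled by the square root of the diagonal finite-difference curvature at
  the start point; without this preconditioning the OFV surface is
  anisotropic enough (residual-variance versus structural directions) that
  the first line search can fail outright. Convergence is declared on
  relative OFV change (ftol 1e−9) within generous but finite bounds that
  keep the line search away from degenerate parameter values.
* Observations below the 0.2 mg/L LLOQ (including the pre-first-dose
  baseline) are dropped from the likelihood and counted — the simplest
  defensible BLQ rule; likelihood-based M3-style handling is out of scope.
* Standard errors, when requested, come from the numerical Hessian of the
  outer objective (cov = 2H⁻¹); for log-transformed parameters the SE of
  the log is reported directly as relative SE. IIV is reported as a
  standard deviation, with %CV approximated by 100·ω for the log-normal.

Diagnostics follow standard pharmacometric practice: FOCE-linearised CWRES
(decorrelated by the Cholesky factor of GΩG′ + diag(g²) at the conditional
mode; approximately standard normal under a correct model), η-shrinkage
100·(1 − sd(η̂)/ω) (population SD, ddof 0; undefined and reported missing at
ω = 0), subject-resampling nonparametric bootstrap with percentile CIs, and
a prediction-corrected VPC: observed and simulated values are normalised by
the bin-median population prediction before the 10/50/90th percentiles are
compared, binned by nominal time-after-dose (one bin per design sampling
time; empty bins merge leftward).

## Renal function

Cockcroft–Gault, MDRD-4 and 2009 CKD-EPI are implemented exactly as
published **except that the race coefficients are omitted**: the cohort the
defaults describe is ethnically homogeneous and the coefficients have been
retired from clinical practice. The MDRD multiplier defaults to the
IDMS-traceable 175 but is an argument (pass 186 for the original
calibration). Indexed eGFR values are converted to absolute mL/min by
eGFR × BSA/1.73 with Du Bois BSA. Cystatin C travels as a covariate column
only; no cystatin-based equation is provided.

The source analysis labels its simulation bands in CL_CR units while the
covariate is CKD-EPI eGFR; this package treats the simulation axis as the
CKD-EPI eGFR fed directly into the clearance model, and applies the same
value to the CL_CR-phrased dose-banding rule. The two scales differ for a
given patient; conflating them is inherited from the simulation design and
documented rather than resolved.

## Dosing simulations

fT>MIC is the percentage of one steady-state dosing interval during which
f·C(t) > multiplier·MIC (f = 0.98); by periodicity this equals the fraction
of any 24-h window for τ ∈ {8, 12, 24} h. Profiles are evaluated on a
0.02-h grid with the infusion-end breakpoint inserted exactly and threshold
crossings located by linear interpolation within grid steps. Targets:
40%fT>MIC, 100%fT>MIC, 100%fT>4×MIC; a regimen is adequate at PTA ≥ 90%.

* **Dose-finding grids** (simulations 2–4): eGFR uniform within each of six
  renal bands (0–10, 10–25, 25–50, 50–90, 90–130, 130–170 mL/min), doses
  0.5/1/2 g, intervals 8/12 h, infusions 0.5/1/2/3 h, MICs on doubling
  dilutions 0.06–16 mg/L. The stated "1000 individual PK parameters" is
  read as 1000 virtual patients *per renal band* (configurable); one cohort
  is drawn per band and shared across all regimens and MICs in that band —
  a common-random-numbers variance reduction that also makes the
  MIC/dose/target monotonicity orderings exact within a band.
* **Empirical therapy** (simulation 1): the renally banded label regimen
  (>50 mL/min: 1 g q8h; 26–50: 1 g q12h; 10–25: 0.5 g q12h; <10: 0.5 g
  q24h; 30-min infusions) applied to a cohort whose eGFR is log-normal
  truncated to (0, 130]. The source text gives the distribution's support
  but not its parameters; the defaults (median 90 mL/min/1.73 m², log-SD
  0.5) centre it on the study cohort's median eGFR and are exposed in the
  config. PTA is computed *conditionally* at every MIC of the supplied
  frequency table (statistically equivalent to random MIC assignment,
  lower Monte Carlo variance), and the overall attainment is the
  frequency-weighted sum. The packaged MIC table is synthetic and
  illustrative only.

At n = 10,000 the Monte Carlo standard error of a PTA near 90% is about
0.3 percentage points; test tolerances use ±2 points.

## Synthetic study generator

The generator emulates the study design, not any individual patient: 26
subjects, ~31% on ECMO (VA:VV ≈ 7:1), regimens restricted to the enrolled
q8/q12 design (the label's q24h band maps to 0.5 g q12h here — the PTA
simulations use the full rule), five first-dose samples (pre-dose and
0.5/1/4/8 h for q8h; 0/0.5/1/6/12 h for q12h) and a steady-state
trough/peak pair at the 4th or 5th dose (chosen at random per subject) used
as the validation split. Covariates are truncated log-normal/normal
marginals moment-matched to the reported cohort medians and IQRs; the eGFR
covariate is always computed from sampled creatinine/age/sex through the
renal module, never sampled independently. The pre-first-dose sample is
recorded at time 0 with concentration 0 and the below-LLOQ flag set. An
optional timing-corruption hook mis-records one observation's time while
simulating at the true time, emulating the documentation error that
produced the original study's validation outliers (no equivalence claimed).

What the generator does **not** emulate: CRRT effects on clearance, assay
chromatography, time-varying renal function, correlated covariates beyond
the creatinine→eGFR chain, or the exact 125/44 build/validation split of
the source data (the nominal design yields 130/52 before BLQ losses).
Passing tests therefore demonstrate internal consistency of the machinery
under the assumed data-generating process, not fidelity to any real
patient population.

## Validation metrics

rPE = (C_P − C_O)/C_O per observation; rBias = 100·mean(rPE);
rRMSE = 100·√mean(rPE²). Predictions used for external validation are
*population* predictions (no empirical-Bayes feedback from the validation
samples) — the stricter convention, selectable via the prediction flag. The
published validation values (17.5%/91.5% with outliers, 1.59%/29.4%
without) require the original patient samples and are not reproduction
targets.

## Problem sizes and determinism

Default problem sizes — 10,000 virtual patients per PTA cell, 1000 per band
in full grids, 10 replicates in the recovery experiment, 200–1000 VPC
replicates — were chosen so each quantity's Monte Carlo error is small
relative to the decisions drawn from it. Every stochastic entry point takes
an explicit `numpy.random.Generator` or seed; with a fixed seed all outputs
are byte-identical across runs, and pipeline runs write a manifest (config
hash, seeds, version) sufficient to reproduce them.

## Known limitations

* The Laplace/FOCE approximation shares the usual small-sample biases of
  conditional-likelihood NLME; with 26 subjects the variance parameters
  (especially ω_VP, whose EBEs are heavily shrunk) are imprecise.
* CLI `fit` is practical for study-sized datasets (seconds to ~1 min);
  the bootstrap at its 200-replicate desk default takes correspondingly
  longer.
* No inter-occasion variability, no ω covariance, no SAEM/importance
  sampling, no three-compartment or nonlinear-elimination variants, no
  PK/PD indices beyond fT>MIC, and no CRRT clearance pathway.
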