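"""Synthetic ICU cohorts and concentration datasets with the study design.

The generator emulates a 26-patient prospective ICU PK study: patients
receive 0.5 or 1 g meropenem infused over 30 min every 8 or 12 h (regimen
chosen by renal banding), five blood samples are drawn around the first
dose (pre-dose and 0.5/1/4/8 h for q8h, 0/0.5/1/6/12 h for q12h) and a
trough/peak pair is drawn at steady state around the 4th or 5th dose for
external validation.  Concentrations are simulated from the population
model (log-normal IIV, power-proportional residual noise) and flagged when
below the assay LLOQ of 0.2 mg/L.

Demographics are drawn from truncated log-normal/normal marginals
moment-matched to the study cohort's reported medians and interquartile
ranges (age ~70 y, weight ~58 kg, serum creatinine ~0.7 mg/dL, ~2/3 male,
~31% on ECMO with a 7:1 VA:VV split); the CKD-EPI eGFR covariate is always
computed from the sampled creatinine/age/sex through the renal module,
never sampled independently of them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pkmodel import (
    DoseEvent,
    DosingRegimen,
    PopulationModel,
    conc_dose_events,
    individual_from_eta,
)
from .renal import DemographicRecord, renal_estimates
from .pta import recommended_regimen

__all__ = ["StudyDesign", "generate_cohort", "generate_study", "make_fixtures"]

#: Observation column order of the generated dataset (the CSV dialect).
DATASET_COLUMNS = [
    "subject_id",
    "time",
    "event_type",
    "amount",
    "infusion_duration",
    "concentration",
    "below_lloq",
    "role",
    "ce",
    "age",
    "sex",
    "weight",
    "height",
    "serum_creatinine",
    "cystatin_c",
    "albumin",
    "ecmo_type",
    "crrt",
]


@dataclass(frozen=True)
class StudyDesign:
    """Sampling design of the emulated study."""

    n_subjects: int = 26
    ecmo_fraction: float = 8 / 26
    va_vv_ratio: float = 7.0  # VA : VV among ECMO patients
    infusion_duration: float = 0.5  # h
    first_dose_samples_q8: tuple[float, ...] = (0.0, 0.5, 1.0, 4.0, 8.0)
    first_dose_samples_q12: tuple[float, ...] = (0.0, 0.5, 1.0, 6.0, 12.0)
    steady_state_dose_options: tuple[int, ...] = (4, 5)
    peak_offset: float = 0.5  # h after start of the steady-state dose
    lloq: float = 0.2  # mg/L

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not (0 <= self.ecmo_fraction <= 1):
            raise ValueError("ecmo_fraction must be in [0, 1]")
        if self.lloq <= 0:
            raise ValueError("lloq must be positive")


# median and (q1, q3) targets for the covariate marginals, pooled across
# the ECMO and non-ECMO strata of the emulated cohort
_MARGINALS = {
    "age": (70.0, 62.0, 79.0),
    "weight": (58.0, 51.5, 65.0),
    "height": (164.0, 155.0, 170.0),
    "serum_creatinine": (0.70, 0.47, 1.30),
    "cystatin_c": (1.40, 1.05, 1.87),
}
_P_MALE = 18 / 26
_IQR_TO_SDLOG = 2.0 * 0.674489750196082  # q3/q1 spans 2 * z_0.75 log-SDs


def _lognormal_from_iqr(median: float, q1: float, q3: float, rng, n: int, lo: float, hi: float):
    sdlog = (math.log(q3) - math.log(q1)) / _IQR_TO_SDLOG
    draw = rng.lognormal(math.log(median), sdlog, size=n)
    return np.clip(draw, lo, hi)


def generate_cohort(design: StudyDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Sample one covariate table of ``design.n_subjects`` patients."""
    n = design.n_subjects
    age = _lognormal_from_iqr(*_MARGINALS["age"], rng, n, 20.0, 95.0)
    weight = _lognormal_from_iqr(*_MARGINALS["weight"], rng, n, 35.0, 120.0)
    height = np.clip(rng.normal(164.0, 9.0, size=n), 140.0, 195.0)
    scr = _lognormal_from_iqr(*_MARGINALS["serum_creatinine"], rng, n, 0.2, 8.0)
    cysc = _lognormal_from_iqr(*_MARGINALS["cystatin_c"], rng, n, 0.4, 6.0)
    albumin = np.clip(rng.normal(2.8, 0.4, size=n), 1.5, 4.5)
    sex = np.where(rng.random(n) < _P_MALE, "male", "female")

    n_ecmo = int(round(design.ecmo_fraction * n))
    ecmo_type = np.array(["none"] * n, dtype=object)
    if n_ecmo:
        idx = rng.choice(n, size=n_ecmo, replace=False)
        p_va = design.va_vv_ratio / (design.va_vv_ratio + 1.0)
        ecmo_type[idx] = np.where(rng.random(n_ecmo) < p_va, "VA", "VV")
    crrt = rng.random(n) < 2 / 26

    rows = []
    for i in range(n):
        demo = DemographicRecord(
            age=float(age[i]),
            sex=str(sex[i]),
            weight=float(weight[i]),
            height=float(height[i]),
            serum_creatinine=float(scr[i]),
            serum_cystatin_c=float(cysc[i]),
            albumin=float(albumin[i]),
        )
        ren = renal_estimates(demo)
        rows.append(
            {
                "subject_id": i + 1,
                "age": demo.age,
                "sex": demo.sex,
                "weight": demo.weight,
                "height": demo.height,
                "serum_creatinine": demo.serum_creatinine,
                "cystatin_c": demo.serum_cystatin_c,
                "albumin": demo.albumin,
                "bsa": ren.bsa,
                "ce": ren.egfr_ckd_epi,
                "crcl_cg": ren.crcl_cg,
                "egfr_mdrd": ren.egfr_mdrd,
                "ecmo_type": ecmo_type[i],
                "crrt": bool(crrt[i]),
            }
        )
    return pd.DataFrame(rows)


def _study_regimen(ce: float, design: StudyDesign) -> DosingRegimen:
    """Renally banded regimen, restricted to the study's q8/q12 design.

    The product label's q24h band (<10 mL/min) is mapped onto 0.5 g q12h:
    the emulated study enrolled only q8h/q12h regimens.
    """
    reg = recommended_regimen(ce)
    if reg.interval > 12.0:
        reg = DosingRegimen(reg.dose, 12.0, reg.infusion_duration)
    return DosingRegimen(reg.dose, reg.interval, design.infusion_duration)


def generate_study(
    model: PopulationModel,
    cohort: pd.DataFrame,
    design: StudyDesign,
    rng: np.random.Generator,
    corrupt_timing: dict | None = None,
) -> pd.DataFrame:
    """Simulate the full dosing/sampling record for every cohort subject.

    Returns a long-format dataset (one row per dose or observation event)
    in the documented CSV dialect.  First-dose samples carry role
    ``build``; the steady-state trough/peak pair carries role
    ``validation``.  The pre-dose sample before the first dose is recorded
    at time 0 with concentration 0 and the below-LLOQ flag set.

    ``corrupt_timing`` optionally mis-records one observation's time while
    simulating it at the true time: a dict with keys ``subject_id``,
    ``obs_index`` and ``recorded_time`` (emulating a documentation error).
    """
    rows = []
    for rec in cohort.itertuples():
        regimen = _study_regimen(rec.ce, design)
        tau = regimen.interval
        eta = rng.normal(
            0.0, [model.omega_cl, model.omega_vc, model.omega_vp]
        )
        ip = individual_from_eta(model, rec.ce, *eta)
        ss_dose = int(rng.choice(design.steady_state_dose_options))
        n_doses = ss_dose
        events = [
            DoseEvent(k * tau, regimen.dose, regimen.infusion_duration)
            for k in range(n_doses)
        ]
        first_times = (
            design.first_dose_samples_q8
            if tau == 8.0
            else design.first_dose_samples_q12
        )
        obs = [(t, "build") for t in first_times]
        trough_time = (ss_dose - 1) * tau  # immediately before the ss dose
        peak_time = trough_time + design.peak_offset
        obs += [(trough_time, "validation"), (peak_time, "validation")]

        true_times = np.array([t for t, _ in obs])
        recorded_times = true_times.copy()
        if corrupt_timing and corrupt_timing.get("subject_id") == rec.subject_id:
            j = int(corrupt_timing["obs_index"])
            recorded_times[j] = float(corrupt_timing["recorded_time"])

        # pre-dose-k observations must not see dose k itself
        conc_true = np.empty(true_times.size)
        for j, t in enumerate(true_times):
            prior = [ev for ev in events if ev.time < t - 1e-9]
            conc_true[j] = conc_dose_events(ip, prior, np.array([t]))[0]

        cov = {
            "ce": rec.ce,
            "age": rec.age,
            "sex": rec.sex,
            "weight": rec.weight,
            "height": rec.height,
            "serum_creatinine": rec.serum_creatinine,
            "cystatin_c": rec.cystatin_c,
            "albumin": rec.albumin,
            "ecmo_type": rec.ecmo_type,
            "crrt": rec.crrt,
        }
        for ev in events:
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "time": ev.time,
                    "event_type": "dose",
                    "amount": ev.amount,
                    "infusion_duration": ev.infusion_duration,
                    "concentration": np.nan,
                    "below_lloq": False,
                    "role": "build",
                    **cov,
                }
            )
        for j, ((_, role), t_rec) in enumerate(zip(obs, recorded_times)):
            pred = conc_true[j]
            if pred <= 0:
                y, flagged = 0.0, True
            else:
                eps = rng.normal(0.0, model.sigma_prop)
                y = pred + pred**model.power * eps
                y = max(y, 0.0)
                flagged = y < design.lloq
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "time": float(t_rec),
                    "event_type": "observation",
                    "amount": np.nan,
                    "infusion_duration": np.nan,
                    "concentration": y,
                    "below_lloq": flagged,
                    "role": role,
                    **cov,
                }
            )
    df = pd.DataFrame(rows)[DATASET_COLUMNS]
    df = df.sort_values(
        ["subject_id", "time", "event_type"], kind="stable"
    ).reset_index(drop=True)
    return df


def make_fixtures() -> dict[str, pd.DataFrame]:
    """Small deterministic datasets for the test suite.

    ``noisefree4``: 4 subjects, no IIV and no residual noise (round-trip
    exact against the closed-form model).  ``noisy26``: the full 26-subject
    design at the default population parameters, fixed seed.
    """
    model = PopulationModel()
    quiet = model.with_updates(omega_cl=0.0, omega_vc=0.0, omega_vp=0.0, sigma_prop=0.0)
    design4 = StudyDesign(n_subjects=4, ecmo_fraction=0.0)
    rng = np.random.default_rng(20211104)
    cohort4 = generate_cohort(design4, rng)
    noisefree = generate_study(quiet, cohort4, design4, rng)

    design26 = StudyDesign()
    rng = np.random.default_rng(1861)
    cohort26 = generate_cohort(design26, rng)
    noisy = generate_study(model, cohort26, design26, rng)
    return {"noisefree4": noisefree, "noisy26": noisy}
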