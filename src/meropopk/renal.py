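"""Renal function and body-size covariates.

Creatinine-based estimators of renal drug-elimination capacity used as
covariates in the clearance model and as axes of the dosing simulations:
Cockcroft-Gault creatinine clearance, the 4-variable MDRD and 2009 CKD-EPI
glomerular filtration rate equations (both indexed to 1.73 m^2 body surface
area), and the Du Bois body-surface-area formula used to de-index them to
absolute mL/min.

The race coefficients of the MDRD and CKD-EPI equations are deliberately
omitted: the study population these defaults describe is ethnically
homogeneous (Korean ICU patients) and the coefficients have been retired
from clinical use.  The MDRD multiplier defaults to the IDMS-traceable 175
form but is exposed as an argument.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

__all__ = [
    "DemographicRecord",
    "RenalEstimates",
    "bsa_dubois",
    "crcl_cockcroft_gault",
    "egfr_ckd_epi",
    "egfr_mdrd",
    "deindex_gfr",
    "renal_estimates",
]

Sex = Literal["male", "female"]

#: BSA reference (m^2) to which MDRD/CKD-EPI eGFR values are indexed.
BSA_REFERENCE = 1.73


@dataclass(frozen=True)
class DemographicRecord:
    """One subject's demographics and renal chemistry.

    Units: age in years, weight in kg, height in cm, serum creatinine in
    mg/dL, serum cystatin C in mg/L, albumin in g/dL.  Cystatin C and
    albumin are carried as covariate columns only; no cystatin-based eGFR
    equation is provided.
    """

    age: float
    sex: Sex
    weight: float
    height: float
    serum_creatinine: float
    serum_cystatin_c: float | None = None
    albumin: float | None = None

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if self.weight <= 0:
            raise ValueError(f"weight must be positive, got {self.weight}")
        if self.height <= 0:
            raise ValueError(f"height must be positive, got {self.height}")
        if self.serum_creatinine <= 0:
            raise ValueError(
                f"serum creatinine must be positive, got {self.serum_creatinine}"
            )
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")


@dataclass(frozen=True)
class RenalEstimates:
    """All renal estimators evaluated for one subject.

    ``*_deindexed`` values are the indexed eGFR rescaled by the subject's
    actual BSA: eGFR (mL/min) = eGFR (mL/min/1.73 m^2) x BSA / 1.73.
    """

    crcl_cg: float  # mL/min
    egfr_mdrd: float  # mL/min/1.73 m^2
    egfr_ckd_epi: float  # mL/min/1.73 m^2
    egfr_mdrd_deindexed: float  # mL/min
    egfr_ckd_epi_deindexed: float  # mL/min
    bsa: float  # m^2


def bsa_dubois(height: float, weight: float) -> float:
    """Du Bois body surface area (m^2) from height (cm) and weight (kg).

    BSA = 0.007184 * height^0.725 * weight^0.425.
    """
    if height <= 0 or weight <= 0:
        raise ValueError("height and weight must be positive")
    return 0.007184 * height**0.725 * weight**0.425


def crcl_cockcroft_gault(demo: DemographicRecord) -> float:
    """Cockcroft-Gault creatinine clearance in mL/min.

    CrCl = (140 - age) * weight / (72 * Scr), multiplied by 0.85 for women.
    """
    if demo.age >= 140:
        raise ValueError("Cockcroft-Gault is undefined for age >= 140 years")
    crcl = (140.0 - demo.age) * demo.weight / (72.0 * demo.serum_creatinine)
    if demo.sex == "female":
        crcl *= 0.85
    return crcl


def egfr_ckd_epi(demo: DemographicRecord) -> float:
    """2009 CKD-EPI creatinine eGFR in mL/min/1.73 m^2 (race term omitted).

    eGFR = 141 * min(Scr/kappa, 1)^alpha * max(Scr/kappa, 1)^-1.209
           * 0.993^age * (1.018 if female)
    with kappa = 0.7 (women) / 0.9 (men) and alpha = -0.329 / -0.411.
    """
    scr = demo.serum_creatinine
    if demo.sex == "female":
        kappa, alpha, sex_mult = 0.7, -0.329, 1.018
    else:
        kappa, alpha, sex_mult = 0.9, -0.411, 1.0
    ratio = scr / kappa
    egfr = (
        141.0
        * min(ratio, 1.0) ** alpha
        * max(ratio, 1.0) ** -1.209
        * 0.993**demo.age
        * sex_mult
    )
    return egfr


def egfr_mdrd(demo: DemographicRecord, coefficient: float = 175.0) -> float:
    """4-variable MDRD eGFR in mL/min/1.73 m^2 (race term omitted).

    eGFR = coefficient * Scr^-1.154 * age^-0.203 * (0.742 if female).
    ``coefficient`` defaults to the IDMS-traceable 175; pass 186 for the
    original calibration.
    """
    egfr = coefficient * demo.serum_creatinine**-1.154 * demo.age**-0.203
    if demo.sex == "female":
        egfr *= 0.742
    return egfr


def deindex_gfr(egfr_indexed: float, bsa: float) -> float:
    """Convert an eGFR indexed to 1.73 m^2 into absolute mL/min."""
    if bsa <= 0:
        raise ValueError("BSA must be positive")
    return egfr_indexed * bsa / BSA_REFERENCE


def renal_estimates(demo: DemographicRecord, mdrd_coefficient: float = 175.0) -> RenalEstimates:
    """Evaluate every renal estimator for one subject."""
    bsa = bsa_dubois(demo.height, demo.weight)
    mdrd = egfr_mdrd(demo, mdrd_coefficient)
    ckd = egfr_ckd_epi(demo)
    return RenalEstimates(
        crcl_cg=crcl_cockcroft_gault(demo),
        egfr_mdrd=mdrd,
        egfr_ckd_epi=ckd,
        egfr_mdrd_deindexed=deindex_gfr(mdrd, bsa),
        egfr_ckd_epi_deindexed=deindex_gfr(ckd, bsa),
        bsa=bsa,
    )
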