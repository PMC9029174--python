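"""Renal-function and body-size covariate calculators.

Pure deterministic functions used both as model inputs (the clearance
covariate link uses body-surface-area-normalised creatinine clearance) and
in covariate screening.  Conventions are configurable where the field has
more than one: Cockcroft-Gault is evaluated on total body weight by
default, and BSA normalisation uses the DuBois-DuBois formula.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PatientCovariates",
    "crcl_cockcroft_gault",
    "bsa_dubois",
    "bsa_normalize",
    "ckd_epi",
    "bmi",
]


@dataclass
class PatientCovariates:
    """Per-subject clinical covariates (adult ICU context).

    ``crcl`` is creatinine clearance normalised to 1.73 m2 body surface
    area (mL/min/1.73 m2) — the covariate entering the clearance link.
    Severity scores (SAPS 3, SOFA, MODS) are carried for covariate
    screening only.
    """

    age: float
    weight: float
    height: float
    sex: str  # "male" | "female"
    serum_creatinine: float | None = None
    crcl: float | None = None
    bmi: float | None = None
    sepsis: bool | None = None
    saps3: int | None = None
    sofa: int | None = None
    mods: int | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.age <= 18:
            raise ValueError(f"age must exceed 18 y (adult cohort), got {self.age}")
        if self.weight <= 0 or self.height <= 0:
            raise ValueError("weight and height must be positive")
        if self.serum_creatinine is not None and self.serum_creatinine <= 0:
            raise ValueError("serum creatinine must be positive")
        if self.crcl is not None and self.crcl <= 0:
            raise ValueError("creatinine clearance must be positive")
        if self.bmi is None:
            self.bmi = bmi(self.weight, self.height)


def crcl_cockcroft_gault(
    age: float, weight: float, sex: str, serum_creatinine: float
) -> float:
    """Cockcroft-Gault creatinine clearance, mL/min.

    CrCL = (140 - age) * weight / (72 * SCr), multiplied by 0.85 for
    females.  ``weight`` in kg (total body weight by convention here),
    ``serum_creatinine`` in mg/dL.
    """
    if serum_creatinine <= 0:
        raise ValueError(f"serum creatinine must be positive, got {serum_creatinine}")
    if age <= 0 or age >= 140 or weight <= 0:
        raise ValueError("age must be in (0, 140) y and weight positive")
    crcl = (140.0 - age) * weight / (72.0 * serum_creatinine)
    if sex == "female":
        crcl *= 0.85
    elif sex != "male":
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    return crcl


def bsa_dubois(weight: float, height: float) -> float:
    """DuBois-DuBois body surface area, m2 (weight kg, height cm)."""
    if weight <= 0 or height <= 0:
        raise ValueError("weight and height must be positive")
    return 0.007184 * weight**0.425 * height**0.725


def bsa_normalize(crcl_ml_min: float, weight: float, height: float) -> float:
    """Normalise a clearance (mL/min) to 1.73 m2 BSA: crcl * 1.73 / BSA."""
    return crcl_ml_min * 1.73 / bsa_dubois(weight, height)


# CKD-EPI 2009 creatinine equation, without the race coefficient (the race
# adjustment derived in North American cohorts is not applicable here).
_CKD_EPI = {
    "female": (0.7, -0.329, 1.018),  # kappa, alpha, sex factor
    "male": (0.9, -0.411, 1.0),
}


def ckd_epi(age: float, sex: str, serum_creatinine: float) -> float:
    """CKD-EPI (2009) estimated GFR, mL/min/1.73 m2.

    eGFR = 141 * min(SCr/k, 1)^a * max(SCr/k, 1)^-1.209 * 0.993^age * f_sex,
    with (k, a) = (0.7, -0.329) for females and (0.9, -0.411) for males and
    f_sex = 1.018 for females.  No race coefficient is applied.
    """
    if serum_creatinine <= 0:
        raise ValueError(f"serum creatinine must be positive, got {serum_creatinine}")
    if sex not in _CKD_EPI:
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    kappa, alpha, f_sex = _CKD_EPI[sex]
    r = serum_creatinine / kappa
    return 141.0 * min(r, 1.0) ** alpha * max(r, 1.0) ** -1.209 * 0.993**age * f_sex


def bmi(weight: float, height: float) -> float:
    """Body mass index kg/m2 (weight kg, height cm)."""
    if weight <= 0 or height <= 0:
        raise ValueError("weight and height must be positive")
    h_m = height / 100.0
    return weight / (h_m * h_m)
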