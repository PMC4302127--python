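"""Patient covariates, Cockcroft-Gault creatinine clearance and the
clearance covariate equation.

The final clearance model has two branches: subjects on renal replacement
therapy (RRT) get the bare typical clearance ``theta_cl``; subjects off RRT
get a creatinine-clearance (CrCL) scaled value.  How CrCL enters is a
configurable *dialect* because raw mL/min multiplication is dimensionally
absurd:

* ``"linear"`` (structural default, used for fitting and recovery):
  ``TVCL = theta_cl * theta_crcl * (crcl / crcl_reference)``
* ``"power"``:
  ``TVCL = theta_cl * theta_crcl * (crcl / crcl_reference) ** exponent``

The dosing-simulation default uses the power dialect with constants
calibrated against the mutually dose-linear columns of the published
simulated-trough table (see :mod:`ecmopk.simulate`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional

__all__ = [
    "PatientCovariates",
    "ClearanceCovariateModel",
    "cockcroft_gault",
    "typical_clearance",
    "scr_mgdl_to_umol",
    "scr_umol_to_mgdl",
    "CRCL_FLOOR",
]

#: Conversion factor: 1 mg/dL creatinine = 88.4 umol/L.
SCR_UMOL_PER_MGDL = 88.4

#: Floor applied to non-RRT creatinine clearances in simulation inputs to
#: avoid degenerate clearances; well below the simulated 20-180 range.
CRCL_FLOOR = 5.0


class MissingCovariateError(ValueError):
    """A covariate required by the clearance model is absent."""


def scr_mgdl_to_umol(scr_mgdl: float) -> float:
    return scr_mgdl * SCR_UMOL_PER_MGDL


def scr_umol_to_mgdl(scr_umol: float) -> float:
    return scr_umol / SCR_UMOL_PER_MGDL


@dataclass(frozen=True)
class PatientCovariates:
    """Demographics and renal-status covariates for one subject.

    ``serum_creatinine`` is in umol/L.  ``crcl`` may be ``None`` for
    RRT-dependent subjects (their clearance does not use it).  ``sofa``
    is carried for synthesis/reporting only and never enters the model.
    """

    age: float
    sex: Literal["male", "female"]
    weight: float
    serum_creatinine: float
    crcl: Optional[float] = None
    rrt: bool = False
    ecmo: bool = False
    sofa: Optional[float] = None

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError(f"age must be > 0, got {self.age}")
        if self.weight <= 0:
            raise ValueError(f"weight must be > 0, got {self.weight}")
        if self.serum_creatinine <= 0:
            raise ValueError(
                f"serum creatinine must be > 0, got {self.serum_creatinine}"
            )
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not self.rrt and self.crcl is not None and self.crcl <= 0:
            raise ValueError(f"crcl must be > 0 when given, got {self.crcl}")


def cockcroft_gault(
    age: float,
    weight: float,
    serum_creatinine: float,
    sex: str,
    scr_unit: Literal["umol/L", "mg/dL"] = "umol/L",
) -> float:
    """Cockcroft-Gault creatinine clearance estimate in mL/min.

    ``CrCL = (140 - age) * weight / (72 * Scr[mg/dL])``, times 0.85 for
    females.
    """
    if age <= 0 or weight <= 0 or serum_creatinine <= 0:
        raise ValueError("age, weight and serum creatinine must be positive")
    if age >= 140:
        raise ValueError("age must be below 140 years for Cockcroft-Gault")
    if scr_unit == "umol/L":
        scr_mgdl = scr_umol_to_mgdl(serum_creatinine)
    elif scr_unit == "mg/dL":
        scr_mgdl = serum_creatinine
    else:
        raise ValueError(f"unknown creatinine unit {scr_unit!r}")
    crcl = (140.0 - age) * weight / (72.0 * scr_mgdl)
    if sex == "female":
        crcl *= 0.85
    elif sex != "male":
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    return crcl


@dataclass(frozen=True)
class ClearanceCovariateModel:
    """Maps covariates to the typical value of clearance (TVCL, L/h).

    ``theta_cl`` applies to both branches; ``theta_crcl`` is the fractional
    CrCL effect for non-RRT subjects.  RRT subjects' TVCL equals
    ``theta_cl`` regardless of CrCL.
    """

    theta_cl: float
    theta_crcl: float = 1.0
    crcl_reference: float = 100.0
    dialect: Literal["linear", "power"] = "linear"
    exponent: float = 1.0
    crcl_floor: float = CRCL_FLOOR

    def __post_init__(self) -> None:
        if self.theta_cl <= 0:
            raise ValueError("theta_cl must be > 0")
        if self.theta_crcl <= 0:
            raise ValueError("theta_crcl must be > 0")
        if self.crcl_reference <= 0:
            raise ValueError("crcl_reference must be > 0")
        if self.dialect not in ("linear", "power"):
            raise ValueError(f"unknown CrCL dialect {self.dialect!r}")

    def tvcl(self, cov: PatientCovariates) -> float:
        return typical_clearance(self, cov)

    def tvcl_from_crcl(self, crcl: float) -> float:
        """Non-RRT branch evaluated directly at a CrCL value."""
        crcl = max(float(crcl), self.crcl_floor)
        ratio = crcl / self.crcl_reference
        if self.dialect == "linear":
            return self.theta_cl * self.theta_crcl * ratio
        return self.theta_cl * self.theta_crcl * ratio ** self.exponent


def typical_clearance(
    model: ClearanceCovariateModel, cov: PatientCovariates
) -> float:
    """TVCL in L/h under the model's dialect.

    RRT branch ignores CrCL entirely; non-RRT branch requires it.
    """
    if cov.rrt:
        return model.theta_cl
    if cov.crcl is None:
        raise MissingCovariateError(
            "crcl is required for subjects not receiving RRT"
        )
    tvcl = model.tvcl_from_crcl(cov.crcl)
    if not (math.isfinite(tvcl) and tvcl > 0):
        raise ValueError(f"degenerate typical clearance {tvcl!r}")
    return tvcl
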