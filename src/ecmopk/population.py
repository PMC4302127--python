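"""Hierarchical layer: between-subject variability (BSV), residual error
and individual-parameter construction.

Subject effects are exponential (log-normal individual parameters):
``CL_i = TVCL * exp(eta_cl)`` etc., with independent zero-mean normal etas
of variances ``omega2_*``.  There is no eta on Q.

Residual error is combined exponential-and-additive:
``y = f * exp(eps1) + eps2``, ``eps1 ~ N(0, sigma_prop^2)``,
``eps2 ~ N(0, sigma_add^2)``.  A proportional variant
(``y = f * (1 + eps1) + eps2``) is available as a sensitivity option.

%CV convention (fixed throughout): ``%CV = 100 * sqrt(exp(omega2) - 1)``,
exact for log-normal quantities, so generation and reporting round-trip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .covariates import ClearanceCovariateModel, PatientCovariates, typical_clearance
from .pk import PKParameters

__all__ = [
    "PopulationModel",
    "FixedEffects",
    "RandomEffectsSpec",
    "ResidualSpec",
    "EtaVector",
    "individual_parameters",
    "sample_etas",
    "apply_residual",
    "cv_to_omega2",
    "omega2_to_cv",
]


@dataclass(frozen=True)
class FixedEffects:
    """Population typical values (theta)."""

    theta_cl: float
    theta_vc: float
    theta_vp: float
    theta_q: float
    theta_crcl: float = 1.0

    def __post_init__(self) -> None:
        for name in ("theta_cl", "theta_vc", "theta_vp", "theta_q", "theta_crcl"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    def clearance_model(
        self,
        crcl_reference: float = 100.0,
        dialect: str = "linear",
        exponent: float = 1.0,
    ) -> ClearanceCovariateModel:
        return ClearanceCovariateModel(
            theta_cl=self.theta_cl,
            theta_crcl=self.theta_crcl,
            crcl_reference=crcl_reference,
            dialect=dialect,  # type: ignore[arg-type]
            exponent=exponent,
        )


@dataclass(frozen=True)
class RandomEffectsSpec:
    """Diagonal BSV variances on log scale; no eta on Q."""

    omega2_cl: float = 0.0
    omega2_vc: float = 0.0
    omega2_vp: float = 0.0

    def __post_init__(self) -> None:
        for name in ("omega2_cl", "omega2_vc", "omega2_vp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def from_cv_percent(cls, cv_cl: float, cv_vc: float, cv_vp: float
                        ) -> "RandomEffectsSpec":
        return cls(cv_to_omega2(cv_cl), cv_to_omega2(cv_vc), cv_to_omega2(cv_vp))

    def as_cv_percent(self) -> tuple[float, float, float]:
        return (
            omega2_to_cv(self.omega2_cl),
            omega2_to_cv(self.omega2_vc),
            omega2_to_cv(self.omega2_vp),
        )


@dataclass(frozen=True)
class ResidualSpec:
    """Combined residual-error magnitudes.

    ``sigma_prop`` is the SD of the exponential (log-scale) term, i.e. a CV
    fraction; ``sigma_add`` is the additive SD in mg/L.
    """

    sigma_prop: float = 0.0
    sigma_add: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_prop < 0 or self.sigma_add < 0:
            raise ValueError("residual magnitudes must be >= 0")


@dataclass(frozen=True)
class EtaVector:
    """Log-scale subject deviations."""

    eta_cl: float = 0.0
    eta_vc: float = 0.0
    eta_vp: float = 0.0

    def __post_init__(self) -> None:
        for name in ("eta_cl", "eta_vc", "eta_vp"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class PopulationModel:
    """The full hierarchical specification: theta, omega^2 and sigma."""

    fixed: FixedEffects
    random_effects: "RandomEffectsSpec"
    residual: "ResidualSpec"


def cv_to_omega2(cv_percent: float) -> float:
    """Log-normal variance from a %CV: ``omega2 = ln(1 + (cv/100)^2)``."""
    if cv_percent < 0:
        raise ValueError("cv must be >= 0")
    frac = cv_percent / 100.0
    return math.log1p(frac * frac)


def omega2_to_cv(omega2: float) -> float:
    """%CV from a log-normal variance: ``100 * sqrt(exp(omega2) - 1)``."""
    if omega2 < 0:
        raise ValueError("omega2 must be >= 0")
    return 100.0 * math.sqrt(math.expm1(omega2))


def individual_parameters(
    fixed: FixedEffects,
    cov: PatientCovariates,
    etas: EtaVector,
    clearance_model: ClearanceCovariateModel | None = None,
) -> PKParameters:
    """Construct one subject's structural parameters.

    ``CL_i = TVCL(cov) * exp(eta_cl)``; Vc and Vp likewise; Q carries no
    eta.  A custom ``clearance_model`` (e.g. the calibrated simulation
    dialect) may replace the default linear one built from ``fixed``.
    """
    model = clearance_model if clearance_model is not None else fixed.clearance_model()
    tvcl = typical_clearance(model, cov)
    return PKParameters(
        cl=tvcl * math.exp(etas.eta_cl),
        vc=fixed.theta_vc * math.exp(etas.eta_vc),
        vp=fixed.theta_vp * math.exp(etas.eta_vp),
        q=fixed.theta_q,
    )


def sample_etas(spec: RandomEffectsSpec, rng: np.random.Generator) -> EtaVector:
    """One independent zero-mean normal draw per eta (variances from spec)."""
    draw = rng.standard_normal(3)
    return EtaVector(
        eta_cl=draw[0] * math.sqrt(spec.omega2_cl),
        eta_vc=draw[1] * math.sqrt(spec.omega2_vc),
        eta_vp=draw[2] * math.sqrt(spec.omega2_vp),
    )


def sample_eta_matrix(
    spec: RandomEffectsSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """``(n, 3)`` matrix of eta draws; columns (cl, vc, vp)."""
    sd = np.sqrt([spec.omega2_cl, spec.omega2_vc, spec.omega2_vp])
    return rng.standard_normal((n, 3)) * sd


def apply_residual(
    pred: float | np.ndarray,
    spec: ResidualSpec,
    rng: np.random.Generator,
    variant: Literal["exponential", "proportional"] = "exponential",
) -> float | np.ndarray:
    """Perturb model predictions with combined residual error.

    The result may be negative (additive term); censoring is applied
    downstream, not here.
    """
    pred = np.asarray(pred, dtype=float)
    if np.any(pred < 0):
        raise ValueError("predictions must be >= 0")
    eps1 = rng.normal(0.0, spec.sigma_prop, size=pred.shape) if spec.sigma_prop else 0.0
    eps2 = rng.normal(0.0, spec.sigma_add, size=pred.shape) if spec.sigma_add else 0.0
    if variant == "exponential":
        y = pred * np.exp(eps1) + eps2
    elif variant == "proportional":
        y = pred * (1.0 + eps1) + eps2
    else:
        raise ValueError(f"unknown residual variant {variant!r}")
    return float(y) if y.ndim == 0 else y
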