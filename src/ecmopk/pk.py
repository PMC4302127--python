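"""Closed-form two-compartment kinetics with zero-order (infusion) input.

All quantities are in a fixed internal unit system: time in hours, amounts
in mg, volumes in L, clearances in L/h, concentrations in mg/L. Unit
conversion happens at I/O boundaries only.

The central-compartment concentration after a single constant-rate infusion
of duration ``T`` is the biexponential

    C(t) = (R/Vc) * [ A/alpha * (1 - e^{-alpha*te}) * e^{-alpha*(t-T)+}
                    + B/beta  * (1 - e^{-beta *te}) * e^{-beta *(t-T)+} ]

with ``te = min(t, T)``, ``R`` the infusion rate and ``A + B = 1`` the
hybrid macro-coefficients. Multi-dose profiles are exact superpositions of
shifted single-dose profiles (the system is linear), which also covers
loading-dose regimens.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PKParameters",
    "Microconstants",
    "DoseEvent",
    "Regimen",
    "microconstants",
    "concentration_at",
    "concentration_profile",
    "auc_infinity",
    "trough_at_interval",
    "steady_state_trough",
    "time_above_threshold",
]

# Relative gap below which the two hybrid rate constants are treated as a
# repeated root and k21 is nudged; measure-zero case, keeps the macro
# coefficients finite.
_REPEATED_ROOT_GUARD = 1e-9


class InvalidParameterError(ValueError):
    """A structural kinetic parameter violates its positivity constraint."""


@dataclass(frozen=True)
class PKParameters:
    """Structural two-compartment parameters of one (virtual) subject.

    Attributes
    ----------
    cl : float
        Elimination clearance from the central compartment, L/h.
    vc : float
        Central volume of distribution, L.
    vp : float
        Peripheral volume of distribution, L.
    q : float
        Inter-compartmental clearance, L/h.
    """

    cl: float
    vc: float
    vp: float
    q: float

    def __post_init__(self) -> None:
        for name in ("cl", "vc", "vp", "q"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0.0):
                raise InvalidParameterError(
                    f"{name} must be strictly positive and finite, got {value!r}"
                )


@dataclass(frozen=True)
class Microconstants:
    """First-order rate constants and hybrid disposition constants, 1/h."""

    k10: float
    k12: float
    k21: float
    alpha: float
    beta: float


@dataclass(frozen=True)
class DoseEvent:
    """A single zero-order input event.

    Boluses are represented as short infusions of their actual
    administration duration; there is no instantaneous-input code path.
    """

    amount: float
    start_time: float = 0.0
    infusion_duration: float = 0.5

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError(f"dose amount must be >= 0, got {self.amount}")
        if self.infusion_duration <= 0:
            raise ValueError(
                f"infusion duration must be > 0, got {self.infusion_duration}"
            )
        if self.start_time < 0:
            raise ValueError(f"dose start time must be >= 0, got {self.start_time}")


@dataclass(frozen=True)
class Regimen:
    """A repeated fixed-dose schedule: ``dose_amount`` mg every ``interval`` h."""

    dose_amount: float
    interval: float = 8.0
    infusion_duration: float = 0.5
    n_doses: int = 1

    def __post_init__(self) -> None:
        if self.interval <= self.infusion_duration:
            raise ValueError(
                "dosing interval must exceed the infusion duration "
                f"({self.interval} <= {self.infusion_duration})"
            )
        if self.n_doses < 1:
            raise ValueError(f"n_doses must be >= 1, got {self.n_doses}")

    def dose_events(self) -> list[DoseEvent]:
        return [
            DoseEvent(self.dose_amount, k * self.interval, self.infusion_duration)
            for k in range(self.n_doses)
        ]


def microconstants(params: PKParameters) -> Microconstants:
    """Convert (CL, Vc, Vp, Q) to micro/hybrid rate constants.

    Satisfies ``alpha * beta = k10 * k21`` and
    ``alpha + beta = k10 + k12 + k21`` with ``alpha > beta > 0``.
    """
    k10 = params.cl / params.vc
    k12 = params.q / params.vc
    k21 = params.q / params.vp
    s = k10 + k12 + k21
    disc = math.sqrt(max(s * s - 4.0 * k10 * k21, 0.0))
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    return Microconstants(k10=k10, k12=k12, k21=k21, alpha=alpha, beta=beta)


def _macro_terms(cl, vc, vp, q):
    """Vectorized hybrid constants and macro coefficients.

    Accepts scalars or broadcastable arrays; returns
    ``(alpha, beta, coef_a, coef_b)`` where the unit-impulse central
    concentration is ``(coef_a * e^{-alpha t} + coef_b * e^{-beta t}) / vc``
    and ``coef_a + coef_b = 1``.
    """
    cl = np.asarray(cl, dtype=float)
    vc = np.asarray(vc, dtype=float)
    vp = np.asarray(vp, dtype=float)
    q = np.asarray(q, dtype=float)
    k10 = cl / vc
    k12 = q / vc
    k21 = q / vp
    s = k10 + k12 + k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 0.0))
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    # repeated-root guard: nudge the pair apart before forming A, B
    near = (alpha - beta) <= _REPEATED_ROOT_GUARD * alpha
    if np.any(near):
        bump = _REPEATED_ROOT_GUARD * alpha
        alpha = np.where(near, alpha * (1.0 + _REPEATED_ROOT_GUARD), alpha)
        beta = np.where(near, beta - bump, beta)
    denom = alpha - beta
    coef_a = (alpha - k21) / denom
    coef_b = (k21 - beta) / denom
    return alpha, beta, coef_a, coef_b


def _expm1_ratio(rate_const, te):
    """``(1 - e^{-k te}) / k`` with the k -> 0 limit handled stably."""
    x = rate_const * te
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = -np.expm1(-x) / rate_const
    small = x < 1e-12
    if np.any(small):
        ratio = np.where(small, te * (1.0 - 0.5 * x), ratio)
    return ratio


def _infusion_conc(alpha, beta, coef_a, coef_b, vc, rate, duration, t):
    """Concentration at time-since-dose-start ``t`` for one infusion."""
    t = np.asarray(t, dtype=float)
    te = np.minimum(t, duration)
    decay = np.maximum(t - duration, 0.0)
    with np.errstate(over="ignore", invalid="ignore"):
        term_a = coef_a * _expm1_ratio(alpha, te) * np.exp(-alpha * decay)
        term_b = coef_b * _expm1_ratio(beta, te) * np.exp(-beta * decay)
    conc = rate / vc * (term_a + term_b)
    return np.where(t <= 0.0, 0.0, conc)


def concentration_profile(
    params: PKParameters,
    doses: Sequence[DoseEvent],
    times: Iterable[float] | np.ndarray,
) -> np.ndarray:
    """Central concentration at each time in ``times`` (superposition)."""
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    out = np.zeros_like(times)
    if not doses:
        return out
    alpha, beta, coef_a, coef_b = _macro_terms(params.cl, params.vc, params.vp, params.q)
    for dose in doses:
        if dose.amount == 0.0:
            continue
        rate = dose.amount / dose.infusion_duration
        out += _infusion_conc(
            alpha, beta, coef_a, coef_b, params.vc, rate,
            dose.infusion_duration, times - dose.start_time,
        )
    return out


def concentration_at(
    params: PKParameters, doses: Sequence[DoseEvent], t: float
) -> float:
    """Central-compartment concentration (mg/L) at a single time point."""
    return float(concentration_profile(params, doses, [t])[0])


def auc_infinity(params: PKParameters, dose: DoseEvent) -> float:
    """AUC from dose start to infinity; analytically ``amount / CL``."""
    return dose.amount / params.cl


def trough_at_interval(
    params: PKParameters, regimen: Regimen, dose_index: int
) -> float:
    """Concentration at the end of the ``dose_index``-th dosing interval.

    ``dose_index`` is 1-based; index ``k`` reads the concentration at
    ``k * interval`` hours after the first dose, with the first
    ``min(k, n_doses)`` doses administered.
    """
    if dose_index < 1:
        raise ValueError("dose_index must be >= 1")
    if dose_index > regimen.n_doses:
        raise ValueError(
            f"dose_index {dose_index} exceeds n_doses {regimen.n_doses}"
        )
    doses = [
        DoseEvent(regimen.dose_amount, k * regimen.interval, regimen.infusion_duration)
        for k in range(dose_index)
    ]
    return concentration_at(params, doses, dose_index * regimen.interval)


def steady_state_trough(
    params: PKParameters,
    regimen: Regimen,
    rel_tol: float = 1e-6,
    max_doses: int = 10_000,
) -> float:
    """Steady-state trough by explicit superposition until convergence.

    Doses are accumulated until the trough changes by less than ``rel_tol``
    relative between successive doses (the accumulation sequence is
    monotone increasing, so this bounds the remaining tail tightly for
    geometric decay).
    """
    alpha, beta, coef_a, coef_b = _macro_terms(params.cl, params.vc, params.vp, params.q)
    rate = regimen.dose_amount / regimen.infusion_duration
    tau, dur = regimen.interval, regimen.infusion_duration
    total = 0.0
    for k in range(1, max_doses + 1):
        add = float(
            _infusion_conc(alpha, beta, coef_a, coef_b, params.vc, rate, dur, k * tau)
        )
        total += add
        if add <= rel_tol * total:
            break
    return total


def time_above_threshold(
    params: PKParameters,
    regimen: Regimen,
    threshold: float,
    n_grid: int = 512,
) -> float:
    """Fraction of the steady-state dosing interval with C(t) > threshold.

    The steady-state interval profile is built by superposing doses until
    the trough converges, then threshold crossings located on a grid and
    refined by bisection.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if threshold == 0.0:
        return 1.0
    # enough doses for the trough to converge
    tmp = PKParameters(params.cl, params.vc, params.vp, params.q)
    prev, n_doses = -1.0, 1
    while n_doses < 4096:
        cur = trough_at_interval(
            tmp,
            Regimen(regimen.dose_amount, regimen.interval,
                    regimen.infusion_duration, n_doses),
            n_doses,
        )
        if prev > 0 and (cur - prev) <= 1e-8 * cur:
            break
        prev, n_doses = cur, n_doses * 2
    doses = [
        DoseEvent(regimen.dose_amount, k * regimen.interval, regimen.infusion_duration)
        for k in range(n_doses)
    ]
    t0 = (n_doses - 1) * regimen.interval
    grid = np.linspace(t0, t0 + regimen.interval, n_grid + 1)
    conc = concentration_profile(params, doses, grid)
    above = conc > threshold

    def _f(t):
        return concentration_at(params, doses, t) - threshold

    from scipy.optimize import brentq

    total = 0.0
    for i in range(n_grid):
        if above[i] and above[i + 1]:
            total += grid[i + 1] - grid[i]
        elif above[i] != above[i + 1]:
            t_cross = brentq(_f, grid[i], grid[i + 1], xtol=1e-10)
            if above[i]:
                total += t_cross - grid[i]
            else:
                total += grid[i + 1] - t_cross
    return min(total / regimen.interval, 1.0)
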