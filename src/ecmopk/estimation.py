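"""Approximate marginal-likelihood estimation of the hierarchical model,
nested-model comparison and stepwise covariate search.

The estimator is FOCE-like: for each subject the conditional mode of the
random effects is found (inner optimization), and the subject's marginal
likelihood contribution is a Laplace approximation around that mode with
the residual variance evaluated at the conditional estimate (interaction).
The objective function value (OFV) is the full -2 log marginal likelihood,
2*pi constants included, so it is directly comparable with independent
quadrature.

For one subject with eta dimension d, n quantified observations and

    m(eta) = sum_j [ ln V_j(eta) + (y_j - f_j(eta))^2 / V_j(eta) ]
             + eta' Omega^-1 eta,
    V_j = sigma_prop^2 * f_j^2 + sigma_add^2,

the contribution is

    OFV_i = n ln(2 pi) + ln|Omega| + m(eta_hat) + ln| Hess(m)(eta_hat) / 2 |.

Below-LOQ observations are excluded from the likelihood (predose zeros are
structural zeros, never likelihood rows).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2

from .covariates import PatientCovariates
from .dataset import StudyDataset, Subject
from .pk import _infusion_conc, _macro_terms
from .population import FixedEffects, RandomEffectsSpec, ResidualSpec, EtaVector

__all__ = [
    "CovariateEffect",
    "ModelSpec",
    "FitResult",
    "fit",
    "ofv",
    "compare_nested",
    "stepwise_covariate_search",
    "SearchResult",
    "goodness_of_fit",
    "initial_estimates",
    "final_model_spec",
    "final_spec_for",
    "OFV_SIGNIFICANCE_DROP",
    "UnderDeterminedError",
]

log = logging.getLogger(__name__)

#: ΔOFV treated as significant at p < 0.05 for one degree of freedom.
OFV_SIGNIFICANCE_DROP = 3.84

_ETA_NAMES = ("cl", "vc", "vp")
_FD_STEP = 1e-4
_MIN_VAR = 1e-12


class UnderDeterminedError(ValueError):
    """Fewer quantified observations than estimated parameters."""


class NotConvergedError(RuntimeError):
    pass


@dataclass(frozen=True)
class CovariateEffect:
    """One multiplicative covariate term on clearance.

    kind:
      * ``"binary"``     multiplier ``theta ** flag`` (flag 0/1)
      * ``"power"``      multiplier ``(value / reference) ** theta``;
                         subjects with the covariate missing get 1
      * ``"rrt_branch"`` the published final structure: multiplier 1 for
                         RRT subjects and ``theta * (crcl / reference)``
                         for non-RRT subjects
    """

    name: str
    covariate: str
    kind: str
    reference: float = 100.0

    def design_value(self, cov: PatientCovariates) -> Optional[float]:
        if self.kind == "rrt_branch":
            return None if cov.rrt else (cov.crcl or 0.0)
        value = getattr(cov, self.covariate)
        if self.covariate == "sex":
            return 1.0 if value == "female" else 0.0
        if isinstance(value, bool):
            return float(value)
        return None if value is None else float(value)

    def multiplier(self, theta: float, cov: PatientCovariates) -> float:
        x = self.design_value(cov)
        if self.kind == "binary":
            return theta ** (x or 0.0)
        if self.kind == "power":
            if x is None:
                return 1.0
            return (x / self.reference) ** theta
        if self.kind == "rrt_branch":
            if x is None:  # RRT subject
                return 1.0
            return theta * (x / self.reference)
        raise ValueError(f"unknown effect kind {self.kind!r}")


@dataclass(frozen=True)
class ModelSpec:
    """Model structure plus initial values and fixed/estimated flags."""

    effects: tuple[CovariateEffect, ...] = ()
    theta_init: tuple[float, float, float, float] = (8.0, 20.0, 15.0, 20.0)
    effect_theta_init: tuple[float, ...] = ()
    omega2_init: tuple[float, float, float] = (0.1, 0.1, 0.1)
    omega2_estimated: tuple[bool, bool, bool] = (True, True, True)
    sigma_init: tuple[float, float] = (0.2, 1.0)
    sigma_estimated: tuple[bool, bool] = (True, True)

    def __post_init__(self) -> None:
        if len(self.effect_theta_init) != len(self.effects):
            object.__setattr__(
                self,
                "effect_theta_init",
                tuple(
                    1.0 if e.kind != "power" else 0.1 for e in self.effects
                ),
            )

    def with_effect(self, effect: CovariateEffect, theta0: float | None = None
                    ) -> "ModelSpec":
        init = theta0 if theta0 is not None else (0.1 if effect.kind == "power" else 1.0)
        return replace(
            self,
            effects=self.effects + (effect,),
            effect_theta_init=self.effect_theta_init + (init,),
        )

    def without_effect(self, name: str) -> "ModelSpec":
        keep = [(e, t) for e, t in zip(self.effects, self.effect_theta_init)
                if e.name != name]
        return replace(
            self,
            effects=tuple(e for e, _ in keep),
            effect_theta_init=tuple(t for _, t in keep),
        )

    @property
    def n_estimated(self) -> int:
        return (
            4
            + len(self.effects)
            + sum(self.omega2_estimated)
            + sum(self.sigma_estimated)
        )


def final_model_spec(**kwargs) -> ModelSpec:
    """Spec with the published final covariate structure on clearance."""
    effect = CovariateEffect("crcl", "crcl", "rrt_branch", reference=100.0)
    kwargs.setdefault("effect_theta_init", (1.5,))
    return ModelSpec(effects=(effect,), **kwargs)


# ---------------------------------------------------------------------------
# batched working arrays: all subjects padded into rectangular tensors so
# one numpy call evaluates every subject (and every finite-difference
# stencil point) at once


class _BatchData:
    """Padded per-study arrays: observations (S, n), doses (S, D)."""

    __slots__ = (
        "subjects", "S", "times", "y", "mask", "n_obs",
        "amounts", "starts", "durs",
    )

    def __init__(self, subjects: Sequence[Subject]):
        self.subjects = list(subjects)
        self.S = len(self.subjects)
        n_max = max(len(s.quantified_observations) for s in self.subjects)
        d_max = max(len(s.doses) for s in self.subjects)
        self.times = np.zeros((self.S, n_max))
        self.y = np.zeros((self.S, n_max))
        self.mask = np.zeros((self.S, n_max), dtype=bool)
        self.n_obs = np.zeros(self.S, dtype=int)
        self.amounts = np.zeros((self.S, d_max))
        self.starts = np.zeros((self.S, d_max))
        self.durs = np.ones((self.S, d_max))  # pad 1.0, amount 0 -> no input
        for i, s in enumerate(self.subjects):
            obs = s.quantified_observations
            self.n_obs[i] = len(obs)
            for j, o in enumerate(obs):
                self.times[i, j] = o.time
                self.y[i, j] = o.dv
                self.mask[i, j] = True
            for j, d in enumerate(s.doses):
                self.amounts[i, j] = d.amount
                self.starts[i, j] = d.start_time
                self.durs[i, j] = d.infusion_duration

    def rows(self, idx: np.ndarray) -> "_BatchRows":
        return _BatchRows(self, idx)

    def tvcl_vector(self, spec: "ModelSpec", theta_cl: float,
                    effect_thetas: Sequence[float]) -> np.ndarray:
        return np.array([
            _tvcl(spec, theta_cl, effect_thetas, s.covariates)
            for s in self.subjects
        ])


class _BatchRows:
    """Row-subset view of a batch (for retiring converged subjects)."""

    __slots__ = ("S", "times", "y", "mask", "amounts", "starts", "durs")

    def __init__(self, batch: _BatchData, idx: np.ndarray):
        self.S = len(idx)
        self.times = batch.times[idx]
        self.y = batch.y[idx]
        self.mask = batch.mask[idx]
        self.amounts = batch.amounts[idx]
        self.starts = batch.starts[idx]
        self.durs = batch.durs[idx]


def _conc_all(batch, cl, vc, vp, q) -> np.ndarray:
    """Concentrations for parameter tensors (S, K) at batch times -> (S, K, n)."""
    cl = np.asarray(cl, dtype=float)[..., None]
    vc = np.asarray(vc, dtype=float)[..., None]
    vp = np.asarray(vp, dtype=float)[..., None]
    q = np.asarray(q, dtype=float)[..., None]
    alpha, beta, ca, cb = _macro_terms(cl, vc, vp, q)
    K = cl.shape[1]
    out = np.zeros((batch.S, K, batch.times.shape[1]))
    for j in range(batch.amounts.shape[1]):
        rate = (batch.amounts[:, j] / batch.durs[:, j])[:, None, None]
        dur = batch.durs[:, j][:, None, None]
        t = (batch.times - batch.starts[:, j][:, None])[:, None, :]
        out += rate * _infusion_conc_unit(alpha, beta, ca, cb, vc, dur, t)
    return out


def _infusion_conc_unit(alpha, beta, ca, cb, vc, duration, t):
    """Per-unit-rate infusion concentration (rate applied by the caller)."""
    from .pk import _expm1_ratio

    te = np.minimum(t, duration)
    decay = np.maximum(t - duration, 0.0)
    with np.errstate(over="ignore", invalid="ignore"):
        term_a = ca * _expm1_ratio(alpha, te) * np.exp(-alpha * decay)
        term_b = cb * _expm1_ratio(beta, te) * np.exp(-beta * decay)
        conc = (term_a + term_b) / vc
    return np.where(t <= 0.0, 0.0, conc)


# ---------------------------------------------------------------------------
# parameter packing


class _Packer:
    """Maps the estimated parameters to/from an unconstrained-ish vector.

    Positive parameters are log-transformed; power-effect exponents stay on
    the natural scale.
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        names: list[str] = ["theta_cl", "theta_vc", "theta_vp", "theta_q"]
        logs: list[bool] = [True] * 4
        inits: list[float] = list(spec.theta_init)
        for eff, t0 in zip(spec.effects, spec.effect_theta_init):
            names.append(f"effect:{eff.name}")
            logs.append(eff.kind != "power")
            inits.append(t0)
        for i, name in enumerate(_ETA_NAMES):
            if spec.omega2_estimated[i]:
                names.append(f"omega2_{name}")
                logs.append(True)
                inits.append(max(spec.omega2_init[i], 1e-4))
        for j, name in enumerate(("sigma_prop", "sigma_add")):
            if spec.sigma_estimated[j]:
                names.append(name)
                logs.append(True)
                inits.append(max(spec.sigma_init[j], 1e-4))
        self.names = names
        self.logs = logs
        self.x0 = np.array(
            [math.log(v) if lg else v for v, lg in zip(inits, logs)], dtype=float
        )
        self.bounds = [
            (math.log(1e-8), math.log(1e6)) if lg else (-8.0, 8.0) for lg in logs
        ]

    def unpack(self, x: np.ndarray) -> dict:
        vals = {
            name: (math.exp(v) if lg else float(v))
            for name, v, lg in zip(self.names, x, self.logs)
        }
        spec = self.spec
        omega2 = list(spec.omega2_init)
        for i, name in enumerate(_ETA_NAMES):
            if spec.omega2_estimated[i]:
                omega2[i] = vals[f"omega2_{name}"]
        sigma = list(spec.sigma_init)
        if spec.sigma_estimated[0]:
            sigma[0] = vals["sigma_prop"]
        if spec.sigma_estimated[1]:
            sigma[1] = vals["sigma_add"]
        effect_thetas = tuple(vals[f"effect:{e.name}"] for e in spec.effects)
        return {
            "theta": (
                vals["theta_cl"], vals["theta_vc"], vals["theta_vp"], vals["theta_q"]
            ),
            "effect_thetas": effect_thetas,
            "omega2": tuple(omega2),
            "sigma": tuple(sigma),
        }


def _tvcl(spec: ModelSpec, theta_cl: float, effect_thetas: Sequence[float],
          cov: PatientCovariates) -> float:
    tvcl = theta_cl
    for eff, th in zip(spec.effects, effect_thetas):
        tvcl *= eff.multiplier(th, cov)
    return tvcl


# ---------------------------------------------------------------------------
# batched conditional objective and Laplace contribution


def _stencil(d: int, h: float) -> np.ndarray:
    """Central-difference stencil points (K, d): center, axis pairs, cross."""
    pts = [np.zeros(d)]
    for i in range(d):
        for s in (h, -h):
            e = np.zeros(d)
            e[i] = s
            pts.append(e)
    for i in range(d):
        for j in range(i + 1, d):
            for si in (h, -h):
                for sj in (h, -h):
                    e = np.zeros(d)
                    e[i], e[j] = si, sj
                    pts.append(e)
    return np.array(pts)


def _m_all(
    batch: _BatchData,
    tvcl: np.ndarray,
    theta: Sequence[float],
    omega2: np.ndarray,
    sigma: Sequence[float],
    active: np.ndarray,
    etas_active: np.ndarray,
) -> np.ndarray:
    """Conditional objective m(eta) for every subject x eta row.

    ``etas_active`` has shape (S, K, d) over the active eta dimensions;
    returns (S, K).
    """
    S, K, _ = etas_active.shape
    etas = np.zeros((S, K, 3))
    # |eta| beyond ~30 is astronomically improbable; clipping keeps the
    # kinetics finite while the eta'/omega2 penalty still rejects the point
    etas[:, :, active] = np.clip(etas_active, -30.0, 30.0)
    with np.errstate(all="ignore"):
        cl = tvcl[:, None] * np.exp(etas[:, :, 0])
        vc = theta[1] * np.exp(etas[:, :, 1])
        vp = theta[2] * np.exp(etas[:, :, 2])
        q = np.full((S, K), theta[3])
        f = _conc_all(batch, cl, vc, vp, q)
        v = np.maximum(sigma[0] ** 2 * f * f + sigma[1] ** 2, _MIN_VAR)
        resid = batch.y[:, None, :] - f
        terms = np.where(batch.mask[:, None, :],
                         np.log(v) + resid * resid / v, 0.0)
        m = terms.sum(axis=2)
        om = omega2[active]
        m = m + np.sum(etas_active * etas_active / om, axis=2)
    return np.where(np.isfinite(m), m, 1e12)


def _grad_hess_from_stencil(vals: np.ndarray, d: int, h: float
                            ) -> tuple[np.ndarray, np.ndarray]:
    """(S, K) stencil values -> gradient (S, d) and Hessian (S, d, d)."""
    S = vals.shape[0]
    m0 = vals[:, 0]
    grad = np.empty((S, d))
    hess = np.empty((S, d, d))
    idx = 1
    for i in range(d):
        mp, mm = vals[:, idx], vals[:, idx + 1]
        grad[:, i] = (mp - mm) / (2 * h)
        hess[:, i, i] = (mp - 2 * m0 + mm) / (h * h)
        idx += 2
    for i in range(d):
        for j in range(i + 1, d):
            mpp, mpm, mmp, mmm = (vals[:, idx], vals[:, idx + 1],
                                  vals[:, idx + 2], vals[:, idx + 3])
            hess[:, i, j] = hess[:, j, i] = (mpp - mpm - mmp + mmm) / (4 * h * h)
            idx += 4
    return grad, hess


def _laplace_all(
    batch: _BatchData,
    spec: ModelSpec,
    params: dict,
    eta_state: np.ndarray,
    max_newton: int = 60,
    n_quadrature: int = 1,
) -> float:
    """Total OFV over all subjects; eta modes updated in ``eta_state`` (S, 3).

    Per subject: damped-Newton search for the conditional eta mode (warm
    started from ``eta_state``), then the Laplace log-determinant from the
    finite-difference Hessian at the mode.  ``n_quadrature > 1`` replaces
    the Laplace integral with adaptive Gauss-Hermite quadrature centered
    and scaled at the mode (single-eta models only).
    """
    theta = params["theta"]
    omega2 = np.asarray(params["omega2"], dtype=float)
    sigma = params["sigma"]
    tvcl = batch.tvcl_vector(spec, theta[0], params["effect_thetas"])
    S = batch.S

    active = np.array(
        [spec.omega2_estimated[i] or spec.omega2_init[i] > 0 for i in range(3)]
    )
    active &= omega2 > 0
    d = int(active.sum())
    const = float(np.sum(batch.n_obs)) * math.log(2 * math.pi)

    if d == 0:
        m0 = _m_all(batch, tvcl, theta, omega2, sigma, active,
                    np.zeros((S, 1, 0)))[:, 0]
        eta_state[:] = 0.0
        return const + float(m0.sum())

    h = 1e-3
    sten = _stencil(d, h)  # (K, d)
    eta = eta_state[:, active].copy()  # (S, d)
    lam = np.zeros(S)
    eye = np.eye(d)
    m0 = np.empty(S)
    hess_final = np.empty((S, d, d))

    # live indices shrink as subjects' modes converge, so the stencil cost
    # tracks the stragglers instead of the whole study
    live = np.arange(S)
    rows = batch.rows(live)
    tv_live = tvcl[live]

    def stencil_vals(center: np.ndarray) -> np.ndarray:
        return _m_all(rows, tv_live, theta, omega2, sigma, active,
                      center[:, None, :] + sten[None, :, :])

    vals = stencil_vals(eta[live])
    m0[live] = vals[:, 0]
    for _ in range(max_newton):
        grad, hess = _grad_hess_from_stencil(vals, d, h)
        hess_final[live] = hess
        gnorm = np.max(np.abs(grad), axis=1)
        pending = gnorm >= 1e-7 * np.maximum(1.0, np.abs(m0[live]))
        if not pending.all():
            # retire converged subjects from the live set
            keep = np.flatnonzero(pending)
            live = live[keep]
            if live.size == 0:
                break
            rows = batch.rows(live)
            tv_live = tvcl[live]
            grad, hess = grad[keep], hess[keep]
        eta_l = eta[live]
        m0_l = m0[live]
        lam_l = lam[live]
        moved = np.zeros(live.size, dtype=bool)
        for _try in range(12):
            with np.errstate(all="ignore"):
                damped = hess + (lam_l[:, None, None] + 1e-12) * eye
                damped = np.where(np.isfinite(damped), damped, 1e8)
            try:
                step = np.linalg.solve(damped, -grad[:, :, None])[:, :, 0]
            except np.linalg.LinAlgError:
                lam_l = np.where(~moved, np.maximum(10 * lam_l, 1e-4), lam_l)
                continue
            step = np.clip(step, -3.0, 3.0)  # trust-region-style cap
            trial = np.where(~moved[:, None], eta_l + step, eta_l)
            m_trial = _m_all(rows, tv_live, theta, omega2, sigma, active,
                             trial[:, None, :])[:, 0]
            ok = ~moved & np.isfinite(m_trial) & (m_trial <= m0_l + 1e-12)
            eta_l = np.where(ok[:, None], trial, eta_l)
            m0_l = np.where(ok, m_trial, m0_l)
            lam_l = np.where(ok, lam_l / 3, lam_l)
            moved |= ok
            if moved.all():
                break
            lam_l = np.where(~moved,
                             np.minimum(np.maximum(10 * lam_l, 1e-4), 1e10),
                             lam_l)
        eta[live] = eta_l
        m0[live] = m0_l
        lam[live] = lam_l
        if not moved.any():
            break
        vals = stencil_vals(eta[live])
        m0[live] = vals[:, 0]

    # final curvature for subjects that ran out of iterations; after a
    # failed-move break `vals` is stale (pre-retirement) and hess_final
    # already holds the current curvature
    if live.size and vals.shape[0] == live.size:
        _, hess = _grad_hess_from_stencil(vals, d, h)
        hess_final[live] = hess

    eigvals = np.linalg.eigvalsh(hess_final / 2.0)
    eigvals = np.maximum(eigvals, 1e-10)
    logdet_half = np.sum(np.log(eigvals), axis=1)
    logdet_omega = float(np.sum(np.log(omega2[active])))

    eta_state[:] = 0.0
    eta_state[:, active] = eta

    if n_quadrature > 1:
        if d != 1:
            raise ValueError(
                "Gauss-Hermite refinement is implemented for single-eta "
                f"models only (model has {d} active etas)"
            )
        from numpy.polynomial.hermite_e import hermegauss
        from scipy.special import logsumexp

        nodes, weights = hermegauss(n_quadrature)
        # scale from the mode curvature: e^{-m/2} ~ N(mode, 2 / m'')
        scale = np.sqrt(2.0 / np.maximum(hess_final[:, 0, 0], 1e-10))  # (S,)
        pts = eta[:, 0][:, None] + scale[:, None] * nodes[None, :]
        m_pts = _m_all(batch, tvcl, theta, omega2, sigma, active,
                       pts[:, :, None])
        # int e^{-m/2} = scale * sum_k w_k exp(-m(pt_k)/2 + x_k^2/2)
        log_int = logsumexp(
            -0.5 * m_pts + 0.5 * nodes[None, :] ** 2 + np.log(weights)[None, :],
            axis=1,
        ) + np.log(scale)
        # the d*ln(2pi) of the eta prior does not cancel outside Laplace
        return const + float(
            np.sum(d * math.log(2 * math.pi) + logdet_omega - 2.0 * log_int)
        )

    return const + float(np.sum(logdet_omega + m0 + logdet_half))


# ---------------------------------------------------------------------------
# fit result


@dataclass
class FitResult:
    spec: ModelSpec
    fixed: FixedEffects
    effect_thetas: dict
    random_effects: RandomEffectsSpec
    residual: ResidualSpec
    ofv: float
    etas: dict
    converged: bool
    message: str
    n_obs: int
    predictions: pd.DataFrame
    trajectory: list = field(default_factory=list)
    n_function_evals: int = 0

    def eta_vector(self, subject_id: str) -> EtaVector:
        e = self.etas[subject_id]
        return EtaVector(eta_cl=e[0], eta_vc=e[1], eta_vp=e[2])

    def parameter_table(self) -> pd.DataFrame:
        """Point-estimate table mirroring the published layout."""
        cvs = self.random_effects.as_cv_percent()
        rows = [
            ("CL (L/h)", self.fixed.theta_cl),
            ("Vc (L)", self.fixed.theta_vc),
            ("Vp (L)", self.fixed.theta_vp),
            ("Q (L/h)", self.fixed.theta_q),
        ]
        for name, value in self.effect_thetas.items():
            rows.append((f"CL_{name.upper()}", value))
        rows += [
            ("BSV CL (%CV)", cvs[0]),
            ("BSV Vc (%CV)", cvs[1]),
            ("BSV Vp (%CV)", cvs[2]),
            ("RUV (%CV)", 100.0 * self.residual.sigma_prop),
            ("RUV (SD, mg/L)", self.residual.sigma_add),
        ]
        return pd.DataFrame(rows, columns=["parameter", "estimate"])


def ofv(dataset: StudyDataset, spec: ModelSpec, n_quadrature: int = 1) -> float:
    """OFV of the model at the spec's initial values (no optimization).

    ``n_quadrature > 1`` uses adaptive Gauss-Hermite quadrature instead of
    the Laplace determinant (single-eta models only); the default is the
    same approximation the fit uses.
    """
    batch = _BatchData(dataset.subjects)
    packer = _Packer(spec)
    params = packer.unpack(packer.x0)
    return _laplace_all(batch, spec, params, np.zeros((batch.S, 3)),
                        n_quadrature=n_quadrature)


def fit(
    dataset: StudyDataset,
    spec: ModelSpec,
    max_iter: int = 300,
    tol: float = 1e-7,
    polish: bool = True,
    max_cycles: int = 3,
) -> FitResult:
    """Estimate the model by Laplace-with-interaction marginal likelihood.

    Raises :class:`UnderDeterminedError` when there are fewer quantified
    observations than estimated parameters.  Non-convergence is flagged on
    the result, never silent.
    """
    dataset.validate()
    batch = _BatchData(dataset.subjects)
    n_obs = int(batch.n_obs.sum())
    if n_obs < spec.n_estimated:
        raise UnderDeterminedError(
            f"{n_obs} quantified observations < {spec.n_estimated} parameters"
        )
    packer = _Packer(spec)
    eta_state = np.zeros((batch.S, 3))
    trajectory: list[float] = []
    best = {"ofv": math.inf}
    n_evals = 0

    def objective(x: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        params = packer.unpack(x)
        try:
            value = _laplace_all(batch, spec, params, eta_state)
        except (np.linalg.LinAlgError, FloatingPointError, OverflowError):
            return 1e12
        if not np.isfinite(value):
            return 1e12
        if value < best["ofv"]:
            best["ofv"] = value
            trajectory.append(value)
        return value

    x_best = packer.x0.copy()
    f_best = math.inf
    converged, message = False, ""
    # restart cycles: a quasi-Newton pass, an optional simplex polish, and
    # another quasi-Newton pass from the polished point; stops when a full
    # cycle no longer improves the OFV materially
    for cycle in range(max_cycles):
        f_at_cycle_start = f_best
        res = optimize.minimize(
            objective,
            x_best,
            method="L-BFGS-B",
            bounds=packer.bounds,
            options={
                "maxiter": max_iter,
                "ftol": tol,
                "gtol": 1e-6,
                "eps": 1e-5,
            },
        )
        if res.fun < f_best:
            x_best, f_best = res.x, res.fun
            converged, message = bool(res.success), str(res.message)
        if polish:
            res2 = optimize.minimize(
                objective,
                x_best,
                method="Nelder-Mead",
                options={"maxfev": 120 * len(x_best), "xatol": 1e-5,
                         "fatol": 1e-6, "adaptive": True},
            )
            if res2.fun < f_best:
                x_best, f_best = res2.x, res2.fun
            if res2.success and res2.fun <= f_best + 1e-6:
                # a converged simplex confirming the point is as good as a
                # clean quasi-Newton exit (which fails on razor-sharp optima)
                converged = True
                message = str(res2.message)
        if f_at_cycle_start - f_best < 0.5:
            break
    if not converged:
        log.warning("fit did not converge: %s", message)

    params = packer.unpack(x_best)
    # refresh eta modes and assemble predictions at the optimum, from a
    # cold start so the reported OFV is a pure function of the estimates
    eta_state[:] = 0.0
    final_ofv = _laplace_all(batch, spec, params, eta_state)
    if abs(final_ofv - f_best) > 1.0:
        log.warning(
            "OFV at the optimum (%.4f) differs from the best objective "
            "value (%.4f); inner modes may be multimodal", final_ofv, f_best,
        )
    theta = params["theta"]
    theta_crcl = 1.0
    effect_thetas = {}
    for eff, th in zip(spec.effects, params["effect_thetas"]):
        effect_thetas[eff.name] = th
        if eff.kind == "rrt_branch":
            theta_crcl = th
    fixed = FixedEffects(theta[0], theta[1], theta[2], theta[3], theta_crcl)
    random_effects = RandomEffectsSpec(*params["omega2"])
    residual = ResidualSpec(*params["sigma"])

    tvcl = batch.tvcl_vector(spec, theta[0], params["effect_thetas"])
    ones = np.ones((batch.S, 1))
    f_pop = _conc_all(batch, tvcl[:, None], theta[1] * ones, theta[2] * ones,
                      theta[3] * ones)[:, 0, :]
    f_ind = _conc_all(
        batch,
        (tvcl * np.exp(eta_state[:, 0]))[:, None],
        (theta[1] * np.exp(eta_state[:, 1]))[:, None],
        (theta[2] * np.exp(eta_state[:, 2]))[:, None],
        theta[3] * ones,
    )[:, 0, :]
    pred_rows = []
    for i, subject in enumerate(batch.subjects):
        for j in range(batch.n_obs[i]):
            pred_rows.append(
                {"subject": subject.id, "time": batch.times[i, j],
                 "observed": batch.y[i, j],
                 "pred_population": f_pop[i, j],
                 "pred_individual": f_ind[i, j]}
            )
    predictions = pd.DataFrame(
        pred_rows,
        columns=["subject", "time", "observed", "pred_population",
                 "pred_individual"],
    )
    eta_cache = {
        subject.id: eta_state[i].copy()
        for i, subject in enumerate(batch.subjects)
    }
    return FitResult(
        spec=spec,
        fixed=fixed,
        effect_thetas=effect_thetas,
        random_effects=random_effects,
        residual=residual,
        ofv=float(final_ofv),
        etas=dict(eta_cache),
        converged=converged,
        message=str(message),
        n_obs=n_obs,
        predictions=predictions,
        trajectory=trajectory,
        n_function_evals=n_evals,
    )


# ---------------------------------------------------------------------------
# model comparison and covariate search


def compare_nested(ofv_full: float, ofv_reduced: float, df: int = 1) -> bool:
    """True when the fuller model is a significant improvement (p < 0.05).

    The drop ``ofv_reduced - ofv_full`` is compared against 3.84 for one
    degree of freedom (boundary inclusive) and the chi-square 95% quantile
    for ``df > 1``.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    drop = ofv_reduced - ofv_full
    if drop < 0:
        log.warning("OFV increased by %.3f for the fuller model", -drop)
        return False
    threshold = OFV_SIGNIFICANCE_DROP if df == 1 else float(chi2.ppf(0.95, df))
    return drop >= threshold


def _bsv_cl_cv(result: FitResult) -> float:
    return result.random_effects.as_cv_percent()[0]


def _seed_from_fit(spec: ModelSpec, result: FitResult) -> ModelSpec:
    """Spec with initial values replaced by a fit's estimates."""
    return replace(
        spec,
        theta_init=(
            result.fixed.theta_cl, result.fixed.theta_vc,
            result.fixed.theta_vp, result.fixed.theta_q,
        ),
        effect_theta_init=tuple(
            result.effect_thetas[e.name] for e in spec.effects
        ),
        omega2_init=(
            max(result.random_effects.omega2_cl, 1e-4),
            max(result.random_effects.omega2_vc, 1e-4),
            max(result.random_effects.omega2_vp, 1e-4),
        ),
        sigma_init=(
            max(result.residual.sigma_prop, 1e-3),
            max(result.residual.sigma_add, 1e-3),
        ),
    )


@dataclass
class SearchResult:
    final_spec: ModelSpec
    final_fit: FitResult
    trace: list

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.trace)


def stepwise_covariate_search(
    dataset: StudyDataset,
    base_spec: ModelSpec,
    candidates: Sequence[CovariateEffect],
    forward_threshold: float = OFV_SIGNIFICANCE_DROP,
    backward_threshold: float = OFV_SIGNIFICANCE_DROP,
    bsv_drop_fraction: float = 0.10,
    max_iter: int = 150,
    polish: bool = False,
    max_cycles: int = 2,
) -> SearchResult:
    """Forward-inclusion / backward-deletion covariate search on clearance.

    A candidate qualifies on a significant OFV drop (>= forward_threshold,
    inclusive) or a relative drop in clearance BSV %CV of at least
    ``bsv_drop_fraction``.  Among qualifiers the largest OFV drop wins;
    exact ties resolve by candidate list order.  Backward deletion removes
    covariates whose deletion worsens the OFV by less than
    ``backward_threshold``.
    """
    trace: list[dict] = []
    current_spec = base_spec
    current_fit = fit(dataset, current_spec, max_iter=max_iter, polish=polish,
                      max_cycles=max_cycles)
    remaining = list(candidates)

    # forward inclusion
    while remaining:
        rows = []
        for cand in remaining:
            # warm start from the current model so the nested optimum is a
            # feasible starting point and the fuller fit can only improve
            cand_spec = _seed_from_fit(current_spec, current_fit).with_effect(cand)
            try:
                cand_fit = fit(dataset, cand_spec, max_iter=max_iter, polish=polish,
                               max_cycles=max_cycles)
            except (UnderDeterminedError, ValueError) as exc:
                trace.append({"phase": "forward", "candidate": cand.name,
                              "status": f"failed: {exc}"})
                continue
            drop = current_fit.ofv - cand_fit.ofv
            bsv_before = _bsv_cl_cv(current_fit)
            bsv_after = _bsv_cl_cv(cand_fit)
            bsv_rel_drop = (
                (bsv_before - bsv_after) / bsv_before if bsv_before > 0 else 0.0
            )
            # a BSV drop only counts when the OFV did not get worse
            qualifies = drop >= forward_threshold or (
                bsv_rel_drop >= bsv_drop_fraction and drop >= 0.0
            )
            rows.append((cand, cand_spec, cand_fit, drop, bsv_rel_drop, qualifies))
            trace.append({
                "phase": "forward", "candidate": cand.name,
                "ofv_drop": drop, "bsv_cl_rel_drop": bsv_rel_drop,
                "qualifies": qualifies, "status": "evaluated",
            })
        qualifying = [r for r in rows if r[5]]
        if not qualifying:
            break
        # largest OFV drop wins; stable max keeps candidate-list order on ties
        best_row = max(qualifying, key=lambda r: r[3])
        cand, current_spec, current_fit = best_row[0], best_row[1], best_row[2]
        remaining = [c for c in remaining if c.name != cand.name]
        trace.append({"phase": "forward", "candidate": cand.name,
                      "status": "included", "ofv": current_fit.ofv})

    # backward deletion
    changed = True
    while changed and current_spec.effects:
        changed = False
        worst: tuple | None = None
        for eff in current_spec.effects:
            red_spec = _seed_from_fit(current_spec, current_fit).without_effect(
                eff.name)
            red_fit = fit(dataset, red_spec, max_iter=max_iter, polish=polish,
                          max_cycles=max_cycles)
            worsening = red_fit.ofv - current_fit.ofv
            trace.append({"phase": "backward", "candidate": eff.name,
                          "ofv_worsening": worsening,
                          "status": "evaluated"})
            if worsening < backward_threshold:
                if worst is None or worsening < worst[0]:
                    worst = (worsening, eff, red_spec, red_fit)
        if worst is not None:
            _, eff, current_spec, current_fit = worst
            trace.append({"phase": "backward", "candidate": eff.name,
                          "status": "removed", "ofv": current_fit.ofv})
            changed = True

    return SearchResult(final_spec=current_spec, final_fit=current_fit, trace=trace)


def goodness_of_fit(result: FitResult) -> dict:
    """Diagnostic table plus r^2 of both prediction types vs observations."""
    frame = result.predictions.copy()
    frame["residual_population"] = frame["observed"] - frame["pred_population"]
    frame["residual_individual"] = frame["observed"] - frame["pred_individual"]

    def _r2(pred: pd.Series) -> float:
        obs = frame["observed"]
        if len(frame) < 2 or obs.std() == 0:
            return float("nan")
        r = np.corrcoef(obs, pred)[0, 1]
        return float(r * r)

    return {
        "table": frame,
        "r2_population": _r2(frame["pred_population"]),
        "r2_individual": _r2(frame["pred_individual"]),
        "sse_population": float((frame["residual_population"] ** 2).sum()),
        "sse_individual": float((frame["residual_individual"] ** 2).sum()),
    }


# ---------------------------------------------------------------------------
# initial estimates


def _per_subject_naive(dataset: StudyDataset) -> list[dict]:
    """Curve-stripping estimates per subject: CL from dose/AUC (trapezoid
    plus log-linear tail), Vc from dose/Cmax."""
    records = []
    for s in dataset.subjects:
        obs = s.quantified_observations
        if len(obs) < 3:
            continue
        times = np.array([o.time for o in obs])
        y = np.array([o.dv for o in obs])
        order = np.argsort(times)
        times, y = times[order], y[order]
        dose = s.doses[0].amount
        auc = float(np.trapezoid(y, times))
        tail = 0.0
        if len(y) >= 3 and np.all(y[-3:] > 0):
            slope = np.polyfit(times[-3:], np.log(y[-3:]), 1)[0]
            if slope < -1e-6:
                tail = y[-1] / (-slope)
        total_auc = auc + tail
        rec = {"covariates": s.covariates}
        if total_auc > 0:
            rec["cl"] = dose / total_auc
        cmax = float(y.max())
        if cmax > 0:
            rec["vc"] = dose / cmax
        records.append(rec)
    return records


def initial_estimates(dataset: StudyDataset) -> tuple[float, float, float, float]:
    """Naive two-stage starting values (theta_cl, theta_vc, theta_vp, theta_q).

    Per-subject clearance from dose / trapezoidal AUC with a log-linear
    tail extrapolation; central volume from dose / Cmax.  Medians across
    subjects; Q starts at the clearance estimate and Vp at Vc.
    """
    records = _per_subject_naive(dataset)
    cls = [r["cl"] for r in records if "cl" in r]
    vcs = [r["vc"] for r in records if "vc" in r]
    cl0 = float(np.median(cls)) if cls else 8.0
    vc0 = float(np.median(vcs)) if vcs else 20.0
    return cl0, vc0, vc0 * 0.8, cl0 * 2.0


def final_spec_for(dataset: StudyDataset, **kwargs) -> ModelSpec:
    """Final-structure spec with branch-aware starting values.

    theta_cl starts at the RRT subjects' median naive clearance; the
    fractional CrCL effect at the median of ``cl_i / (theta_cl *
    crcl_i / 100)`` over non-RRT subjects.  This targets the ridge between
    the two branch parameters that defeats generic starts.
    """
    records = _per_subject_naive(dataset)
    cl0, vc0, vp0, q0 = initial_estimates(dataset)
    rrt_cls = [r["cl"] for r in records
               if "cl" in r and r["covariates"].rrt]
    cl_rrt0 = float(np.median(rrt_cls)) if rrt_cls else cl0
    ratios = [
        r["cl"] / (cl_rrt0 * r["covariates"].crcl / 100.0)
        for r in records
        if "cl" in r and not r["covariates"].rrt
        and r["covariates"].crcl
    ]
    theta_crcl0 = float(np.clip(np.median(ratios), 0.1, 10.0)) if ratios else 1.5
    kwargs.setdefault("theta_init", (cl_rrt0, vc0, vp0, q0))
    kwargs.setdefault("effect_theta_init", (theta_crcl0,))
    return final_model_spec(**kwargs)
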