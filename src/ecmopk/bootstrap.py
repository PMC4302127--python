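"""Nonparametric subject-level bootstrap for percentile confidence intervals.

Whole subjects (all doses and observations) are resampled with replacement,
stratified by RRT status so every replicate keeps both branches of the
clearance covariate equation identifiable.  Non-converged replicates are
dropped and counted, never fabricated or redrawn.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dataset import StudyDataset
from .estimation import FitResult, ModelSpec, fit

__all__ = [
    "BootstrapResult",
    "bootstrap",
    "stratified_indices",
    "percentile_interval",
]

log = logging.getLogger(__name__)


def stratified_indices(
    strata: Sequence[int], rng: np.random.Generator
) -> np.ndarray:
    """One stratified with-replacement resample of ``range(len(strata))``.

    Each stratum is resampled within itself, preserving stratum sizes.
    """
    strata = np.asarray(strata)
    out = np.empty(len(strata), dtype=int)
    pos = 0
    for value in pd.unique(strata):
        members = np.flatnonzero(strata == value)
        draw = rng.choice(members, size=len(members), replace=True)
        out[pos:pos + len(members)] = draw
        pos += len(members)
    return out


def percentile_interval(
    values: np.ndarray, lower: float = 2.5, upper: float = 97.5
) -> tuple[float, float]:
    """Percentile bounds (linear interpolation)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no values")
    lo, hi = np.percentile(values, [lower, upper], method="linear")
    return float(lo), float(hi)


@dataclass
class BootstrapResult:
    replicates: pd.DataFrame          # one row per converged replicate
    summary: pd.DataFrame             # parameter, mean, ci_low, ci_high
    n_requested: int
    n_converged: int
    n_failed: int
    replicate_indices: list = field(default_factory=list)  # index -> resample

    def to_csv(self, path) -> None:
        self.summary.to_csv(path, index=False)


def _estimate_record(result: FitResult) -> dict:
    cvs = result.random_effects.as_cv_percent()
    rec = {
        "theta_cl": result.fixed.theta_cl,
        "theta_vc": result.fixed.theta_vc,
        "theta_vp": result.fixed.theta_vp,
        "theta_q": result.fixed.theta_q,
        "bsv_cv_cl": cvs[0],
        "bsv_cv_vc": cvs[1],
        "bsv_cv_vp": cvs[2],
        "ruv_cv": 100.0 * result.residual.sigma_prop,
        "ruv_sd": result.residual.sigma_add,
        "ofv": result.ofv,
    }
    for name, value in result.effect_thetas.items():
        rec[f"theta_{name}"] = value
    return rec


def bootstrap(
    dataset: StudyDataset,
    spec: ModelSpec,
    n: int,
    rng: np.random.Generator,
    base_fit: Optional[FitResult] = None,
    max_iter: int = 150,
) -> BootstrapResult:
    """``n`` stratified subject resamples, each refit from scratch.

    When a converged ``base_fit`` is available its estimates seed each
    replicate's starting values (faster, same optimum).  Replicates whose
    fit does not converge (or errors) are excluded and tallied.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    dataset.validate()
    strata = [int(s.covariates.rrt) for s in dataset.subjects]
    if base_fit is not None:
        from dataclasses import replace

        spec = replace(
            spec,
            theta_init=(
                base_fit.fixed.theta_cl, base_fit.fixed.theta_vc,
                base_fit.fixed.theta_vp, base_fit.fixed.theta_q,
            ),
            effect_theta_init=tuple(
                base_fit.effect_thetas[e.name] for e in spec.effects
            ),
            omega2_init=(
                base_fit.random_effects.omega2_cl,
                base_fit.random_effects.omega2_vc,
                base_fit.random_effects.omega2_vp,
            ),
            sigma_init=(
                base_fit.residual.sigma_prop, base_fit.residual.sigma_add
            ),
        )
    records = []
    indices_log = []
    n_failed = 0
    for rep in range(n):
        idx = stratified_indices(strata, rng)
        indices_log.append(idx.tolist())
        sample = dataset.subset(idx)
        try:
            result = fit(sample, spec, max_iter=max_iter, polish=False)
        except Exception as exc:  # noqa: BLE001 - tallied, not silenced
            log.warning("replicate %d failed: %s", rep, exc)
            n_failed += 1
            continue
        if not result.converged:
            log.warning("replicate %d did not converge", rep)
            n_failed += 1
            continue
        rec = _estimate_record(result)
        rec["replicate"] = rep
        records.append(rec)
    replicates = pd.DataFrame(records)
    rows = []
    if not replicates.empty:
        for col in replicates.columns:
            if col in ("replicate", "ofv"):
                continue
            values = replicates[col].to_numpy()
            lo, hi = percentile_interval(values)
            rows.append({
                "parameter": col,
                "mean": float(values.mean()),
                "ci_low": lo,
                "ci_high": hi,
            })
    summary = pd.DataFrame(rows, columns=["parameter", "mean", "ci_low", "ci_high"])
    return BootstrapResult(
        replicates=replicates,
        summary=summary,
        n_requested=n,
        n_converged=len(records),
        n_failed=n_failed,
        replicate_indices=indices_log,
    )
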