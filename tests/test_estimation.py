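"""Estimation: noiseless identifiability, quadrature oracle, model
comparison, covariate search and diagnostics."""

import dataclasses
import math

import numpy as np
import pytest
from scipy.special import logsumexp

import ecmopk.estimation as est
from ecmopk.covariates import PatientCovariates
from ecmopk.dataset import Observation, StudyDataset, Subject
from ecmopk.estimation import (
    CovariateEffect,
    ModelSpec,
    UnderDeterminedError,
    compare_nested,
    final_model_spec,
    final_spec_for,
    fit,
    goodness_of_fit,
    initial_estimates,
    ofv,
    stepwise_covariate_search,
)
from ecmopk.pk import DoseEvent, PKParameters, concentration_profile
from ecmopk.synth import default_config, generate_study


def _scaled_default(factor, clean_signal=False):
    cfg = default_config()
    groups = tuple(dataclasses.replace(g, n=g.n * factor,
                                       n_male=g.n_male * factor)
                   for g in cfg.groups)
    cfg = dataclasses.replace(cfg, groups=groups)
    if clean_signal:
        from ecmopk.population import RandomEffectsSpec, ResidualSpec
        cfg = dataclasses.replace(
            cfg,
            random_effects=RandomEffectsSpec.from_cv_percent(30, 30, 20),
            residual=ResidualSpec(0.10, 1.0))
    return cfg


@pytest.fixture(scope="module")
def noisy_fit():
    """One moderately sized noisy fit shared by the diagnostics tests."""
    ds = generate_study(_scaled_default(2), np.random.default_rng(100))
    return ds, fit(ds, final_spec_for(ds), polish=False)


class TestNoiselessIdentifiability:
    def test_theta_recovery(self):
        cfg = default_config(bsv=False, residual=False)
        ds = generate_study(cfg, np.random.default_rng(1))
        spec = final_model_spec(
            theta_init=(4.0, 25.0, 10.0, 15.0),
            effect_theta_init=(1.2,),
            omega2_init=(0.0, 0.0, 0.0),
            omega2_estimated=(False, False, False),
            sigma_init=(0.0, 0.01),
            sigma_estimated=(False, False),
        )
        result = fit(ds, spec, max_iter=600, tol=1e-12)
        assert result.converged
        assert result.fixed.theta_cl == pytest.approx(5.1, rel=1e-4)
        assert result.fixed.theta_vc == pytest.approx(18.7, rel=1e-4)
        assert result.fixed.theta_vp == pytest.approx(13.2, rel=1e-4)
        assert result.fixed.theta_q == pytest.approx(21.0, rel=1e-4)
        assert result.fixed.theta_crcl == pytest.approx(1.89, rel=1e-4)

    def test_under_determined(self):
        cov = PatientCovariates(age=50, sex="male", weight=80,
                                serum_creatinine=100, crcl=90)
        ds = StudyDataset([Subject(
            "1", cov, [DoseEvent(1000, 0, 0.5)],
            [Observation(1.0, 30.0), Observation(4.0, 10.0)])])
        with pytest.raises(UnderDeterminedError):
            fit(ds, ModelSpec())


def _one_eta_toy(seed=3):
    cov = PatientCovariates(age=50, sex="male", weight=80,
                            serum_creatinine=88.4, crcl=100, rrt=True)
    doses = [DoseEvent(1000, 0.0, 0.5)]
    theta = (6.0, 20.0, 14.0, 18.0)
    times = [0.5, 1, 1.5, 2, 3, 4, 6, 8]
    omega2, sig = 0.09, (0.15, 0.5)
    rng = np.random.default_rng(seed)
    p = PKParameters(theta[0] * math.exp(0.3), theta[1], theta[2], theta[3])
    f = concentration_profile(p, doses, times)
    y = (f * np.exp(rng.normal(0, sig[0], len(times)))
         + rng.normal(0, sig[1], len(times)))
    subj = Subject("1", cov, doses,
                   [Observation(t, float(v)) for t, v in zip(times, y)])
    ds = StudyDataset([subj])
    spec = ModelSpec(theta_init=theta, omega2_init=(omega2, 0, 0),
                     omega2_estimated=(False, False, False),
                     sigma_init=sig, sigma_estimated=(False, False))

    def oracle_ofv():
        """Independent: dense trapezoid integration of the exact marginal."""
        def m2ll(eta):
            pp = PKParameters(theta[0] * math.exp(eta), *theta[1:])
            ff = concentration_profile(pp, doses, times)
            v = sig[0] ** 2 * ff ** 2 + sig[1] ** 2
            return float(np.sum(np.log(2 * np.pi * v) + (y - ff) ** 2 / v))

        grid = np.linspace(-4, 4, 20001)
        log_joint = np.array([
            -0.5 * m2ll(x)
            - 0.5 * (np.log(2 * np.pi * omega2) + x ** 2 / omega2)
            for x in grid
        ])
        return -2 * (logsumexp(log_joint) + np.log(grid[1] - grid[0]))

    return ds, spec, oracle_ofv


class TestMarginalLikelihoodOracle:
    def test_quadrature_matches_independent_oracle(self):
        for seed in (3, 17, 42):
            ds, spec, oracle = _one_eta_toy(seed)
            assert ofv(ds, spec, n_quadrature=21) == \
                pytest.approx(oracle(), abs=1e-3)

    def test_laplace_close_to_exact(self):
        # the default (Laplace) approximation carries a small positive bias
        ds, spec, oracle = _one_eta_toy()
        exact = oracle()
        laplace = ofv(ds, spec)
        assert abs(laplace - exact) < 0.05

    def test_quadrature_requires_single_eta(self):
        ds = generate_study(default_config(), np.random.default_rng(0))
        spec = final_model_spec()
        with pytest.raises(ValueError, match="single-eta"):
            ofv(ds, spec, n_quadrature=21)


class TestCompareNested:
    def test_boundary_inclusive(self):
        assert compare_nested(100.0, 103.84, df=1) is True

    def test_zero_drop(self):
        assert compare_nested(100.0, 100.0, df=1) is False

    def test_large_drop(self):
        assert compare_nested(90.0, 100.0, df=1) is True

    def test_wrong_direction(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="ecmopk.estimation"):
            assert compare_nested(105.0, 100.0, df=1) is False
        assert any("increased" in rec.message for rec in caplog.records)

    def test_df2_uses_chi2(self):
        assert compare_nested(100.0, 105.0, df=2) is False   # needs 5.99
        assert compare_nested(100.0, 106.1, df=2) is True

    def test_invalid_df(self):
        with pytest.raises(ValueError):
            compare_nested(1.0, 2.0, df=0)


class TestDiagnostics:
    def test_zero_noise_gof(self):
        cfg = default_config(bsv=False, residual=False)
        ds = generate_study(cfg, np.random.default_rng(2))
        spec = final_model_spec(
            theta_init=(5.1, 18.7, 13.2, 21.0), effect_theta_init=(1.89,),
            omega2_init=(0, 0, 0), omega2_estimated=(False,) * 3,
            sigma_init=(0.0, 0.01), sigma_estimated=(False, False),
        )
        result = fit(ds, spec, polish=False)
        gof = goodness_of_fit(result)
        np.testing.assert_allclose(
            gof["table"]["observed"], gof["table"]["pred_population"],
            rtol=1e-5)
        assert gof["r2_population"] > 0.999999

    def test_censored_rows_excluded(self, noisy_fit):
        ds, result = noisy_fit
        n_quant = sum(len(s.quantified_observations) for s in ds.subjects)
        assert len(result.predictions) == n_quant
        assert len(goodness_of_fit(result)["table"]) == n_quant

    def test_individual_never_worse_than_population(self, noisy_fit):
        _, result = noisy_fit
        gof = goodness_of_fit(result)
        assert gof["sse_individual"] <= gof["sse_population"]

    def test_trajectory_monotone(self, noisy_fit):
        _, result = noisy_fit
        traj = result.trajectory
        assert len(traj) >= 2
        assert all(b < a for a, b in zip(traj, traj[1:]))

    def test_parameter_table_layout(self, noisy_fit):
        _, result = noisy_fit
        table = result.parameter_table()
        assert list(table.columns) == ["parameter", "estimate"]
        assert "CL (L/h)" in set(table["parameter"])
        assert "RUV (SD, mg/L)" in set(table["parameter"])

    def test_eta_shrinks_with_small_omega(self):
        cfg = default_config()
        ds = generate_study(cfg, np.random.default_rng(5))
        spec = final_model_spec(
            theta_init=(5.1, 18.7, 13.2, 21.0), effect_theta_init=(1.89,),
            omega2_init=(1e-6, 1e-6, 1e-6), omega2_estimated=(False,) * 3,
            sigma_init=(0.137, 2.3), sigma_estimated=(False, False),
        )
        result = fit(ds, spec, max_iter=30, polish=False)
        for eta in result.etas.values():
            assert np.max(np.abs(eta)) < 0.02


class TestStepwiseSearch:
    def test_empty_candidates_returns_base(self):
        ds = generate_study(default_config(), np.random.default_rng(4))
        base = ModelSpec(theta_init=initial_estimates(ds))
        search = stepwise_covariate_search(ds, base, [], max_iter=40)
        assert search.final_spec.effects == ()

    def test_tie_break_by_candidate_order(self):
        ds = generate_study(default_config(), np.random.default_rng(6))
        base = ModelSpec(theta_init=initial_estimates(ds))
        # two names for the identical effect: exact OFV tie by construction
        candidates = [
            CovariateEffect("rrt_first", "rrt", "binary"),
            CovariateEffect("rrt_second", "rrt", "binary"),
        ]
        search = stepwise_covariate_search(ds, base, candidates, max_iter=60)
        included = [row["candidate"] for row in search.trace
                    if row.get("status") == "included"]
        assert included[0] == "rrt_first"
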