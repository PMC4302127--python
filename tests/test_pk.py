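"""Kinetics core: closed-form identities, ODE-oracle agreement, linearity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad, solve_ivp

from ecmopk.pk import (
    DoseEvent,
    PKParameters,
    Regimen,
    auc_infinity,
    concentration_at,
    concentration_profile,
    microconstants,
    steady_state_trough,
    time_above_threshold,
    trough_at_interval,
)
from ecmopk.pk import InvalidParameterError


def ode_concentration(params, doses, times):
    """Independent oracle: stiff-safe integration of the two-compartment ODEs."""
    k10 = params.cl / params.vc
    k12 = params.q / params.vc
    k21 = params.q / params.vp

    def rate_in(t):
        total = 0.0
        for d in doses:
            if d.start_time <= t < d.start_time + d.infusion_duration:
                total += d.amount / d.infusion_duration
        return total

    def rhs(t, y):
        a_c, a_p = y
        return [
            rate_in(t) - (k10 + k12) * a_c + k21 * a_p,
            k12 * a_c - k21 * a_p,
        ]

    # break integration at every infusion edge so LSODA never smooths a step
    edges = sorted({d.start_time for d in doses}
                   | {d.start_time + d.infusion_duration for d in doses})
    out = []
    for t_end in times:
        sol = solve_ivp(
            rhs, (0.0, max(t_end, 1e-12)), [0.0, 0.0], method="LSODA",
            rtol=1e-11, atol=1e-12, dense_output=True, max_step=np.inf,
            t_eval=[t_end],
        )
        out.append(sol.y[0, -1] / params.vc)
    return np.array(out)


class TestMicroconstants:
    def test_table_values(self, table_params):
        mc = microconstants(table_params)
        assert mc.k10 == pytest.approx(0.2727, abs=5e-5)
        assert mc.k12 == pytest.approx(1.1230, abs=5e-5)
        assert mc.k21 == pytest.approx(1.5909, abs=5e-5)

    def test_identities(self, table_params):
        mc = microconstants(table_params)
        assert mc.alpha * mc.beta == pytest.approx(mc.k10 * mc.k21, rel=1e-12)
        assert mc.alpha + mc.beta == pytest.approx(
            mc.k10 + mc.k12 + mc.k21, rel=1e-12
        )
        assert mc.alpha > mc.beta > 0

    def test_cl_equals_q_forces_k10_equals_k12(self):
        mc = microconstants(PKParameters(7.0, 14.0, 10.0, 7.0))
        assert mc.k10 == pytest.approx(mc.k12, rel=1e-12)

    def test_large_vp_limit(self):
        mc = microconstants(PKParameters(5.0, 20.0, 1e9, 10.0))
        assert mc.k21 == pytest.approx(0.0, abs=1e-8)
        assert mc.beta == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("bad", [
        dict(cl=-1, vc=10, vp=10, q=10),
        dict(cl=5, vc=0, vp=10, q=10),
        dict(cl=5, vc=10, vp=10, q=float("nan")),
    ])
    def test_invalid_parameters(self, bad):
        with pytest.raises(InvalidParameterError):
            PKParameters(**bad)


class TestConcentration:
    def test_no_doses(self, table_params):
        assert concentration_at(table_params, [], 3.0) == 0.0

    def test_zero_at_infusion_start(self, table_params):
        dose = DoseEvent(1000, 2.0, 0.5)
        assert concentration_at(table_params, [dose], 2.0) == 0.0
        assert concentration_at(table_params, [dose], 1.0) == 0.0

    def test_against_ode_oracle_at_table_values(self, table_params):
        doses = [DoseEvent(1000, 0.0, 0.5)]
        times = [0.5, 8.0]
        closed = concentration_profile(table_params, doses, times)
        oracle = ode_concentration(table_params, doses, times)
        np.testing.assert_allclose(closed, oracle, rtol=1e-6)

    @settings(max_examples=15, deadline=None)
    @given(
        cl=st.floats(0.5, 30), vc=st.floats(5, 60), vp=st.floats(3, 80),
        q=st.floats(1, 50), amount=st.floats(100, 3000),
        dur=st.floats(0.05, 1.0),
    )
    def test_against_ode_oracle_random(self, cl, vc, vp, q, amount, dur):
        params = PKParameters(cl, vc, vp, q)
        doses = [DoseEvent(amount, 0.0, dur)]
        times = [dur / 2, dur, 2.0, 8.0]
        closed = concentration_profile(params, doses, times)
        oracle = ode_concentration(params, doses, times)
        np.testing.assert_allclose(closed, oracle, rtol=1e-6, atol=1e-12)

    def test_superposition_exact(self, table_params):
        d1 = DoseEvent(1000, 0.0, 0.5)
        d2 = DoseEvent(500, 8.0, 0.5)
        times = np.linspace(0, 24, 97)
        both = concentration_profile(table_params, [d1, d2], times)
        sep = (concentration_profile(table_params, [d1], times)
               + concentration_profile(table_params, [d2], times))
        np.testing.assert_allclose(both, sep, rtol=1e-12)

    def test_dose_linearity_exact(self, table_params):
        times = np.linspace(0, 16, 65)
        base = concentration_profile(
            table_params, [DoseEvent(500, 0, 0.5)], times)
        double = concentration_profile(
            table_params, [DoseEvent(1000, 0, 0.5)], times)
        np.testing.assert_allclose(double, 2 * base, rtol=1e-12)

    def test_nonnegative_and_continuous(self, table_params):
        times = np.linspace(0, 24, 2001)
        conc = concentration_profile(
            table_params, [DoseEvent(1000, 0, 0.5), DoseEvent(1000, 8, 0.5)],
            times)
        assert np.all(conc >= 0)
        assert np.max(np.abs(np.diff(conc))) < 2.0  # no jumps on a fine grid


class TestAUC:
    def test_analytic_value(self, table_params):
        assert auc_infinity(table_params, DoseEvent(1000, 0, 0.5)) == \
            pytest.approx(196.08, abs=0.005)

    def test_zero_dose(self, table_params):
        assert auc_infinity(table_params, DoseEvent(0, 0, 0.5)) == 0.0

    def test_doubling(self, table_params):
        a1 = auc_infinity(table_params, DoseEvent(700, 0, 0.5))
        a2 = auc_infinity(table_params, DoseEvent(1400, 0, 0.5))
        assert a2 == pytest.approx(2 * a1, rel=1e-12)

    @pytest.mark.parametrize("cl,vc,vp,q", [
        (5.1, 18.7, 13.2, 21.0), (2.0, 40.0, 8.0, 4.0), (15.0, 10.0, 30.0, 25.0),
    ])
    def test_quadrature_confirms(self, cl, vc, vp, q):
        params = PKParameters(cl, vc, vp, q)
        dose = DoseEvent(1000, 0.0, 0.5)
        head, _ = quad(
            lambda t: concentration_at(params, [dose], t), 0, 200,
            points=[0.5, 5, 20], limit=400,
        )
        # analytic tail beyond t=200 h from the terminal exponential
        mc = microconstants(params)
        tail = concentration_at(params, [dose], 200.0) / mc.beta
        assert head + tail == pytest.approx(auc_infinity(params, dose), rel=1e-6)


class TestTrough:
    def test_single_dose_definition(self, table_params):
        reg = Regimen(1000, 8.0, 0.5, n_doses=1)
        expected = concentration_at(
            table_params, [DoseEvent(1000, 0, 0.5)], 8.0)
        assert trough_at_interval(table_params, reg, 1) == pytest.approx(expected)

    def test_dose_linearity(self, table_params):
        r1 = Regimen(500, 8.0, 0.5, n_doses=5)
        r2 = Regimen(1000, 8.0, 0.5, n_doses=5)
        t1 = trough_at_interval(table_params, r1, 4)
        t2 = trough_at_interval(table_params, r2, 4)
        assert t2 == pytest.approx(2 * t1, rel=1e-12)

    def test_monotone_accumulation(self, table_params):
        reg = Regimen(1000, 8.0, 0.5, n_doses=25)
        troughs = [trough_at_interval(table_params, reg, k)
                   for k in range(1, 25)]
        assert all(b >= a for a, b in zip(troughs, troughs[1:]))

    def test_steady_state_by_dose_20(self, table_params):
        reg = Regimen(1000, 8.0, 0.5, n_doses=21)
        t20 = trough_at_interval(table_params, reg, 20)
        t21 = trough_at_interval(table_params, reg, 21)
        assert abs(t21 - t20) / t21 < 1e-3

    def test_steady_state_trough_matches_superposition(self, table_params):
        reg = Regimen(1000, 8.0, 0.5, n_doses=60)
        explicit = trough_at_interval(table_params, reg, 60)
        assert steady_state_trough(table_params, reg) == \
            pytest.approx(explicit, rel=1e-5)

    def test_index_bounds(self, table_params):
        reg = Regimen(1000, 8.0, 0.5, n_doses=3)
        with pytest.raises(ValueError):
            trough_at_interval(table_params, reg, 4)
        with pytest.raises(ValueError):
            trough_at_interval(table_params, reg, 0)


class TestTimeAboveThreshold:
    def test_zero_threshold(self, table_params):
        assert time_above_threshold(
            table_params, Regimen(1000, 8, 0.5, 1), 0.0) == 1.0

    def test_above_peak(self, table_params):
        assert time_above_threshold(
            table_params, Regimen(1000, 8, 0.5, 1), 1e5) == 0.0

    def test_rrt_patient_full_interval_above_2(self, table_params):
        # steady-state trough at these parameters exceeds 2 mg/L
        frac = time_above_threshold(table_params, Regimen(1000, 8, 0.5, 1), 2.0)
        assert frac == 1.0

    def test_monotone_in_threshold(self, table_params):
        reg = Regimen(500, 8, 0.5, 1)
        fracs = [time_above_threshold(table_params, reg, thr)
                 for thr in (0.5, 2.0, 8.0, 20.0, 40.0)]
        assert all(b <= a for a, b in zip(fracs, fracs[1:]))

    def test_matches_grid_counting_oracle(self):
        params = PKParameters(12.0, 25.0, 15.0, 10.0)
        reg = Regimen(1000, 8, 0.5, 1)
        thr = 4.0
        frac = time_above_threshold(params, reg, thr)
        # oracle: dense-grid counting at steady state (many superposed doses)
        doses = [DoseEvent(1000, k * 8.0, 0.5) for k in range(80)]
        grid = np.linspace(79 * 8.0, 80 * 8.0, 200_001)
        conc = concentration_profile(params, doses, grid)
        oracle = np.mean(conc > thr)
        assert frac == pytest.approx(oracle, abs=2e-4)


class TestValidation:
    def test_regimen_interval_vs_duration(self):
        with pytest.raises(ValueError):
            Regimen(1000, 0.4, 0.5, 1)

    def test_dose_event_validation(self):
        with pytest.raises(ValueError):
            DoseEvent(-5, 0, 0.5)
        with pytest.raises(ValueError):
            DoseEvent(100, 0, 0.0)
        with pytest.raises(ValueError):
            DoseEvent(100, -1.0, 0.5)
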