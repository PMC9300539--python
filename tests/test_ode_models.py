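"""ODE systems: ritonavir, oral paclitaxel, IV paclitaxel, TSP-1."""

import dataclasses

import numpy as np
import pytest

from oralpax import pkmodels as pkm
from oralpax.errors import InputError
from oralpax.params import (DispositionParams, IVPaclitaxelParams,
                            PhysioConstants, RitonavirPopParams, TSP1Params)
from oralpax.trial import DoseEvent


RTV = RitonavirPopParams(clearance=10.0, vc=60.0, q_inter=8.0, vp=40.0,
                         bioavailable_fraction=1.0,
                         mean_absorption_time=1.2, input_shape=0.4)


def _dose(time=0.0, amount=100.0):
    return DoseEvent(time=time, amount=amount, route="oral",
                     formulation="solution", daily_dose_index="first")


class TestRitonavir:
    def test_zero_state_zero_derivative(self):
        d = pkm.ritonavir_rhs([0.0, 0.0], 5.0, RTV, [])
        np.testing.assert_array_equal(d, [0.0, 0.0])

    def test_mass_conservation_without_clearance(self):
        params = dataclasses.replace(RTV, clearance=1e-12,
                                     bioavailable_fraction=0.8)
        doses = [_dose(amount=100.0)]
        t = np.array([0.0, 48.0])

        def rhs(t_, y):
            return pkm.ritonavir_rhs(y, t_, params, doses)

        from oralpax.pkmodels import _segment_solve
        states = _segment_solve(rhs, [0.0, 0.0], [0.0], t, 1e-10, 1e-12)
        total = states[-1].sum()
        assert total == pytest.approx(0.8 * 100.0 * 1000.0, rel=1e-4)

    def test_monoexponential_terminal_slope(self):
        """With Q = 0 the terminal log-slope is -CL/Vc."""
        params = dataclasses.replace(RTV, q_inter=1e-12)
        profile = pkm.solve_ritonavir([_dose()], params, horizon=60.0)
        sel = (profile.t > 30) & (profile.t < 60)
        slope = np.polyfit(profile.t[sel], np.log(profile.c[sel]), 1)[0]
        assert slope == pytest.approx(-params.clearance / params.vc,
                                      rel=1e-3)


class TestOralPaclitaxel:
    disp = DispositionParams(clint0=746.0, ki=375.0, imax=570.0,
                             vc=128.0, q=33.4, vp=375.0)
    physio = PhysioConstants()

    def gut(self, amount_ug=20000.0):
        return [pkm.GutDose(0.0, amount_ug, 1.68, 3.57),
                pkm.GutDose(7.0, amount_ug * 0.59, 1.97, 3.57)]

    def test_zero_state_zero_derivative(self, pac, physio):
        doses = [pkm.GutDose(0.0, 1000.0, 1.68, 3.57)]
        d = pkm.oral_paclitaxel_rhs(np.zeros(4), 2.0, pac, physio,
                                    lambda t: 500.0, doses)
        np.testing.assert_allclose(d, 0.0, atol=1e-12)

    def test_mass_conservation_without_elimination(self, pac, physio):
        """With fu*CLint ~ 0 the absorbed dose is fully retained:
        total amount = dose x applied relative bioavailability."""
        disp = dataclasses.replace(self.disp, clint0=1e-9, imax=1e-10)
        t = np.array([0.0, 48.0])
        _, states = pkm.solve_oral_paclitaxel(
            self.gut(), disp, physio, lambda t_: 0.0, t,
            return_states=True)
        total = states[-1].sum()
        expected = 20000.0 * (1 + 0.59)
        assert total == pytest.approx(expected, rel=1e-4)

    def test_full_state_solver_agrees_with_reduced(self, physio):
        t = np.arange(0.0, 24.01, 0.5)
        rtv = pkm.ConcProfile.constant(800.0)
        c_red = pkm.solve_oral_paclitaxel(self.gut(), self.disp, physio,
                                          rtv, t)
        c_full, _ = pkm.solve_oral_paclitaxel_full(
            self.gut(), self.disp, physio, rtv, t)
        np.testing.assert_allclose(c_full, c_red, rtol=2e-5, atol=1e-8)

    def test_rate_and_input_interpretations_coincide(self, physio):
        t = np.arange(0.0, 24.01, 0.5)
        rtv = pkm.ConcProfile.constant(800.0)
        c_rate, _ = pkm.solve_oral_paclitaxel_full(
            self.gut(), self.disp, physio, rtv, t, absorption_mode="rate")
        c_inp, _ = pkm.solve_oral_paclitaxel_full(
            self.gut(), self.disp, physio, rtv, t, absorption_mode="input")
        np.testing.assert_allclose(c_inp, c_rate, rtol=1e-5, atol=1e-8)

    def test_literal_pdf_rate_leaves_exp_minus_one_unabsorbed(self, physio):
        """Applying the Weibull *density* itself as the gut rate constant
        absorbs only 1 - exp(-1) of the dose (why the hazard form is the
        default)."""
        disp = dataclasses.replace(self.disp, clint0=1e-9, imax=1e-10)
        gut = [pkm.GutDose(0.0, 10000.0, 1.68, 3.57)]
        t = np.array([0.0, 48.0])
        _, states = pkm.solve_oral_paclitaxel_full(
            gut, disp, physio, lambda t_: 0.0, t,
            absorption_mode="pdf_rate")
        absorbed = states[-1, 1:].sum()  # liver+central+peripheral
        assert absorbed / 10000.0 == pytest.approx(1 - np.exp(-1), rel=1e-4)

    def test_unknown_mode_rejected(self, pac, physio):
        with pytest.raises(InputError):
            pkm.oral_paclitaxel_rhs(np.zeros(4), 1.0, pac, physio,
                                    lambda t: 0.0,
                                    [pkm.GutDose(0.0, 1.0, 1.68, 3.57)],
                                    absorption_mode="bogus")

    def test_auc_monotone_in_ritonavir_exposure(self, physio):
        """Raising the ritonavir concentration pointwise never decreases
        paclitaxel AUC (less first-pass extraction, lower clearance)."""
        t = np.arange(0.0, 48.01, 0.1)
        aucs = []
        for c_rtv in (0.0, 200.0, 800.0, 3000.0):
            c = pkm.solve_oral_paclitaxel(
                self.gut(), self.disp, physio,
                pkm.ConcProfile.constant(c_rtv), t)
            aucs.append(np.trapezoid(c, t))
        assert np.all(np.diff(aucs) > 0)


class TestIVPaclitaxel:
    linear = IVPaclitaxelParams(vc=16.0, v2=57.0, v3=260.0, q2=16.0,
                                q3=11.0, elimination="linear", cl=20.0)

    def test_linear_auc_is_dose_over_clearance(self):
        """In the linear mode AUC_0-inf equals dose/CL."""
        inf = [pkm.Infusion(0.0, 315_000.0, 1.0)]
        t = np.arange(0.0, 500.01, 0.02)
        c = pkm.solve_iv_paclitaxel(inf, self.linear, t)
        auc = np.trapezoid(c, t)
        assert auc == pytest.approx(315_000.0 / 20.0, rel=1e-3)

    def test_saturable_low_concentration_is_linear(self):
        """For C << km the saturable model behaves as CL = vmax/km."""
        sat = IVPaclitaxelParams(vc=16.0, v2=57.0, v3=260.0, q2=16.0,
                                 q3=11.0, elimination="saturable",
                                 vmax=20000.0, km=1000.0)
        lin = dataclasses.replace(sat, elimination="linear", cl=20.0,
                                  vmax=None, km=None)
        inf = [pkm.Infusion(0.0, 100.0, 1.0)]  # 0.1 mg: C in the ng/L range
        t = np.arange(0.0, 48.01, 0.05)
        c_sat = pkm.solve_iv_paclitaxel(inf, sat, t)
        c_lin = pkm.solve_iv_paclitaxel(inf, lin, t)
        auc_sat = np.trapezoid(c_sat, t)
        auc_lin = np.trapezoid(c_lin, t)
        assert auc_sat == pytest.approx(auc_lin, rel=0.01)

    def test_zero_infusion_zero_derivative(self):
        d = pkm.iv_paclitaxel_rhs([0.0, 0.0, 0.0], 1.0, self.linear, [])
        np.testing.assert_array_equal(d, 0.0)

    def test_negative_rate_rejected(self):
        with pytest.raises(InputError):
            pkm.Infusion(0.0, -5.0, 1.0)

    def test_overlapping_infusions_additive(self):
        infs = [pkm.Infusion(0.0, 1000.0, 2.0), pkm.Infusion(1.0, 1000.0, 2.0)]
        rate = sum(i.rate for i in infs if i.time < 1.5 <= i.time + i.duration)
        d = pkm.iv_paclitaxel_rhs([0.0, 0.0, 0.0], 1.5, self.linear, infs)
        assert d[0] == pytest.approx(rate)


class TestTSP1:
    params = TSP1Params(ec50=284.0, baseline=43.8, turnover_time=233.0)

    def test_kin_stimulation_bounds_and_values(self):
        assert pkm.kin_stimulation(0.0, 284.0) == 1.0
        assert pkm.kin_stimulation(284.0, 284.0) == 1.5
        assert pkm.kin_stimulation(1e15, 284.0) == pytest.approx(2.0)
        c = np.linspace(0, 1e4, 100)
        s = pkm.kin_stimulation(c, 284.0)
        assert np.all(np.diff(s) > 0) and np.all((s >= 1) & (s < 2))

    def test_baseline_is_steady_state(self):
        assert pkm.tsp1_rhs(43.8, 0.0, self.params) == pytest.approx(0.0)
        assert self.params.kin0 == pytest.approx(43.8 / 233.0, rel=1e-12)
        t = np.linspace(0, 2000, 50)
        traj = pkm.solve_tsp1(lambda t_: 0.0, self.params, t)
        np.testing.assert_allclose(traj, 43.8, rtol=1e-9)

    def test_sustained_ec50_reaches_1p5_baseline(self):
        """Constant paclitaxel at EC50 moves the steady state to
        1.5 x baseline after >= 10 turnover times."""
        t = np.array([0.0, 10.5 * 233.0])
        traj = pkm.solve_tsp1(lambda t_: 284.0, self.params, t)
        assert traj[-1] == pytest.approx(1.5 * 43.8, rel=1e-3)

    def test_matches_closed_form_exponential_approach(self):
        """With a constant driver the trajectory is the analytic
        relaxation towards kin/kout at rate kout."""
        c_pac = 150.0
        stim = pkm.kin_stimulation(c_pac, self.params.ec50)
        target = 43.8 * stim
        t = np.linspace(0.0, 1500.0, 40)
        expected = target + (43.8 - target) * np.exp(-t / 233.0)
        traj = pkm.solve_tsp1(lambda t_: c_pac, self.params, t)
        np.testing.assert_allclose(traj, expected, rtol=1e-6)

    def test_fast_path_matches_reference(self):
        from oralpax._fast import tsp1_fast
        grid = np.linspace(0.0, 500.0, 2001)
        driver = 300.0 * np.exp(-grid / 40.0) * (1 + 0.5 * np.sin(grid / 5))
        t_obs = np.array([24.0, 100.0, 250.0, 500.0])
        ref = pkm.solve_tsp1(pkm.ConcProfile(grid, driver), self.params,
                             t_obs)
        fast = tsp1_fast(t_obs, grid, driver, 284.0, 43.8, 1 / 233.0, 0.25)
        np.testing.assert_allclose(fast, ref, rtol=1e-5)
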