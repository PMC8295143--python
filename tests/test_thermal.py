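"""Bioheat integration: sources, exact discrete balances, stability and
treatment-level behaviour."""

import numpy as np
import pytest

import ireplan as ip
from ireplan.electric import FieldMagnitude
from ireplan.thermal import SourceTerm, TemperatureField, _BioheatStepper


def _tiny_grid(spacing=1.0, voltage=1000.0):
    dom = ip.DomainSpec(width_mm=20.0, height_mm=20.0, spacing_mm=spacing, margin_mm=2.0)
    return ip.build_grid(dom, ip.ElectrodeConfig(6.0, 8.0, voltage, insertion_depth_mm=10.0))


class TestPulseProtocol:
    def test_duty_and_duration(self):
        p = ip.PulseProtocol(50, 41.21, 1.0)
        assert p.duty == pytest.approx(41.21e-6)
        assert p.duration_s == pytest.approx(50.0)

    def test_duty_over_unity_rejected(self):
        with pytest.raises(ValueError):
            ip.PulseProtocol(10, 2e6, 1.0)


class TestJouleSource:
    def test_zero_field_zero_source(self, liver):
        g = _tiny_grid()
        fm = FieldMagnitude(np.zeros(g.shape), np.full(g.shape, liver.sigma_min))
        q = ip.joule_source(fm, liver, ip.PulseProtocol(90, 100.0), g)
        assert np.all(q.power == 0.0)

    def test_uniform_field_arithmetic(self, liver):
        g = _tiny_grid()
        e = np.full(g.shape, 1.0e5)
        fm = FieldMagnitude(e, np.asarray(liver.sigma_of_field(e)))
        q = ip.joule_source(fm, liver, ip.PulseProtocol(90, 100.0, 1.0), g)
        # duty 1e-4, sigma at ceiling: 1e-4 * 0.1483 * 1e10
        assert q.power[g.tissue_mask].max() == pytest.approx(1.483e5)
        assert np.all(q.power[~g.tissue_mask] == 0.0)

    def test_linear_in_pulse_width(self, liver):
        g = _tiny_grid()
        e = np.full(g.shape, 5.0e4)
        fm = FieldMagnitude(e, np.asarray(liver.sigma_of_field(e)))
        q1 = ip.joule_source(fm, liver, ip.PulseProtocol(90, 100.0), g)
        q2 = ip.joule_source(fm, liver, ip.PulseProtocol(90, 50.0), g)
        np.testing.assert_allclose(q2.power, 0.5 * q1.power)


class TestStepBioheat:
    def test_equilibrium_is_exact(self, liver, blood):
        g = _tiny_grid()
        T = TemperatureField(np.full(g.shape, 37.0))
        src = SourceTerm(np.zeros(g.shape))
        for _ in range(3):
            T = ip.step_bioheat(T, src, liver, blood, g, dt=0.5)
        np.testing.assert_allclose(T.temperature, 37.0, rtol=1e-12)

    def test_uniform_relaxation_matches_discrete_closed_form(self, liver, blood):
        # uniform T0: no conduction flux; backward Euler equals
        # (1 + dt*p/(rho c))^-n relaxation toward blood temperature
        g = _tiny_grid()
        t0, dt, n = 45.0, 0.5, 10
        T = TemperatureField(np.full(g.shape, t0))
        src = SourceTerm(np.zeros(g.shape))
        for _ in range(n):
            T = ip.step_bioheat(T, src, liver, blood, g, dt=dt)
        lam = blood.perfusion_coefficient / (liver.density * liver.heat_capacity)
        exact = 37.0 + (t0 - 37.0) / (1.0 + dt * lam) ** n
        np.testing.assert_allclose(T.temperature[g.tissue_mask], exact, rtol=1e-9)

    def test_pure_heating_balance(self, liver, blood):
        # perfusion off, uniform source: dT = Q dt / (rho c) exactly
        g = _tiny_grid()
        q0 = 1.0e5
        src = SourceTerm(np.where(g.tissue_mask, q0, 0.0))
        stepper = _BioheatStepper(g, liver, blood, dt=0.25, perfusion=False)
        T = np.full(g.shape, 37.0)
        for _ in range(4):
            T = stepper.step(T, src)
        expected = 37.0 + q0 * 1.0 / (liver.density * liver.heat_capacity)
        # interior tissue nodes away from the insulated electrodes are exact
        interior = g.tissue_mask.copy()
        np.testing.assert_allclose(np.max(T[interior]), expected, rtol=1e-6)


class TestSimulateTreatment:
    def test_zero_duration_stays_at_initial(self, liver, blood):
        g = _tiny_grid()
        sim = ip.simulate_treatment(g, liver, blood, ip.PulseProtocol(0, 100.0))
        assert sim.max_temperature == pytest.approx(37.0)

    def test_maximum_principle_with_nonnegative_source(self, optimal_sim_coarse):
        assert optimal_sim_coarse.time_series["T_max_C"].min() >= 37.0
        tissue = optimal_sim_coarse.grid.tissue_mask
        assert optimal_sim_coarse.final_temperature[tissue].min() >= 37.0 - 1e-9

    def test_energy_balance_without_perfusion(self, liver, blood):
        g = _tiny_grid(spacing=0.5)
        sim = ip.simulate_treatment(
            g, liver, blood, ip.PulseProtocol(20, 100.0, 1.0), perfusion=False
        )
        tissue = g.tissue_mask
        rho_c = liver.density * liver.heat_capacity
        stored = rho_c * np.sum(sim.final_temperature[tissue] - 37.0) * g.cell_area
        deposited = 20.0 * np.sum(sim.source.power[tissue]) * g.cell_area
        assert stored == pytest.approx(deposited, rel=5e-3)

    def test_max_temperature_monotone_in_pulse_number(self, liver, blood):
        g = _tiny_grid(spacing=0.5)
        temps = [
            ip.simulate_treatment(g, liver, blood, ip.PulseProtocol(n, 100.0)).max_temperature
            for n in (30, 60, 90)
        ]
        assert temps[0] <= temps[1] <= temps[2]

    def test_time_step_halving_changes_center_under_tenth_degree(self, liver, blood):
        g = _tiny_grid(spacing=0.5)
        finals = {}
        for dt in (0.1, 0.05):
            sim = ip.simulate_treatment(g, liver, blood, ip.PulseProtocol(20, 100.0), dt=dt)
            finals[dt] = sim.time_series["T_center_C"].iloc[-1]
        assert abs(finals[0.1] - finals[0.05]) < 0.1

    def test_duty_averaged_close_to_pulse_resolved(self, liver, blood):
        g = _tiny_grid(voltage=100.0)
        prot = ip.PulseProtocol(5, 5.0e4, 1.0)  # 5% duty so dt resolves pulses
        avg = ip.simulate_treatment(g, liver, blood, prot, dt=0.05)
        res = ip.simulate_treatment(g, liver, blood, prot, dt=0.05, pulse_resolved=True)
        # equal energy delivered: end-of-treatment temperatures agree even
        # though the resolved trace carries an intra-period sawtooth
        t_avg = avg.time_series["T_center_C"].iloc[-1]
        t_res = res.time_series["T_center_C"].iloc[-1]
        assert t_res == pytest.approx(t_avg, abs=0.2)

    def test_centerline_profile_peaks_inside_active_span(self, optimal_sim_coarse):
        sim = optimal_sim_coarse
        g = sim.grid
        _, ix = g.center_index
        profile = sim.final_temperature[:, ix]
        e = g.electrodes
        iy_top = int(round((e.insertion_depth_mm - e.active_length_mm) / 0.5))
        iy_tip = int(round(e.insertion_depth_mm / 0.5))
        iy_peak = int(np.argmax(profile))
        assert iy_top < iy_peak < iy_tip
        assert profile[0] < profile[iy_peak]
        assert profile[-1] < profile[iy_peak]

    def test_time_series_columns(self, optimal_sim_coarse):
        assert list(optimal_sim_coarse.time_series.columns) == [
            "time_s",
            "T_center_C",
            "T_outer_C",
            "T_max_C",
        ]
        assert len(optimal_sim_coarse.time_series) == 50 * 10 + 1
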