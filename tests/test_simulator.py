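"""Integration orchestration: events, determinism, oracle equivalence, warm-up."""

import dataclasses

import numpy as np
import pytest

import slurrygas as sg
from slurrygas.simulator import ForcingSeries, run_to_periodic_steady_state, steady_state_biomass


class TestForcingSeries:
    def test_interpolation_and_constant_extrapolation(self):
        f = ForcingSeries(times=np.array([10.0, 20.0]),
                          temperature=np.array([10.0, 30.0]),
                          pH=np.array([7.0, 6.0]))
        assert f.temperature_at(15.0) == pytest.approx(20.0)
        assert f.temperature_at(0.0) == 10.0       # before range: constant
        assert f.temperature_at(99.0) == 30.0      # after range: constant
        assert f.ph_at(17.5) == pytest.approx(6.25)

    def test_nonmonotone_times_rejected(self):
        with pytest.raises(ValueError):
            ForcingSeries(times=np.array([0.0, 5.0, 5.0]),
                          temperature=np.array([1.0, 2.0, 3.0]),
                          pH=np.array([7.0, 7.0, 7.0]))


class TestSimulate:
    def test_deterministic(self, short_scenario):
        a = sg.simulate(short_scenario)
        b = sg.simulate(short_scenario)
        np.testing.assert_array_equal(a.states.to_numpy(), b.states.to_numpy())
        np.testing.assert_array_equal(a.event_times(), b.event_times())

    def test_no_methanogens_no_methane(self, short_scenario):
        groups = [g.with_(C_X_in=0.0, X_init=0.0) for g in short_scenario.groups]
        traj = sg.simulate(short_scenario.replace(groups=groups))
        assert traj.summary["CH4_cum"] == 0.0
        assert np.all(traj.states["CH4_cum"] == 0.0)

    def test_default_emptying_cadence(self, short_scenario):
        traj = sg.simulate(short_scenario)
        spacing = np.diff(traj.event_times())
        np.testing.assert_allclose(spacing, 30.0, atol=0.1)
        # capacity never exceeded between events
        assert traj.states["M_m"].max() <= short_scenario.management.M_m_max + 1e-3

    def test_smaller_residual_fraction_reduces_biomass_and_ch4(self):
        lo = sg.simulate(sg.default_scenario(duration=180.0).replace(
            management=sg.ManagementScheme(f_resid=0.005)))
        hi = sg.simulate(sg.default_scenario(duration=180.0).replace(
            management=sg.ManagementScheme(f_resid=0.5)))
        assert lo.summary["CH4_cum"] < hi.summary["CH4_cum"]
        assert lo.methanogen_biomass()[-1] < hi.methanogen_biomass()[-1]

    def test_forced_mass_series_follows_imposed_mass(self):
        forc = ForcingSeries(
            times=np.array([0.0, 10.0, 20.0]),
            temperature=np.array([20.0, 20.0, 20.0]),
            pH=np.array([7.0, 7.0, 7.0]),
            slurry_mass=np.array([5000.0, 15000.0, 3000.0]),
        )
        scen = sg.default_scenario(duration=20.0).replace(
            forcings=forc,
            management=sg.ManagementScheme(mode="forced-mass-series", f_resid=0.1),
        )
        traj = sg.simulate(scen)
        assert traj.states["M_m"].iloc[0] == pytest.approx(5000.0)
        assert traj.states["M_m"].loc[10.0] == pytest.approx(15000.0, rel=1e-6)
        assert traj.states["M_m"].iloc[-1] == pytest.approx(3000.0, rel=1e-6)
        assert len(traj.events) == 1
        assert traj.events[0].f_resid == pytest.approx(3000.0 / 15000.0)
        from slurrygas.stoichiometry import cod_balance
        assert cod_balance(traj) < 1e-6


class TestEulerOracleEquivalence:
    def test_adaptive_solver_matches_fixed_step_euler(self):
        """5-day horizon with one emptying event, explicit Euler at dt = 1e-4 d."""
        scen = sg.default_scenario(duration=5.0)
        m_max = scen.management.M_m_max
        init = scen.default_initial_state()
        init.M_m = m_max - 2000.0          # event lands near t = 2 d
        scen = scen.replace(initial_state=init)

        traj = sg.simulate(scen)
        assert len(traj.events) == 1

        model = scen.build_model()
        from slurrygas.management import apply_removal
        y = model.initial_vector(init)
        dt = 1e-4
        t = 0.0
        while t < 5.0 - 1e-12:
            if y[0] >= m_max:
                state, _ = apply_removal(model.unpack(y), scen.management, time=t)
                tail = y[model.N_FIXED + model.k:].copy()
                y = model.pack(state)
                y[model.N_FIXED + model.k:] = tail
            y = y + dt * model.rhs(t, y, 20.0, 7.0, scen.management.F_in)
            t += dt

        adaptive = traj.states.iloc[-1]
        cols = (["M_m", "S_p", "VFA", "TAN"]
                + [f"X_{g.id}" for g in scen.groups] + ["CH4_cum", "CO2_cum"])
        euler = model.unpack(y)
        euler_vals = {
            "M_m": euler.M_m, "S_p": euler.S_p, "VFA": euler.VFA,
            "TAN": euler.TAN, "CH4_cum": euler.CH4_cum, "CO2_cum": euler.CO2_cum,
        }
        for i, g in enumerate(scen.groups):
            euler_vals[f"X_{g.id}"] = euler.X[i]
        for col in cols:
            assert adaptive[col] == pytest.approx(euler_vals[col], rel=1e-3), col


class TestPeriodicSteadyState:
    def test_infinite_tolerance_is_single_cycle(self, short_scenario):
        one = run_to_periodic_steady_state(short_scenario, tol=np.inf, max_cycles=5)
        direct = sg.simulate(short_scenario)
        assert one.summary["n_cycles_run"] == 1
        assert one.summary["CH4_cum"] == direct.summary["CH4_cum"]

    def test_constant_forcings_converge_quickly(self):
        scen = sg.default_scenario(duration=365.0)
        traj = run_to_periodic_steady_state(scen, max_cycles=6, tol=0.02)
        assert traj.summary["converged"]
        assert traj.summary["n_cycles_run"] <= 4

    def test_five_cycle_protocol_runs(self):
        scen = sg.default_scenario(duration=120.0)
        traj = run_to_periodic_steady_state(scen, max_cycles=5, tol=1e-9)
        assert traj.summary["n_cycles_run"] == 5
        assert "converged" in traj.summary


class TestSteadyStateBiomass:
    def test_cold_storage_supports_little_biomass(self):
        cold = steady_state_biomass(T=5.0, chunk=300.0, max_time=1200.0)
        warm = steady_state_biomass(T=25.0, chunk=300.0, max_time=1200.0)
        assert cold["total_methanogen"] < 0.05 * warm["total_methanogen"]

    def test_biomass_increases_with_temperature_above_ten(self):
        b15 = steady_state_biomass(T=15.0, chunk=300.0, max_time=1200.0)
        b25 = steady_state_biomass(T=25.0, chunk=300.0, max_time=1200.0)
        assert b25["total_methanogen"] > b15["total_methanogen"]
        # dominance shifts with temperature
        def dominant(b):
            groups = {k: v for k, v in b.items() if k != "total_methanogen"}
            return max(groups, key=groups.get)
        assert dominant(b15) != dominant(b25)
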