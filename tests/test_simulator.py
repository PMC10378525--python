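import numpy as np
import pytest

from gelprint import flow, simulator as sim
from gelprint.rheology import PowerLawModel


class TestThermostat:
    @pytest.mark.parametrize(
        "heater_on,T,expected",
        [(True, 32.5, False),  # above the band: stop heating
         (False, 29.0, True),  # below the band: start heating
         (True, 31.0, True),  # inside the band: hysteresis keeps the state
         (False, 31.0, False)],
    )
    def test_bang_bang_hysteresis(self, heater_on, T, expected):
        state = sim.ThermostatState(heater_on=heater_on)
        assert sim.thermostat_step(state, T).heater_on is expected

    def test_band_ordering_enforced(self):
        with pytest.raises(sim.SimulationError):
            sim.ThermostatState(lower_band=33.0, upper_band=32.0)


class TestStepThermal:
    def test_uniform_insulated_no_flow_equilibrium(self, geometry, material):
        cond = sim.ProcessConditions(inlet_velocity=0.03,
                                     initial_material_temperature=28.0)
        state = sim.initial_state(geometry, cond, material, sim.GridSpec(nr=17, nz=20))
        state.u = np.zeros_like(state.u)  # no flow
        new = sim.step_thermal(state, 0.05, geometry, cond, material,
                               wall_T=28.0, h_exterior=0.0)
        assert np.max(np.abs(new.T - 28.0)) < 1e-12

    def test_unstable_dt_names_admissible_bound(self, geometry, material, warm_conditions):
        state = sim.initial_state(geometry, warm_conditions, material,
                                  sim.GridSpec(nr=17, nz=20))
        dt_max = sim.admissible_dt(state, geometry, warm_conditions, material)
        with pytest.raises(sim.StabilityError, match="admissible dt"):
            sim.step_thermal(state, 10.0 * dt_max, geometry, warm_conditions, material)

    def test_slug_advects_at_local_velocity(self):
        # wide nozzle keeps the CFL step large; conduction off isolates advection
        geom = flow.ChannelGeometry(nozzle_diameter=10.0)
        mat = sim.MaterialProperties(rheology=PowerLawModel(k=5.0, n=0.5),
                                     k_cond=0.0)
        cond = sim.ProcessConditions(inlet_velocity=0.5,
                                     initial_material_temperature=20.0)
        state = sim.initial_state(geom, cond, mat, sim.GridSpec(nr=9, nz=14))
        z = state.z
        row = 2  # near-axis radial row
        state.T = state.T + 10.0 * np.exp(-((z - 20.0) / 4.0) ** 2)[None, :]
        dt = 0.8 * sim.admissible_dt(state, geom, cond, mat)
        t_total, n_steps = 20.0, int(round(20.0 / dt))

        def centroid(T_row):
            w = T_row - 20.0
            mask = z < geom.barrel_length  # stay clear of the taper
            return float(np.sum(w[mask] * z[mask]) / np.sum(w[mask]))

        c0 = centroid(state.T[row])
        for _ in range(n_steps):
            state = sim.step_thermal(state, dt, geom, cond, mat, h_exterior=0.0)
        u_row = state.u[row, 2]  # barrel velocity of that radial row, mm/s
        expected = c0 + u_row * n_steps * dt
        assert centroid(state.T[row]) == pytest.approx(expected, rel=0.05)


class TestRadialSolver:
    def test_thomas_solver_matches_scipy_banded(self, geometry, material,
                                                warm_conditions, rng):
        """The pre-factorised tridiagonal sweeps agree with an independent
        banded solve of the same systems."""
        from scipy.linalg import solve_banded

        from gelprint.simulator import _ThermalStepper

        state = sim.initial_state(geometry, warm_conditions, material,
                                  sim.GridSpec(nr=17, nz=20))
        stepper = _ThermalStepper(geometry, warm_conditions, material,
                                  state.s, state.z, state.u, dt=0.01,
                                  h_exterior=8.0)
        d = rng.normal(25.0, 3.0, size=state.T.shape)
        ours = stepper._solve(d.copy())
        nr = state.s.size
        for j in range(0, state.z.size, 5):
            ab = np.zeros((3, nr))
            ab[0, 1:] = stepper._c[:-1, j]
            ab[1, :] = stepper._b[:, j]
            ab[2, :-1] = stepper._a[1:, j]
            ref = solve_banded((1, 1), ab, d[:, j])
            assert np.allclose(ours[:, j], ref, rtol=1e-10, atol=1e-10)


class TestRunSimulation:
    def test_outlet_cools_then_equilibrates(self, inlet_velocity_sweep):
        r = inlet_velocity_sweep[0.03]
        assert np.all(np.diff(r.times) > 0)
        out = r.outlet_mean_T
        assert out[0] == pytest.approx(30.0, abs=1e-9)
        assert out.min() < out[0] - 1.0  # material cools toward the chilled ambient
        # equilibrium: late drift much smaller than the initial transient
        late = np.abs(np.diff(out[r.times > 0.8 * r.times[-1]])).max()
        early = np.abs(np.diff(out[:20])).max()
        assert late < 0.05 * early

    def test_deterministic_reruns(self, geometry, material, warm_conditions):
        a = sim.run_simulation(geometry, warm_conditions, material, duration=20.0)
        b = sim.run_simulation(geometry, warm_conditions, material, duration=20.0)
        assert np.array_equal(a.outlet_mean_T, b.outlet_mean_T)
        assert np.array_equal(a.delta_p, b.delta_p)

    def test_mass_conserved_at_every_station(self, inlet_velocity_sweep):
        r = inlet_velocity_sweep[0.03]
        Q = flow.volumetric_flow(0.03, 14.0)
        for snap in r.snapshots:
            rates = snap.section_flow_rates()
            assert np.max(np.abs(rates - Q)) / Q < 1e-3

    def test_cold_feed_reaches_lower_minimum(self, geometry, material):
        runs = {}
        for T0 in (25.0, 30.0):
            cond = sim.ProcessConditions(inlet_velocity=0.03,
                                         initial_material_temperature=T0)
            runs[T0] = sim.run_simulation(geometry, cond, material, duration=200.0)
        assert runs[25.0].outlet_mean_T.min() < runs[30.0].outlet_mean_T.min()

    def test_viscosity_field_shear_thinning_structure(self, inlet_velocity_sweep,
                                                      material):
        snap = inlet_velocity_sweep[0.03].final_state
        eta = sim.viscosity_field(snap, material)
        # n < 1: viscosity falls from the axis toward the wall on every section
        assert np.all(eta[0, :] >= eta[-1, :])
        # off the shear-rate floor the power law holds pointwise
        n = material.rheology.n
        inner = snap.shear_rate > 1e-2
        k_eff = material.rheology.k_eff(snap.T[inner])
        assert np.allclose(eta[inner],
                           k_eff * snap.shear_rate[inner] ** (n - 1.0), rtol=1e-9)

    def test_newtonian_viscosity_varies_only_with_temperature(self, geometry,
                                                              warm_conditions):
        mat = sim.MaterialProperties(rheology=PowerLawModel(k=5.0, n=1.0))
        state = sim.initial_state(geometry, warm_conditions, mat,
                                  sim.GridSpec(nr=17, nz=20))
        eta = sim.viscosity_field(state, mat)
        assert np.ptp(eta) == pytest.approx(0.0, abs=1e-12)  # uniform T here

    def test_thermostat_trace_confined_to_band(self, inlet_velocity_sweep):
        r = inlet_velocity_sweep[0.03]
        burn_in = r.times > 120.0
        wall = r.wall_T[burn_in]
        assert wall.min() > 30.0 - 0.5
        assert wall.max() < 32.0 + 0.5
        assert r.heater_on[burn_in].any() and not r.heater_on[burn_in].all()
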