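"""Flow solver verification: analytic benchmarks, conservation, determinism."""

import numpy as np
import pytest

from chipflow.geometry import build_model, channel_grid, rasterize_plan, strip_grid
from chipflow.solver import (FluidProps, FlowSolver, FlowState, SolverConfig,
                             local_reynolds_map, reynolds_number,
                             run_transient, stable_dt, step,
                             wall_shear_extract)
from chipflow.waveform import WaveformSpec, build_peristaltic, build_steady


class TestReynoldsNumber:
    def test_study_inlet_value(self, props):
        # 3.61 mm/s through the 1 mm inlet with culture-medium properties
        assert reynolds_number(props, 3.61e-3, 1e-3) == pytest.approx(3.35,
                                                                      abs=0.02)

    def test_linearity_in_velocity(self, props):
        assert reynolds_number(props, 2e-3, 1e-3) == pytest.approx(
            2 * reynolds_number(props, 1e-3, 1e-3), rel=1e-12)

    def test_round_number_case(self):
        p = FluidProps(density=1000.0, viscosity=1e-3)
        assert reynolds_number(p, 0.01, 0.001) == pytest.approx(10.0)


class TestStep:
    def test_zero_inflow_stays_zero(self, props, solver_cfg):
        g = strip_grid(2.0, 1.0, 1.0, 0.25)
        state = FlowState(u=np.zeros((g.n_y, g.n_x + 1)),
                          v=np.zeros((g.n_y + 1, g.n_x)),
                          p=np.zeros((g.n_y, g.n_x)))
        out = step(state, g, props, 0.0, 1e-3, solver_cfg)
        assert np.all(out.u == 0.0) and np.all(out.v == 0.0)

    def test_divergence_enforced_every_step(self, poiseuille_runs):
        for run in poiseuille_runs.values():
            assert run["max_div"] <= 1e-8

    def test_poiseuille_profile_ratio(self, poiseuille_runs):
        # centerline / mean velocity -> 3/2 for the parabolic profile
        assert poiseuille_runs[16]["ratio"] == pytest.approx(1.5, rel=0.02)

    def test_poiseuille_wall_shear(self, poiseuille_runs):
        assert poiseuille_runs[16]["shear_err"] < 0.02

    def test_hele_shaw_pressure_gradient(self, hele_shaw_run):
        assert hele_shaw_run["err"] < 0.02

    def test_refinement_errors_decrease_monotonically(self, poiseuille_runs):
        errs = [poiseuille_runs[n]["shear_err"] for n in (8, 16, 32)]
        assert errs[0] > errs[1] > errs[2]
        # finest two levels agree within 2 percent (mesh-independence proxy)
        assert abs(errs[1] - errs[2]) < 0.02

    def test_inlet_outlet_flux_balance(self, poiseuille_runs):
        fin, fout = poiseuille_runs[16]["flux"]
        assert fout == pytest.approx(fin, rel=5e-3)

    def test_creeping_flow_linearity(self, props, solver_cfg):
        # halving the inlet velocity halves the steady shear within 1%
        g = strip_grid(3.0, 2.0, 1.0, 0.25)
        taus = []
        for u_in in (2e-3, 1e-3):
            s = FlowSolver(g, props, solver_cfg,
                           stable_dt(g, props, solver_cfg, 0.01))
            for _ in range(3000):
                s.step(u_in)
            taus.append(wall_shear_extract(s.state, g, props))
        assert np.allclose(taus[0][:, 0], 2 * taus[1][:, 0], rtol=0.01)

    def test_determinism_bit_identical(self, props, solver_cfg):
        g = strip_grid(2.0, 1.0, 1.0, 0.25)
        outs = []
        for _ in range(2):
            s = FlowSolver(g, props, solver_cfg, 1e-3)
            for _ in range(200):
                s.step(2e-3)
            outs.append((s.state.u.copy(), s.state.p.copy()))
        assert np.array_equal(outs[0][0], outs[1][0])
        assert np.array_equal(outs[0][1], outs[1][1])


class TestWallShear:
    def test_plan_mode_closure_exact(self, hele_shaw_run, props):
        # tau = 6 mu ubar / h holds exactly under the parabolic closure
        s, g = hele_shaw_run["solver"], hele_shaw_run["grid"]
        tau = wall_shear_extract(s.state, g, props).reshape(g.n_y, g.n_x, 2)
        uc = 0.5 * (s.state.u[:, :-1] + s.state.u[:, 1:])
        row, col = g.n_y // 2, g.n_x // 2
        assert tau[row, col, 0] == pytest.approx(
            6 * props.viscosity * uc[row, col] / 0.5e-3, rel=1e-12)

    def test_zero_flow_zero_shear(self, props):
        g = strip_grid(2.0, 1.0, 1.0, 0.25)
        state = FlowState(u=np.zeros((g.n_y, g.n_x + 1)),
                          v=np.zeros((g.n_y + 1, g.n_x)),
                          p=np.zeros((g.n_y, g.n_x)))
        assert np.all(wall_shear_extract(state, g, props) == 0.0)

    def test_under_pillar_gap_doubles_shear_at_equal_velocity(self, props):
        # same depth-averaged velocity through a 0.5 mm gap vs the 1 mm
        # open chamber -> shear ratio exactly 2
        taus = {}
        for h in (0.5, 1.0):
            g = strip_grid(2.0, 1.0, h, 0.25)
            u = np.full((g.n_y, g.n_x + 1), 2e-3)
            state = FlowState(u=u, v=np.zeros((g.n_y + 1, g.n_x)),
                              p=np.zeros((g.n_y, g.n_x)))
            taus[h] = wall_shear_extract(state, g, props)[0, 0]
        assert taus[0.5] == pytest.approx(2 * taus[1.0], rel=1e-12)


class TestLocalReynolds:
    def test_zero_flow(self, props):
        g = strip_grid(2.0, 1.0, 1.0, 0.25)
        state = FlowState(u=np.zeros((g.n_y, g.n_x + 1)),
                          v=np.zeros((g.n_y + 1, g.n_x)),
                          p=np.zeros((g.n_y, g.n_x)))
        assert np.all(local_reynolds_map(state, g, props) == 0.0)

    def test_uniform_strip_matches_inlet_value(self, props):
        g = strip_grid(2.0, 1.0, 1.0, 0.25)
        u = np.full((g.n_y, g.n_x + 1), 3.61e-3)
        state = FlowState(u=u, v=np.zeros((g.n_y + 1, g.n_x)),
                          p=np.zeros((g.n_y, g.n_x)))
        re = local_reynolds_map(state, g, props)
        assert np.allclose(re, 3.35, atol=0.02)

    def test_linear_in_speed(self, props):
        g = strip_grid(2.0, 1.0, 1.0, 0.25)
        states = []
        for u0 in (1e-3, 3e-3):
            u = np.full((g.n_y, g.n_x + 1), u0)
            states.append(FlowState(u=u, v=np.zeros((g.n_y + 1, g.n_x)),
                                    p=np.zeros((g.n_y, g.n_x))))
        r1 = local_reynolds_map(states[0], g, props)
        r3 = local_reynolds_map(states[1], g, props)
        assert np.allclose(r3, 3 * r1, rtol=1e-12)


class TestRunTransient:
    def test_steady_waveform_constant_history(self, props, solver_cfg):
        spec = WaveformSpec(kind="steady", n_cycles=3)
        wf = build_steady(spec, spec.period / 400)
        g = strip_grid(3.0, 2.0, 1.0, 0.25)
        res = run_transient(g, wf, props, solver_cfg)
        mag = res.history.magnitude()
        drift = np.abs(mag - mag[0]).max() / mag[0].max()
        assert drift < 1e-3

    def test_womersley_amplitude_and_phase(self, womersley_run):
        tau_hat = womersley_run["tau_hat"]
        tau_an = womersley_run["tau_analytic"]
        assert abs(abs(tau_hat) - abs(tau_an)) / abs(tau_an) < 0.05
        assert abs(np.angle(tau_hat / tau_an)) / (2 * np.pi) < 0.05

    def test_matched_mean_flow_between_modes(self):
        # steady and pulsatile waveforms built from one spec share the
        # cycle-averaged inlet velocity to high precision
        spec = WaveformSpec()
        dt = spec.period / 400
        wp = build_peristaltic(spec, dt)
        ws = build_steady(spec, dt)
        assert wp.time_average() == pytest.approx(ws.time_average(),
                                                  rel=1e-6)

    def test_non_integer_cycles_rejected(self, props, solver_cfg):
        from chipflow.waveform import WaveformSeries

        t = np.linspace(0.0, 2.5, 1001)
        wf = WaveformSeries(times=t, velocities=np.full_like(t, 2.0),
                            period=1.0, mean_velocity=2.0)
        g = strip_grid(2.0, 1.0, 1.0, 0.25)
        with pytest.raises(ValueError, match="integer number"):
            run_transient(g, wf, props, solver_cfg)

    def test_chamber_run_conserves_flux(self, props, solver_cfg):
        spec = WaveformSpec(kind="steady", n_cycles=3)
        wf = build_steady(spec, spec.period / 400)
        g = rasterize_plan(build_model(2), 0.2)
        res = run_transient(g, wf, props, solver_cfg)
        assert res.outlet_flux[-1] == pytest.approx(res.inlet_flux[-1],
                                                    rel=5e-3)
        assert res.max_divergence <= solver_cfg.pressure_tolerance
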