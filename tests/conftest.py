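"""Shared fixtures: fluid properties, benchmark runs and the default study.

The expensive solver runs are session-scoped so the acceptance checks and
unit tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from chipflow.geometry import channel_grid, strip_grid
from chipflow.solver import (FluidProps, FlowSolver, SolverConfig,
                             run_transient, stable_dt, wall_shear_extract)
from chipflow.waveform import WaveformSeries


@pytest.fixture(scope="session")
def props() -> FluidProps:
    return FluidProps()          # culture medium: 1020 kg/m^3, 1.1 mPa s


@pytest.fixture(scope="session")
def solver_cfg() -> SolverConfig:
    return SolverConfig()


@pytest.fixture(scope="session")
def poiseuille_runs(props, solver_cfg):
    """Steady channel solves at three resolutions -> (shear_err, ratio_err)."""
    out = {}
    for nz in (8, 16, 32):
        g = channel_grid(length=3.0, height=1.0, cell_size=1.0 / nz)
        s = FlowSolver(g, props, solver_cfg,
                       stable_dt(g, props, solver_cfg, 0.02))
        for _ in range(4000):
            s.step(3.61e-3)
        uc = 0.5 * (s.state.u[:, :-1] + s.state.u[:, 1:])
        mid = g.n_x // 2
        prof = uc[:, mid]
        tau = wall_shear_extract(s.state, g, props)
        expect = 6 * props.viscosity * prof.mean() / 1e-3
        out[nz] = {
            "shear_err": abs(tau[mid, 0] - expect) / expect,
            "ratio": prof.max() / prof.mean(),
            "max_div": s.max_divergence,
            "flux": s.fluxes(),
        }
    return out


@pytest.fixture(scope="session")
def hele_shaw_run(props, solver_cfg):
    """Steady plan-mode strip solve -> pressure-gradient error and fields."""
    g = strip_grid(length=4.0, width=4.0, gap_height=0.5, cell_size=0.125)
    s = FlowSolver(g, props, solver_cfg, stable_dt(g, props, solver_cfg, 0.02))
    for _ in range(4000):
        s.step(2e-3)
    uc = 0.5 * (s.state.u[:, :-1] + s.state.u[:, 1:])
    row, i1, i2 = g.n_y // 2, g.n_x // 4, 3 * g.n_x // 4
    dpdx = (s.state.p[row, i2] - s.state.p[row, i1]) / ((i2 - i1) * s.d)
    ubar = uc[row, g.n_x // 2]
    expect = -12 * props.viscosity * ubar / 0.5e-3 ** 2
    return {"err": abs(dpdx - expect) / abs(expect), "solver": s, "grid": g,
            "ubar": ubar}


@pytest.fixture(scope="session")
def womersley_run(props, solver_cfg):
    """Oscillatory channel run compared against the complex closed form."""
    from chipflow.benchmarks import womersley_shear_transfer

    f, beta, vbar = 0.4, 0.7, 3.61
    T = 1.0 / f
    t = np.linspace(0.0, 3 * T, 6001)
    wf = WaveformSeries(times=t,
                        velocities=vbar * (1 + beta * np.cos(2 * np.pi * f * t)),
                        period=T, mean_velocity=vbar)
    g = channel_grid(length=4.0, height=1.0, cell_size=0.0625)
    res = run_transient(g, wf, props, solver_cfg)
    hist = res.history.last_cycle()
    mid = int(np.argmin(np.abs(hist.cell_xy[:, 0] - 2.0)))
    om = 2 * np.pi * f
    tau_hat = 2 * np.trapezoid(hist.tau[:, mid, 0]
                               * np.exp(-1j * om * hist.times), hist.times) / T
    tau_an = womersley_shear_transfer(1e-3, om, props) * beta * vbar * 1e-3
    return {"tau_hat": tau_hat, "tau_analytic": tau_an,
            "max_div": res.max_divergence, "result": res}


@pytest.fixture(scope="session")
def study_report():
    """Full default 3x2 study (plan metrics + section phase analysis)."""
    from chipflow.pipeline import StudyConfig, run_study

    cfg = StudyConfig(log_level="WARNING")
    report = run_study(cfg)
    assert not report.failed, f"study conditions failed: {report.failed}"
    return report
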