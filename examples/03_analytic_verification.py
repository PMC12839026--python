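"""Verify the solver against closed-form channel flows.

Plane Poiseuille fixes the steady viscous balance and the wall-shear
extraction; the oscillatory (Womersley) channel fixes the transient terms,
including the phase lead of wall shear over the bulk velocity.
"""

import numpy as np

from chipflow import FluidProps, SolverConfig, channel_grid, run_transient
from chipflow.benchmarks import make_benchmark, womersley_shear_transfer
from chipflow.solver import FlowSolver, stable_dt, wall_shear_extract
from chipflow.waveform import WaveformSeries

props = FluidProps()
cfg = SolverConfig()

# --- steady: parabolic profile between floor and lid
g = channel_grid(length=3.0, height=1.0, cell_size=0.0625)
s = FlowSolver(g, props, cfg, stable_dt(g, props, cfg, 0.02))
for _ in range(4000):
    s.step(3.61e-3)
tau = wall_shear_extract(s.state, g, props)
mid = g.n_x // 2
uc = 0.5 * (s.state.u[:, :-1] + s.state.u[:, 1:])
expect = make_benchmark("plane_poiseuille",
                        {"u_mean_mm_s": uc[:, mid].mean() * 1e3}).wall_shear()
print(f"Poiseuille floor shear: {tau[mid, 0]:.4e} Pa "
      f"(closed form {expect:.4e}, error "
      f"{abs(tau[mid, 0] - expect) / expect * 100:.2f}%)")

# --- oscillatory: compare the fundamental of the floor shear
f, beta, vbar = 0.4, 0.7, 3.61
T = 1.0 / f
t = np.linspace(0, 3 * T, 6001)
wf = WaveformSeries(times=t,
                    velocities=vbar * (1 + beta * np.cos(2 * np.pi * f * t)),
                    period=T, mean_velocity=vbar)
res = run_transient(channel_grid(3.0, 1.0, 0.0625), wf, props, cfg)
hist = res.history.last_cycle()
cell = int(np.argmin(np.abs(hist.cell_xy[:, 0] - 1.5)))
om = 2 * np.pi * f
tau_hat = 2 * np.trapezoid(hist.tau[:, cell, 0]
                           * np.exp(-1j * om * hist.times), hist.times) / T
tau_an = womersley_shear_transfer(1e-3, om, props) * beta * vbar * 1e-3
print(f"Womersley shear amplitude: {abs(tau_hat):.4e} Pa "
      f"(closed form {abs(tau_an):.4e})")
print(f"shear phase lead over inlet velocity: "
      f"{np.degrees(np.angle(tau_hat)):.2f} deg "
      f"(closed form {np.degrees(np.angle(tau_an)):.2f} deg)")

# The positive phase angle is the Stokes-layer effect that makes wall
# shear higher during acceleration than deceleration at the same
# instantaneous inflow velocity.
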