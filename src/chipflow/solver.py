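"""Transient incompressible laminar flow on structured grids.

A classic staggered-grid (MAC) projection scheme: explicit advection
(hybrid centred/upwind) and viscous diffusion advance the momentum,
a pressure Poisson solve projects the face velocities onto a discretely
divergence-free field.  Two modes share the machinery:

* ``plan`` — depth-averaged (Hele-Shaw/Brinkman) view of the chamber
  floor plane.  The vertical structure is assumed locally parabolic across
  the gap ``h(x, y)``, contributing a drag sink ``-12 mu u / h^2`` and a
  floor shear closure ``tau = 6 mu u_bar / h``.  Continuity is enforced on
  the depth-weighted volume flux ``div(h u) = 0``, the conserved quantity
  of a variable-gap thin film.
* ``section`` — the vertical x-z mid-plane with a resolved wall-normal
  velocity profile; floor shear is ``mu du/dz`` evaluated with a one-sided
  second-order difference honouring the no-slip floor.

Boundary conditions: no-slip on walls and pillar faces, a prescribed plug
inflow, and a zero-pressure outlet with zero-gradient velocity.  The flow
here is creeping (inlet Re about 3, local Re below 20 everywhere), so a
laminar model with mild advection is the appropriate regime.

All solver-internal quantities are SI (m, s, Pa); grids carry mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .geometry import DomainGrid
from .waveform import WaveformSeries

__all__ = [
    "FluidProps",
    "SolverConfig",
    "FlowState",
    "ShearHistory",
    "RunResult",
    "FlowSolver",
    "reynolds_number",
    "step",
    "run_transient",
    "wall_shear_extract",
    "local_reynolds_map",
    "CULTURE_MEDIUM",
]


@dataclass(frozen=True)
class FluidProps:
    """Newtonian fluid: density (kg/m^3) and dynamic viscosity (kg/(m s)).

    Gravity is omitted: the system is isothermal single-phase liquid, so
    gravity only adds a hydrostatic offset while the pump drives the motion.
    """

    density: float = 1020.0
    viscosity: float = 0.0011

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("density and viscosity must be positive")

    @property
    def nu(self) -> float:
        return self.viscosity / self.density


#: Standard culture-medium properties used throughout the study.
CULTURE_MEDIUM = FluidProps()


@dataclass(frozen=True)
class SolverConfig:
    cfl_limit: float = 0.4
    pressure_tolerance: float = 1e-8      # relative divergence residual
    max_pressure_iterations: int = 2000   # contract field; direct solve used
    snapshot_stride: int = 20
    dt_max: float = 1e-3
    steady_tol: float = 1e-6              # rel. change of area-avg floor shear
    steady_max_steps: int = 60000
    store_fields: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.cfl_limit <= 0.5:
            raise ValueError("cfl_limit must lie in (0, 0.5]")
        if self.pressure_tolerance <= 0:
            raise ValueError("pressure_tolerance must be positive")


@dataclass
class FlowState:
    """Staggered velocities (m/s), cell pressures (Pa) and time (s)."""

    u: np.ndarray          # (ny, nx+1) x-face velocities
    v: np.ndarray          # (ny+1, nx) y-face velocities
    p: np.ndarray          # (ny, nx)
    time: float = 0.0


@dataclass
class ShearHistory:
    """Wall-shear vector time series on the culture-surface cells.

    ``tau`` has shape (n_times, n_cells, 2), Pa.  ``inlet_velocity`` is the
    inlet tube velocity in mm/s at each snapshot, kept for phase-matched
    comparisons.
    """

    times: np.ndarray
    tau: np.ndarray
    cell_indices: np.ndarray    # (n_cells, 2) of (j, i)
    cell_xy: np.ndarray         # (n_cells, 2) cell centres, mm
    cycle_period: float
    cell_area: float            # mm^2 per cell (uniform grid)
    inlet_velocity: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return self.tau.shape[1]

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.tau, axis=2)

    def last_cycle(self) -> "ShearHistory":
        """Slice covering exactly the final cycle period (both ends inclusive)."""
        t_end = self.times[-1]
        t_start = t_end - self.cycle_period
        i0 = int(np.argmin(np.abs(self.times - t_start)))
        if abs(self.times[i0] - t_start) > 1e-9 * max(self.cycle_period, 1.0):
            raise ValueError("history does not span an integer number of cycles")
        return ShearHistory(times=self.times[i0:], tau=self.tau[i0:],
                            cell_indices=self.cell_indices, cell_xy=self.cell_xy,
                            cycle_period=self.cycle_period,
                            cell_area=self.cell_area,
                            inlet_velocity=None if self.inlet_velocity is None
                            else self.inlet_velocity[i0:])

    def to_csv(self, path) -> None:
        import pandas as pd

        nt, nc, _ = self.tau.shape
        df = pd.DataFrame({
            "cell_id": np.repeat(np.arange(nc), nt),
            "x_mm": np.repeat(self.cell_xy[:, 0], nt),
            "y_mm": np.repeat(self.cell_xy[:, 1], nt),
            "time_s": np.tile(self.times, nc),
            "tau_x_pa": self.tau[:, :, 0].T.ravel(),
            "tau_y_pa": self.tau[:, :, 1].T.ravel(),
        })
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, cycle_period: float,
                 cell_area: float = 1.0) -> "ShearHistory":
        import pandas as pd

        df = pd.read_csv(path)
        ids = np.sort(df["cell_id"].unique())
        times = np.sort(df["time_s"].unique())
        nt, nc = len(times), len(ids)
        df = df.sort_values(["cell_id", "time_s"])
        tau = np.empty((nt, nc, 2))
        tau[:, :, 0] = df["tau_x_pa"].to_numpy().reshape(nc, nt).T
        tau[:, :, 1] = df["tau_y_pa"].to_numpy().reshape(nc, nt).T
        xy = df.groupby("cell_id")[["x_mm", "y_mm"]].first().to_numpy()
        idx = np.zeros((nc, 2), dtype=int)
        return cls(times=times, tau=tau, cell_indices=idx, cell_xy=xy,
                   cycle_period=cycle_period, cell_area=cell_area)


@dataclass
class RunResult:
    grid: DomainGrid
    history: ShearHistory
    pressure_drop: np.ndarray      # Pa, at snapshot times
    times: np.ndarray
    inlet_velocity: np.ndarray     # mm/s (tube velocity) at snapshot times
    max_local_re: float
    final_state: FlowState
    max_divergence: float
    inlet_flux: np.ndarray         # m^3/s per unit convention of the mode
    outlet_flux: np.ndarray
    fields: list[FlowState] = field(default_factory=list)


def reynolds_number(props: FluidProps, velocity: float, length: float) -> float:
    """Re = rho U D / mu (SI inputs)."""
    if velocity < 0 or length <= 0:
        raise ValueError("velocity must be >= 0 and length > 0")
    return props.density * velocity * length / props.viscosity


# ---------------------------------------------------------------------------


class FlowSolver:
    """Projection solver bound to one grid, fluid and time step.

    The pressure Poisson operator is assembled and LU-factorised once; each
    ``step`` costs a handful of vectorised array operations plus one
    triangular solve, and is fully deterministic.
    """

    def __init__(self, grid: DomainGrid, props: FluidProps, cfg: SolverConfig,
                 dt: float):
        self.grid = grid
        self.props = props
        self.cfg = cfg
        self.dt = dt
        self.d = grid.cell_size * 1e-3
        ny, nx = grid.n_y, grid.n_x
        fluid = grid.fluid_mask

        # heights (m): plan mode uses the gap map, section mode unit weight
        if grid.mode == "plan":
            h = grid.height_map * 1e-3
        else:
            h = np.where(fluid, 1.0, 0.0)
        self.h = h

        inlet_col = np.where(grid.inlet_cells.any(axis=0))[0]
        outlet_col = np.where(grid.outlet_cells.any(axis=0))[0]
        if len(inlet_col) != 1 or len(outlet_col) != 1:
            raise ValueError("expected single-column inlet and outlet labels")
        self.ic, self.oc = int(inlet_col[0]), int(outlet_col[0])
        self.inlet_rows = grid.inlet_cells[:, self.ic]
        self.outlet_rows = grid.outlet_cells[:, self.oc]

        # face openness
        open_u = np.zeros((ny, nx + 1), dtype=bool)
        open_u[:, 1:nx] = fluid[:, :-1] & fluid[:, 1:]
        open_v = np.zeros((ny + 1, nx), dtype=bool)
        open_v[1:ny, :] = fluid[:-1, :] & fluid[1:, :]
        self.inlet_u = np.zeros_like(open_u)
        self.inlet_u[self.inlet_rows, self.ic] = True
        self.outlet_u = np.zeros_like(open_u)
        self.outlet_u[self.outlet_rows, self.oc + 1] = True
        self.open_u_int = open_u & ~self.inlet_u & ~self.outlet_u
        self.open_u = open_u | self.inlet_u | self.outlet_u
        self.open_v = open_v

        # face gaps (m)
        gu = np.zeros((ny, nx + 1))
        gu[:, 1:nx] = np.minimum(h[:, :-1], h[:, 1:])
        gu[self.inlet_u] = h[self.inlet_rows, self.ic]
        gu[self.outlet_u] = h[self.outlet_rows, self.oc]
        gu[~self.open_u] = 0.0
        gv = np.zeros((ny + 1, nx))
        gv[1:ny, :] = np.minimum(h[:-1, :], h[1:, :])
        gv[~open_v] = 0.0
        self.gu, self.gv = gu, gv

        # plan-mode Brinkman drag factors (implicit).  The drag also scales
        # the pressure correction, so it is folded into the face conductance
        # of the Poisson operator: the steady balance then recovers
        # dp/dx = -12 mu u / h^2 without splitting bias.
        if grid.mode == "plan":
            nu = props.nu
            with np.errstate(divide="ignore"):
                ku = np.where(gu > 0, 12.0 * nu / gu ** 2, 0.0)
                kv = np.where(gv > 0, 12.0 * nu / gv ** 2, 0.0)
            self.drag_u = 1.0 / (1.0 + dt * ku)
            self.drag_v = 1.0 / (1.0 + dt * kv)
            self.cu = gu * self.drag_u
            self.cv = gv * self.drag_v
        else:
            self.drag_u = self.drag_v = None
            self.cu, self.cv = gu, gv

        self._assemble_poisson()
        self.state = FlowState(u=np.zeros((ny, nx + 1)),
                               v=np.zeros((ny + 1, nx)),
                               p=np.zeros((ny, nx)), time=0.0)
        self.max_divergence = 0.0

    # -- Poisson operator --------------------------------------------------

    def _assemble_poisson(self) -> None:
        grid, d = self.grid, self.d
        fluid = grid.fluid_mask
        ny, nx = grid.n_y, grid.n_x
        idx = -np.ones((ny, nx), dtype=int)
        idx[fluid] = np.arange(fluid.sum())
        self.idx = idx
        n = int(fluid.sum())

        rows, cols, vals = [], [], []

        def add(r, c, v):
            rows.append(r)
            cols.append(c)
            vals.append(v)

        inv_d2 = 1.0 / d ** 2
        # interior u faces couple (j, i-1) <-> (j, i)
        jj, ii = np.where(self.open_u_int)
        for j, i in zip(jj, ii):
            g = self.cu[j, i] * inv_d2
            P, N = idx[j, i - 1], idx[j, i]
            add(P, P, g); add(P, N, -g); add(N, N, g); add(N, P, -g)
        # interior v faces couple (j-1, i) <-> (j, i)
        jj, ii = np.where(self.open_v)
        for j, i in zip(jj, ii):
            g = self.cv[j, i] * inv_d2
            P, N = idx[j - 1, i], idx[j, i]
            add(P, P, g); add(P, N, -g); add(N, N, g); add(N, P, -g)
        # outlet faces: ghost phi = 0 one cell outside
        jj = np.where(self.outlet_rows)[0]
        for j in jj:
            g = self.cu[j, self.oc + 1] * inv_d2
            P = idx[j, self.oc]
            add(P, P, g)
        A = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()
        self.lu = splu(A)

    # -- helpers -----------------------------------------------------------

    def _divergence(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        gu_u = self.gu * u
        gv_v = self.gv * v
        return (gu_u[:, 1:] - gu_u[:, :-1] + gv_v[1:, :] - gv_v[:-1, :]) / self.d

    def _apply_bc(self, u: np.ndarray, v: np.ndarray, u_in: float) -> None:
        u[~self.open_u] = 0.0
        v[~self.open_v] = 0.0
        u[self.inlet_u] = u_in
        # zero-gradient outlet: copy the first interior face
        u[self.outlet_rows, self.oc + 1] = u[self.outlet_rows, self.oc]

    def _advect_diffuse(self, u: np.ndarray, v: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
        """Explicit advection + diffusion increments for u and v faces."""
        d, nu = self.d, self.props.nu

        def ghost(q_near, q_far, far_open):
            # quadratic ghost through the no-slip wall at the cell edge:
            # exact second derivative for a parabolic profile; falls back to
            # linear reflection when no second neighbour is available
            return np.where(far_open, (q_far - 6.0 * q_near) / 3.0, -q_near)

        def neighbors_y(q, open_q):
            # tangential neighbour across a wall uses the no-slip ghost
            pad = np.zeros((1, q.shape[1]))
            padm = np.zeros((1, q.shape[1]), dtype=bool)
            q_up = np.vstack([q[1:], pad])          # q[j+1]
            q_dn = np.vstack([pad, q[:-1]])         # q[j-1]
            open_up = np.vstack([open_q[1:], padm])
            open_dn = np.vstack([padm, open_q[:-1]])
            qn = np.where(open_up, q_up, ghost(q, q_dn, open_dn))
            qs = np.where(open_dn, q_dn, ghost(q, q_up, open_up))
            return qn, qs

        def hybrid(a, q, qm, qp):
            """d(q)/dx along one axis: centred where cell Peclet < 2."""
            centred = (qp - qm) / (2 * d)
            up = np.where(a > 0, (q - qm) / d, (qp - q) / d)
            pe_ok = np.abs(a) * d / (2 * nu) <= 1.0
            return np.where(pe_ok, centred, up)

        # ---- u faces; normal-direction neighbours: closed faces hold zero
        uw = np.empty_like(u); uw[:, 1:] = u[:, :-1]; uw[:, 0] = 0.0
        ue = np.empty_like(u); ue[:, :-1] = u[:, 1:]; ue[:, -1] = 0.0
        un, us = neighbors_y(u, self.open_u)
        vbar = np.zeros_like(u)
        vbar[:, 1:-1] = 0.25 * (v[:-1, :-1] + v[:-1, 1:] + v[1:, :-1] + v[1:, 1:])
        lap_u = (ue - 2 * u + uw) / d ** 2 + (un - 2 * u + us) / d ** 2
        adv_u = u * hybrid(u, u, uw, ue) + vbar * hybrid(vbar, u, us, un)
        du = self.dt * (-adv_u + nu * lap_u)

        # ---- v faces
        vn = np.empty_like(v); vn[:-1, :] = v[1:, :]; vn[-1, :] = 0.0
        vs = np.empty_like(v); vs[1:, :] = v[:-1, :]; vs[0, :] = 0.0
        vw_t, ve_t = self._neighbors_x_v(v)
        ubar = np.zeros_like(v)
        ubar[1:-1, :] = 0.25 * (u[:-1, :-1] + u[:-1, 1:] + u[1:, :-1] + u[1:, 1:])
        lap_v = (ve_t - 2 * v + vw_t) / d ** 2 + (vn - 2 * v + vs) / d ** 2
        adv_v = ubar * hybrid(ubar, v, vw_t, ve_t) + v * hybrid(v, v, vs, vn)
        dv = self.dt * (-adv_v + nu * lap_v)
        return du, dv

    def _neighbors_x_v(self, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        open_v = self.open_v
        pad = np.zeros((v.shape[0], 1))
        padm = np.zeros((v.shape[0], 1), dtype=bool)
        v_e = np.hstack([v[:, 1:], pad])
        v_w = np.hstack([pad, v[:, :-1]])
        open_e = np.hstack([open_v[:, 1:], padm])
        open_w = np.hstack([padm, open_v[:, :-1]])

        def ghost(q_near, q_far, far_open):
            return np.where(far_open, (q_far - 6.0 * q_near) / 3.0, -q_near)

        ve = np.where(open_e, v_e, ghost(v, v_w, open_w))
        vw = np.where(open_w, v_w, ghost(v, v_e, open_e))
        return vw, ve

    # -- one projection step ----------------------------------------------

    def step(self, u_in: float) -> None:
        st = self.state
        u, v = st.u, st.v
        self._apply_bc(u, v, u_in)
        du, dv = self._advect_diffuse(u, v)
        u_star = u + du
        v_star = v + dv
        if self.drag_u is not None:
            u_star = u_star * self.drag_u
            v_star = v_star * self.drag_v
        u_star[~self.open_u] = 0.0
        v_star[~self.open_v] = 0.0
        u_star[self.inlet_u] = u_in
        u_star[self.outlet_rows, self.oc + 1] = u_star[self.outlet_rows, self.oc]

        div = self._divergence(u_star, v_star)
        rhs = -div[self.grid.fluid_mask]
        phi_vec = self.lu.solve(rhs)
        phi = np.zeros_like(div)
        phi[self.grid.fluid_mask] = phi_vec

        du_fac = np.ones_like(u_star) if self.drag_u is None else self.drag_u
        dv_fac = np.ones_like(v_star) if self.drag_v is None else self.drag_v
        u_new = u_star.copy()
        grad_x = du_fac[:, 1:-1] * (phi[:, 1:] - phi[:, :-1]) / self.d
        interior = self.open_u_int[:, 1:-1]
        u_new[:, 1:-1][interior] -= grad_x[interior]
        u_new[self.outlet_rows, self.oc + 1] += (
            du_fac[self.outlet_rows, self.oc + 1]
            * phi[self.outlet_rows, self.oc] / self.d)
        v_new = v_star.copy()
        grad_y = dv_fac[1:-1, :] * (phi[1:, :] - phi[:-1, :]) / self.d
        interior_v = self.open_v[1:-1, :]
        v_new[1:-1, :][interior_v] -= grad_y[interior_v]

        res = self._divergence(u_new, v_new)
        scale = max(np.abs(self.gu * u_new).max() / self.d, 1e-30)
        rel = np.abs(res[self.grid.fluid_mask]).max() / scale
        if rel > self.cfg.pressure_tolerance:
            raise RuntimeError(f"pressure projection residual {rel:.2e} exceeds "
                               f"tolerance {self.cfg.pressure_tolerance:.2e}")
        self.max_divergence = max(self.max_divergence, rel)

        vmax = max(np.abs(u_new).max(), np.abs(v_new).max())
        if u_in > 0 and vmax > 1e6 * abs(u_in):
            raise RuntimeError("solver instability detected: velocity magnitude "
                               f"{vmax:.3e} m/s exceeds 1e6 x inlet velocity")

        st.u, st.v = u_new, v_new
        st.p = self.props.density * phi / self.dt
        st.time += self.dt

    # -- diagnostics -------------------------------------------------------

    def fluxes(self) -> tuple[float, float]:
        """Inlet and outlet volume fluxes (m^3/s in plan, m^2/s in section)."""
        u = self.state.u
        fin = float((self.gu[:, self.ic] * u[:, self.ic]).sum() * self.d)
        fout = float((self.gu[:, self.oc + 1] * u[:, self.oc + 1]).sum() * self.d)
        return fin, fout

    def pressure_drop(self, u_in: float) -> float:
        """Area-averaged inlet total pressure minus outlet total pressure (Pa)."""
        st, rho = self.state, self.props.density
        p_in = float(st.p[self.inlet_rows, self.ic].mean())
        p_out = float(st.p[self.outlet_rows, self.oc].mean())
        u_out = float(np.abs(st.u[self.outlet_rows, self.oc + 1]).mean())
        return (p_in + 0.5 * rho * u_in ** 2) - (p_out + 0.5 * rho * u_out ** 2)


# ---------------------------------------------------------------------------
# Module-level operations


def _cell_center_velocity(state: FlowState) -> tuple[np.ndarray, np.ndarray]:
    uc = 0.5 * (state.u[:, :-1] + state.u[:, 1:])
    vc = 0.5 * (state.v[:-1, :] + state.v[1:, :])
    return uc, vc


def wall_shear_extract(state: FlowState, grid: DomainGrid,
                       props: FluidProps) -> np.ndarray:
    """Wall-shear vectors (Pa) on the culture-surface cells.

    Plan mode reconstructs the local parabolic profile across the gap:
    ``tau = 6 mu u_bar / h`` componentwise.  Section mode differentiates
    the resolved profile at the floor with a second-order one-sided stencil
    (exact for a parabola).
    """
    mu = props.viscosity
    if grid.mode == "plan":
        uc, vc = _cell_center_velocity(state)
        h = grid.height_map * 1e-3
        jj, ii = np.where(grid.culture_mask)
        if (grid.solid_mask[jj, ii]).any():
            raise ValueError("wall shear requested on a solid cell")
        tau = np.empty((len(jj), 2))
        tau[:, 0] = 6.0 * mu * uc[jj, ii] / h[jj, ii]
        tau[:, 1] = 6.0 * mu * vc[jj, ii] / h[jj, ii]
        return tau
    # section: floor row, tau_x = mu du/dz via quadratic through no-slip wall
    d = grid.cell_size * 1e-3
    uc = 0.5 * (state.u[:, :-1] + state.u[:, 1:])
    jj, ii = np.where(grid.culture_mask)
    if (jj != 0).any():
        raise ValueError("section-mode culture cells must lie on the floor row")
    u1 = uc[0, ii]
    u2 = uc[1, ii] if grid.n_y > 1 else np.zeros_like(u1)
    dudz = (9.0 * u1 - u2) / (3.0 * d)
    tau = np.zeros((len(ii), 2))
    tau[:, 0] = mu * dudz
    return tau


def local_reynolds_map(state: FlowState, grid: DomainGrid,
                       props: FluidProps) -> np.ndarray:
    """Per-cell Re = rho |u| h_local / mu with the local gap as length scale."""
    uc, vc = _cell_center_velocity(state)
    speed = np.hypot(uc, vc)
    if grid.mode == "plan":
        h = grid.height_map * 1e-3
    else:
        open_height = grid.fluid_mask.sum(axis=0) * grid.cell_size * 1e-3
        h = np.broadcast_to(open_height, speed.shape).copy()
        h[grid.solid_mask] = 0.0
    re = props.density * speed * h / props.viscosity
    re[grid.solid_mask] = 0.0
    return re


def step(state: FlowState, grid: DomainGrid, props: FluidProps,
         inlet_velocity: float, dt: float,
         cfg: SolverConfig | None = None) -> FlowState:
    """Advance one projection step (functional wrapper around FlowSolver)."""
    cfg = cfg or SolverConfig()
    solver = FlowSolver(grid, props, cfg, dt)
    solver.state = FlowState(u=state.u.copy(), v=state.v.copy(),
                             p=state.p.copy(), time=state.time)
    solver.step(inlet_velocity)
    return solver.state


def stable_dt(grid: DomainGrid, props: FluidProps, cfg: SolverConfig,
              u_max: float) -> float:
    """CFL-derived time step for the explicit scheme (capped at cfg.dt_max)."""
    d = grid.cell_size * 1e-3
    dt_adv = d / max(u_max, 1e-12)
    dt_diff = d ** 2 / (4.0 * props.nu)
    return min(cfg.cfl_limit * min(dt_adv, dt_diff), cfg.dt_max)


def _inlet_scale(grid: DomainGrid, solver: FlowSolver,
                 waveform: WaveformSeries, inlet_diameter_mm: float) -> float:
    """Convert tube velocity (mm/s) to the plug BC velocity (m/s).

    Plan mode matches the volumetric flow rate: the tube of diameter D
    carries Q = v * pi D^2/4, pushed through the rasterized inlet area.
    Section mode imposes the tube velocity directly (per-unit-width slice).
    """
    if grid.mode == "section":
        return 1e-3
    a_tube = np.pi * (inlet_diameter_mm * 1e-3) ** 2 / 4.0
    a_in = float(solver.gu[:, solver.ic].sum() * solver.d)
    return 1e-3 * a_tube / a_in


def run_transient(grid: DomainGrid, waveform: WaveformSeries,
                  props: FluidProps, cfg: SolverConfig | None = None,
                  inlet_diameter_mm: float = 1.0) -> RunResult:
    """Run a transient simulation through the full waveform window.

    A converged steady solve at the waveform mean initialises the field
    (relative change of area-averaged floor shear below ``cfg.steady_tol``
    between successive windows); the solver then advances through every
    cycle, recording wall-shear vectors on the culture surface every
    ``snapshot_stride`` steps.  The returned history spans the whole run;
    its final full cycle is the metric-evaluation window.
    """
    cfg = cfg or SolverConfig()
    T = waveform.period
    n_cycles = waveform.duration / T
    if abs(n_cycles - round(n_cycles)) > 1e-9 or round(n_cycles) < 3:
        raise ValueError("waveform must span an integer number (>= 3) of cycles")
    n_cycles = int(round(n_cycles))

    v_peak = float(waveform.velocities.max()) * 1e-3
    # internal speeds exceed the inlet plug where the flow squeezes through
    # narrow gaps; budget a 4x margin when choosing the step
    probe = FlowSolver(grid, props, cfg, 1.0)
    scale = _inlet_scale(grid, probe, waveform, inlet_diameter_mm)
    u_bc_peak = v_peak / 1e-3 * scale
    dt0 = stable_dt(grid, props, cfg, 4.0 * max(u_bc_peak, v_peak))
    steps_per_cycle = int(np.ceil(T / dt0))
    # snap so the snapshot stride divides the cycle exactly
    stride = cfg.snapshot_stride
    steps_per_cycle = int(np.ceil(steps_per_cycle / stride)) * stride
    dt = T / steps_per_cycle

    solver = FlowSolver(grid, props, cfg, dt)
    mu = props.viscosity

    def floor_shear_avg() -> float:
        tau = wall_shear_extract(solver.state, grid, props)
        return float(np.linalg.norm(tau, axis=1).mean())

    # steady initialisation at the waveform mean
    u_in_mean = waveform.mean_velocity * scale
    prev = None
    window = 100
    for it in range(cfg.steady_max_steps):
        solver.step(u_in_mean)
        if (it + 1) % window == 0:
            cur = floor_shear_avg()
            if prev is not None and abs(cur - prev) <= cfg.steady_tol * max(cur, 1e-30):
                break
            prev = cur
    solver.state.time = 0.0

    n_steps = steps_per_cycle * n_cycles
    n_snap = n_steps // stride + 1
    jj, ii = np.where(grid.culture_mask)
    xy = np.column_stack([grid.x_centers()[ii], grid.y_centers()[jj]])
    tau_hist = np.empty((n_snap, len(jj), 2))
    times = np.empty(n_snap)
    vel_in = np.empty(n_snap)
    dp = np.empty(n_snap)
    fin = np.empty(n_snap)
    fout = np.empty(n_snap)
    max_re = 0.0
    fields: list[FlowState] = []

    def record(k: int, t: float, v_tube: float) -> None:
        tau_hist[k] = wall_shear_extract(solver.state, grid, props)
        times[k] = t
        vel_in[k] = v_tube
        dp[k] = solver.pressure_drop(v_tube * scale)
        fin[k], fout[k] = solver.fluxes()

    v0 = float(waveform(0.0))
    record(0, 0.0, v0)
    k = 1
    for n in range(1, n_steps + 1):
        t = n * dt
        v_tube = float(waveform(t))
        solver.step(v_tube * scale)
        if n % stride == 0:
            record(k, t, v_tube)
            re_map = local_reynolds_map(solver.state, grid, props)
            max_re = max(max_re, float(re_map.max()))
            if cfg.store_fields and n > n_steps - steps_per_cycle:
                fields.append(FlowState(u=solver.state.u.copy(),
                                        v=solver.state.v.copy(),
                                        p=solver.state.p.copy(), time=t))
            k += 1

    history = ShearHistory(times=times, tau=tau_hist,
                           cell_indices=np.column_stack([jj, ii]),
                           cell_xy=xy, cycle_period=T,
                           cell_area=grid.cell_size ** 2,
                           inlet_velocity=vel_in)
    return RunResult(grid=grid, history=history, pressure_drop=dp,
                     times=times, inlet_velocity=vel_in, max_local_re=max_re,
                     final_state=solver.state,
                     max_divergence=solver.max_divergence,
                     inlet_flux=fin, outlet_flux=fout, fields=fields)
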