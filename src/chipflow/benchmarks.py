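"""Analytic flow benchmarks and synthetic wall-shear histories.

This is the verification backbone: every downstream stage (metrics, solver
modes) can be exercised against closed forms without running the full
study.

Analytic benchmarks
    * ``plane_poiseuille`` — steady flow between parallel plates a gap ``h``
      apart: parabolic profile, floor shear ``6 mu u_bar / h``, pressure
      gradient ``-12 mu u_bar / h^2``.
    * ``hele_shaw_strip`` — depth-averaged strip of uniform gap: same
      closed forms for the depth-averaged field, plus the lateral Brinkman
      boundary-layer profile between the side walls.
    * ``womersley_channel`` — oscillatory laminar channel flow driven at a
      prescribed cross-section mean velocity.  The complex closed form
      (cosh/tanh of ``sqrt(i omega / nu) h/2``) is exact, so there is no
      series-truncation error to budget.

Synthetic shear histories
    Per-cell wall-shear vector time series whose TAWSS and OSI are known
    in closed form.  Direction reversal is built from an antisymmetric
    lobe construction: the cycle is divided into ``n_lobes`` equal
    raised-cosine lobes and ``reversal_fraction`` maps to the number of
    lobes whose direction is flipped, which gives OSI = k / n_lobes
    exactly.  Sample points are aligned with lobe boundaries (and
    discontinuities of piecewise-constant magnitudes are emitted as
    duplicated time samples), so trapezoid quadrature on the samples
    reproduces the closed-form integrals to round-off.

Randomness lives only here; a single seed fully determines every output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .solver import FluidProps, ShearHistory

__all__ = [
    "AnalyticBenchmark",
    "SyntheticShearSpec",
    "SyntheticShearResult",
    "make_benchmark",
    "generate_shear_history",
    "womersley_shear_transfer",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 20260108


@dataclass(frozen=True)
class AnalyticBenchmark:
    """Closed-form evaluators for one verification flow (pure functions)."""

    name: str
    params: dict
    velocity_profile: Callable      # position (m) [, time (s)] -> m/s
    wall_shear: Callable            # [time] -> Pa (floor shear)
    pressure_gradient: Callable     # [time] -> Pa/m
    womersley_number: float = 0.0


def womersley_shear_transfer(height_m: float, omega: float,
                             props: FluidProps) -> complex:
    """Complex transfer H = tau_hat / v_hat for oscillatory channel flow.

    ``v_hat`` is the complex amplitude of the cross-section mean velocity
    at angular frequency ``omega``; ``tau_hat`` the floor shear amplitude.
    The quasi-static limit recovers H -> 6 mu / h.
    """
    a = height_m / 2.0
    lam = np.sqrt(1j * omega / props.nu)
    t = np.tanh(lam * a)
    return props.viscosity * lam * t / (1.0 - t / (lam * a))


def make_benchmark(name: str, params: dict | None = None) -> AnalyticBenchmark:
    """Build one of the named analytic benchmarks.

    Common parameters (with defaults): ``height_mm`` (1.0), ``u_mean_mm_s``
    (3.61), ``props`` (culture medium); ``womersley_channel`` additionally
    takes ``frequency_hz`` (0.4) and oscillation fraction ``beta`` (0.7);
    ``hele_shaw_strip`` takes ``width_mm`` (4.0).
    """
    p = dict(params or {})
    props: FluidProps = p.setdefault("props", FluidProps())
    h = p.setdefault("height_mm", 1.0) * 1e-3
    ub = p.setdefault("u_mean_mm_s", 3.61) * 1e-3
    mu = props.viscosity
    if h <= 0 or ub <= 0:
        raise ValueError("height and mean velocity must be positive")

    if name == "plane_poiseuille":
        def profile(z):
            return 6.0 * ub * (z / h) * (1.0 - z / h)

        return AnalyticBenchmark(
            name=name, params=p,
            velocity_profile=profile,
            wall_shear=lambda: 6.0 * mu * ub / h,
            pressure_gradient=lambda: -12.0 * mu * ub / h ** 2)

    if name == "hele_shaw_strip":
        w = p.setdefault("width_mm", 4.0) * 1e-3
        kappa = np.sqrt(12.0) / h   # lateral Brinkman decay rate

        def profile(y):
            # depth-averaged speed across the strip width, y in (-w/2, w/2),
            # normalised so the flat core carries u_bar
            return ub * (1.0 - np.cosh(kappa * y) / np.cosh(kappa * w / 2.0))

        return AnalyticBenchmark(
            name=name, params=p,
            velocity_profile=profile,
            wall_shear=lambda: 6.0 * mu * ub / h,
            pressure_gradient=lambda: -12.0 * mu * ub / h ** 2)

    if name == "womersley_channel":
        f = p.setdefault("frequency_hz", 0.4)
        beta = p.setdefault("beta", 0.7)
        if f <= 0:
            raise ValueError("frequency must be positive")
        omega = 2.0 * np.pi * f
        alpha = (h / 2.0) * np.sqrt(omega / props.nu)
        lam = np.sqrt(1j * omega / props.nu)
        a = h / 2.0
        H = womersley_shear_transfer(h, omega, props)

        def profile(z, t):
            # mean velocity v(t) = ub (1 + beta cos wt); z measured from floor
            y = z - a
            shape = (1.0 - np.cosh(lam * y) / np.cosh(lam * a)) \
                / (1.0 - np.tanh(lam * a) / (lam * a))
            osc = beta * ub * np.real(shape * np.exp(1j * omega * t))
            steady = 6.0 * ub * (z / h) * (1.0 - z / h)
            return steady + osc

        def wall_shear(t):
            osc = beta * ub * np.real(H * np.exp(1j * omega * t))
            return 6.0 * mu * ub / h + osc

        def pressure_gradient(t):
            # dp/dx = -rho i w G-term; from the momentum balance at the wall
            g_osc = (1j * omega * props.density * beta * ub
                     / (1.0 - np.tanh(lam * a) / (lam * a)))
            return float(-12.0 * mu * ub / h ** 2
                         - np.real(g_osc * np.exp(1j * omega * t)))

        return AnalyticBenchmark(
            name=name, params=p,
            velocity_profile=profile,
            wall_shear=wall_shear,
            pressure_gradient=pressure_gradient,
            womersley_number=float(alpha))

    raise ValueError(f"unknown benchmark {name!r}")


# ---------------------------------------------------------------------------
# Synthetic shear histories


@dataclass(frozen=True)
class SyntheticShearSpec:
    """Recipe for a reproducible synthetic wall-shear history.

    ``reversal_fraction`` r in [0, 1] controls directional reversal:
    r = 0 is purely unidirectional (OSI 0), r = 1 perfectly antisymmetric
    (OSI 0.5).  For the lobed raised-cosine construction r is quantised to
    the nearest k / (n_lobes/2); the actually realised fraction and the
    exact metric ground truth are reported with the result.
    """

    n_cells: int = 16
    period: float = 1.0
    magnitude_waveform: str = "raised_cosine"   # constant|raised_cosine|sinusoid
    amplitude: float = 0.02                     # Pa scale
    reversal_fraction: float = 0.0
    direction_jitter: float = 0.0               # degrees, per-cell rotation
    n_lobes: int = 8
    samples_per_lobe: int = 64
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.period <= 0 or self.amplitude <= 0:
            raise ValueError("n_cells, period and amplitude must be positive")
        if not 0.0 <= self.reversal_fraction <= 1.0:
            raise ValueError("reversal_fraction must lie in [0, 1]")
        if self.magnitude_waveform not in ("constant", "raised_cosine", "sinusoid"):
            raise ValueError(f"unknown magnitude_waveform "
                             f"{self.magnitude_waveform!r}")
        if self.magnitude_waveform == "sinusoid" and self.reversal_fraction > 0:
            raise ValueError("the smooth sinusoid magnitude does not support "
                             "direction reversal; use raised_cosine or constant")
        if self.n_lobes % 2 or self.n_lobes < 2:
            raise ValueError("n_lobes must be even and >= 2")


@dataclass
class SyntheticShearResult:
    """Generated history plus its exact per-cell metric ground truth."""

    history: ShearHistory
    tawss: np.ndarray            # (n_cells,) Pa
    osi: np.ndarray              # (n_cells,)
    realised_reversal_fraction: float


def generate_shear_history(spec: SyntheticShearSpec) -> SyntheticShearResult:
    rng = np.random.default_rng(spec.seed)
    nc, T, K = spec.n_cells, spec.period, spec.n_lobes
    amp = spec.amplitude * rng.uniform(0.5, 1.5, size=nc)
    base_angle = rng.uniform(0.0, 2.0 * np.pi)
    jitter = np.radians(spec.direction_jitter) * rng.standard_normal(nc)
    angles = base_angle + jitter
    dirs = np.column_stack([np.cos(angles), np.sin(angles)])

    k_flip = int(round(spec.reversal_fraction * K / 2.0))
    realised = 2.0 * k_flip / K

    if spec.magnitude_waveform == "constant":
        # piecewise-constant signal; the flip instant is emitted twice so
        # the trapezoid rule integrates the jump exactly
        q = realised / 2.0
        t_flip = T * (1.0 - q)
        if k_flip == 0:
            t = np.linspace(0.0, T, K * spec.samples_per_lobe + 1)
            sign = np.ones_like(t)
        else:
            n1 = max(int(round((1.0 - q) * K * spec.samples_per_lobe)), 1)
            n2 = max(int(round(q * K * spec.samples_per_lobe)), 1)
            t = np.concatenate([np.linspace(0.0, t_flip, n1 + 1),
                                np.linspace(t_flip, T, n2 + 1)])
            sign = np.concatenate([np.ones(n1 + 1), -np.ones(n2 + 1)])
        mag = np.ones_like(t)
        tawss = amp.copy()
        osi = np.full(nc, 0.5 * (1.0 - abs(1.0 - 2.0 * q)))
    elif spec.magnitude_waveform == "raised_cosine":
        w = T / K
        t = np.linspace(0.0, T, K * spec.samples_per_lobe + 1)
        mag = (1.0 - np.cos(2.0 * np.pi * np.mod(t, w) / w)) / 2.0
        mag[-1] = 0.0
        lobe = np.minimum((t // w).astype(int), K - 1)
        sign = np.where(lobe >= K - k_flip, -1.0, 1.0)
        tawss = amp / 2.0
        osi = np.full(nc, k_flip / K)
    else:  # sinusoid, no reversal: m(t) = amp (1 + 0.5 sin wt)
        t = np.linspace(0.0, T, K * spec.samples_per_lobe + 1)
        mag = 1.0 + 0.5 * np.sin(2.0 * np.pi * t / T)
        sign = np.ones_like(t)
        tawss = amp.copy()
        osi = np.zeros(nc)

    signed = mag * sign
    tau = amp[None, :, None] * signed[:, None, None] * dirs[None, :, :]
    xy = np.column_stack([np.arange(nc, dtype=float), np.zeros(nc)])
    idx = np.column_stack([np.zeros(nc, dtype=int), np.arange(nc)])
    history = ShearHistory(times=t, tau=tau, cell_indices=idx, cell_xy=xy,
                           cycle_period=T, cell_area=1.0)
    return SyntheticShearResult(history=history, tawss=tawss, osi=osi,
                                realised_reversal_fraction=realised)
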