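"""Wall-shear stress metrics on the culture surface.

Given a per-cell wall-shear vector history over one perfusion cycle of
duration T:

    TAWSS = (1/T) integral |tau| dt                       (Pa)
    OSI   = 1/2 (1 - |integral tau dt| / integral |tau| dt)
    RRT   = 1 / ((1 - 2 OSI) * TAWSS)                     (1/Pa)

OSI is 0 for purely unidirectional shear and 0.5 for fully oscillatory
shear with zero net direction; RRT is a near-wall residence surrogate that
grows where shear is weak or strongly reversing.  Surface-level summaries
follow the population statistics over the N culture-surface cells:
mean, SD (divisor N), CV = SD/mean, and the uniformity index
U% = (1 - CV) * 100.

All time integrals use the trapezoid rule on the stored snapshots of the
final full pump cycle, so initialisation transients are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .solver import ShearHistory, RunResult

__all__ = [
    "MetricsMap",
    "SurfaceSummary",
    "tawss",
    "osi",
    "rrt",
    "compute_metrics",
    "surface_summary",
    "area_weighted_wss",
    "phase_matched_comparison",
    "RRT_CAP",
]

#: RRT reported when (1 - 2 OSI) * TAWSS falls below the denominator floor.
RRT_EPS = 1e-12
RRT_CAP = 1.0 / RRT_EPS


@dataclass
class MetricsMap:
    """Per-cell TAWSS (Pa), OSI (-), RRT (1/Pa) over one evaluation period."""

    tawss: np.ndarray
    osi: np.ndarray
    rrt: np.ndarray
    capped: np.ndarray           # True where the RRT denominator was floored
    cell_xy: np.ndarray
    cell_indices: np.ndarray
    evaluation_period: float
    cell_area: float

    def __post_init__(self) -> None:
        if (self.tawss < -1e-15).any():
            raise ValueError("TAWSS must be non-negative")
        if ((self.osi < -1e-12) | (self.osi > 0.5 + 1e-12)).any():
            raise ValueError("OSI must lie in [0, 0.5]")


@dataclass
class SurfaceSummary:
    mean_tawss: float
    sd_tawss: float
    cv: float
    uniformity_percent: float
    mean_osi: float
    mean_rrt: float
    rrt_quartiles: tuple[float, float, float]
    n_cells: int
    area_weighted_wss_series: np.ndarray | None = None

    def to_frame(self):
        import pandas as pd

        q1, q2, q3 = self.rrt_quartiles
        return pd.DataFrame([{
            "mean_tawss_pa": self.mean_tawss, "sd_tawss_pa": self.sd_tawss,
            "cv": self.cv, "uniformity_percent": self.uniformity_percent,
            "mean_osi": self.mean_osi, "mean_rrt_inv_pa": self.mean_rrt,
            "rrt_q25_inv_pa": q1, "rrt_median_inv_pa": q2,
            "rrt_q75_inv_pa": q3, "n_cells": self.n_cells,
        }])


def _check_single_cycle(history: ShearHistory) -> float:
    span = history.times[-1] - history.times[0]
    if history.tau.shape[0] < 2:
        raise ValueError("history is empty or has a single sample")
    if abs(span - history.cycle_period) > 1e-9 * max(history.cycle_period, 1.0):
        raise ValueError("metric window must span exactly one cycle period; "
                         "pass history.last_cycle()")
    return span


def tawss(history: ShearHistory, cell: int | None = None) -> np.ndarray | float:
    """Time-averaged magnitude of the wall-shear vector, Pa."""
    T = _check_single_cycle(history)
    mag = history.magnitude()
    out = np.trapezoid(mag, history.times, axis=0) / T
    return float(out[cell]) if cell is not None else out


def osi(history: ShearHistory, cell: int | None = None) -> np.ndarray | float:
    """Oscillatory shear index in [0, 0.5]; all-zero histories give 0."""
    T = _check_single_cycle(history)
    vec = np.trapezoid(history.tau, history.times, axis=0)
    num = np.linalg.norm(vec, axis=1)
    den = np.trapezoid(history.magnitude(), history.times, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 0.5 * (1.0 - num / den)
    out[den == 0.0] = 0.0
    out = np.clip(out, 0.0, 0.5)    # guard round-off at the limits
    return float(out[cell]) if cell is not None else out


def rrt(tawss_value, osi_value):
    """Relative residence time 1/((1-2 OSI) TAWSS), capped at the
    denominator floor; returns (rrt, capped_flag) arrays or scalars."""
    t = np.asarray(tawss_value, dtype=float)
    o = np.asarray(osi_value, dtype=float)
    if (t < 0).any():
        raise ValueError("TAWSS must be >= 0")
    if ((o < 0) | (o > 0.5)).any():
        raise ValueError("OSI must lie in [0, 0.5]")
    den = (1.0 - 2.0 * o) * t
    capped = den <= RRT_EPS
    out = np.where(capped, RRT_CAP, 1.0 / np.where(capped, 1.0, den))
    if np.isscalar(tawss_value) and np.isscalar(osi_value):
        return float(out), bool(capped)
    return out, capped


def compute_metrics(history: ShearHistory) -> MetricsMap:
    """TAWSS/OSI/RRT map from the final full cycle of a shear history."""
    last = history.last_cycle()
    t = tawss(last)
    o = osi(last)
    r, capped = rrt(t, o)
    return MetricsMap(tawss=t, osi=o, rrt=r, capped=capped,
                      cell_xy=history.cell_xy,
                      cell_indices=history.cell_indices,
                      evaluation_period=history.cycle_period,
                      cell_area=history.cell_area)


def surface_summary(metrics: MetricsMap,
                    roi_radius: float | None = None,
                    area_weighted_series: np.ndarray | None = None
                    ) -> SurfaceSummary:
    """Population statistics over culture-surface cells inside the ROI.

    Cells are weighted equally (uniform grid), so area weighting reduces
    to the arithmetic mean.  RRT-capped cells are excluded from the mean
    RRT and its quartiles.
    """
    sel = np.ones(metrics.tawss.shape[0], dtype=bool)
    if roi_radius is not None:
        rr = np.linalg.norm(metrics.cell_xy, axis=1)
        sel = rr <= roi_radius
    if not sel.any():
        raise ValueError("ROI contains no culture-surface cells")
    t = metrics.tawss[sel]
    mean = float(t.mean())
    sd = float(t.std(ddof=0))
    cv = sd / mean if mean > 0 else np.inf
    r_ok = metrics.rrt[sel & ~metrics.capped]
    q = (np.percentile(r_ok, [25, 50, 75]) if r_ok.size
         else np.array([np.nan] * 3))
    return SurfaceSummary(
        mean_tawss=mean, sd_tawss=sd, cv=cv,
        uniformity_percent=(1.0 - cv) * 100.0,
        mean_osi=float(metrics.osi[sel].mean()),
        mean_rrt=float(r_ok.mean()) if r_ok.size else np.nan,
        rrt_quartiles=(float(q[0]), float(q[1]), float(q[2])),
        n_cells=int(sel.sum()),
        area_weighted_wss_series=area_weighted_series)


def area_weighted_wss(history: ShearHistory,
                      areas: np.ndarray | None = None) -> np.ndarray:
    """Area-weighted mean |tau| over the surface at each snapshot, Pa."""
    mag = history.magnitude()
    if areas is None:
        return mag.mean(axis=1)
    w = np.asarray(areas, dtype=float)
    return (mag * w).sum(axis=1) / w.sum()


def _flank_crossings(t: np.ndarray, v: np.ndarray,
                     target: float) -> tuple[float, float]:
    """Times where v crosses target on the rising and falling flanks."""
    if v.max() - v.min() < 1e-12 and abs(v[0] - target) < 1e-9:
        return float(t[0]), float(t[0])   # degenerate: constant at target
    rising = falling = None
    for k in range(len(t) - 1):
        a, b = v[k], v[k + 1]
        if rising is None and a <= target < b:
            rising = t[k] + (target - a) / (b - a) * (t[k + 1] - t[k])
        if a > target >= b and falling is None:
            falling = t[k] + (target - a) / (b - a) * (t[k + 1] - t[k])
    if rising is None or falling is None:
        raise ValueError("target velocity is not crossed on both flanks "
                         "of the final cycle")
    return float(rising), float(falling)


def phase_matched_comparison(pulsatile: RunResult, steady: RunResult,
                             target_velocity: float) -> tuple[float, float, float]:
    """Area-weighted WSS at matched instantaneous inflow velocity.

    Returns (acceleration, steady, deceleration): the pulsatile surface
    WSS interpolated to the instants on the rising and falling flanks of
    the final cycle where the inlet velocity equals ``target_velocity``
    (mm/s), bracketing the steady-run value at that same velocity.
    """
    hist = pulsatile.history.last_cycle()
    if hist.inlet_velocity is None:
        raise ValueError("pulsatile history lacks an inlet velocity record")
    v = hist.inlet_velocity
    if not (v.min() - 1e-12 <= target_velocity <= v.max() + 1e-12):
        raise ValueError("target velocity outside the pulsatile waveform range")
    wss = area_weighted_wss(hist)
    t_rise, t_fall = _flank_crossings(hist.times, v, target_velocity)
    w_rise = float(np.interp(t_rise, hist.times, wss))
    w_fall = float(np.interp(t_fall, hist.times, wss))
    s_hist = steady.history.last_cycle()
    w_steady = float(area_weighted_wss(s_hist)[-1])
    return w_rise, w_steady, w_fall
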