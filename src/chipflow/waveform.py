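"""Inlet velocity waveforms: steady perfusion and peristaltic pulse trains.

A roller pump does not deliver a smooth sinusoid: each roller pass produces
a short pulse, partly smoothed by the elastic tubing.  The pulsatile model
here is a train of raised-cosine pulses

    v(t) = b + A * (1 - cos(2*pi*t' / (d*T))) / 2      on the pulse support,
    v(t) = b                                           between pulses,

with pulse frequency f = RPM * rollers / 60, period T = 1/f, duty cycle d
(fraction of the period the pulse occupies) and baseline b.  The amplitude
A is solved in closed form so that the cycle average equals the mean
velocity implied by the target volumetric flow rate, which makes steady
and pulsatile conditions comparable at matched mean flow.

Velocities are mm/s, times seconds, flow rates uL/min.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WaveformSpec",
    "WaveformSeries",
    "mean_velocity_from_flow",
    "pulse_frequency",
    "build_peristaltic",
    "build_steady",
]


@dataclass(frozen=True)
class WaveformSpec:
    kind: str = "peristaltic"            # "steady" | "peristaltic"
    target_flow_rate: float = 170.0      # uL/min
    inlet_diameter: float = 1.0          # mm (circular inlet)
    pump_rpm: float = 30.0
    rollers: int = 2
    duty_cycle: float = 0.5
    baseline_fraction: float = 0.0
    n_cycles: int = 3

    def __post_init__(self) -> None:
        if self.kind not in ("steady", "peristaltic"):
            raise ValueError("kind must be 'steady' or 'peristaltic'")
        if self.target_flow_rate <= 0:
            raise ValueError("target_flow_rate must be positive")
        if self.inlet_diameter <= 0:
            raise ValueError("inlet_diameter must be positive")
        if self.rollers < 1:
            raise ValueError("rollers must be >= 1")
        if not 0.0 < self.duty_cycle <= 1.0:
            raise ValueError("duty_cycle must lie in (0, 1]")
        if not 0.0 <= self.baseline_fraction < 1.0:
            raise ValueError("baseline_fraction must lie in [0, 1)")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")

    @property
    def mean_velocity(self) -> float:
        return mean_velocity_from_flow(self.target_flow_rate, self.inlet_diameter)

    @property
    def period(self) -> float:
        return 1.0 / pulse_frequency(self.pump_rpm, self.rollers)


@dataclass(frozen=True)
class WaveformSeries:
    """Uniformly sampled inlet velocity v(t), mm/s, spanning whole periods."""

    times: np.ndarray
    velocities: np.ndarray
    period: float
    mean_velocity: float

    def __post_init__(self) -> None:
        if (self.velocities < -1e-15).any():
            raise ValueError("pump waveform cannot reverse (negative velocity)")
        tavg = self.time_average()
        if abs(tavg - self.mean_velocity) > 1e-9 * max(self.mean_velocity, 1e-30):
            raise ValueError("series average does not match declared mean")

    def time_average(self) -> float:
        span = self.times[-1] - self.times[0]
        return float(np.trapezoid(self.velocities, self.times) / span)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        """Linear interpolation, periodic continuation outside the window."""
        tt = self.times[0] + np.mod(np.asarray(t) - self.times[0],
                                    self.times[-1] - self.times[0])
        return np.interp(tt, self.times, self.velocities)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"time_s": self.times,
                      "velocity_mm_s": self.velocities}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, period: float | None = None) -> "WaveformSeries":
        import pandas as pd

        df = pd.read_csv(path)
        t = df["time_s"].to_numpy()
        v = df["velocity_mm_s"].to_numpy()
        span = t[-1] - t[0]
        mean = float(np.trapezoid(v, t) / span)
        return cls(times=t, velocities=v,
                   period=period if period is not None else span,
                   mean_velocity=mean)


def mean_velocity_from_flow(flow_rate: float, inlet_diameter: float) -> float:
    """Mean inlet velocity (mm/s) for a volumetric flow through a circular inlet.

    flow_rate in uL/min, inlet_diameter in mm.  170 uL/min through a 1 mm
    inlet gives 3.61 mm/s.
    """
    if flow_rate <= 0 or inlet_diameter <= 0:
        raise ValueError("flow_rate and inlet_diameter must be positive")
    q_mm3_s = flow_rate / 60.0          # 1 uL = 1 mm^3
    area = np.pi * inlet_diameter ** 2 / 4.0
    return q_mm3_s / area


def pulse_frequency(rpm: float, rollers: int) -> float:
    """Pulse repetition frequency (Hz): one pulse per roller pass."""
    if rpm <= 0 or rollers < 1:
        raise ValueError("rpm must be positive and rollers >= 1")
    return rpm * rollers / 60.0


def _series_times(period: float, n_cycles: int, dt: float,
                  duty_cycle: float = 1.0) -> np.ndarray:
    """Uniform sample grid spanning whole periods.

    The number of steps per cycle is nudged upward (never beyond doubling)
    so that the pulse edges fall exactly on sample points; the trapezoid
    rule is then exact for the raised-cosine pulse and the analytic
    amplitude reproduces the target mean to round-off.
    """
    base = max(int(round(period / dt)), 1)
    steps_per_cycle = base
    for m in range(base, 2 * base + 1):
        if abs(m * duty_cycle - round(m * duty_cycle)) < 1e-9:
            steps_per_cycle = m
            break
    n = steps_per_cycle * n_cycles
    return np.linspace(0.0, n_cycles * period, n + 1)


def build_peristaltic(spec: WaveformSpec, dt: float) -> WaveformSeries:
    """Raised-cosine pulse train with the cycle mean matched to the target flow.

    With duty cycle d and baseline b, each pulse contributes A*d/2 to the
    cycle average, so A = 2*(v_mean - b)/d exactly.  dt must resolve the
    pulse (dt <= T/200); the sample grid is snapped to an integer number of
    steps per period so the series spans whole cycles.
    """
    T = spec.period
    if dt > T / 200.0 + 1e-15:
        raise ValueError(f"dt={dt} too coarse; need dt <= period/200 = {T/200}")
    v_mean = spec.mean_velocity
    b = spec.baseline_fraction * v_mean
    A = 2.0 * (v_mean - b) / spec.duty_cycle
    if A < 0:
        raise ValueError("baseline exceeds the target mean; amplitude would be negative")
    t = _series_times(T, spec.n_cycles, dt, spec.duty_cycle)
    phase = np.mod(t, T)
    width = spec.duty_cycle * T
    v = np.full_like(t, b)
    on = phase < width * (1.0 - 1e-12)
    v[on] = b + A * (1.0 - np.cos(2.0 * np.pi * phase[on] / width)) / 2.0
    return WaveformSeries(times=t, velocities=v, period=T, mean_velocity=v_mean)


def build_steady(spec: WaveformSpec, dt: float,
                 duration: float | None = None) -> WaveformSeries:
    """Constant series at the target mean velocity.

    Spans the same physical window as ``n_cycles`` pulsatile periods unless
    an explicit duration is given, so steady and pulsatile runs cover
    identical time windows.
    """
    T = spec.period
    if duration is None:
        duration = spec.n_cycles * T
    n = max(int(round(duration / dt)), 1)
    t = np.linspace(0.0, duration, n + 1)
    v = np.full_like(t, spec.mean_velocity)
    return WaveformSeries(times=t, velocities=v, period=T,
                          mean_velocity=spec.mean_velocity)
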