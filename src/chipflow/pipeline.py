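"""Orchestration of the 3-geometry x 2-inflow perfusion study.

``run_study`` sweeps the requested chamber models (1 = flat control,
2 = large herringbone pillars, 3 = small pillars) and inflow modes
(steady / peristaltic) at a matched cycle-averaged flow rate, runs the
depth-averaged plan-view solver for the culture-surface metrics, and the
mid-plane section solver for the phase-resolved wall-shear comparison.
``trend_assertions`` then evaluates the study's headline ordinal claims
as a pass/fail ledger.

Every stage is deterministic: re-running the same configuration
reproduces all outputs bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .geometry import build_model, rasterize_plan, rasterize_section
from .metrics import (MetricsMap, SurfaceSummary, area_weighted_wss,
                      compute_metrics, phase_matched_comparison,
                      surface_summary)
from .solver import CULTURE_MEDIUM, FluidProps, RunResult, SolverConfig, run_transient
from .waveform import WaveformSpec, build_peristaltic, build_steady

__all__ = ["StudyConfig", "ConditionResult", "StudyReport",
           "run_study", "trend_assertions"]

log = logging.getLogger("chipflow")


@dataclass(frozen=True)
class StudyConfig:
    models: tuple[int, ...] = (1, 2, 3)
    inflow_modes: tuple[str, ...] = ("steady", "peristaltic")
    flow_rate: float = 170.0            # uL/min, cycle-averaged
    inlet_diameter: float = 1.0         # mm
    pump_rpm: float = 30.0
    rollers: int = 2
    duty_cycle: float = 0.5
    baseline_fraction: float = 0.0
    n_cycles: int = 3
    cell_size: float = 0.125            # mm, plan-view grid
    section_cell_size: float = 0.05     # mm, mid-plane grid
    include_phase_analysis: bool = True
    culture_surface_radius: float | None = None
    output_dir: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.models or not set(self.models) <= {1, 2, 3}:
            raise ValueError("models must be a non-empty subset of {1, 2, 3}")
        bad = set(self.inflow_modes) - {"steady", "peristaltic"}
        if not self.inflow_modes or bad:
            raise ValueError(f"unknown inflow modes {bad}")
        if self.flow_rate <= 0:
            raise ValueError("flow_rate must be positive")

    def waveform_spec(self, kind: str) -> WaveformSpec:
        return WaveformSpec(kind=kind, target_flow_rate=self.flow_rate,
                            inlet_diameter=self.inlet_diameter,
                            pump_rpm=self.pump_rpm, rollers=self.rollers,
                            duty_cycle=self.duty_cycle,
                            baseline_fraction=self.baseline_fraction,
                            n_cycles=self.n_cycles)


@dataclass
class ConditionResult:
    model: int
    inflow: str
    metrics: MetricsMap
    summary: SurfaceSummary
    aw_wss_times: np.ndarray
    aw_wss: np.ndarray                 # over the final cycle
    max_pressure_drop: float
    max_local_re: float
    mean_inlet_flow: float             # cycle-averaged, m^3/s
    run: RunResult


@dataclass
class StudyReport:
    config: StudyConfig
    conditions: dict[tuple[int, str], ConditionResult]
    phase_triples: dict[int, tuple[float, float, float]]
    failed: dict[tuple[int, str], str] = field(default_factory=dict)

    def summary_table(self):
        import pandas as pd

        rows = []
        for (m, mode), c in sorted(self.conditions.items()):
            s = c.summary
            q1, q2, q3 = s.rrt_quartiles
            rows.append({
                "model": m, "inflow": mode,
                "mean_tawss_pa": s.mean_tawss, "sd_tawss_pa": s.sd_tawss,
                "uniformity_percent": s.uniformity_percent,
                "mean_osi": s.mean_osi, "mean_rrt_inv_pa": s.mean_rrt,
                "rrt_q25": q1, "rrt_median": q2, "rrt_q75": q3,
                "max_tawss_pa": float(c.metrics.tawss.max()),
                "max_pressure_drop_pa": c.max_pressure_drop,
                "max_local_re": c.max_local_re,
                "cycle_avg_aw_wss_pa": float(np.trapezoid(c.aw_wss, c.aw_wss_times)
                                             / (c.aw_wss_times[-1] - c.aw_wss_times[0])),
            })
        return pd.DataFrame(rows)

    def phase_table(self):
        import pandas as pd

        return pd.DataFrame(
            [{"model": m, "accel_wss_pa": a, "steady_wss_pa": s,
              "decel_wss_pa": d} for m, (a, s, d) in
             sorted(self.phase_triples.items())])


def _run_condition(cfg: StudyConfig, model: int, mode: str,
                   props: FluidProps, solver_cfg: SolverConfig
                   ) -> ConditionResult:
    spec = build_model(model)
    if cfg.culture_surface_radius is not None:
        from dataclasses import replace

        spec = replace(spec, culture_surface_radius=cfg.culture_surface_radius)
    grid = rasterize_plan(spec, cfg.cell_size)
    wspec = cfg.waveform_spec(mode)
    dt_w = wspec.period / 400.0
    wf = (build_steady(wspec, dt_w) if mode == "steady"
          else build_peristaltic(wspec, dt_w))
    res = run_transient(grid, wf, props, solver_cfg,
                        inlet_diameter_mm=cfg.inlet_diameter)
    met = compute_metrics(res.history)
    last = res.history.last_cycle()
    aw = area_weighted_wss(last)
    summ = surface_summary(met, area_weighted_series=aw)
    q_mean = wspec.mean_velocity * 1e-3 * np.pi * (cfg.inlet_diameter * 1e-3) ** 2 / 4
    return ConditionResult(model=model, inflow=mode, metrics=met,
                           summary=summ, aw_wss_times=last.times, aw_wss=aw,
                           max_pressure_drop=float(res.pressure_drop.max()),
                           max_local_re=res.max_local_re,
                           mean_inlet_flow=q_mean, run=res)


def _phase_analysis(cfg: StudyConfig, model: int, props: FluidProps,
                    solver_cfg: SolverConfig) -> tuple[float, float, float]:
    spec = build_model(model)
    grid = rasterize_section(spec, cfg.section_cell_size)
    wspec_p = cfg.waveform_spec("peristaltic")
    wspec_s = cfg.waveform_spec("steady")
    dt_w = wspec_p.period / 400.0
    rp = run_transient(grid, build_peristaltic(wspec_p, dt_w), props,
                       solver_cfg, inlet_diameter_mm=cfg.inlet_diameter)
    rs = run_transient(grid, build_steady(wspec_s, dt_w), props,
                       solver_cfg, inlet_diameter_mm=cfg.inlet_diameter)
    return phase_matched_comparison(rp, rs, wspec_p.mean_velocity)


def run_study(config: StudyConfig,
              props: FluidProps = CULTURE_MEDIUM,
              solver_cfg: SolverConfig | None = None) -> StudyReport:
    """Run every requested condition and assemble the report.

    A failing condition is recorded in ``report.failed`` with its
    diagnostic instead of being silently dropped.
    """
    logging.basicConfig(level=config.log_level)
    solver_cfg = solver_cfg or SolverConfig()
    conditions: dict[tuple[int, str], ConditionResult] = {}
    failed: dict[tuple[int, str], str] = {}
    for model in config.models:
        for mode in config.inflow_modes:
            log.info("running model %d, %s inflow", model, mode)
            try:
                conditions[(model, mode)] = _run_condition(
                    config, model, mode, props, solver_cfg)
            except Exception as exc:   # noqa: BLE001 - report, don't drop
                log.error("condition (%d, %s) failed: %s", model, mode, exc)
                failed[(model, mode)] = str(exc)

    phase: dict[int, tuple[float, float, float]] = {}
    if (config.include_phase_analysis
            and {"steady", "peristaltic"} <= set(config.inflow_modes)):
        for model in config.models:
            log.info("phase analysis, model %d (section mode)", model)
            try:
                phase[model] = _phase_analysis(config, model, props, solver_cfg)
            except Exception as exc:   # noqa: BLE001
                log.error("phase analysis for model %d failed: %s", model, exc)
                failed[(model, "phase")] = str(exc)

    report = StudyReport(config=config, conditions=conditions,
                         phase_triples=phase, failed=failed)
    if config.output_dir:
        _write_outputs(report)
    return report


def _write_outputs(report: StudyReport) -> None:
    import pandas as pd

    from .io import write_vtk_cells

    out = Path(report.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.summary_table().to_csv(out / "surface_summaries.csv", index=False)
    if report.phase_triples:
        report.phase_table().to_csv(out / "phase_comparison.csv", index=False)
    for (m, mode), c in sorted(report.conditions.items()):
        tag = f"model{m}_{mode}"
        met = c.metrics
        pd.DataFrame({
            "x_mm": met.cell_xy[:, 0], "y_mm": met.cell_xy[:, 1],
            "tawss_pa": met.tawss, "osi": met.osi, "rrt_inv_pa": met.rrt,
            "rrt_capped": met.capped.astype(int),
        }).to_csv(out / f"metrics_{tag}.csv", index=False)
        pd.DataFrame({"time_s": c.aw_wss_times, "aw_wss_pa": c.aw_wss}
                     ).to_csv(out / f"aw_wss_{tag}.csv", index=False)
        pd.DataFrame({"time_s": c.run.times,
                      "pressure_drop_pa": c.run.pressure_drop}
                     ).to_csv(out / f"pressure_drop_{tag}.csv", index=False)
        grid = c.run.grid
        full = {}
        for name, vals in (("tawss_pa", met.tawss), ("osi", met.osi),
                           ("rrt_inv_pa", met.rrt)):
            arr = np.zeros((grid.n_y, grid.n_x))
            arr[met.cell_indices[:, 0], met.cell_indices[:, 1]] = vals
            full[name] = arr
        full["gap_height_mm"] = grid.height_map
        write_vtk_cells(out / f"metrics_{tag}.vtk", grid, full,
                        title=f"culture-surface metrics {tag}")
    manifest = asdict(report.config)
    manifest["failed_conditions"] = {f"{k}": v for k, v in report.failed.items()}
    try:
        from importlib.metadata import version

        manifest["chipflow_version"] = version("chipflow")
    except Exception:   # pragma: no cover - not installed
        manifest["chipflow_version"] = "unknown"
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


# ---------------------------------------------------------------------------


def trend_assertions(report: StudyReport) -> dict[str, bool | None]:
    """Evaluate the study's ordinal claims; None marks a claim that the
    report does not contain enough conditions to evaluate."""
    conds = report.conditions
    modes = [m for m in ("steady", "peristaltic")
             if all((k, m) in conds for k in report.config.models)]
    have_all_models = {1, 2, 3} <= set(report.config.models)

    def mean_rrt(m, mode):
        return conds[(m, mode)].summary.mean_rrt

    def iqr(m, mode):
        q = conds[(m, mode)].summary.rrt_quartiles
        return q[2] - q[0]

    def upct(m, mode):
        return conds[(m, mode)].summary.uniformity_percent

    def aw_mean(m, mode):
        c = conds[(m, mode)]
        return float(np.trapezoid(c.aw_wss, c.aw_wss_times)
                     / (c.aw_wss_times[-1] - c.aw_wss_times[0]))

    ledger: dict[str, bool | None] = {}

    if have_all_models and modes:
        ledger["mean_rrt_model1_highest"] = all(
            mean_rrt(1, md) > mean_rrt(2, md)
            and mean_rrt(1, md) > mean_rrt(3, md) for md in modes)
        ledger["rrt_iqr_model3_smallest"] = all(
            iqr(3, md) < iqr(1, md) and iqr(3, md) < iqr(2, md)
            for md in modes)
        ledger["uniformity_model3_highest_model2_lowest"] = all(
            upct(3, md) > upct(1, md) and upct(3, md) > upct(2, md)
            and upct(2, md) < upct(1, md) for md in modes)
        ledger["aw_wss_ranking_m2_m3_m1"] = all(
            aw_mean(2, md) > aw_mean(3, md) > aw_mean(1, md) for md in modes)
    else:
        for key in ("mean_rrt_model1_highest", "rrt_iqr_model3_smallest",
                    "uniformity_model3_highest_model2_lowest",
                    "aw_wss_ranking_m2_m3_m1"):
            ledger[key] = None

    both_modes = len(modes) == 2
    if both_modes:
        ledger["rrt_pulsatile_exceeds_steady"] = all(
            mean_rrt(m, "peristaltic") > mean_rrt(m, "steady")
            for m in report.config.models)
        ledger["tawss_steady_ge_pulsatile"] = all(
            conds[(m, "steady")].summary.mean_tawss
            >= conds[(m, "peristaltic")].summary.mean_tawss
            for m in report.config.models)
    else:
        ledger["rrt_pulsatile_exceeds_steady"] = None
        ledger["tawss_steady_ge_pulsatile"] = None

    if report.phase_triples:
        ledger["phase_ordering_accel_steady_decel"] = all(
            a > s > d for a, s, d in report.phase_triples.values())
    else:
        ledger["phase_ordering_accel_steady_decel"] = None

    if conds:
        ledger["surface_osi_below_0p01"] = all(
            c.summary.mean_osi < 0.01 for c in conds.values())
    else:
        ledger["surface_osi_below_0p01"] = None
    return ledger
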