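"""End-to-end study orchestration.

The pipeline mirrors the study design: screen the five-factor space with an
L18 orthogonal array by coupled electro-thermal simulation, fit quadratic
response surfaces to the screening responses, find the desirability-optimal
protocol, and verify it by re-simulating at the (rounded) optimum.

Optimization objectives
-----------------------
Three responses drive the composite desirability:

* **field strength** (maximum tissue |E|, maximize, importance 1) — the
  primary treatment-intensity objective; its surface is fit on the
  geometry/voltage factors only, because the static field cannot depend on
  the pulse schedule.  Field-strength responses come from the package's own
  electric solver at screening resolution.
* **maximum temperature** (target at the 50 °C damage limit, importance 1)
  — the optimal protocol should use the full thermal budget without
  crossing it.
* **ablation area** (larger-is-better over the observed range, importance
  0.25) — a secondary criterion: field strength and temperature alone leave
  a one-parameter family of equally desirable pulse schedules, and the area
  response selects among them.
"""

from __future__ import annotations

import importlib.resources as resources
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .doe import DesignTable, FactorSpec, default_factors, full_factorial, taguchi_l18
from .geometry import DomainSpec, ElectrodeConfig, build_grid
from .electric import solve_potential
from .responses import (
    ABLATION_THRESHOLD_V_PER_M,
    DAMAGE_LIMIT_C,
    RESPONSE_COLUMNS,
    extract_responses,
    max_field,
    read_response_table,
    write_response_table,
)
from .rsm import (
    OptimizationResult,
    ResponseSurface,
    fit_rsm,
    larger_is_better,
    main_effects,
    optimize_desirability,
    target_at_limit,
)
from .thermal import PulseProtocol, simulate_treatment
from .tissue import BloodConstants, TissueProperties, blood_defaults, bovine_liver

__all__ = [
    "RunConfig",
    "StudyReport",
    "load_screening_table",
    "load_factor_levels",
    "load_verification_table",
    "run_screening",
    "screen_field_strength",
    "run_optimization_and_verify",
]

_DATA = resources.files("ireplan") / "data"


def load_screening_table() -> pd.DataFrame:
    """The printed 18-run screening design with its simulated responses."""
    with resources.as_file(_DATA / "screening_design_responses.csv") as p:
        return read_response_table(p)


def load_factor_levels() -> pd.DataFrame:
    with resources.as_file(_DATA / "factor_levels.csv") as p:
        return pd.read_csv(p)


def load_verification_table() -> pd.DataFrame:
    """Printed optimum-verification comparison (RSM prediction vs simulation)."""
    with resources.as_file(_DATA / "optimum_verification.csv") as p:
        return pd.read_csv(p)


@dataclass
class RunConfig:
    """Study configuration in clinician units (mm, µs, V); SI conversion
    happens once at the solver boundary."""

    domain: DomainSpec = dc_field(default_factory=DomainSpec)
    factors: list[FactorSpec] = dc_field(default_factory=default_factors)
    design: str = "taguchi_L18"  # full_factorial | taguchi_L18 | csv
    design_csv: str | None = None
    electrode_diameter_mm: float = 1.0
    insertion_depth_mm: float = 20.0
    frequency_hz: float = 1.0
    dt_s: float = 0.1
    screening_spacing_mm: float = 0.5
    verification_spacing_mm: float = 0.25
    ablation_threshold: float = ABLATION_THRESHOLD_V_PER_M
    damage_limit: float = DAMAGE_LIMIT_C
    perfusion: bool = True
    solver_tol: float = 1.0e-8
    solver_max_iter: int = 100
    area_importance: float = 0.25
    seed: int = 0
    output_dir: str = "ireplan_out"
    strict: bool = False
    tissue: TissueProperties = dc_field(default_factory=bovine_liver)
    blood: BloodConstants = dc_field(default_factory=blood_defaults)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw = {}
        if "domain" in raw:
            kw["domain"] = DomainSpec(**raw.pop("domain"))
        if "factors" in raw:
            kw["factors"] = [
                FactorSpec(f["name"], tuple(f["levels"]), f.get("role", "continuous-range"))
                for f in raw.pop("factors")
            ]
        tissue_cfg = raw.pop("tissue", {})
        if tissue_cfg:
            from .tissue import PropertyCurve

            tkw = {}
            for key, attr in (
                ("sigma_vs_field_csv", "electrical_conductivity"),
                ("k_vs_temperature_csv", "thermal_conductivity"),
                ("permittivity_csv", "relative_permittivity"),
            ):
                if key in tissue_cfg:
                    tkw[attr] = PropertyCurve.from_csv(tissue_cfg.pop(key))
            tkw.update(tissue_cfg)
            kw["tissue"] = TissueProperties(**tkw)
        if "blood" in raw:
            kw["blood"] = BloodConstants(**raw.pop("blood"))
        kw.update(raw)
        return cls(**kw)

    def make_design(self) -> DesignTable:
        if self.design == "full_factorial":
            return full_factorial(self.factors)
        if self.design == "taguchi_L18":
            return taguchi_l18(self.factors)
        if self.design == "csv":
            if not self.design_csv:
                raise ValueError("design 'csv' needs design_csv")
            return DesignTable.from_csv(self.design_csv, self.factors)
        raise ValueError(f"unknown design {self.design!r}")

    def grid_for(self, active_length_mm: float, distance_mm: float, voltage: float,
                 spacing_mm: float | None = None):
        elec = ElectrodeConfig(
            active_length_mm=active_length_mm,
            distance_mm=distance_mm,
            voltage=voltage,
            diameter_mm=self.electrode_diameter_mm,
            insertion_depth_mm=self.insertion_depth_mm,
        )
        dom = DomainSpec(
            width_mm=self.domain.width_mm,
            height_mm=self.domain.height_mm,
            spacing_mm=spacing_mm if spacing_mm is not None else self.domain.spacing_mm,
            margin_mm=self.domain.margin_mm,
        )
        return build_grid(dom, elec)


@dataclass
class StudyReport:
    """Screening table, optimum, verification re-simulation and their
    relative errors (|prediction − simulation| / prediction, percent)."""

    responses: pd.DataFrame
    optimum: OptimizationResult
    verification: dict[str, float]
    relative_errors_pct: dict[str, float]
    thermal_damage: bool

    def to_json(self, path: str | Path) -> None:
        payload = {
            "optimum": {k: float(v) for k, v in self.optimum.natural.items()},
            "pulse_number_rounded": self.optimum.pulse_number_rounded,
            "desirability": self.optimum.desirability,
            "predictions": self.optimum.predictions,
            "verification": self.verification,
            "relative_errors_pct": self.relative_errors_pct,
            "thermal_damage": self.thermal_damage,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _simulate_row(config: RunConfig, row: pd.Series, spacing_mm: float, run_id: int):
    grid = config.grid_for(
        row["active_length_mm"], row["distance_mm"], row["voltage_V"], spacing_mm
    )
    protocol = PulseProtocol(
        pulse_number=int(round(row["pulse_number"])),
        pulse_width_us=float(row["pulse_width_us"]),
        frequency_hz=config.frequency_hz,
    )
    sim = simulate_treatment(
        grid,
        config.tissue,
        config.blood,
        protocol,
        dt=config.dt_s,
        perfusion=config.perfusion,
        solver_kwargs=dict(tol=config.solver_tol, max_iter=config.solver_max_iter),
    )
    return sim, protocol


def run_screening(
    config: RunConfig,
    design: DesignTable | None = None,
    output_dir: str | Path | None = None,
    log: list | None = None,
) -> pd.DataFrame:
    """One coupled simulation per design row at screening resolution.

    Deterministic given the configuration; resumable: rows whose run_id is
    already present in ``<output_dir>/responses.csv`` are not re-simulated.
    Individual solver failures are recorded and skipped; the study aborts if
    more than a quarter of the rows fail.
    """
    design = design or config.make_design()
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    table_path = out / "responses.csv"
    done: dict[int, dict] = {}
    if table_path.exists():
        prev = read_response_table(table_path)
        done = {int(r["run_id"]): r.to_dict() for _, r in prev.iterrows()}

    records, failures = [], []
    for i, (_, row) in enumerate(design.natural.iterrows(), start=1):
        if i in done:
            records.append(done[i])
            continue
        try:
            sim, protocol = _simulate_row(config, row, config.screening_spacing_mm, i)
            rec = extract_responses(sim, protocol, run_id=i, threshold=config.ablation_threshold)
            records.append(rec.as_row())
            if log is not None:
                log.append(
                    {
                        "run_id": i,
                        "picard_iterations": sim.potential.iterations,
                        "residual": sim.potential.residual,
                        "dt_s": config.dt_s,
                        "steps": len(sim.time_series) - 1,
                    }
                )
        except Exception as exc:  # record and continue
            failures.append((i, str(exc)))
            if log is not None:
                log.append({"run_id": i, "error": str(exc)})
    if failures and len(failures) > 0.25 * design.n_runs:
        raise RuntimeError(f"screening aborted: {len(failures)}/{design.n_runs} rows failed")

    df = pd.DataFrame(records, columns=RESPONSE_COLUMNS)
    write_response_table(df, table_path)
    return df


def screen_field_strength(
    config: RunConfig, design: DesignTable | None = None
) -> np.ndarray:
    """Maximum tissue |E| (V/m) per design row from electric-only solves.

    Rows sharing a (geometry, voltage) triple reuse one solve; the pulse
    factors cannot affect the static field.
    """
    design = design or config.make_design()
    cache: dict[tuple, float] = {}
    out = np.zeros(design.n_runs)
    for i, (_, row) in enumerate(design.natural.iterrows()):
        key = (row["active_length_mm"], row["distance_mm"], row["voltage_V"])
        if key not in cache:
            grid = config.grid_for(*key, spacing_mm=config.screening_spacing_mm)
            _, fm = solve_potential(
                grid,
                config.tissue,
                tol=config.solver_tol,
                max_iter=config.solver_max_iter,
            )
            cache[key] = max_field(fm, grid)
        out[i] = cache[key]
    return out


def fit_study_models(
    config: RunConfig,
    responses: pd.DataFrame,
    design: DesignTable | None = None,
    field_strength: np.ndarray | None = None,
) -> dict[str, ResponseSurface]:
    """Fit the three response surfaces used by the optimizer."""
    design = design or config.make_design()
    models = {
        "ablation_area_mm2": fit_rsm(design, responses["ablation_area_mm2"].to_numpy()),
        "max_temperature_C": fit_rsm(design, responses["max_temperature_C"].to_numpy()),
    }
    if field_strength is None:
        field_strength = screen_field_strength(config, design)
    models["field_strength"] = fit_rsm(
        design,
        field_strength,
        active_factors=("active_length_mm", "distance_mm", "voltage_V"),
    )
    return models


def optimize_protocol(
    config: RunConfig,
    responses: pd.DataFrame,
    design: DesignTable | None = None,
    models: dict[str, ResponseSurface] | None = None,
) -> OptimizationResult:
    design = design or config.make_design()
    if models is None:
        models = fit_study_models(config, responses, design)
    area = responses["ablation_area_mm2"].to_numpy()
    efld = models["field_strength"]
    e_obs = efld.predict_coded(design.coded)
    desirabilities = {
        "field_strength": larger_is_better(float(e_obs.min()), float(e_obs.max()), weight=1.0),
        "max_temperature_C": target_at_limit(37.0, config.damage_limit, weight=1.0),
        "ablation_area_mm2": larger_is_better(
            float(area.min()), float(area.max()), weight=config.area_importance
        ),
    }
    return optimize_desirability(
        models, desirabilities, config.factors, seed=config.seed
    )


def run_optimization_and_verify(
    config: RunConfig,
    responses: pd.DataFrame,
    design: DesignTable | None = None,
    models: dict[str, ResponseSurface] | None = None,
    verify_rounded: bool = True,
) -> StudyReport:
    """Fit, optimize, re-simulate at the optimum and report relative errors."""
    design = design or config.make_design()
    if models is None:
        models = fit_study_models(config, responses, design)
    opt = optimize_protocol(config, responses, design, models)

    nat = opt.natural
    pulse_number = opt.pulse_number_rounded if verify_rounded else int(round(nat["pulse_number"]))
    grid = config.grid_for(
        nat["active_length_mm"], nat["distance_mm"], nat["voltage_V"],
        spacing_mm=config.verification_spacing_mm,
    )
    protocol = PulseProtocol(
        pulse_number=pulse_number,
        pulse_width_us=float(nat["pulse_width_us"]),
        frequency_hz=config.frequency_hz,
    )
    sim = simulate_treatment(
        grid,
        config.tissue,
        config.blood,
        protocol,
        dt=config.dt_s,
        perfusion=config.perfusion,
        solver_kwargs=dict(tol=config.solver_tol, max_iter=config.solver_max_iter),
    )
    rec = extract_responses(sim, protocol, threshold=config.ablation_threshold)
    verification = {
        "ablation_area_mm2": rec.ablation_area_mm2,
        "max_temperature_C": rec.max_temperature_C,
    }
    rel = {
        name: abs(opt.predictions[name] - verification[name]) / abs(opt.predictions[name]) * 100.0
        for name in verification
    }
    return StudyReport(
        responses=responses,
        optimum=opt,
        verification=verification,
        relative_errors_pct=rel,
        thermal_damage=rec.max_temperature_C >= config.damage_limit,
    )


def study_main_effects(design: DesignTable, responses: pd.DataFrame) -> pd.DataFrame:
    """Mean area and temperature per factor level (factorial-trend table)."""
    return main_effects(design, responses, ["ablation_area_mm2", "max_temperature_C"])
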