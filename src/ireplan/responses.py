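"""Scalar treatment responses extracted from a simulation.

Two responses summarise each protocol: the ablation area — the tissue area
where the field magnitude reaches the lethal-electroporation threshold
(default 800 V/cm = 8.0e4 V/m for liver) — and the maximum tissue
temperature over the treatment, with a boolean thermal-damage verdict at
the 50 °C limit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import Grid
from .electric import FieldMagnitude
from .thermal import SimulationResult

__all__ = [
    "ABLATION_THRESHOLD_V_PER_M",
    "DAMAGE_LIMIT_C",
    "RESPONSE_COLUMNS",
    "ResponseRecord",
    "ablation_area",
    "max_field",
    "thermal_damage_flag",
    "extract_responses",
    "write_response_table",
    "read_response_table",
]

#: Lethal electric-field threshold, V/m (800 V/cm).
ABLATION_THRESHOLD_V_PER_M = 8.0e4

#: Thermal damage temperature limit, °C.
DAMAGE_LIMIT_C = 50.0

#: Byte-stable response-table column order.
RESPONSE_COLUMNS = [
    "run_id",
    "active_length_mm",
    "distance_mm",
    "voltage_V",
    "pulse_number",
    "pulse_width_us",
    "ablation_area_mm2",
    "max_temperature_C",
    "thermal_damage",
]


@dataclass
class ResponseRecord:
    """Per-run responses plus an echo of the five protocol factors."""

    run_id: int
    active_length_mm: float
    distance_mm: float
    voltage_V: float
    pulse_number: float
    pulse_width_us: float
    ablation_area_mm2: float
    max_temperature_C: float

    @property
    def thermal_damage(self) -> bool:
        return self.max_temperature_C >= DAMAGE_LIMIT_C

    def as_row(self) -> dict:
        d = {c: getattr(self, c) for c in RESPONSE_COLUMNS if c != "thermal_damage"}
        d["thermal_damage"] = self.thermal_damage
        return d


def ablation_area(
    field: FieldMagnitude, grid: Grid, threshold: float = ABLATION_THRESHOLD_V_PER_M
) -> float:
    """Ablated tissue area in mm² by cell counting.

    Counts tissue nodes (electrode interiors excluded) whose |E| reaches the
    threshold and multiplies by the nodal cell area.  The threshold is
    inclusive.
    """
    if threshold <= 0:
        raise ValueError("ablation threshold must be positive")
    n = int(np.sum((field.magnitude >= threshold) & grid.tissue_mask))
    return n * grid.cell_area * 1.0e6


def max_field(field: FieldMagnitude, grid: Grid) -> float:
    """Maximum field magnitude over tissue nodes, V/m."""
    return float(field.magnitude[grid.tissue_mask].max())


def thermal_damage_flag(max_temperature: float, limit: float = DAMAGE_LIMIT_C) -> bool:
    """True iff the space-time maximum temperature reaches the limit
    (boundary inclusive)."""
    return bool(max_temperature >= limit)


def extract_responses(
    sim: SimulationResult,
    protocol,
    run_id: int = 0,
    threshold: float = ABLATION_THRESHOLD_V_PER_M,
) -> ResponseRecord:
    """Reduce a simulation to its response record.

    The tabulated maximum temperature is the domain (tissue) maximum over
    all time steps; the centre-probe maximum is available from the
    simulation's time series separately.
    """
    e = sim.grid.electrodes
    return ResponseRecord(
        run_id=run_id,
        active_length_mm=e.active_length_mm,
        distance_mm=e.distance_mm,
        voltage_V=e.voltage,
        pulse_number=protocol.pulse_number,
        pulse_width_us=protocol.pulse_width_us,
        ablation_area_mm2=ablation_area(sim.field, sim.grid, threshold),
        max_temperature_C=sim.max_temperature,
    )


def write_response_table(records: list[ResponseRecord] | pd.DataFrame, path: str | Path) -> None:
    if isinstance(records, pd.DataFrame):
        df = records[RESPONSE_COLUMNS]
    else:
        df = pd.DataFrame([r.as_row() for r in records], columns=RESPONSE_COLUMNS)
    df.to_csv(path, index=False)


def read_response_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing response columns {missing}")
    return df[RESPONSE_COLUMNS]
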