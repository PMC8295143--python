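"""Tissue and blood material properties for electroporation modelling.

Bovine liver is described by two scalar constants (density, heat capacity)
and three property curves: thermal conductivity and relative permittivity as
functions of temperature, and electrical conductivity as a function of the
local electric-field magnitude.  The conductivity rise with field strength
is the standard electroporation effect: permeabilised membranes conduct, so
bulk conductivity climbs from a baseline to a saturated value as the field
exceeds the electroporation threshold range.

Curves are piecewise linear through an ordered knot set and clamp to their
endpoint values outside the knot range, which keeps every evaluated property
bounded and non-negative.  Relative permittivity is carried for interface
completeness only: the quasi-static (DC) potential solve has no displacement
current, so permittivity never enters the equations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "PropertyCurve",
    "TissueProperties",
    "BloodConstants",
    "bovine_liver",
    "blood_defaults",
    "sigma_of_field",
    "k_of_temperature",
    "perfusion_sink",
]

#: Electrical conductivity floor and ceiling for bovine liver, S/m.
SIGMA_MIN = 0.0650
SIGMA_MAX = 0.1483

#: Field-magnitude range over which the default conductivity curve rises, V/m.
SIGMA_RAMP_LOW = 1.0e4
SIGMA_RAMP_HIGH = 7.0e4


class PropertyCurve:
    """Piecewise-linear property curve with clamp-to-endpoint extrapolation.

    Parameters
    ----------
    knots : sequence of (x, value) pairs
        Strictly increasing in ``x``.
    abscissa : str
        ``"temperature"`` (°C) or ``"field_magnitude"`` (V/m); recorded for
        unit bookkeeping and CSV round-trips.
    """

    def __init__(self, knots: Iterable[tuple[float, float]], abscissa: str = "temperature"):
        pts = [(float(x), float(v)) for x, v in knots]
        if not pts:
            raise ValueError("a property curve needs at least one knot")
        xs = np.array([p[0] for p in pts])
        if np.any(~np.isfinite(xs)) or np.any(np.diff(xs) <= 0):
            raise ValueError("curve knots must be finite and strictly increasing in x")
        if abscissa not in ("temperature", "field_magnitude"):
            raise ValueError(f"unknown abscissa {abscissa!r}")
        self.x = xs
        self.values = np.array([p[1] for p in pts])
        self.abscissa = abscissa

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        if np.any(~np.isfinite(x)):
            raise ValueError("curve evaluated at a non-finite abscissa")
        # np.interp clamps to the first/last value outside the knot range
        return np.interp(x, self.x, self.values)

    @property
    def vmin(self) -> float:
        return float(self.values.min())

    @property
    def vmax(self) -> float:
        return float(self.values.max())

    @classmethod
    def constant(cls, value: float, abscissa: str = "temperature") -> "PropertyCurve":
        return cls([(0.0, value)], abscissa=abscissa)

    @classmethod
    def from_csv(cls, path: str | Path, abscissa: str | None = None) -> "PropertyCurve":
        """Read a two-column ``x,value`` CSV (header row, SI units)."""
        df = pd.read_csv(path)
        if df.shape[1] != 2:
            raise ValueError(f"{path}: expected two columns 'x,value'")
        name = abscissa
        if name is None:
            name = "field_magnitude" if "field" in df.columns[0].lower() else "temperature"
        return cls(list(zip(df.iloc[:, 0], df.iloc[:, 1])), abscissa=name)

    def to_csv(self, path: str | Path) -> None:
        label = "field_V_per_m" if self.abscissa == "field_magnitude" else "temperature_C"
        pd.DataFrame({label: self.x, "value": self.values}).to_csv(path, index=False)

    def __repr__(self) -> str:  # pragma: no cover
        return f"PropertyCurve({self.abscissa}, {len(self.x)} knots)"


def default_sigma_curve() -> PropertyCurve:
    """Default σ(|E|): smoothstep-shaped rise from ``SIGMA_MIN`` below 10 kV/m
    to ``SIGMA_MAX`` above 70 kV/m, symmetric about the ramp midpoint."""
    ts = np.linspace(0.0, 1.0, 5)
    s = 3 * ts**2 - 2 * ts**3  # smoothstep, symmetric: s(t) + s(1-t) = 1
    xs = SIGMA_RAMP_LOW + ts * (SIGMA_RAMP_HIGH - SIGMA_RAMP_LOW)
    vals = SIGMA_MIN + s * (SIGMA_MAX - SIGMA_MIN)
    return PropertyCurve(list(zip(xs, vals)), abscissa="field_magnitude")


@dataclass
class TissueProperties:
    """Electrical and thermophysical properties of the target tissue.

    Defaults are bovine liver: density 1050 kg/m³, heat capacity
    3400 J/(kg·°C), thermal conductivity k(T), relative permittivity ε_r(T)
    and field-dependent electrical conductivity σ(|E|) bounded by
    [0.0650, 0.1483] S/m.
    """

    density: float = 1050.0  # kg/m^3
    heat_capacity: float = 3400.0  # J/(kg C)
    thermal_conductivity: PropertyCurve = field(
        default_factory=lambda: PropertyCurve([(37.0, 0.52)])
    )
    relative_permittivity: PropertyCurve = field(
        default_factory=lambda: PropertyCurve.constant(5.0e4)
    )
    electrical_conductivity: PropertyCurve = field(default_factory=default_sigma_curve)

    def __post_init__(self) -> None:
        if self.density <= 0 or self.heat_capacity <= 0:
            raise ValueError("density and heat capacity must be positive")
        sig = self.electrical_conductivity
        if sig.abscissa != "field_magnitude":
            raise ValueError("electrical conductivity must be a curve in field magnitude")
        if np.any(np.diff(sig.values) < 0):
            raise ValueError("electrical conductivity must be non-decreasing in |E|")
        if sig.vmin <= 0:
            raise ValueError("electrical conductivity must be positive")
        if self.thermal_conductivity.vmin <= 0:
            raise ValueError("thermal conductivity must be positive")

    @property
    def sigma_min(self) -> float:
        return self.electrical_conductivity.vmin

    @property
    def sigma_max(self) -> float:
        return self.electrical_conductivity.vmax

    def sigma_of_field(self, field_magnitude):
        """σ(|E|) in S/m; clamps to [sigma_min, sigma_max] outside the knots."""
        e = np.asarray(field_magnitude, dtype=float)
        if np.any(~np.isfinite(e)) or np.any(e < 0):
            raise ValueError("field magnitude must be finite and non-negative")
        return self.electrical_conductivity(e)

    def k_of_temperature(self, temperature):
        """k(T) in W/(m·°C); clamps to endpoint values outside the knots."""
        return self.thermal_conductivity(np.asarray(temperature, dtype=float))


@dataclass
class BloodConstants:
    """Blood-side constants of the perfusion term plus the metabolic source.

    Defaults: ρ_b = 1000 kg/m³, c_p,b = 3640 J/(kg·°C), ω_b = 5e-4 1/s,
    T_b = 37 °C, Q_met = 0 W/m³.
    """

    density: float = 1000.0  # kg/m^3
    heat_capacity: float = 3640.0  # J/(kg C)
    perfusion_rate: float = 5.0e-4  # 1/s
    blood_temperature: float = 37.0  # C
    metabolic_heat: float = 0.0  # W/m^3

    def __post_init__(self) -> None:
        for name in ("density", "heat_capacity", "perfusion_rate", "metabolic_heat"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def perfusion_coefficient(self) -> float:
        """ρ_b·c_p,b·ω_b in W/(m³·°C)."""
        return self.density * self.heat_capacity * self.perfusion_rate

    def perfusion_sink(self, temperature):
        """Volumetric perfusion power ρ_b·c_p,b·ω_b·(T_b − T), W/m³.

        Positive below blood temperature (heating), negative above (cooling).
        """
        t = np.asarray(temperature, dtype=float)
        if np.any(~np.isfinite(t)):
            raise ValueError("temperature must be finite")
        return self.perfusion_coefficient * (self.blood_temperature - t)


def bovine_liver() -> TissueProperties:
    """Bovine liver with the default property curves."""
    return TissueProperties()


def blood_defaults() -> BloodConstants:
    return BloodConstants()


# Thin functional wrappers over the dataclass methods.

def sigma_of_field(props: TissueProperties, field_magnitude):
    return props.sigma_of_field(field_magnitude)


def k_of_temperature(props: TissueProperties, temperature):
    t = np.asarray(temperature, dtype=float)
    if np.any(~np.isfinite(t)):
        raise ValueError("temperature must be finite")
    return props.k_of_temperature(t)


def perfusion_sink(blood: BloodConstants, temperature):
    return blood.perfusion_sink(temperature)
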