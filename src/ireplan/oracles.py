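"""Analytic oracles and synthetic-response generators for verification.

Everything here is deliberately independent code: closed forms and direct
simulation that share no numerical kernels with the solvers and optimizers
they are used to check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .doe import DesignTable
from .geometry import ElectrodeConfig, MM

__all__ = [
    "two_wire_potential",
    "two_wire_field",
    "SyntheticResponseSpec",
    "generate_synthetic_responses",
]


def _wire_positions(electrodes: ElectrodeConfig, width_mm: float) -> tuple[float, float]:
    xc = width_mm * MM / 2.0
    half = electrodes.distance_mm * MM / 2.0
    return xc - half, xc + half


def two_wire_potential(
    x: np.ndarray,
    electrodes: ElectrodeConfig,
    width_mm: float,
    voltage: float | None = None,
) -> np.ndarray:
    """Closed-form potential of a bipolar pair of long parallel cylinders.

    The exact solution for two cylinders of radius a at centre separation d
    held at V₀ and 0 is generated by two image line charges at x = ±c,
    c = √((d/2)² − a²), about the pair midpoint:

        V(p) = V₀/2 + (V₀/2) · ln(r₂/r₁) / acosh(d / 2a),

    with r₁, r₂ the distances from p to the left (high) and right (ground)
    image positions.  Valid in the plane transverse to the cylinders, away
    from their ends; here evaluated along the x-axis through both centres.

    Raises on evaluation closer than the radius a to either centre.
    """
    V0 = electrodes.voltage if voltage is None else float(voltage)
    a = electrodes.diameter_mm * MM / 2.0
    d = electrodes.distance_mm * MM
    xl, xr = _wire_positions(electrodes, width_mm)
    xm = 0.5 * (xl + xr)
    c = math.sqrt((d / 2.0) ** 2 - a**2)
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x - xl) < a - 1e-12) or np.any(np.abs(x - xr) < a - 1e-12):
        raise ValueError("evaluation point inside a wire (singular)")
    r1 = np.abs(x - (xm - c))
    r2 = np.abs(x - (xm + c))
    return V0 / 2.0 + (V0 / 2.0) * np.log(r2 / r1) / math.acosh(d / (2.0 * a))


def two_wire_field(
    x: np.ndarray,
    electrodes: ElectrodeConfig,
    width_mm: float,
    voltage: float | None = None,
) -> np.ndarray:
    """Analytic |E| of the bipolar two-cylinder potential along the
    centre axis: |dV/dx| = (V₀/2)/acosh(d/2a) · |1/r₁ + 1/r₂| between the
    image charges (distances r to the image positions, not the centres)."""
    V0 = electrodes.voltage if voltage is None else float(voltage)
    a = electrodes.diameter_mm * MM / 2.0
    d = electrodes.distance_mm * MM
    xl, xr = _wire_positions(electrodes, width_mm)
    xm = 0.5 * (xl + xr)
    c = math.sqrt((d / 2.0) ** 2 - a**2)
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x - xl) < a - 1e-12) or np.any(np.abs(x - xr) < a - 1e-12):
        raise ValueError("evaluation point inside a wire (singular)")
    lam = (V0 / 2.0) / math.acosh(d / (2.0 * a))
    s1 = np.sign(x - (xm - c))
    s2 = np.sign(x - (xm + c))
    r1 = np.abs(x - (xm - c))
    r2 = np.abs(x - (xm + c))
    return np.abs(lam * (s1 / r1 - s2 / r2))


@dataclass
class SyntheticResponseSpec:
    """Known-truth quadratic surface for parameter-recovery harnesses.

    ``coefficients`` follows the response-surface term order: intercept,
    linear terms for every factor, then square terms for the 3-level
    factors.  Noise is i.i.d. Gaussian.
    """

    coefficients: np.ndarray
    noise_sd: float = 0.0
    seed: int = 0


def generate_synthetic_responses(spec: SyntheticResponseSpec, design: DesignTable) -> np.ndarray:
    """response = quadratic(coded settings) + noise, reproducible by seed."""
    coded = design.coded
    cols = [np.ones(len(coded))]
    cols += [coded[:, j] for j in range(len(design.factors))]
    cols += [coded[:, j] ** 2 for j, f in enumerate(design.factors) if f.n_levels == 3]
    X = np.column_stack(cols)
    beta = np.asarray(spec.coefficients, dtype=float)
    if beta.shape != (X.shape[1],):
        raise ValueError(f"expected {X.shape[1]} coefficients, got {beta.shape}")
    y = X @ beta
    if spec.noise_sd:
        rng = np.random.default_rng(spec.seed)
        y = y + rng.normal(0.0, spec.noise_sd, size=len(y))
    return y
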