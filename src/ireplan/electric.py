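"""Quasi-static potential solver with field-dependent conductivity.

The potential obeys the conservation form ∇·(σ∇V) = 0 with Dirichlet data
on the active electrode segments (left at the applied voltage, right at
ground) and zero-flux insulation on the outer boundary.  In
``field_dependent`` mode σ = σ(|E|) of the converged solution, closed by
Picard (fixed-point) iteration with under-relaxation on the conductivity;
``constant_sigma`` mode freezes σ at its zero-field value, which reduces the
problem to the linear Laplace equation.

The inactive shafts are insulating: they are excluded from conduction by
assigning them a conductivity many orders of magnitude below tissue, which
drives the harmonic-mean face coefficients — and hence the flux through the
shaft — to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse.linalg as spla

from ._assembly import apply_dirichlet, diffusion_matrix
from .geometry import Grid, Region
from .tissue import TissueProperties

__all__ = [
    "PotentialField",
    "FieldMagnitude",
    "ConvergenceError",
    "solve_potential",
    "field_magnitude",
]

#: Relative conductivity assigned to insulating shaft nodes.
SHAFT_SIGMA_FACTOR = 1.0e-9


class ConvergenceError(RuntimeError):
    """Picard iteration failed to reach tolerance within the allowed iterations."""

    def __init__(self, message: str, residual_history: list[float]):
        super().__init__(message)
        self.residual_history = residual_history


@dataclass
class PotentialField:
    """Converged nodal potential (V) plus solve diagnostics."""

    potential: np.ndarray  # [y, x], volts
    applied_voltage: float
    iterations: int
    residual: float
    residual_history: list[float] = field(default_factory=list)


@dataclass
class FieldMagnitude:
    """Nodal electric-field magnitude |E| (V/m) and the conductivity at it."""

    magnitude: np.ndarray  # [y, x], V/m
    sigma: np.ndarray  # [y, x], S/m, σ(|E|) used by the converged solve


def _gradient_magnitude(V: np.ndarray, spacing: float) -> np.ndarray:
    gy, gx = np.gradient(V, spacing)
    return np.hypot(gx, gy)


def solve_potential(
    grid: Grid,
    props: TissueProperties,
    voltage: float | None = None,
    mode: str = "field_dependent",
    relax: float = 0.5,
    tol: float = 1.0e-8,
    max_iter: int = 100,
) -> tuple[PotentialField, FieldMagnitude]:
    """Solve for the potential and return it with the converged |E| map.

    Parameters
    ----------
    voltage : float, optional
        Applied voltage; defaults to ``grid.electrodes.voltage``.
    mode : {"field_dependent", "constant_sigma"}
        Conductivity closure (see module docstring).
    relax : float
        Under-relaxation factor for the σ update in Picard iteration.
    tol : float
        Relative conservation-residual tolerance, ‖A(σ)V − b‖ / ‖b‖.

    Raises
    ------
    ConvergenceError
        If the nonlinear residual does not reach ``tol`` within ``max_iter``.
    """
    if mode not in ("field_dependent", "constant_sigma"):
        raise ValueError(f"unknown mode {mode!r}")
    V0 = grid.electrodes.voltage if voltage is None else float(voltage)
    if V0 < 0:
        raise ValueError("applied voltage must be non-negative")

    region = grid.region
    h = grid.spacing
    dir_mask = (region == Region.LEFT_ACTIVE) | (region == Region.RIGHT_ACTIVE)
    dir_vals = np.where(region == Region.LEFT_ACTIVE, V0, 0.0)
    shaft = region == Region.SHAFT

    if V0 == 0.0:
        zeros = np.zeros_like(dir_vals)
        sig0 = np.asarray(props.sigma_of_field(zeros))
        return (
            PotentialField(zeros, 0.0, 0, 0.0, [0.0]),
            FieldMagnitude(zeros.copy(), sig0),
        )

    sigma = np.full(region.shape, props.sigma_min)
    V = np.zeros(region.shape)
    history: list[float] = []
    n_iter = max_iter if mode == "field_dependent" else 1

    for it in range(n_iter):
        sig_eff = sigma.copy()
        sig_eff[shaft] = props.sigma_min * SHAFT_SIGMA_FACTOR
        A = diffusion_matrix(sig_eff, h)
        b = np.zeros(A.shape[0])
        A, b = apply_dirichlet(A, b, dir_mask, dir_vals)
        V = spla.spsolve(A.tocsc(), b).reshape(region.shape)

        E = _gradient_magnitude(V, h)
        sigma_new = np.asarray(props.sigma_of_field(E))
        if mode == "constant_sigma":
            history.append(0.0)
            sigma = np.full(region.shape, props.sigma_min)
            break

        # conservation residual of the updated conductivity field
        sig_chk = sigma_new.copy()
        sig_chk[shaft] = props.sigma_min * SHAFT_SIGMA_FACTOR
        Ac = diffusion_matrix(sig_chk, h)
        bc = np.zeros(Ac.shape[0])
        Ac, bc = apply_dirichlet(Ac, bc, dir_mask, dir_vals)
        res = float(np.linalg.norm(Ac @ V.ravel() - bc) / np.linalg.norm(bc))
        history.append(res)
        if res < tol:
            sigma = sigma_new
            break
        sigma = relax * sigma_new + (1.0 - relax) * sigma
    else:
        raise ConvergenceError(
            f"Picard iteration did not converge below {tol:g} in {max_iter} iterations "
            f"(last residual {history[-1]:.3e})",
            history,
        )

    lo, hi = min(0.0, V0), max(0.0, V0)
    vmin, vmax = float(V.min()), float(V.max())
    if vmin < lo - 1e-6 * hi or vmax > hi * (1 + 1e-6):
        raise ConvergenceError(
            f"discrete maximum principle violated: V in [{vmin:.3g}, {vmax:.3g}] "
            f"outside [{lo:.3g}, {hi:.3g}]",
            history,
        )

    E = _gradient_magnitude(V, h)
    pf = PotentialField(V, V0, len(history), history[-1], history)
    # σ consistent with the mode: σ(|E|) after a field-dependent solve,
    # the zero-field floor after a constant-σ solve
    fm = FieldMagnitude(E, sigma.copy())
    return pf, fm


def field_magnitude(potential: PotentialField, grid: Grid) -> FieldMagnitude:
    """|E| from the potential gradient: central differences in the interior,
    one-sided at the boundaries."""
    E = _gradient_magnitude(potential.potential, grid.spacing)
    return FieldMagnitude(E, np.full_like(E, np.nan))
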