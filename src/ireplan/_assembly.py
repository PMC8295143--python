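"""Finite-volume assembly helpers shared by the electric and thermal solvers.

Uniform node-centred lattice, 5-point stencil, harmonic-mean face
coefficients.  Outer boundaries are natural zero-flux (a missing face simply
contributes nothing), which is the insulated condition both solvers need.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp


def face_harmonic(c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Harmonic means of a nodal coefficient across x- and y-faces."""
    cx = 2.0 * c[:, :-1] * c[:, 1:] / (c[:, :-1] + c[:, 1:])
    cy = 2.0 * c[:-1, :] * c[1:, :] / (c[:-1, :] + c[1:, :])
    return cx, cy


def diffusion_matrix(coef: np.ndarray, spacing: float) -> sp.csr_matrix:
    """Assemble −∇·(c∇·) (positive semi-definite) scaled by 1/h².

    ``coef`` is the nodal diffusivity (σ or k); faces take harmonic means so
    a near-zero node coefficient shuts off flux through that face.
    """
    ny, nx = coef.shape
    n = nx * ny
    idx = np.arange(n).reshape(ny, nx)
    cx, cy = face_harmonic(coef)
    w = 1.0 / spacing**2

    rows, cols, vals = [], [], []
    a = idx[:, :-1].ravel()
    b = idx[:, 1:].ravel()
    wx = (cx * w).ravel()
    rows += [a, b, a, b]
    cols += [b, a, a, b]
    vals += [-wx, -wx, wx, wx]

    a = idx[:-1, :].ravel()
    b = idx[1:, :].ravel()
    wy = (cy * w).ravel()
    rows += [a, b, a, b]
    cols += [b, a, a, b]
    vals += [-wy, -wy, wy, wy]

    return sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    ).tocsr()


def apply_dirichlet(
    A: sp.csr_matrix, b: np.ndarray, mask: np.ndarray, values: np.ndarray
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Fold Dirichlet rows/columns into (A, b), keeping A symmetric-free form.

    ``mask`` and ``values`` are flat arrays over all nodes.  Constrained rows
    become identity rows with the prescribed value on the right-hand side.
    """
    flat_mask = mask.ravel()
    vals = np.where(flat_mask, values.ravel(), 0.0)
    b = b - A @ vals
    keep = sp.diags((~flat_mask).astype(float))
    A = keep @ A @ keep + sp.diags(flat_mask.astype(float))
    b = np.where(flat_mask, values.ravel(), b)
    return A.tocsr(), b
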