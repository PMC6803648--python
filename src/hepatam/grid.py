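"""Finite-difference operators on the 2D node-centered lattice.

All fields live on an ``n × n`` node-centered square lattice with spacing
``h`` (mm). Diffusion operators use the standard 5-point stencil with
zero-flux (Neumann) boundaries implemented by mirror ghost nodes, so the
discrete Laplacian row sums vanish and constants are in its null space.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import scipy.sparse as sp


@lru_cache(maxsize=8)
def neumann_laplacian(n: int, h: float) -> sp.csr_matrix:
    """Sparse 5-point Laplacian with zero-Neumann boundaries.

    Returns L such that (L u)/h^2 approximates ∇²u; the 1/h^2 factor is
    included. Row sums are exactly zero (mirror ghosts).
    """
    # 1D second-difference with mirrored ghosts: u_{-1} = u_1 etc.
    main = -2.0 * np.ones(n)
    main[0] = main[-1] = -1.0
    off = np.ones(n - 1)
    d1 = sp.diags([off, main, off], [-1, 0, 1], format="csr")
    eye = sp.identity(n, format="csr")
    lap = sp.kron(d1, eye) + sp.kron(eye, d1)
    return (lap / (h * h)).tocsr()


def gradient(field: np.ndarray, h: float) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference gradient (gy, gx) with one-sided edges."""
    gy, gx = np.gradient(field, h, edge_order=1)
    return gy, gx


def gradient_magnitude(field: np.ndarray, h: float) -> np.ndarray:
    gy, gx = gradient(field, h)
    return np.hypot(gy, gx)


def face_divergence_matrixfree(flux_y: np.ndarray, flux_x: np.ndarray, h: float) -> np.ndarray:
    """Divergence of a staggered (face-centered) flux field.

    ``flux_y`` has shape (n-1, n): flux across the face between rows i and
    i+1. ``flux_x`` analogous for columns. Zero flux is assumed on the
    domain boundary, matching the Neumann Laplacian.
    """
    n = flux_y.shape[1]
    div = np.zeros((n, n))
    div[:-1, :] += flux_y
    div[1:, :] -= flux_y
    div[:, :-1] += flux_x
    div[:, 1:] -= flux_x
    return div / h


def face_gradient(field: np.ndarray, h: float) -> tuple[np.ndarray, np.ndarray]:
    """Forward differences onto cell faces: (gy on (n-1,n), gx on (n,n-1))."""
    gy = (field[1:, :] - field[:-1, :]) / h
    gx = (field[:, 1:] - field[:, :-1]) / h
    return gy, gx
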