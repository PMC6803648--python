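"""Quasi-steady and explicit reaction-diffusion solvers.

Oxygen and cytokines are treated as quasi-steady (diffusion is fast
relative to tissue dynamics): each is a linear elliptic problem solved
by sparse direct factorization on the 5-point Neumann Laplacian. The
matrix-degrading enzyme field evolves by explicit Euler under its CFL
bound, and the Darcy pressure/velocity system is a gauge-fixed Neumann
Poisson problem.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .config import ConfigurationError, CytokineSpec, SimulationConfig
from .grid import face_divergence_matrixfree, face_gradient, gradient, neumann_laplacian
from .state import HYPOXIC, NECROTIC, PROLIFERATING, RegionMap
from .vasculature import VesselNetwork, extravasation_conductance, vessel_indicator


class SolverError(RuntimeError):
    """Linear solve failed or produced a model-inconsistent field."""


_BOUNDS_EPS = 1e-7


def _solve_helmholtz(D: float, decay: np.ndarray, source: np.ndarray,
                     h: float, what: str) -> np.ndarray:
    """Solve 0 = D ∇²u − decay(x) u + source(x) with zero-Neumann boundaries."""
    n = source.shape[0]
    lap = neumann_laplacian(n, h)
    A = (-D) * lap + sp.diags(decay.ravel())
    try:
        u = spla.spsolve(A.tocsc(), source.ravel())
    except Exception as exc:  # pragma: no cover - solver backend failure
        raise SolverError(f"{what}: sparse solve failed: {exc}") from exc
    if not np.all(np.isfinite(u)):
        raise SolverError(f"{what}: non-finite solution")
    return u.reshape(n, n)


def _check_bounds(u: np.ndarray, what: str) -> np.ndarray:
    if u.min() < -_BOUNDS_EPS or u.max() > 1.0 + _BOUNDS_EPS:
        raise SolverError(
            f"{what}: solution escapes [0,1] (min={u.min():.3g}, max={u.max():.3g}); "
            "this indicates inconsistent rates, not a clipping situation"
        )
    return np.clip(u, 0.0, 1.0)


def oxygen_uptake_field(region: RegionMap, config: SimulationConfig) -> np.ndarray:
    """Region-wise oxygen uptake/decay rate lambda^sigma(x)."""
    op = config.oxygen
    lam = np.full(region.labels.shape, op.lambda_tissue_sigma)
    lam[region.labels == PROLIFERATING] = op.lambda_tumor_sigma
    lam[region.labels == HYPOXIC] = op.q_sigma
    lam[region.labels == NECROTIC] = op.lambda_N_sigma
    return lam


def solve_oxygen(region: RegionMap, network: VesselNetwork, pressure: np.ndarray,
                 config: SimulationConfig) -> np.ndarray:
    """Quasi-steady oxygen field sigma in [0, 1].

    Solves 0 = ∇·(D∇σ) − λ^σ(x)σ + s(x)(1−σ) where s is the
    pressure-modulated vessel extravasation conductance. The source is
    linear in sigma, so the discrete maximum principle bounds the
    solution in [0, 1] without clipping.
    """
    s = extravasation_conductance(network, pressure, config)
    lam = oxygen_uptake_field(region, config)
    sigma = _solve_helmholtz(config.oxygen.D_sigma, lam + s, s,
                             config.node_spacing, "oxygen")
    return _check_bounds(sigma, "oxygen")


def production_indicator(spec: CytokineSpec, region: RegionMap,
                         agents=None) -> np.ndarray:
    """Indicator lattice of the production region for one cytokine."""
    if spec.production_region == "viable_tumor":
        return region.viable_mask.astype(float)
    if spec.production_region == "hypoxic_tumor":
        return region.hypoxic_mask.astype(float)
    if spec.production_region == "M2_agents":
        ind = np.zeros(region.labels.shape)
        if agents is not None and len(agents):
            m2 = agents.phenotype == agents.M2
            np.add.at(ind, (agents.row[m2], agents.col[m2]), 1.0)
            ind = np.minimum(ind, 1.0)
        return ind
    raise ConfigurationError(f"unknown production_region {spec.production_region!r}")


def solve_cytokine(spec: CytokineSpec, region: RegionMap, network: VesselNetwork,
                   h: float, agents=None) -> np.ndarray:
    """Quasi-steady cytokine field C in [0, 1].

    0 = ∇·(D∇C) + λ_prod(1−C)·1_Ω − λ_circ·1_vessel·C − λ_decay·C.
    The circulation washout is proportional to C so the sink cannot
    drive the field negative.
    """
    ind = production_indicator(spec, region, agents)
    ves = vessel_indicator(network, region.labels.shape)
    decay = (spec.lambda_production_C * ind
             + spec.lambda_circulation_C * ves
             + spec.lambda_decay_C)
    source = spec.lambda_production_C * ind
    c = _solve_helmholtz(spec.D_C, decay, source, h, f"cytokine {spec.name}")
    return _check_bounds(c, f"cytokine {spec.name}")


def solve_pressure_velocity(lambda_p: np.ndarray, E: np.ndarray,
                            mech, h: float):
    """Darcy pressure and tissue velocity from the net proliferation rate.

    Solves −∇·(µ∇P) = λ_p − mean(λ_p) − ∇·(χ_E∇E) with zero-Neumann
    boundaries; the mean subtraction makes the singular Neumann system
    compatible and the returned pressure uses the zero-mean gauge.
    Velocity v_c = −µ∇P + χ_E∇E (node-centered central differences).
    """
    n = lambda_p.shape[0]
    lap = neumann_laplacian(n, h)
    rhs = lambda_p - lambda_p.mean()
    rhs = rhs - mech.chi_E * (lap @ E.ravel()).reshape(n, n)
    A = ((-mech.mu) * lap).tolil()
    # pin one node to fix the gauge of the compatible singular system
    A[0, :] = 0.0
    A[0, 0] = 1.0
    b = rhs.ravel().copy()
    b[0] = 0.0
    P = spla.spsolve(A.tocsc(), b).reshape(n, n)
    if not np.all(np.isfinite(P)):
        raise SolverError("pressure: non-finite solution")
    P = P - P.mean()
    gy, gx = gradient(P, h)
    ey, ex = gradient(E, h)
    vy = -mech.mu * gy + mech.chi_E * ey
    vx = -mech.mu * gx + mech.chi_E * ex
    return P, vy, vx


def face_velocity(P: np.ndarray, E: np.ndarray, mech, h: float):
    """Velocity on cell faces: (vy on (n-1,n) faces, vx on (n,n-1) faces).

    Staggered form of v_c = −µ∇P + χ_E∇E using the same forward
    differences as the pressure discretization, so the haptotaxis term
    inside the pressure solve cancels exactly and no spurious interface
    flow arises from sharp ECM gradients at the tumor edge.
    """
    gy, gx = face_gradient(P, h)
    ey, ex = face_gradient(E, h)
    return (-mech.mu * gy + mech.chi_E * ey,
            -mech.mu * gx + mech.chi_E * ex)


def velocity_divergence(P: np.ndarray, E: np.ndarray, mech, h: float) -> np.ndarray:
    """Discrete ∇·v_c evaluated with face-centered fluxes.

    Uses the same staggered discretization as the pressure solve, so for
    the solved P this equals λ_p − mean(λ_p) to solver tolerance.
    """
    vy, vx = face_velocity(P, E, mech, h)
    return face_divergence_matrixfree(vy, vx, h)


def step_mde(M: np.ndarray, region: RegionMap, tip_mask: np.ndarray,
             E: np.ndarray, params, h: float, dt: float) -> np.ndarray:
    """Explicit Euler step of the matrix-degrading enzyme field.

    dM/dt = ∇·(D_M∇M) + λ_prod(1−M)1_Ω_V + λ_sprout(1−M)1_tips
            − λ_degradation·E·M/(1+k_d E) − λ_decay·M
    """
    if params.D_M > 0 and dt > h * h / (4.0 * params.D_M):
        raise ConfigurationError(
            f"dt={dt} violates MDE CFL bound {h * h / (4.0 * params.D_M):.4g}"
        )
    n = M.shape[0]
    lap = neumann_laplacian(n, h)
    viable = region.viable_mask.astype(float)
    tips = tip_mask.astype(float)
    dM = (params.D_M * (lap @ M.ravel()).reshape(n, n)
          + params.lambda_production_M * (1.0 - M) * viable
          + params.lambda_sprout_production_M * (1.0 - M) * tips
          - params.lambda_degradation_M * E * M / (1.0 + params.k_d * E)
          - params.lambda_decay_M * M)
    return np.clip(M + dt * dM, 0.0, 1.0)
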