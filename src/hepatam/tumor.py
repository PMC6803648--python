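"""Tissue classification, proliferation with macrophage effects, ECM
evolution, and advance of the tumor interface.

The net proliferation rate is region-wise:

    normal          0
    proliferating   (λ_M + λ_M2)σ − (λ_A + λ_M1)
    hypoxic         λ_M2 σ − (λ_A + λ_M1)
    necrotic        −G_N

where λ_M1 is the local M1 nitric-oxide kill rate and λ_M2 the
M2-growth-factor proliferation boost. The quiescence oxygen threshold
separating proliferating from hypoxic tissue is itself a dynamic field,
transiently lowered by the M2 growth factor F.
"""

from __future__ import annotations

import numpy as np

from .config import ECMParams, TumorParams
from .state import HYPOXIC, NECROTIC, NORMAL, PROLIFERATING, RegionMap


def classify_regions(sigma: np.ndarray, tumor_mask: np.ndarray,
                     q_ol_current: np.ndarray, necrotic_threshold: float,
                     prev_region: RegionMap | None = None) -> RegionMap:
    """Label lattice nodes by oxygenation.

    Within the tumor mask: necrotic below the necrotic threshold,
    hypoxic below the local quiescence threshold, proliferating above.
    Necrosis is irreversible: nodes necrotic in ``prev_region`` stay
    necrotic. Hypoxic tissue may recover to proliferating.
    """
    labels = np.zeros(sigma.shape, dtype=np.int8)
    labels[tumor_mask & (sigma >= q_ol_current)] = PROLIFERATING
    labels[tumor_mask & (sigma < q_ol_current)] = HYPOXIC
    labels[tumor_mask & (sigma < necrotic_threshold)] = NECROTIC
    if prev_region is not None:
        labels[prev_region.necrotic_mask & tumor_mask] = NECROTIC
    return RegionMap(labels)


def proliferation_field(region: RegionMap, sigma: np.ndarray,
                        lambda_M1_field: np.ndarray, lambda_M2_rate: np.ndarray,
                        params: TumorParams) -> np.ndarray:
    """Region-wise net proliferation rate λ_p."""
    lam = np.zeros(sigma.shape)
    p = region.proliferating_mask
    h = region.hypoxic_mask
    nec = region.necrotic_mask
    lam[p] = ((params.lambda_M + lambda_M2_rate[p]) * sigma[p]
              - (params.lambda_A + lambda_M1_field[p]))
    lam[h] = lambda_M2_rate[h] * sigma[h] - (params.lambda_A + lambda_M1_field[h])
    lam[nec] = -params.G_N
    return lam


def update_m2_rate(lambda_M2: np.ndarray, F: np.ndarray, lambda_F: float,
                   lambda_M: float, dt: float) -> np.ndarray:
    """Euler step of dλ_M2/dt = λ_F F (1 − (λ_M + λ_M2)), capped so the
    combined mitysis+boost rate never exceeds 1."""
    out = lambda_M2 + dt * lambda_F * F * (1.0 - (lambda_M + lambda_M2))
    return np.clip(out, 0.0, max(0.0, 1.0 - lambda_M))


def update_quiescence(q_ol: np.ndarray, F: np.ndarray, params: TumorParams,
                      dt: float) -> np.ndarray:
    """Euler step of the quiescence-threshold relaxation.

    dQ/dt = λ_OL (1−F)(Q̄ − Q) − λ_OT F (Q − Q_min), clamped to
    [Q_min, Q̄] afterwards.
    """
    dq = (params.lambda_OL * (1.0 - F) * (params.Q_OL_bar - q_ol)
          - params.lambda_OT * F * (q_ol - params.Q_OL_min))
    return np.clip(q_ol + dt * dq, params.Q_OL_min, params.Q_OL_bar)


def step_ecm(E: np.ndarray, M: np.ndarray, region: RegionMap,
             tip_mask: np.ndarray, params: ECMParams, dt: float) -> np.ndarray:
    """Euler step of the ECM density balance.

    Production by viable tumor and sprout tips saturates with existing
    density (1/(1+k_p E)); degradation is MDE-mediated
    (λ_deg E M/(1+k_d E)). Density stays non-negative.
    """
    viable = region.viable_mask.astype(float)
    tips = tip_mask.astype(float)
    dE = (params.lambda_production_E / (1.0 + params.k_p * E) * viable
          + params.lambda_sprout_production_E / (1.0 + params.k_p * E) * tips
          - params.lambda_degradation_E * E * M / (1.0 + params.k_d * E))
    return np.maximum(E + dt * dE, 0.0)


def _boundary_mask(tumor_mask: np.ndarray) -> np.ndarray:
    """Tumor nodes with at least one 4-neighbor outside the mask."""
    pad = np.pad(tumor_mask, 1, constant_values=False)
    nb_all = (pad[:-2, 1:-1] & pad[2:, 1:-1] & pad[1:-1, :-2] & pad[1:-1, 2:])
    return tumor_mask & ~nb_all


def advance_tumor(region: RegionMap, vy_face: np.ndarray, vx_face: np.ndarray,
                  lambda_p: np.ndarray, deficit: np.ndarray,
                  rng: np.random.Generator, h: float, dt: float) -> RegionMap:
    """Advance (or retreat) the tumor interface on the lattice.

    ``vy_face``/``vx_face`` are the staggered (face-centered) Darcy
    velocities. A boundary tumor node converts an adjacent normal node
    with probability min(1, v_n dt/h) when the face velocity between
    them points outward. Shrinkage is handled by cumulative
    bookkeeping: ``deficit`` (updated in place) accumulates λ_p dt at
    boundary nodes with λ_p < 0 (necrotic debris clears at −G_N); a
    node reverts to normal once its deficit reaches −1.
    """
    labels = region.labels.copy()
    tumor = labels != NORMAL
    if not tumor.any():
        return RegionMap(labels)
    boundary = _boundary_mask(tumor)
    n = labels.shape[0]

    def face_component(rows, cols, dr, dc):
        """Outward velocity across the face from (r,c) toward (r+dr,c+dc)."""
        if dr == 1:
            return vy_face[rows, cols]
        if dr == -1:
            return -vy_face[rows - 1, cols]
        if dc == 1:
            return vx_face[rows, cols]
        return -vx_face[rows, cols - 1]

    # growth: per direction, boundary tumor node -> normal neighbor
    for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        src = np.zeros_like(tumor)
        src[max(0, -dr):n - max(0, dr), max(0, -dc):n - max(0, dc)] = True
        cand = boundary & src
        rows, cols = np.nonzero(cand)
        if rows.size == 0:
            continue
        tr, tc = rows + dr, cols + dc
        open_t = labels[tr, tc] == NORMAL
        rows, cols, tr, tc = rows[open_t], cols[open_t], tr[open_t], tc[open_t]
        if rows.size == 0:
            continue
        vn = face_component(rows, cols, dr, dc)
        p = np.clip(vn * dt / h, 0.0, 1.0)
        hit = rng.random(rows.size) < p
        labels[tr[hit], tc[hit]] = PROLIFERATING

    # shrinkage bookkeeping on boundary nodes with negative net growth
    shrink = boundary & (lambda_p < 0.0)
    deficit[shrink] += lambda_p[shrink] * dt
    deficit[~shrink] = 0.0
    gone = shrink & (deficit <= -1.0)
    labels[gone] = NORMAL
    deficit[gone] = 0.0
    return RegionMap(labels)
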