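"""Discrete macrophage agents: extravasation, chemotactic migration,
M1/M2 polarization, and effector fields.

Naive monocytes leave the vasculature in proportion to the local
chemoattractant (TAF) gradient, random-walk through the interstitium
with a bias up the chemoattractant gradient and down the oxygen and
pressure gradients, and polarize terminally inside the tumor
microenvironment: high TNF-α drives the pro-inflammatory M1 fate, high
TGF-β1 the trophic M2 fate. M1 agents release nitric oxide in their
immediate vicinity (a local kill-rate field); M2 agents source the
diffusible growth factor F.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .config import MacrophageParams
from .state import AgentPopulation, RegionMap


class ContractError(RuntimeError):
    """An operation was invoked outside its stated preconditions."""


class PopulationFractions(NamedTuple):
    naive: float
    m1: float
    m2: float
    empty: bool


def tme_mask(region: RegionMap, margin: int) -> np.ndarray:
    """Tumor microenvironment: the tumor mask dilated by ``margin`` nodes."""
    if margin <= 0:
        return region.tumor_mask.copy()
    struct = ndimage.generate_binary_structure(2, 1)
    return ndimage.binary_dilation(region.tumor_mask, structure=struct,
                                   iterations=margin)


def center_bias_field(region: RegionMap) -> np.ndarray:
    """Concentric field: 1 at the tumor centroid, 0 at the lesion boundary.

    Linear in distance from the centroid within the tumor mask, zero
    outside; used to bias M1 migration toward the lesion core.
    """
    mask = region.tumor_mask
    out = np.zeros(mask.shape)
    if not mask.any():
        return out
    rows, cols = np.nonzero(mask)
    cr, cc = rows.mean(), cols.mean()
    d = np.hypot(rows - cr, cols - cc)
    dmax = d.max()
    if dmax == 0:
        out[rows, cols] = 1.0
    else:
        out[rows, cols] = 1.0 - d / dmax
    return out


def extravasate(network, chemoattractant: np.ndarray, params: MacrophageParams,
                rng: np.random.Generator, dt: float, h: float) -> tuple[np.ndarray, np.ndarray]:
    """Spawn naive agents at vessel nodes.

    Each vessel node spawns with probability
    min(1, extravasation_rate * |∇C| * dt); the gradient magnitude is
    the central-difference estimate in physical (per-mm) units.
    """
    from .grid import gradient_magnitude

    gmag = gradient_magnitude(chemoattractant, h)
    rows, cols = np.nonzero(network.vessel_mask())
    if rows.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    p = np.minimum(1.0, params.extravasation_rate * gmag[rows, cols] * dt)
    hit = rng.random(rows.size) < p
    return rows[hit], cols[hit]


def _migration_potentials(fields, region: RegionMap, params: MacrophageParams):
    """Scalar potentials whose neighbor differences give the step scores."""
    base = (params.w_chem * fields.taf
            - params.w_oxy * fields.sigma
            - params.w_press * fields.pressure)
    m1 = base + params.m1_center_bias_weight * center_bias_field(region)
    return base, m1


def migrate(agents: AgentPopulation, fields, region: RegionMap,
            params: MacrophageParams, rng: np.random.Generator, dt: float) -> None:
    """Move all agents by up to motility*dt biased lattice steps (in place).

    Each step samples among the in-bounds 4-neighbors with probability
    proportional to exp(score), where the score is the change of the
    taxis potential (chemoattractant up; oxygen and pressure down; plus
    the concentric center bias for M1 agents). Agents never leave the
    domain.
    """
    n_agents = len(agents)
    if n_agents == 0:
        return
    base, m1pot = _migration_potentials(fields, region, params)
    n = base.shape[0]
    # pad potentials with -inf so out-of-bounds neighbors get zero weight
    pads = []
    for pot in (base, m1pot):
        p = np.full((n + 2, n + 2), -np.inf)
        p[1:-1, 1:-1] = pot
        pads.append(p)
    offsets = np.array([(-1, 0), (1, 0), (0, -1), (0, 1)])

    total = params.motility * dt
    k_full = int(total)
    frac = total - k_full
    for sub in range(k_full + 1):
        if sub == k_full:
            active = rng.random(n_agents) < frac
        else:
            active = np.ones(n_agents, dtype=bool)
        if not active.any():
            continue
        r = agents.row[active]
        c = agents.col[active]
        is_m1 = agents.phenotype[active] == AgentPopulation.M1
        here = np.where(is_m1, pads[1][r + 1, c + 1], pads[0][r + 1, c + 1])
        scores = np.empty((r.size, 4))
        for k, (dr, dc) in enumerate(offsets):
            nb = np.where(is_m1, pads[1][r + 1 + dr, c + 1 + dc],
                          pads[0][r + 1 + dr, c + 1 + dc])
            scores[:, k] = nb - here
        w = np.exp(scores - scores.max(axis=1, keepdims=True))
        w /= w.sum(axis=1, keepdims=True)
        cum = np.cumsum(w, axis=1)
        u = rng.random(r.size)[:, None]
        choice = (u > cum).sum(axis=1)
        agents.row[active] = r + offsets[choice, 0]
        agents.col[active] = c + offsets[choice, 1]
    agents.age += dt


def polarize(agents: AgentPopulation, c_tnf: np.ndarray, c_tgf: np.ndarray,
             in_tme: np.ndarray, params: MacrophageParams,
             rng: np.random.Generator, dt: float,
             idx: np.ndarray | None = None) -> None:
    """Terminal polarization of naive agents inside the tumor microenvironment.

    A naive agent whose local TNF-α exceeds its threshold commits to M1
    (TGF-β1 to M2) with probability polarization_prob*dt; when both
    thresholds are exceeded, the species with the larger normalized
    excess (C − θ)/θ wins, ties going to M1. Raises ContractError if
    invoked on already-polarized agents.
    """
    if idx is None:
        idx = np.arange(len(agents))
    idx = np.asarray(idx, dtype=np.int64)
    if idx.size == 0:
        return
    if np.any(agents.phenotype[idx] != AgentPopulation.NAIVE):
        raise ContractError("polarize called on non-naive agent(s)")
    r, c = agents.row[idx], agents.col[idx]
    eligible = in_tme[r, c]
    tnf = c_tnf[r, c]
    tgf = c_tgf[r, c]
    ex_tnf = (tnf - params.tnf_threshold) / params.tnf_threshold
    ex_tgf = (tgf - params.tgf_threshold) / params.tgf_threshold
    above_tnf = tnf >= params.tnf_threshold
    above_tgf = tgf >= params.tgf_threshold
    fires = eligible & (above_tnf | above_tgf) & (
        rng.random(idx.size) < min(1.0, params.polarization_prob * dt))
    to_m1 = fires & (above_tnf & (~above_tgf | (ex_tnf >= ex_tgf)))
    to_m2 = fires & ~to_m1
    agents.phenotype[idx[to_m1]] = AgentPopulation.M1
    agents.phenotype[idx[to_m2]] = AgentPopulation.M2


def m1_effect_field(agents: AgentPopulation, shape: tuple[int, int],
                    params: MacrophageParams) -> np.ndarray:
    """Nitric-oxide kill-rate field λ_M1 = λ_NO × (M1 count within the
    Chebyshev neighborhood radius), additive across agents."""
    counts = np.zeros(shape)
    m1 = agents.phenotype == AgentPopulation.M1
    if m1.any():
        np.add.at(counts, (agents.row[m1], agents.col[m1]), 1.0)
    r = params.m1_neighborhood
    if r > 0:
        size = 2 * r + 1
        counts = ndimage.uniform_filter(counts, size=size, mode="constant") * size**2
        counts = np.round(counts)  # window sums are integers up to rounding
    return params.lambda_NO * counts


def population_fractions(agents: AgentPopulation) -> PopulationFractions:
    """Naive/M1/M2 fractions of the agent population; flagged if empty."""
    total = len(agents)
    if total == 0:
        return PopulationFractions(0.0, 0.0, 0.0, True)
    m1 = int((agents.phenotype == AgentPopulation.M1).sum())
    m2 = int((agents.phenotype == AgentPopulation.M2).sum())
    return PopulationFractions((total - m1 - m2) / total, m1 / total, m2 / total, False)
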