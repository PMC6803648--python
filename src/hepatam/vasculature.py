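"""Capillary grid, TAF-driven angiogenic sprouting, and oxygen extravasation.

The pre-existing vasculature is an evenly spaced grid of capillary lines
(denser for the metastatic liver environment). Hypoxic tumor tissue
releases tumor angiogenic factors (TAF) that trigger new sprouts from
nearby vessels; sprout tips climb the TAF gradient on the lattice and
anastomose when they meet other vessels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import SimulationConfig

NEIGHBOR_OFFSETS = np.array([(-1, 0), (1, 0), (0, -1), (0, 1)])


@dataclass
class VesselNetwork:
    """Pre-existing capillary grid plus angiogenic sprout segments."""

    n: int
    pre_mask: np.ndarray                      # bool lattice, pre-existing vessels
    neo_mask: np.ndarray                      # bool lattice, sprout path nodes
    sprout_paths: list = field(default_factory=list)   # list of [(r, c), ...]
    tips: list = field(default_factory=list)           # active tip (path_index, r, c)
    connections: list = field(default_factory=list)    # recorded anastomoses (r, c)

    def vessel_mask(self) -> np.ndarray:
        return self.pre_mask | self.neo_mask

    @property
    def tip_mask(self) -> np.ndarray:
        m = np.zeros((self.n, self.n), dtype=bool)
        for _, r, c in self.tips:
            m[r, c] = True
        return m

    def node_count(self) -> int:
        return int(self.vessel_mask().sum())

    def copy(self) -> "VesselNetwork":
        return VesselNetwork(self.n, self.pre_mask.copy(), self.neo_mask.copy(),
                             [list(p) for p in self.sprout_paths], list(self.tips),
                             list(self.connections))


def build_vessel_grid(n: int, line_spacing: int) -> VesselNetwork:
    """Evenly spaced capillary grid: lines on rows/cols ≡ 0 mod spacing."""
    pre = np.zeros((n, n), dtype=bool)
    pre[::line_spacing, :] = True
    pre[:, ::line_spacing] = True
    return VesselNetwork(n=n, pre_mask=pre, neo_mask=np.zeros((n, n), dtype=bool))


def vessel_indicator(network: VesselNetwork, shape: tuple[int, int]) -> np.ndarray:
    """Characteristic function: 1 at vessel nodes (pre-existing + sprouts)."""
    ind = np.zeros(shape)
    ind[network.pre_mask] = 1.0
    ind[network.neo_mask] = 1.0
    return ind


def oxygen_source(network: VesselNetwork, pressure: np.ndarray, sigma: np.ndarray,
                  config: SimulationConfig) -> np.ndarray:
    """Pressure-modulated oxygen extravasation rate field.

    lambda_ev(x) = 1_vessel(x) * lambda_supply * h * (1 - sigma) *
    max(0, 1 - P/P_eff), with the supply rate taken per node from the
    pre-existing or neovascular flag.
    """
    vp = config.vessels
    supply = np.zeros_like(pressure)
    supply[network.pre_mask] = vp.lambda_pre_sigma
    supply[network.neo_mask & ~network.pre_mask] = vp.lambda_neo_sigma
    mod = np.maximum(0.0, 1.0 - pressure / vp.effective_pressure)
    return supply * vp.hematocrit_h * (1.0 - sigma) * mod


def extravasation_conductance(network: VesselNetwork, pressure: np.ndarray,
                              config: SimulationConfig) -> np.ndarray:
    """The sigma-independent factor s(x) with lambda_ev = s * (1 - sigma).

    Splitting out s(x) lets the quasi-steady oxygen solve treat the
    extravasation source implicitly (linear in sigma), which keeps the
    solution in [0, 1] by the discrete maximum principle.
    """
    vp = config.vessels
    supply = np.zeros_like(pressure)
    supply[network.pre_mask] = vp.lambda_pre_sigma
    supply[network.neo_mask & ~network.pre_mask] = vp.lambda_neo_sigma
    mod = np.maximum(0.0, 1.0 - pressure / vp.effective_pressure)
    return supply * vp.hematocrit_h * mod


def _near_vessel(mask: np.ndarray, r: int, c: int, radius: int,
                 exclude: set | None = None) -> tuple[int, int] | None:
    """Closest vessel node within a Chebyshev radius, or None."""
    n = mask.shape[0]
    best = None
    for dr in range(-radius, radius + 1):
        for dc in range(-radius, radius + 1):
            rr, cc = r + dr, c + dc
            if 0 <= rr < n and 0 <= cc < n and mask[rr, cc]:
                if exclude and (rr, cc) in exclude:
                    continue
                d = max(abs(dr), abs(dc))
                if best is None or d < best[0]:
                    best = (d, rr, cc)
    return None if best is None else (best[1], best[2])


def sprout_step(network: VesselNetwork, taf: np.ndarray, region,
                rng: np.random.Generator, config: SimulationConfig,
                dt: float) -> VesselNetwork:
    """One angiogenesis step: launch new tips and advance existing ones.

    Vessel nodes above the TAF sprouting threshold launch a tip with
    probability sprout_rate*dt; each active tip advances tip_step*dt
    lattice nodes along the steepest local TAF ascent (with a small
    random perturbation breaking ties) and terminates by anastomosis
    when it reaches another vessel. The vessel node set only grows.
    """
    vp = config.vessels
    net = network
    n = net.n
    vmask = net.vessel_mask()

    # --- tip launches ---------------------------------------------------
    candidates = np.argwhere(vmask & (taf > vp.taf_sprout_threshold))
    if candidates.size:
        draws = rng.random(len(candidates))
        launch_p = min(1.0, vp.sprout_rate * dt)
        for (r, c), u in zip(candidates, draws):
            if u < launch_p:
                net.sprout_paths.append([(int(r), int(c))])
                net.tips.append((len(net.sprout_paths) - 1, int(r), int(c)))

    # --- tip advance ----------------------------------------------------
    steps_f = vp.tip_step * dt
    n_steps = int(steps_f) + (1 if rng.random() < steps_f - int(steps_f) else 0)
    surviving = []
    for path_idx, r, c in net.tips:
        alive = True
        path = net.sprout_paths[path_idx]
        own = set(path)
        for _ in range(n_steps):
            scores = []
            for dr, dc in NEIGHBOR_OFFSETS:
                rr, cc = r + dr, c + dc
                if not (0 <= rr < n and 0 <= cc < n) or (rr, cc) in own:
                    scores.append(-np.inf)
                else:
                    scores.append(taf[rr, cc] + 0.01 * rng.standard_normal())
            k = int(np.argmax(scores))
            if not np.isfinite(scores[k]):
                alive = False  # boxed in
                break
            r, c = r + NEIGHBOR_OFFSETS[k][0], c + NEIGHBOR_OFFSETS[k][1]
            r, c = int(r), int(c)
            path.append((r, c))
            own.add((r, c))
            net.neo_mask[r, c] = True
            hit = _near_vessel(net.vessel_mask() | net.pre_mask, r, c,
                               vp.anastomosis_radius, exclude=own)
            if hit is not None:
                net.connections.append((r, c))
                alive = False
                break
        if alive:
            surviving.append((path_idx, r, c))
    net.tips = surviving
    return net
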