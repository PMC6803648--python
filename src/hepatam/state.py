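"""Simulation state containers and tumor geometry metrics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ConfigurationError, SimulationConfig

# Region labels
NORMAL = 0
PROLIFERATING = 1
HYPOXIC = 2
NECROTIC = 3
REGION_NAMES = {NORMAL: "normal", PROLIFERATING: "proliferating",
                HYPOXIC: "hypoxic", NECROTIC: "necrotic"}


@dataclass
class RegionMap:
    """Per-node tissue label: normal / proliferating / hypoxic / necrotic."""

    labels: np.ndarray  # int8 lattice of region codes

    @property
    def tumor_mask(self) -> np.ndarray:
        return self.labels != NORMAL

    @property
    def viable_mask(self) -> np.ndarray:
        """Proliferating or hypoxic tumor tissue."""
        return (self.labels == PROLIFERATING) | (self.labels == HYPOXIC)

    @property
    def necrotic_mask(self) -> np.ndarray:
        return self.labels == NECROTIC

    @property
    def hypoxic_mask(self) -> np.ndarray:
        return self.labels == HYPOXIC

    @property
    def proliferating_mask(self) -> np.ndarray:
        return self.labels == PROLIFERATING

    def copy(self) -> "RegionMap":
        return RegionMap(self.labels.copy())


@dataclass
class FieldState:
    """All scalar lattices of the continuum model."""

    sigma: np.ndarray        # oxygen, [0, 1]
    pressure: np.ndarray     # oncotic/solid pressure (zero-mean gauge)
    ecm: np.ndarray          # ECM density E >= 0
    mde: np.ndarray          # matrix-degrading enzyme M, [0, 1]
    c_tnf: np.ndarray        # TNF-alpha, [0, 1]
    c_tgf: np.ndarray        # TGF-beta1, [0, 1]
    taf: np.ndarray          # tumor angiogenic factor, [0, 1]
    f_m2: np.ndarray         # M2 growth factor F, [0, 1]
    lambda_p: np.ndarray     # net proliferation rate field
    lambda_M1_field: np.ndarray  # M1 nitric-oxide kill-rate field
    lambda_M2_rate: np.ndarray   # spatial state of the M2 proliferation-boost ODE
    q_ol_current: np.ndarray     # spatial state of the quiescence-threshold ODE

    @classmethod
    def zeros(cls, n: int, e_far: float, q_ol_bar: float) -> "FieldState":
        z = lambda: np.zeros((n, n))
        return cls(sigma=z(), pressure=z(), ecm=np.full((n, n), e_far),
                   mde=z(), c_tnf=z(), c_tgf=z(), taf=z(), f_m2=z(),
                   lambda_p=z(), lambda_M1_field=z(), lambda_M2_rate=z(),
                   q_ol_current=np.full((n, n), q_ol_bar))

    def copy(self) -> "FieldState":
        return FieldState(**{k: v.copy() for k, v in self.__dict__.items()})


@dataclass
class AgentPopulation:
    """Discrete macrophage agents stored as parallel arrays."""

    row: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    col: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    phenotype: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int8))
    age: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=float))

    NAIVE, M1, M2 = 0, 1, 2

    def __len__(self) -> int:
        return self.row.size

    def append(self, rows: np.ndarray, cols: np.ndarray) -> None:
        k = len(rows)
        self.row = np.concatenate([self.row, np.asarray(rows, dtype=np.int64)])
        self.col = np.concatenate([self.col, np.asarray(cols, dtype=np.int64)])
        self.phenotype = np.concatenate([self.phenotype, np.zeros(k, dtype=np.int8)])
        self.age = np.concatenate([self.age, np.zeros(k)])

    def copy(self) -> "AgentPopulation":
        return AgentPopulation(self.row.copy(), self.col.copy(),
                               self.phenotype.copy(), self.age.copy())


def seed_region(n: int, radius_nodes: int) -> RegionMap:
    """Proliferating disc of the given node radius at the domain center."""
    labels = np.zeros((n, n), dtype=np.int8)
    if radius_nodes > 0:
        c = (n - 1) / 2.0
        yy, xx = np.mgrid[0:n, 0:n]
        labels[(yy - c) ** 2 + (xx - c) ** 2 <= radius_nodes**2] = PROLIFERATING
    return RegionMap(labels)


def tumor_radius(region: RegionMap, spacing: float) -> float:
    """Equivalent circular radius of the tumor mask (mm).

    Uses the area-equivalent definition r = sqrt(A/pi) with
    A = (number of tumor nodes) * spacing^2; the whole lesion including
    the necrotic core counts as tumor.
    """
    count = int(region.tumor_mask.sum())
    return float(np.sqrt(count * spacing**2 / np.pi))


def build_state(config: SimulationConfig):
    """Initialize (FieldState, RegionMap, VesselNetwork, AgentPopulation).

    The tumor is seeded as a small proliferating disc at the domain
    center, ECM starts at the case's far-field density, oxygen is
    obtained from one quasi-steady solve against the initial regions,
    and the capillary grid spacing follows the tumor type. No
    macrophages are present at t = 0.
    """
    from .rd import solve_oxygen
    from .vasculature import build_vessel_grid

    try:
        config.validate()
    except ConfigurationError:
        raise
    n = config.grid_nodes_per_side
    region = seed_region(n, config.seed_radius_nodes)
    network = build_vessel_grid(n, config.line_spacing)
    fields = FieldState.zeros(n, config.e_far, config.tumor.Q_OL_bar)
    fields.sigma = solve_oxygen(region, network, fields.pressure, config)
    agents = AgentPopulation()
    return fields, region, network, agents
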