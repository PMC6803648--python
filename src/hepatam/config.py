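"""Configuration schema for the hybrid tumor-macrophage-ECM model.

All rates are non-dimensional: lengths are in mm, time in days, and every
concentration field (oxygen, cytokines, MDE) is normalized to [0, 1]
against its vascular or saturation reference. ECM density is in units of
the normal-liver far-field density and is unbounded above.

The dataclass defaults ARE the shipped calibrated parameter set: the
four study cases (primary/metastatic tumor × control/transitional ECM)
are produced from these defaults by :func:`case_config`, which applies
the case-specific settings (10-fold TNF-α production and a denser
capillary grid plus a lower necrotic threshold for metastatic tumors; a
denser, slower-degrading matrix for transitional ECM).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Literal

TumorType = Literal["primary", "metastatic"]
EcmType = Literal["cECM", "tECM"]


class ConfigurationError(ValueError):
    """Raised when a configuration violates a model invariant."""


@dataclass
class TumorParams:
    """Tumor tissue kinetics (all rates 1/day, thresholds dimensionless)."""

    lambda_M: float = 1.0          # native mitosis rate
    lambda_A: float = 0.1          # native apoptosis rate
    G_N: float = 0.5               # necrotic debris degradation rate
    Q_OL_bar: float = 0.45         # standard quiescence oxygen threshold
    Q_OL_min: float = 0.30         # floor of the quiescence threshold
    necrotic_threshold: float = 0.25
    lambda_OL: float = 1.0         # quiescence-threshold recovery rate
    lambda_OT: float = 1.0         # M2-growth-factor threshold-lowering rate
    lambda_F: float = 0.25         # M2 growth-factor effect rate on proliferation

    def validate(self) -> None:
        if not (0.0 <= self.necrotic_threshold < self.Q_OL_min <= self.Q_OL_bar <= 1.0):
            raise ConfigurationError(
                "TumorParams requires 0 <= necrotic_threshold < Q_OL_min <= Q_OL_bar <= 1"
            )
        if self.lambda_M <= self.lambda_A:
            raise ConfigurationError("TumorParams.lambda_M must exceed lambda_A")
        for name in ("lambda_M", "lambda_A", "G_N", "lambda_OL", "lambda_OT", "lambda_F"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"TumorParams.{name} must be >= 0")


@dataclass
class MechanicsParams:
    mu: float = 1.0        # Darcy tissue mobility
    chi_E: float = 0.01    # haptotaxis coefficient

    def validate(self) -> None:
        if self.mu <= 0:
            raise ConfigurationError("MechanicsParams.mu must be > 0")
        if self.chi_E < 0:
            raise ConfigurationError("MechanicsParams.chi_E must be >= 0")


@dataclass
class OxygenParams:
    """Oxygen transport: quasi-steady diffusion with region-wise uptake."""

    D_sigma: float = 1.0
    lambda_tissue_sigma: float = 8.0    # uptake by normal tissue
    lambda_tumor_sigma: float = 30.0    # uptake by proliferating tumor
    q_sigma: float = 25.0               # uptake in hypoxic tumor (linear in sigma)
    lambda_N_sigma: float = 3.0         # decay in necrotic region

    def validate(self) -> None:
        for name in dataclasses.asdict(self):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"OxygenParams.{name} must be >= 0")
        if self.q_sigma > self.lambda_tumor_sigma:
            raise ConfigurationError("OxygenParams.q_sigma must not exceed lambda_tumor_sigma")


@dataclass
class CytokineSpec:
    """One diffusible species solved by the quasi-steady cytokine equation."""

    name: str
    D_C: float
    lambda_production_C: float
    lambda_circulation_C: float
    lambda_decay_C: float
    production_region: Literal["viable_tumor", "hypoxic_tumor", "M2_agents"]

    def validate(self) -> None:
        for f in ("D_C", "lambda_production_C", "lambda_circulation_C", "lambda_decay_C"):
            if getattr(self, f) < 0:
                raise ConfigurationError(f"CytokineSpec[{self.name}].{f} must be >= 0")
        if self.name == "TAF" and self.production_region != "hypoxic_tumor":
            raise ConfigurationError("TAF must be produced by hypoxic tumor tissue")
        if self.name == "F" and self.production_region != "M2_agents":
            raise ConfigurationError("F must be produced by M2 agents")


@dataclass
class ECMParams:
    lambda_production_E: float = 1.0
    lambda_sprout_production_E: float = 0.5
    lambda_degradation_E: float = 8.0
    k_p: float = 1.0
    k_d: float = 1.0
    E_far_cECM: float = 0.5
    E_far_tECM: float = 0.75

    def validate(self) -> None:
        for name in dataclasses.asdict(self):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"ECMParams.{name} must be >= 0")
        if self.E_far_tECM <= self.E_far_cECM:
            raise ConfigurationError("ECMParams.E_far_tECM must exceed E_far_cECM")


@dataclass
class MDEParams:
    D_M: float = 0.004
    lambda_production_M: float = 2.0
    lambda_sprout_production_M: float = 1.0
    lambda_degradation_M: float = 1.0
    lambda_decay_M: float = 2.0
    k_d: float = 1.0

    def validate(self) -> None:
        for name in dataclasses.asdict(self):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"MDEParams.{name} must be >= 0")


@dataclass
class MacrophageParams:
    extravasation_rate: float = 1.0    # agents/day per vessel node per unit |grad C|
    motility: float = 20.0             # lattice steps/day
    w_chem: float = 10.0               # taxis weight: chemoattractant gradient (up)
    w_oxy: float = 2.0                 # taxis weight: oxygen gradient (down)
    w_press: float = 5.0               # taxis weight: pressure gradient (down)
    m1_center_bias_weight: float = 20.0
    tnf_threshold: float = 0.24
    tgf_threshold: float = 0.172
    polarization_prob: float = 2.0     # 1/day once threshold exceeded
    lambda_NO: float = 0.007           # M1 nitric-oxide kill-rate contribution
    m1_neighborhood: int = 2           # Chebyshev radius of NO action (nodes)
    f_production: float = 10.0         # M2 growth-factor production rate
    tme_margin: int = 5                # polarization margin beyond tumor mask (nodes)

    def validate(self) -> None:
        for name in ("tnf_threshold", "tgf_threshold"):
            if not (0.0 < getattr(self, name) < 1.0):
                raise ConfigurationError(f"MacrophageParams.{name} must lie in (0, 1)")
        for name in ("extravasation_rate", "motility", "w_chem", "w_oxy", "w_press",
                     "m1_center_bias_weight", "polarization_prob", "lambda_NO",
                     "f_production"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"MacrophageParams.{name} must be >= 0")
        if self.m1_neighborhood < 0:
            raise ConfigurationError("MacrophageParams.m1_neighborhood must be >= 0")


@dataclass
class VesselParams:
    line_spacing_primary: int = 10     # nodes between capillary lines
    line_spacing_metastatic: int = 6   # denser grid for the liver environment
    sprout_rate: float = 0.2           # tip-launch probability/day at high TAF
    tip_step: float = 10.0             # tip advance, nodes/day
    taf_sprout_threshold: float = 0.15
    anastomosis_radius: int = 1
    lambda_pre_sigma: float = 150.0    # oxygen supply rate, pre-existing vessels
    lambda_neo_sigma: float = 30.0     # oxygen supply rate, neovasculature
    hematocrit_h: float = 0.45
    effective_pressure: float = 0.01   # pressure scale choking intratumoral supply

    def validate(self) -> None:
        if self.line_spacing_metastatic >= self.line_spacing_primary:
            raise ConfigurationError(
                "VesselParams.line_spacing_metastatic must be < line_spacing_primary"
            )
        if not (0.0 <= self.hematocrit_h <= 1.0):
            raise ConfigurationError("VesselParams.hematocrit_h must lie in [0, 1]")
        for name in ("sprout_rate", "tip_step", "taf_sprout_threshold",
                     "lambda_pre_sigma", "lambda_neo_sigma", "effective_pressure"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"VesselParams.{name} must be >= 0")
        if self.anastomosis_radius < 0:
            raise ConfigurationError("VesselParams.anastomosis_radius must be >= 0")


def _default_cytokines() -> dict[str, CytokineSpec]:
    return {
        "TNF": CytokineSpec("TNF", D_C=0.05, lambda_production_C=20.0,
                            lambda_circulation_C=60.0, lambda_decay_C=20.0,
                            production_region="viable_tumor"),
        "TGFB1": CytokineSpec("TGFB1", D_C=0.5, lambda_production_C=10.0,
                              lambda_circulation_C=1.0, lambda_decay_C=10.0,
                              production_region="viable_tumor"),
        "TAF": CytokineSpec("TAF", D_C=0.75, lambda_production_C=10.0,
                            lambda_circulation_C=2.0, lambda_decay_C=8.0,
                            production_region="hypoxic_tumor"),
        "F": CytokineSpec("F", D_C=0.3, lambda_production_C=10.0,
                          lambda_circulation_C=1.0, lambda_decay_C=10.0,
                          production_region="M2_agents"),
    }


@dataclass
class SimulationConfig:
    grid_nodes_per_side: int = 61
    node_spacing: float = 2.0 / 61     # mm; domain side = nodes * spacing = 2 mm
    t_end: float = 13.0                # simulated days
    dt: float = 0.025                  # days per step
    tumor_type: TumorType = "primary"
    ecm_type: EcmType = "cECM"
    polarization_enabled: bool = True
    rng_seed: int = 0
    seed_radius_nodes: int = 3
    tnf_metastatic_fold: float = 10.0  # calibrated from the co-culture assay
    tumor: TumorParams = field(default_factory=TumorParams)
    mechanics: MechanicsParams = field(default_factory=MechanicsParams)
    oxygen: OxygenParams = field(default_factory=OxygenParams)
    cytokines: dict[str, CytokineSpec] = field(default_factory=_default_cytokines)
    ecm: ECMParams = field(default_factory=ECMParams)
    mde: MDEParams = field(default_factory=MDEParams)
    macrophage: MacrophageParams = field(default_factory=MacrophageParams)
    vessels: VesselParams = field(default_factory=VesselParams)

    def validate(self) -> None:
        if self.grid_nodes_per_side < 16:
            raise ConfigurationError("SimulationConfig.grid_nodes_per_side must be >= 16")
        if self.node_spacing <= 0:
            raise ConfigurationError("SimulationConfig.node_spacing must be > 0")
        if self.dt <= 0:
            raise ConfigurationError("SimulationConfig.dt must be > 0")
        if self.t_end <= 0:
            raise ConfigurationError("SimulationConfig.t_end must be > 0")
        if self.tumor_type not in ("primary", "metastatic"):
            raise ConfigurationError(f"unknown tumor_type {self.tumor_type!r}")
        if self.ecm_type not in ("cECM", "tECM"):
            raise ConfigurationError(f"unknown ecm_type {self.ecm_type!r}")
        if self.seed_radius_nodes < 0:
            raise ConfigurationError("SimulationConfig.seed_radius_nodes must be >= 0")
        # MDE explicit Euler stability
        cfl = self.node_spacing**2 / (4.0 * self.mde.D_M) if self.mde.D_M > 0 else float("inf")
        if self.dt > cfl:
            raise ConfigurationError(
                f"SimulationConfig.dt={self.dt} violates the MDE CFL bound h^2/(4 D_M)={cfl:.4g}"
            )
        self.tumor.validate()
        self.mechanics.validate()
        self.oxygen.validate()
        self.ecm.validate()
        self.mde.validate()
        self.macrophage.validate()
        self.vessels.validate()
        for spec in self.cytokines.values():
            spec.validate()

    # -- case resolution -------------------------------------------------
    @property
    def domain_side(self) -> float:
        """Physical domain side length (mm)."""
        return self.grid_nodes_per_side * self.node_spacing

    @property
    def line_spacing(self) -> int:
        """Capillary line spacing for this case's tumor type."""
        return (self.vessels.line_spacing_metastatic
                if self.tumor_type == "metastatic"
                else self.vessels.line_spacing_primary)

    @property
    def e_far(self) -> float:
        """Far-field ECM density for this case's construct."""
        return self.ecm.E_far_tECM if self.ecm_type == "tECM" else self.ecm.E_far_cECM

    def resolved_cytokines(self) -> dict[str, CytokineSpec]:
        """Cytokine specs with case-dependent rates applied.

        The metastatic TNF-α production rate is ``tnf_metastatic_fold``
        times the primary baseline; F production follows the macrophage
        block.
        """
        specs = {k: dataclasses.replace(v) for k, v in self.cytokines.items()}
        if self.tumor_type == "metastatic":
            specs["TNF"].lambda_production_C *= self.tnf_metastatic_fold
        specs["F"].lambda_production_C = self.macrophage.f_production
        return specs

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        for key, sub in (("tumor", TumorParams), ("mechanics", MechanicsParams),
                         ("oxygen", OxygenParams), ("ecm", ECMParams),
                         ("mde", MDEParams), ("macrophage", MacrophageParams),
                         ("vessels", VesselParams)):
            if key in data and isinstance(data[key], dict):
                data[key] = sub(**data[key])
        if "cytokines" in data:
            data["cytokines"] = {
                name: spec if isinstance(spec, CytokineSpec) else CytokineSpec(**spec)
                for name, spec in data["cytokines"].items()
            }
        return cls(**data)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def case_config(tumor_type: TumorType = "primary",
                ecm_type: EcmType = "cECM",
                polarization_enabled: bool = True,
                rng_seed: int = 0,
                **overrides) -> SimulationConfig:
    """Build a validated configuration for one study case.

    Case-specific calibration applied here:
      * metastatic tumors: denser capillary grid, lower necrotic
        threshold (more hypoxic, less necrotic nodules), and 10x TNF-α
        production (via :meth:`SimulationConfig.resolved_cytokines`);
      * transitional ECM: higher far-field matrix density with a lower
        degradation/production ratio.
    """
    cfg = SimulationConfig(tumor_type=tumor_type, ecm_type=ecm_type,
                           polarization_enabled=polarization_enabled,
                           rng_seed=rng_seed, **overrides)
    if tumor_type == "metastatic":
        # hypoxic-nodule calibration: lower necrotic threshold, higher
        # oxygen demand, and a weaker pressure choke in the highly
        # conductive hepatic vasculature
        cfg.tumor.necrotic_threshold = 0.15
        cfg.oxygen.lambda_tumor_sigma = 50.0
        cfg.oxygen.q_sigma = 45.0
        cfg.vessels.effective_pressure = 0.05
    if ecm_type == "tECM":
        # degradation rate set so the scalar matrix balance yields the
        # configured transitional:control density ratio (see assays.calibrate_ecm)
        cfg.ecm.lambda_degradation_E = (
            cfg.ecm.lambda_degradation_E * cfg.ecm.E_far_cECM / cfg.ecm.E_far_tECM
        )
    cfg.validate()
    return cfg
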