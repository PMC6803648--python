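"""Simulation orchestration: the time-stepping loop, the study's
four-case (× naive/polarized) design, replicate seeds, and reporting.

Each simulated day couples, in a fixed operator-splitting order, the
quasi-steady oxygen and cytokine fields, tissue-region classification,
angiogenic sprouting, discrete macrophage dynamics, the macrophage
effector updates, matrix/enzyme evolution, and the Darcy pressure
system that advances the tumor interface.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import macrophages as mac
from . import rd, tumor, vasculature
from .config import SimulationConfig, case_config
from .state import AgentPopulation, FieldState, RegionMap, build_state, tumor_radius


@dataclass
class CaseSpec:
    """One cell of the simulation design."""

    tumor_type: str = "primary"
    ecm_type: str = "cECM"
    polarization_enabled: bool = True
    n_replicates: int = 3
    seeds: list[int] = field(default_factory=lambda: [1, 2, 3])

    def __post_init__(self) -> None:
        if len(self.seeds) != self.n_replicates or self.n_replicates < 1:
            raise ValueError("n_replicates must equal len(seeds) >= 1")

    @property
    def label(self) -> str:
        pol = "polarized" if self.polarization_enabled else "naive"
        return f"{self.tumor_type}-{self.ecm_type}-{pol}"


@dataclass
class RunResult:
    """Per-replicate output series and final snapshot."""

    seed: int
    days: list[float]
    radius_series: list[float]                 # mm
    fraction_series: list[tuple[float, float, float]]  # (naive, M1, M2)
    ecm_mean_series: list[float]
    final_fields: FieldState | None = None
    final_region: RegionMap | None = None
    final_network: vasculature.VesselNetwork | None = None
    final_agents: AgentPopulation | None = None

    @property
    def final_radius(self) -> float:
        return self.radius_series[-1]

    @property
    def final_fractions(self) -> tuple[float, float, float]:
        return self.fraction_series[-1]


@dataclass
class SimState:
    """Mutable simulation state advanced by :func:`step`."""

    config: SimulationConfig
    fields: FieldState
    region: RegionMap
    network: vasculature.VesselNetwork
    agents: AgentPopulation
    rng: np.random.Generator
    t: float = 0.0
    deficit: np.ndarray | None = None   # interface-shrinkage bookkeeping

    def __post_init__(self) -> None:
        if self.deficit is None:
            n = self.config.grid_nodes_per_side
            self.deficit = np.zeros((n, n))

    def copy(self) -> "SimState":
        rng = np.random.Generator(type(self.rng.bit_generator)())
        rng.bit_generator.state = self.rng.bit_generator.state
        return SimState(self.config, self.fields.copy(), self.region.copy(),
                        self.network.copy(), self.agents.copy(), rng,
                        self.t, self.deficit.copy())


def init_state(config: SimulationConfig) -> SimState:
    fields, region, network, agents = build_state(config)
    rng = np.random.default_rng(config.rng_seed)
    return SimState(config, fields, region, network, agents, rng)


def step(state: SimState) -> SimState:
    """Advance the simulation by one dt (in place; returns the state).

    Fixed order: oxygen solve → region classification → cytokine
    solves → angiogenesis → macrophage extravasation/migration/
    polarization → effector updates → MDE and ECM steps →
    proliferation field → pressure/velocity → interface advance.
    """
    cfg = state.config
    dt = cfg.dt
    h = cfg.node_spacing
    f = state.fields
    specs = cfg.resolved_cytokines()

    # (1) quasi-steady oxygen
    f.sigma = rd.solve_oxygen(state.region, state.network, f.pressure, cfg)
    # (2) classify tissue regions (necrosis irreversible)
    state.region = tumor.classify_regions(f.sigma, state.region.tumor_mask,
                                          f.q_ol_current,
                                          cfg.tumor.necrotic_threshold,
                                          prev_region=state.region)
    # (3) quasi-steady cytokines
    f.taf = rd.solve_cytokine(specs["TAF"], state.region, state.network, h)
    f.c_tnf = rd.solve_cytokine(specs["TNF"], state.region, state.network, h)
    f.c_tgf = rd.solve_cytokine(specs["TGFB1"], state.region, state.network, h)
    f.f_m2 = rd.solve_cytokine(specs["F"], state.region, state.network, h,
                               agents=state.agents)
    # (4) angiogenic sprouting
    state.network = vasculature.sprout_step(state.network, f.taf, state.region,
                                            state.rng, cfg, dt)
    # (5) macrophage agents
    rows, cols = mac.extravasate(state.network, f.taf, cfg.macrophage,
                                 state.rng, dt, h)
    state.agents.append(rows, cols)
    mac.migrate(state.agents, f, state.region, cfg.macrophage, state.rng, dt)
    if cfg.polarization_enabled and len(state.agents):
        naive_idx = np.nonzero(state.agents.phenotype == AgentPopulation.NAIVE)[0]
        if naive_idx.size:
            tme = mac.tme_mask(state.region, cfg.macrophage.tme_margin)
            mac.polarize(state.agents, f.c_tnf, f.c_tgf, tme, cfg.macrophage,
                         state.rng, dt, idx=naive_idx)
    # (6) effector updates
    f.lambda_M1_field = mac.m1_effect_field(state.agents, f.sigma.shape,
                                            cfg.macrophage)
    f.lambda_M2_rate = tumor.update_m2_rate(f.lambda_M2_rate, f.f_m2,
                                            cfg.tumor.lambda_F,
                                            cfg.tumor.lambda_M, dt)
    f.q_ol_current = tumor.update_quiescence(f.q_ol_current, f.f_m2,
                                             cfg.tumor, dt)
    # (7) enzyme and matrix
    tips = state.network.tip_mask
    f.mde = rd.step_mde(f.mde, state.region, tips, f.ecm, cfg.mde, h, dt)
    f.ecm = tumor.step_ecm(f.ecm, f.mde, state.region, tips, cfg.ecm, dt)
    # (8) net proliferation
    f.lambda_p = tumor.proliferation_field(state.region, f.sigma,
                                           f.lambda_M1_field, f.lambda_M2_rate,
                                           cfg.tumor)
    # (9) Darcy pressure and velocity
    f.pressure, _, _ = rd.solve_pressure_velocity(f.lambda_p, f.ecm,
                                                  cfg.mechanics, h)
    vy_face, vx_face = rd.face_velocity(f.pressure, f.ecm, cfg.mechanics, h)
    # (10) interface advance
    state.region = tumor.advance_tumor(state.region, vy_face, vx_face,
                                       f.lambda_p, state.deficit,
                                       state.rng, h, dt)
    state.t += dt
    return state


def run_simulation(config: SimulationConfig, output_interval: float = 0.5,
                   keep_final_state: bool = True) -> RunResult:
    """Run one replicate to t_end, sampling series every output interval."""
    state = init_state(config)
    n_steps = int(round(config.t_end / config.dt))
    sample_every = max(1, int(round(output_interval / config.dt)))
    days, radii, fracs, ecm_means = [0.0], [tumor_radius(state.region, config.node_spacing)], \
        [(0.0, 0.0, 0.0)], [float(state.fields.ecm.mean())]
    for i in range(1, n_steps + 1):
        step(state)
        if i % sample_every == 0 or i == n_steps:
            days.append(state.t)
            radii.append(tumor_radius(state.region, config.node_spacing))
            fr = mac.population_fractions(state.agents)
            fracs.append((fr.naive, fr.m1, fr.m2))
            ecm_means.append(float(state.fields.ecm.mean()))
    return RunResult(
        seed=config.rng_seed, days=days, radius_series=radii,
        fraction_series=fracs, ecm_mean_series=ecm_means,
        final_fields=state.fields if keep_final_state else None,
        final_region=state.region if keep_final_state else None,
        final_network=state.network if keep_final_state else None,
        final_agents=state.agents if keep_final_state else None,
    )


def run_case(case: CaseSpec, config: SimulationConfig | None = None,
             output_interval: float = 0.5,
             keep_final_state: bool = False) -> list[RunResult]:
    """Run all replicates of one design cell.

    ``config``, when given, supplies the non-case parameters (a base
    configuration before case resolution); the case selectors and seed
    come from ``case``.
    """
    results = []
    for seed in case.seeds:
        kwargs = _non_case_kwargs(config) if config is not None else {}
        cfg = case_config(case.tumor_type, case.ecm_type,
                          case.polarization_enabled, rng_seed=seed, **kwargs)
        try:
            results.append(run_simulation(cfg, output_interval, keep_final_state))
        except Exception as exc:
            raise RuntimeError(f"replicate seed={seed} of {case.label} failed") from exc
    return results


def _non_case_kwargs(config: SimulationConfig) -> dict:
    """Config fields that are not case selectors, as constructor kwargs."""
    skip = {"tumor_type", "ecm_type", "polarization_enabled", "rng_seed"}
    out = {}
    for fld in dataclasses.fields(SimulationConfig):
        if fld.name in skip:
            continue
        val = getattr(config, fld.name)
        if fld.name in ("tumor", "mechanics", "oxygen", "ecm", "mde",
                        "macrophage", "vessels"):
            val = dataclasses.replace(val)
        elif fld.name == "cytokines":
            val = {k: dataclasses.replace(v) for k, v in val.items()}
        out[fld.name] = val
    return out


def summarize_case(results: list[RunResult]) -> dict:
    """Mean and SD of final radius and final population fractions."""
    radii = np.array([r.final_radius for r in results])
    fr = np.array([r.final_fractions for r in results])
    sd = radii.std(ddof=1) if len(results) > 1 else 0.0
    fr_sd = fr.std(axis=0, ddof=1) if len(results) > 1 else np.zeros(3)
    return {
        "n": len(results),
        "final_radius_mean": float(radii.mean()),
        "final_radius_sd": float(sd),
        "f_naive_mean": float(fr[:, 0].mean()), "f_naive_sd": float(fr_sd[0]),
        "f_m1_mean": float(fr[:, 1].mean()), "f_m1_sd": float(fr_sd[1]),
        "f_m2_mean": float(fr[:, 2].mean()), "f_m2_sd": float(fr_sd[2]),
    }


def percent_radius_difference(primary_mean: float, metastatic_mean: float) -> float:
    """Percent by which the metastatic radius falls short of the primary."""
    if primary_mean <= 0:
        raise ValueError("primary_mean must be positive")
    return 100.0 * (primary_mean - metastatic_mean) / primary_mean


def full_design(n_replicates: int = 3, seeds: list[int] | None = None) -> list[CaseSpec]:
    """The eight design cells: 2 tumor types × 2 ECM constructs ×
    naive/polarized macrophages."""
    seeds = seeds or list(range(1, n_replicates + 1))
    cases = []
    for pol in (False, True):
        for tt in ("primary", "metastatic"):
            for et in ("cECM", "tECM"):
                cases.append(CaseSpec(tt, et, pol, n_replicates, list(seeds)))
    return cases


def report(case_results: dict[str, list[RunResult]], outdir,
           config: SimulationConfig | None = None) -> dict:
    """Write summary/time-series CSVs, field panels, and a run manifest.

    Returns the manifest dict. ``case_results`` maps case labels to
    replicate results.
    """
    import pandas as pd
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "cases": sorted(case_results),
        "seeds": {label: [r.seed for r in res] for label, res in case_results.items()},
    }
    if config is not None:
        blob = json.dumps(config.to_dict(), sort_keys=True).encode()
        manifest["config_sha256"] = hashlib.sha256(blob).hexdigest()
    if not case_results:
        warnings.warn("report called with no results; writing manifest only")
    else:
        rows, ts_rows = [], []
        for label, results in sorted(case_results.items()):
            for r in results:
                rows.append({"case": label, "kind": "replicate", "seed": r.seed,
                             "final_radius_mm": r.final_radius,
                             "f_naive": r.final_fractions[0],
                             "f_m1": r.final_fractions[1],
                             "f_m2": r.final_fractions[2]})
                for d, rad, fr, em in zip(r.days, r.radius_series,
                                          r.fraction_series, r.ecm_mean_series):
                    ts_rows.append({"case": label, "seed": r.seed, "day": d,
                                    "radius_mm": rad, "f_naive": fr[0],
                                    "f_m1": fr[1], "f_m2": fr[2],
                                    "ecm_mean": em})
            s = summarize_case(results)
            rows.append({"case": label, "kind": "aggregate", "seed": -1,
                         "final_radius_mm": s["final_radius_mean"],
                         "f_naive": s["f_naive_mean"], "f_m1": s["f_m1_mean"],
                         "f_m2": s["f_m2_mean"]})
        pd.DataFrame(rows).to_csv(outdir / "summary.csv", index=False)
        pd.DataFrame(ts_rows).to_csv(outdir / "time_series.csv", index=False)
        for label, results in case_results.items():
            r = results[0]
            if r.final_fields is not None:
                write_panel_figure(r, outdir / f"panels_{label}.png")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def write_panel_figure(result: RunResult, path) -> None:
    """3 × 3 field panel: regions+vessels, TNF-α, TGF-β1 / naive, M1, M2
    agent density / TAF, oxygen, ECM."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    f = result.final_fields
    region = result.final_region
    agents = result.final_agents
    net = result.final_network
    n = region.labels.shape[0]

    def agent_density(phen):
        d = np.zeros((n, n))
        sel = agents.phenotype == phen
        np.add.at(d, (agents.row[sel], agents.col[sel]), 1.0)
        return d

    fig, axes = plt.subplots(3, 3, figsize=(9, 9))
    ax = axes[0, 0]
    ax.imshow(region.labels, cmap="hot", vmin=0, vmax=3)
    vr, vc = np.nonzero(net.vessel_mask())
    ax.scatter(vc, vr, s=0.3, c="saddlebrown")
    ax.set_title("tumor regions + vessels")
    panels = [(axes[0, 1], f.c_tnf, "TNF-α"), (axes[0, 2], f.c_tgf, "TGF-β1"),
              (axes[1, 0], agent_density(AgentPopulation.NAIVE), "naive MΦ"),
              (axes[1, 1], agent_density(AgentPopulation.M1), "M1 MΦ"),
              (axes[1, 2], agent_density(AgentPopulation.M2), "M2 MΦ"),
              (axes[2, 0], f.taf, "TAF"), (axes[2, 1], f.sigma, "oxygen"),
              (axes[2, 2], f.ecm, "ECM")]
    for a, img, title in panels:
        a.imshow(img, cmap="viridis")
        a.set_title(title)
    for a in axes.ravel():
        a.set_xticks([])
        a.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
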