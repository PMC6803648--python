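"""Snapshot serialization: HDF5 field stacks and CSV tables for the
vessel network, macrophage agents, and tissue-region map."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .state import AgentPopulation, FieldState, RegionMap
from .vasculature import VesselNetwork

FIELD_NAMES = ("sigma", "pressure", "ecm", "mde", "c_tnf", "c_tgf", "taf",
               "f_m2", "lambda_p", "lambda_M1_field", "lambda_M2_rate",
               "q_ol_current")


def write_fields_h5(path, fields: FieldState, region: RegionMap,
                    network: VesselNetwork, t: float,
                    mode: str = "a") -> None:
    """Append one timestep: one HDF5 group per species under /t<t>."""
    with h5py.File(path, mode) as fh:
        grp = fh.create_group(f"t{t:08.3f}")
        grp.attrs["time_days"] = t
        for name in FIELD_NAMES:
            grp.create_dataset(name, data=getattr(fields, name),
                               compression="gzip", compression_opts=4)
        grp.create_dataset("region", data=region.labels)
        grp.create_dataset("vessels", data=network.vessel_mask().astype(np.int8))


def read_fields_h5(path) -> dict[float, dict[str, np.ndarray]]:
    out = {}
    with h5py.File(path, "r") as fh:
        for key in fh:
            grp = fh[key]
            out[float(grp.attrs["time_days"])] = {
                name: grp[name][...] for name in grp}
    return out


def vessels_to_csv(path, network: VesselNetwork) -> None:
    """Node list with pre-existing/neovascular and tip flags."""
    rows = []
    tips = {(r, c) for _, r, c in network.tips}
    rr, cc = np.nonzero(network.vessel_mask())
    for r, c in zip(rr.tolist(), cc.tolist()):
        rows.append({"row": r, "col": c,
                     "neovascular": int(network.neo_mask[r, c]
                                        and not network.pre_mask[r, c]),
                     "active_tip": int((r, c) in tips)})
    pd.DataFrame(rows, columns=["row", "col", "neovascular", "active_tip"]
                 ).to_csv(path, index=False)


def agents_to_csv(path, agents: AgentPopulation, step: int = 0) -> None:
    """Agent table: step, id, x, y, phenotype, age."""
    names = {AgentPopulation.NAIVE: "naive", AgentPopulation.M1: "M1",
             AgentPopulation.M2: "M2"}
    df = pd.DataFrame({
        "step": step,
        "id": np.arange(len(agents)),
        "x": agents.col,
        "y": agents.row,
        "phenotype": [names[p] for p in agents.phenotype.tolist()],
        "age": agents.age,
    })
    df.to_csv(path, index=False)


def region_to_csv(path, region: RegionMap) -> None:
    """Integer-coded lattice (0 normal, 1 proliferating, 2 hypoxic,
    3 necrotic), one row per lattice row."""
    np.savetxt(path, region.labels, fmt="%d", delimiter=",")


def load_region_csv(path) -> RegionMap:
    return RegionMap(np.loadtxt(path, dtype=np.int8, delimiter=","))


def write_snapshot_bundle(outdir, state, step: int = 0) -> None:
    """Write the full state of one simulation to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fields_h5(outdir / "fields.h5", state.fields, state.region,
                    state.network, state.t)
    vessels_to_csv(outdir / "vessels.csv", state.network)
    agents_to_csv(outdir / "agents.csv", state.agents, step)
    region_to_csv(outdir / "region.csv", state.region)
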