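"""Run output: hierarchical state container (HDF5) and CSV summaries."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .geometry import RootMap, build_root_map, GridSpec
from .state import GRID_SPECIES, MEMBRANE_SPECIES, SpeciesState
from .solver import SteadyStateResult


def save_result(result: SteadyStateResult, path) -> None:
    """Write a converged run to one HDF5 file: every species field, the
    membrane pools, solver diagnostics and the grid spec."""
    state = result.state
    spec = state.rmap.spec
    with h5py.File(path, "w") as f:
        g = f.create_group("species")
        for name in GRID_SPECIES:
            g.create_dataset(name, data=state.grid[name])
        m = f.create_group("membrane")
        for name in MEMBRANE_SPECIES:
            m.create_dataset(name, data=state.mem[name])
        f.attrs["converged"] = result.converged
        f.attrs["n_steps"] = result.n_steps
        f.attrs["n_picard"] = result.n_picard
        f.attrs["n_linear"] = result.n_linear
        f.attrs["max_residual"] = result.max_residual
        f.attrs["grid_spec"] = json.dumps({
            "spacing": spec.spacing,
            "file_widths": list(spec.file_widths),
            "file_types": list(spec.file_types),
            "columella_tier_lengths": list(spec.columella_tier_lengths),
            "qc_length": spec.qc_length,
            "mz_cell_length": spec.mz_cell_length,
            "mz_length": spec.mz_length,
            "ez_cell_lengths": list(spec.ez_cell_lengths),
        })


def load_state(path) -> SpeciesState:
    from .geometry import interfaces

    with h5py.File(path, "r") as f:
        d = json.loads(f.attrs["grid_spec"])
        for k in ("file_widths", "file_types", "columella_tier_lengths",
                  "ez_cell_lengths"):
            d[k] = tuple(d[k])
        rmap = build_root_map(GridSpec(**d))
        faces = interfaces(rmap)
        grid = {k: f["species"][k][()] for k in GRID_SPECIES}
        mem = {k: f["membrane"][k][()] for k in MEMBRANE_SPECIES}
    return SpeciesState(rmap=rmap, faces=faces, grid=grid, mem=mem)


def write_summary(result: SteadyStateResult, out_dir) -> Path:
    """CSV of whole-root and per-cell-type averages plus the flux totals."""
    from . import postprocess as pp

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    species = list(GRID_SPECIES) + ["pin_protein", "aux1_protein"]
    regions = {"whole": {}, "vascular": {"cell_types": ("vascular",)},
               "pericycle": {"cell_types": ("pericycle",)},
               "epidermis": {"cell_types": ("epidermis",)}}
    for sp in species:
        for rname, sel in regions.items():
            try:
                mean = pp.region_average(result, sp, **sel)
            except ValueError:   # region absent from this geometry
                continue
            rows.append({"species": sp, "region": rname, "mean_uM": mean})
    pd.DataFrame(rows).to_csv(out_dir / "averages.csv", index=False)
    pd.DataFrame([result.ledger.totals()]).to_csv(
        out_dir / "boundary_fluxes.csv", index=False)
    return out_dir
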