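"""Structured run configuration: grid, parameters, solver and genotype.

A config file is YAML with optional sections::

    grid:
      spacing: 4
      mz_length: 344
      ez_cell_lengths: [12, 16, 20, ...]
    parameters:
      P_pin: 2.0
    solver:
      steady_tol: 1.0e-9
    genotype: pls

Anything omitted falls back to the package defaults.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

from .geometry import GridSpec, RootMap, build_root_map
from .genotypes import apply_genotype, get_genotype
from .params import KineticParameters, default_parameters
from .solver import Simulator, SolverSettings, SteadyStateResult


@dataclass
class RunConfig:
    spec: GridSpec
    params: KineticParameters
    settings: SolverSettings
    genotype: str = "wt"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        grid = data.get("grid", {})
        for key in ("file_widths", "file_types", "ez_cell_lengths",
                    "columella_tier_lengths"):
            if key in grid and isinstance(grid[key], list):
                grid[key] = tuple(grid[key])
        spec = GridSpec(**grid)
        params = default_parameters().copy(**data.get("parameters", {}))
        settings = SolverSettings(**data.get("solver", {}))
        return cls(spec=spec, params=params, settings=settings,
                   genotype=data.get("genotype", "wt"))


def default_spec(spacing: float = 2.0) -> GridSpec:
    """The default root geometry at a chosen grid spacing (2 um nominal;
    4 um is the reduced resolution used for batch runs)."""
    return GridSpec(spacing=spacing)


def run_steady_state(spec: GridSpec | None = None,
                     genotype: str = "wt",
                     params: KineticParameters | None = None,
                     settings: SolverSettings | None = None,
                     rmap: RootMap | None = None) -> SteadyStateResult:
    """Build the map, apply the genotype and solve to steady state."""
    if rmap is None:
        rmap = build_root_map(spec or default_spec())
    p = apply_genotype(params or default_parameters(), get_genotype(genotype))
    sim = Simulator(rmap, p, settings or SolverSettings())
    return sim.steady_state()
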