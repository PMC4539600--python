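"""Concentration state of all model species on a root map.

Sixteen species live on the grid: the three hormones (auxin, ethylene,
cytokinin) occupy both cytosol and wall points; mRNAs, proteins, receptors
and the downstream ethylene signal X occupy cytosol points only.  The
membrane-bound carrier pools (PIN, AUX1) are stored per membrane face
rather than per point; :meth:`membrane_field` deposits them onto wall
points for export and inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import FaceSet, RootMap, interfaces

HORMONES = ("auxin", "et", "ck")
CYTOSOLIC = (
    "plsm", "plsp", "pinm", "pinp_cyt", "aux1m", "aux1p_cyt",
    "ra", "ras", "re", "res", "ctr", "ctrs", "x",
)
GRID_SPECIES = HORMONES + CYTOSOLIC
MEMBRANE_SPECIES = ("pinp_mem", "aux1p_mem")
ALL_SPECIES = GRID_SPECIES + MEMBRANE_SPECIES


@dataclass
class SpeciesState:
    rmap: RootMap
    faces: FaceSet
    grid: dict           # name -> (nr, nc) float64 array
    mem: dict            # name -> (n_membrane,) float64 array

    @classmethod
    def initial(cls, rmap: RootMap, params, faces: FaceSet | None = None,
                hormone0: float = 0.1, species0: float = 0.01) -> "SpeciesState":
        """Deterministic uniform initial condition.

        Hormones start at ``hormone0`` everywhere; receptor pools start all
        inactive at their configured totals; other cytosolic species and the
        membrane pools start at ``species0``.
        """
        faces = faces if faces is not None else interfaces(rmap)
        cyt = rmap.cytosol_mask.astype(float)
        grid = {}
        for name in HORMONES:
            grid[name] = np.full(rmap.dims, hormone0, dtype=float)
        for name in CYTOSOLIC:
            grid[name] = species0 * cyt.copy()
        grid["ra"] = params.ra_total * cyt.copy()
        grid["ras"] = np.zeros(rmap.dims)
        grid["re"] = params.re_total * cyt.copy()
        grid["res"] = np.zeros(rmap.dims)
        grid["ctr"] = params.ctr_total * cyt.copy()
        grid["ctrs"] = np.zeros(rmap.dims)
        mem = {name: np.full(faces.n_membrane, species0, dtype=float)
               for name in MEMBRANE_SPECIES}
        return cls(rmap=rmap, faces=faces, grid=grid, mem=mem)

    def copy(self) -> "SpeciesState":
        return SpeciesState(
            rmap=self.rmap, faces=self.faces,
            grid={k: v.copy() for k, v in self.grid.items()},
            mem={k: v.copy() for k, v in self.mem.items()},
        )

    def __getitem__(self, name: str) -> np.ndarray:
        return self.grid[name] if name in self.grid else self.mem[name]

    def __setitem__(self, name: str, value: np.ndarray) -> None:
        if name in self.grid:
            self.grid[name] = value
        else:
            self.mem[name] = value

    def membrane_field(self, name: str) -> np.ndarray:
        """Membrane pool summed onto wall grid points (uM per point)."""
        out = np.zeros(self.rmap.dims)
        np.add.at(out.ravel(), self.faces.mem_wall, self.mem[name])
        return out

    def min_value(self) -> float:
        vals = [v.min() for v in self.grid.values()]
        vals += [v.min() for v in self.mem.values() if v.size]
        return float(min(vals))

    def assert_valid(self, tol: float = 0.0) -> None:
        if self.min_value() < -tol:
            raise ValueError(f"negative concentration: {self.min_value()}")
        wall = self.rmap.wall_mask
        for name in CYTOSOLIC:
            if np.any(self.grid[name][wall] != 0.0):
                raise ValueError(f"{name} is nonzero on wall points")

    def max_abs(self) -> dict:
        out = {k: float(np.max(np.abs(v))) for k, v in self.grid.items()}
        out.update({k: float(np.max(np.abs(v))) if v.size else 0.0
                    for k, v in self.mem.items()})
        return out
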