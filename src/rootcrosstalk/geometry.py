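"""Discretized 2-D root map: grid points, cell files, zones and finite-volume faces.

The root is represented on a regular grid of square elements (default
2 um x 2 um).  Each grid point is either cytosol or wall; the wall layer is
one point thick and stands for the merged cell wall + plasma membrane.  Cells
are rectangles tiled in longitudinal *tiers* (columella tiers and an optional
QC tier at the distal tip, then meristematic-zone cells of constant length,
then elongation-zone cells of increasing length) and transverse *files*
(mirrored left/right around the central axis, outer epidermis to inner
vasculature).  Adjacent cells share a single wall line.

Row 0 is the distal tip; rows increase shootwards.  The proximal (last) row
is the shoot boundary, where auxin is loaded into the pericycle/vascular
files, unloaded from the epidermal files, and ethylene/cytokinin exchange
with fixed shoot-side pools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

# point kinds
CYTOSOL = 0
WALL = 1
EXTERIOR = 2

# cell types
EPIDERMIS = 0
OUTER = 1          # cortex-like outer file
PERICYCLE = 2      # pericycle/border file
VASCULAR = 3
COLUMELLA = 4
QC = 5

CELL_TYPE_NAMES = {
    "epidermis": EPIDERMIS,
    "outer": OUTER,
    "pericycle": PERICYCLE,
    "vascular": VASCULAR,
    "columella": COLUMELLA,
    "qc": QC,
}
CELL_TYPE_LABELS = {v: k for k, v in CELL_TYPE_NAMES.items()}

# zones
ZONE_MZ = 0
ZONE_EZ = 1
ZONE_CAP = 2       # columella/QC cap

ZONE_NAMES = {"MZ": ZONE_MZ, "EZ": ZONE_EZ, "cap": ZONE_CAP}

# face orientations (seen from the cytosol side of a membrane face)
ROOTWARD = 0
SHOOTWARD = 1
LATERAL_IN = 2
LATERAL_OUT = 3


class GeometryError(ValueError):
    """Raised when a grid specification cannot be tiled by its spacing."""


@dataclass(frozen=True)
class GridSpec:
    """Geometric specification of the root, all lengths in micrometres.

    ``file_widths`` lists the cell files of ONE side, outer to inner; the map
    is mirrored about the central axis.  ``file_types`` gives the matching
    cell-type names.  Every length must be a positive multiple of ``spacing``
    and every cell must be at least two spacings long/wide so that it
    encloses at least one cytosol point inside its wall ring.
    """

    spacing: float = 2.0
    file_widths: tuple = (24.0, 24.0, 16.0, 44.0)
    file_types: tuple = ("epidermis", "outer", "pericycle", "vascular")
    columella_tier_lengths: tuple = (16.0, 16.0, 16.0)
    qc_length: float = 8.0
    mz_cell_length: float = 8.0
    mz_length: float = 344.0
    ez_cell_lengths: tuple = (
        12.0, 16.0, 20.0, 24.0, 28.0, 32.0, 36.0, 40.0,
        44.0, 48.0, 52.0, 56.0, 60.0, 64.0, 68.0,
    )
    wall_thickness: int = 1

    def __post_init__(self):
        h = self.spacing
        if h <= 0:
            raise GeometryError("spacing must be positive")
        if self.wall_thickness != 1:
            raise GeometryError("only one-point-thick walls are supported")
        if len(self.file_widths) != len(self.file_types):
            raise GeometryError("file_widths and file_types lengths differ")
        for t in self.file_types:
            if t not in CELL_TYPE_NAMES:
                raise GeometryError(f"unknown cell type {t!r}")
        for name, values in (
            ("file_widths", self.file_widths),
            ("columella_tier_lengths", self.columella_tier_lengths),
            ("ez_cell_lengths", self.ez_cell_lengths),
        ):
            for v in values:
                self._check_multiple(v, name)
        if self.qc_length:
            self._check_multiple(self.qc_length, "qc_length")
        if self.mz_length:
            self._check_multiple(self.mz_cell_length, "mz_cell_length")
            self._check_multiple(self.mz_length, "mz_length")
            if round(self.mz_length / self.mz_cell_length, 9) % 1:
                raise GeometryError("mz_length must be a multiple of mz_cell_length")
        ez = self.ez_cell_lengths
        if any(b < a for a, b in zip(ez, ez[1:])):
            raise GeometryError("ez_cell_lengths must be non-decreasing")
        if not self.tier_lengths:
            raise GeometryError("root has no cell tiers")

    def _check_multiple(self, v: float, name: str) -> None:
        h = self.spacing
        if v < 2 * h or round(v / h, 9) % 1:
            raise GeometryError(
                f"{name} entry {v} um is not a multiple >= 2x of spacing {h} um"
            )

    @property
    def tier_lengths(self) -> tuple:
        """Longitudinal cell lengths, tip to shoot (um)."""
        tiers = list(self.columella_tier_lengths)
        if self.qc_length:
            tiers.append(self.qc_length)
        n_mz = int(round(self.mz_length / self.mz_cell_length)) if self.mz_length else 0
        tiers.extend([self.mz_cell_length] * n_mz)
        tiers.extend(self.ez_cell_lengths)
        return tuple(tiers)

    @property
    def root_length(self) -> float:
        return float(sum(self.tier_lengths))

    @property
    def root_half_width(self) -> float:
        return float(sum(self.file_widths))

    @property
    def n_cap_tiers(self) -> int:
        return len(self.columella_tier_lengths) + (1 if self.qc_length else 0)

    @property
    def qc_tier(self) -> int | None:
        """0-based tier of the QC, or None if the cap has no QC tier."""
        return len(self.columella_tier_lengths) if self.qc_length else None


@dataclass
class RootMap:
    """Labelled grid plus the cell table and shoot-boundary flags."""

    spec: GridSpec
    point_kind: np.ndarray          # (nr, nc) int8
    cell_id: np.ndarray             # (nr, nc) int32, -1 on walls
    n_cells: int
    cell_file: np.ndarray           # (n_cells,) full-file index, left to right
    cell_tier: np.ndarray           # (n_cells,) 0-based tier from tip
    cell_type: np.ndarray           # (n_cells,) type codes
    cell_zone: np.ndarray           # (n_cells,) zone codes
    row_bounds: np.ndarray          # wall row index of each tier boundary
    col_bounds: np.ndarray          # wall col index of each file boundary
    file_types_full: np.ndarray     # type code per full-width file

    @property
    def dims(self) -> tuple:
        return self.point_kind.shape

    @property
    def spacing(self) -> float:
        return self.spec.spacing

    @property
    def n_points(self) -> int:
        return self.point_kind.size

    @property
    def cytosol_mask(self) -> np.ndarray:
        return self.point_kind == CYTOSOL

    @property
    def wall_mask(self) -> np.ndarray:
        return self.point_kind == WALL

    @property
    def tier_index(self) -> np.ndarray:
        """1-based tier index per cell, counted from the most distal tier."""
        return self.cell_tier + 1

    # ---- shoot boundary -------------------------------------------------
    @property
    def shoot_row(self) -> int:
        return self.dims[0] - 1

    def _boundary_cols(self, types: Iterable[int]) -> np.ndarray:
        """Cytosol columns of the given file types (for boundary flags)."""
        cols = []
        nb = self.col_bounds
        for f, t in enumerate(self.file_types_full):
            if t in types:
                cols.extend(range(nb[f] + 1, nb[f + 1]))
        return np.asarray(sorted(cols), dtype=np.int64)

    @property
    def shoot_influx_cols(self) -> np.ndarray:
        """Columns of shoot-boundary auxin influx (pericycle + vascular)."""
        return self._boundary_cols({PERICYCLE, VASCULAR})

    @property
    def shoot_efflux_cols(self) -> np.ndarray:
        """Columns of shoot-boundary auxin efflux (epidermis)."""
        return self._boundary_cols({EPIDERMIS})

    @property
    def shoot_gas_cols(self) -> np.ndarray:
        """Columns exchanging ethylene/cytokinin with the shoot (all)."""
        return np.arange(self.dims[1], dtype=np.int64)

    # ---- queries --------------------------------------------------------
    def cells_of_type(self, *names: str) -> np.ndarray:
        codes = [CELL_TYPE_NAMES[n] for n in names]
        return np.flatnonzero(np.isin(self.cell_type, codes))

    def rows_of_tier(self, tier: int) -> tuple:
        """Half-open cytosol row range (lo, hi) of a 0-based tier."""
        return int(self.row_bounds[tier]) + 1, int(self.row_bounds[tier + 1])

    def cell_rows(self, cid: int) -> tuple:
        return self.rows_of_tier(int(self.cell_tier[cid]))

    def cell_cols(self, cid: int) -> tuple:
        f = int(self.cell_file[cid])
        return int(self.col_bounds[f]) + 1, int(self.col_bounds[f + 1])

    def label_matrix(self) -> np.ndarray:
        """Integer export: -1 walls, otherwise cell id (for CSV/image preview)."""
        return np.where(self.wall_mask, -1, self.cell_id)


def build_root_map(spec: GridSpec) -> RootMap:
    """Construct the mirrored multicellular root map from a grid spec."""
    h = spec.spacing
    tiers = spec.tier_lengths
    half = list(spec.file_widths)
    widths = half + half[::-1]
    type_names = list(spec.file_types) + list(spec.file_types)[::-1]
    file_types_full = np.array(
        [CELL_TYPE_NAMES[t] for t in type_names], dtype=np.int8
    )

    row_bounds = np.concatenate(
        [[0], np.cumsum(np.round(np.asarray(tiers) / h).astype(int))]
    )
    col_bounds = np.concatenate(
        [[0], np.cumsum(np.round(np.asarray(widths) / h).astype(int))]
    )
    nr = int(row_bounds[-1]) + 1
    nc = int(col_bounds[-1]) + 1
    n_tiers = len(tiers)
    n_files = len(widths)

    point_kind = np.full((nr, nc), CYTOSOL, dtype=np.int8)
    point_kind[row_bounds, :] = WALL
    point_kind[:, col_bounds] = WALL

    cell_id = np.full((nr, nc), -1, dtype=np.int32)
    n_cells = n_tiers * n_files
    cell_file = np.empty(n_cells, dtype=np.int32)
    cell_tier = np.empty(n_cells, dtype=np.int32)
    cell_type = np.empty(n_cells, dtype=np.int8)
    cell_zone = np.empty(n_cells, dtype=np.int8)

    n_cap = spec.n_cap_tiers
    qc_tier = spec.qc_tier
    n_mz = int(round(spec.mz_length / spec.mz_cell_length)) if spec.mz_length else 0

    cid = 0
    for t in range(n_tiers):
        r0, r1 = row_bounds[t] + 1, row_bounds[t + 1]
        for f in range(n_files):
            c0, c1 = col_bounds[f] + 1, col_bounds[f + 1]
            cell_id[r0:r1, c0:c1] = cid
            cell_file[cid] = f
            cell_tier[cid] = t
            base = file_types_full[f]
            if t < n_cap:
                cell_zone[cid] = ZONE_CAP
                if qc_tier is not None and t == qc_tier and base in (PERICYCLE, VASCULAR):
                    cell_type[cid] = QC
                else:
                    cell_type[cid] = COLUMELLA
            else:
                cell_type[cid] = base
                cell_zone[cid] = ZONE_MZ if t < n_cap + n_mz else ZONE_EZ
            cid += 1

    return RootMap(
        spec=spec,
        point_kind=point_kind,
        cell_id=cell_id,
        n_cells=n_cells,
        cell_file=cell_file,
        cell_tier=cell_tier,
        cell_type=cell_type,
        cell_zone=cell_zone,
        row_bounds=row_bounds,
        col_bounds=col_bounds,
        file_types_full=file_types_full,
    )


# ---------------------------------------------------------------------------
# Finite-volume faces
# ---------------------------------------------------------------------------

# face kinds
FACE_CYT_CYT = 0
FACE_MEMBRANE = 1
FACE_WALL_WALL = 2

FACE_KIND_NAMES = {FACE_CYT_CYT: "cytosol-cytosol",
                   FACE_MEMBRANE: "membrane",
                   FACE_WALL_WALL: "wall-wall"}


@dataclass
class FaceSet:
    """All nearest-neighbour faces of a map, grouped by kind.

    Index arrays are flat indices into the (nr, nc) grid.  For membrane
    faces, ``a`` is the cytosol point and ``b`` the wall point; ``cell`` is
    the owning cell and ``orientation`` the direction of the wall as seen
    from the cytosol point.
    """

    shape: tuple
    cyt_a: np.ndarray
    cyt_b: np.ndarray
    wall_a: np.ndarray
    wall_b: np.ndarray
    mem_cyt: np.ndarray
    mem_wall: np.ndarray
    mem_cell: np.ndarray
    mem_orientation: np.ndarray

    @property
    def n_membrane(self) -> int:
        return self.mem_cyt.size

    def counts(self) -> dict:
        return {
            "cytosol-cytosol": self.cyt_a.size,
            "membrane": self.mem_cyt.size,
            "wall-wall": self.wall_a.size,
        }


def interfaces(rmap: RootMap) -> FaceSet:
    """Enumerate every unordered nearest-neighbour pair, classified by kind."""
    nr, nc = rmap.dims
    kind = rmap.point_kind
    cid = rmap.cell_id
    flat = np.arange(nr * nc).reshape(nr, nc)
    axis_col = (nc - 1) / 2.0

    cyt_a, cyt_b = [], []
    wall_a, wall_b = [], []
    mem_cyt, mem_wall, mem_cell, mem_orient = [], [], [], []

    def classify(a_idx, b_idx, ka, kb, ca, cb, orient_ab, orient_ba):
        both_cyt = (ka == CYTOSOL) & (kb == CYTOSOL)
        if np.any(both_cyt & (ca != cb)):  # pragma: no cover - construction forbids
            raise GeometryError("adjacent cytosol points in different cells")
        cyt_a.append(a_idx[both_cyt])
        cyt_b.append(b_idx[both_cyt])
        both_wall = (ka == WALL) & (kb == WALL)
        wall_a.append(a_idx[both_wall])
        wall_b.append(b_idx[both_wall])
        m1 = (ka == CYTOSOL) & (kb == WALL)
        mem_cyt.append(a_idx[m1]); mem_wall.append(b_idx[m1])
        mem_cell.append(ca[m1]); mem_orient.append(orient_ab[m1])
        m2 = (ka == WALL) & (kb == CYTOSOL)
        mem_cyt.append(b_idx[m2]); mem_wall.append(a_idx[m2])
        mem_cell.append(cb[m2]); mem_orient.append(orient_ba[m2])

    # vertical pairs: a=(r,c), b=(r+1,c); wall at b is shootward of a
    a = flat[:-1, :].ravel(); b = flat[1:, :].ravel()
    ka = kind[:-1, :].ravel(); kb = kind[1:, :].ravel()
    ca = cid[:-1, :].ravel(); cb = cid[1:, :].ravel()
    up = np.full(a.size, SHOOTWARD, dtype=np.int8)
    down = np.full(a.size, ROOTWARD, dtype=np.int8)
    classify(a, b, ka, kb, ca, cb, up, down)

    # horizontal pairs: a=(r,c), b=(r,c+1)
    a = flat[:, :-1].ravel(); b = flat[:, 1:].ravel()
    ka = kind[:, :-1].ravel(); kb = kind[:, 1:].ravel()
    ca = cid[:, :-1].ravel(); cb = cid[:, 1:].ravel()
    cols_a = np.tile(np.arange(nc - 1), nr)
    cols_b = cols_a + 1
    # orientation of b seen from a: outward if b is further from the axis
    ab = np.where(np.abs(cols_b - axis_col) > np.abs(cols_a - axis_col),
                  LATERAL_OUT, LATERAL_IN).astype(np.int8)
    ba = np.where(np.abs(cols_a - axis_col) > np.abs(cols_b - axis_col),
                  LATERAL_OUT, LATERAL_IN).astype(np.int8)
    classify(a, b, ka, kb, ca, cb, ab, ba)

    cat = lambda parts: (np.concatenate(parts) if parts else
                         np.empty(0, dtype=np.int64))
    return FaceSet(
        shape=(nr, nc),
        cyt_a=cat(cyt_a), cyt_b=cat(cyt_b),
        wall_a=cat(wall_a), wall_b=cat(wall_b),
        mem_cyt=cat(mem_cyt), mem_wall=cat(mem_wall),
        mem_cell=cat(mem_cell),
        mem_orientation=cat(mem_orient).astype(np.int8),
    )


def region_mask(
    rmap: RootMap,
    cell_types: Sequence[str] | None = None,
    zones: Sequence[str] | None = None,
    tiers: tuple | None = None,
    rows: tuple | None = None,
    include_walls: bool = False,
) -> np.ndarray:
    """Boolean point mask selecting cytosol points by type/zone/tier/row.

    ``tiers`` is an inclusive (lo, hi) range of 1-based tier indices counted
    from the tip ("five to 25 cell tiers from the tip" is ``(5, 25)``);
    ``rows`` is a half-open grid-row range.  Selectors combine with AND.
    """
    ok = np.ones(rmap.n_cells, dtype=bool)
    if cell_types is not None:
        for t in cell_types:
            if t not in CELL_TYPE_NAMES:
                raise KeyError(f"unknown cell type selector {t!r}")
        ok &= np.isin(rmap.cell_type, [CELL_TYPE_NAMES[t] for t in cell_types])
    if zones is not None:
        for z in zones:
            if z not in ZONE_NAMES:
                raise KeyError(f"unknown zone selector {z!r}")
        ok &= np.isin(rmap.cell_zone, [ZONE_NAMES[z] for z in zones])
    if tiers is not None:
        lo, hi = tiers
        ok &= (rmap.tier_index >= lo) & (rmap.tier_index <= hi)

    mask = np.zeros(rmap.dims, dtype=bool)
    sel = np.flatnonzero(ok)
    inside = np.isin(rmap.cell_id, sel) & rmap.cytosol_mask
    mask |= inside
    if include_walls:
        # walls adjacent to a selected cytosol point
        grown = np.zeros_like(mask)
        grown[1:, :] |= inside[:-1, :]
        grown[:-1, :] |= inside[1:, :]
        grown[:, 1:] |= inside[:, :-1]
        grown[:, :-1] |= inside[:, 1:]
        mask |= grown & rmap.wall_mask
    if rows is not None:
        lo, hi = rows
        keep = np.zeros(rmap.dims, dtype=bool)
        keep[lo:hi, :] = True
        mask &= keep
    return mask


def minimal_spec(
    n_tiers: int = 2,
    files: tuple = (("vascular", 8.0),),
    cell_length: float = 8.0,
    spacing: float = 2.0,
) -> GridSpec:
    """Small test geometry: ``n_tiers`` MZ cells per file, no cap, mirrored."""
    types, widths = zip(*files)
    return GridSpec(
        spacing=spacing,
        file_widths=tuple(widths),
        file_types=tuple(types),
        columella_tier_lengths=(),
        qc_length=0.0,
        mz_cell_length=cell_length,
        mz_length=cell_length * n_tiers,
        ez_cell_lengths=(),
    )
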