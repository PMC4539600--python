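"""Root-map construction, face enumeration and region selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rootcrosstalk import GridSpec, build_root_map, interfaces, region_mask
from rootcrosstalk.geometry import (
    CYTOSOL, WALL, EPIDERMIS, GeometryError, minimal_spec,
)
from rootcrosstalk.config import default_spec


def brute_force_face_counts(rmap):
    """O(N) pair scan over the label grid: the independent face oracle."""
    kind, cid = rmap.point_kind, rmap.cell_id
    nr, nc = rmap.dims
    counts = {"cytosol-cytosol": 0, "membrane": 0, "wall-wall": 0}
    for r in range(nr):
        for c in range(nc):
            for dr, dc in ((1, 0), (0, 1)):
                r2, c2 = r + dr, c + dc
                if r2 >= nr or c2 >= nc:
                    continue
                pair = {kind[r, c], kind[r2, c2]}
                if pair == {CYTOSOL}:
                    counts["cytosol-cytosol"] += 1
                elif pair == {CYTOSOL, WALL}:
                    counts["membrane"] += 1
                else:
                    counts["wall-wall"] += 1
    return counts


class TestBuildRootMap:
    def test_minimal_map_has_four_enclosed_cells(self):
        rmap = build_root_map(minimal_spec(n_tiers=2, files=(("vascular", 8.0),)))
        assert rmap.n_cells == 4
        # every cytosol point belongs to exactly one cell
        cyt = rmap.cytosol_mask
        assert np.all(rmap.cell_id[cyt] >= 0)
        assert np.all(rmap.cell_id[~cyt] == -1)
        # each cell's surrounding ring is wall
        for cid in range(rmap.n_cells):
            r0, r1 = rmap.cell_rows(cid)
            c0, c1 = rmap.cell_cols(cid)
            ring = np.concatenate([
                rmap.point_kind[r0 - 1, c0 - 1:c1 + 1],
                rmap.point_kind[r1, c0 - 1:c1 + 1],
                rmap.point_kind[r0 - 1:r1 + 1, c0 - 1].ravel(),
                rmap.point_kind[r0 - 1:r1 + 1, c1].ravel(),
            ])
            assert np.all(ring == WALL)

    def test_partition_covers_grid(self):
        rmap = build_root_map(default_spec(spacing=4.0))
        assert np.all((rmap.point_kind == CYTOSOL) | (rmap.point_kind == WALL))

    def test_mirror_symmetry(self):
        rmap = build_root_map(default_spec(spacing=4.0))
        pk = rmap.point_kind
        assert np.array_equal(pk, pk[:, ::-1])
        # cell types mirror: type of cell at (tier, file f) == (tier, -1-f)
        n_files = len(rmap.file_types_full)
        for t in range(len(rmap.spec.tier_lengths)):
            row = [rmap.cell_type[t * n_files + f] for f in range(n_files)]
            assert row == row[::-1]

    def test_cell_pixel_area_matches_dimensions(self):
        """On the 2 um grid each cell pitch covers length*width/4 points."""
        spec = default_spec(spacing=2.0)
        rmap = build_root_map(spec)
        widths = list(spec.file_widths) + list(spec.file_widths)[::-1]
        for cid in (0, rmap.n_cells // 2, rmap.n_cells - 1):
            t, f = rmap.cell_tier[cid], rmap.cell_file[cid]
            length = spec.tier_lengths[t]
            width = widths[f]
            r0, r1 = rmap.cell_rows(cid)
            c0, c1 = rmap.cell_cols(cid)
            # pitch = cytosol block plus one shared wall row/column
            assert (r1 - r0 + 1) * (c1 - c0 + 1) == length * width / 4.0

    def test_tier_rows_follow_spec_lists(self):
        """Tier indices count up from the tip and EZ tiers span more rows
        than MZ tiers, following the configured cell lengths."""
        spec = default_spec(spacing=4.0)
        rmap = build_root_map(spec)
        n_files = len(rmap.file_types_full)
        vasc = [c for c in range(rmap.n_cells)
                if rmap.cell_file[c] == n_files // 2 - 1]
        tiers = [rmap.tier_index[c] for c in vasc]
        assert tiers == list(range(1, len(spec.tier_lengths) + 1))
        rows_of = [np.diff(rmap.rows_of_tier(t))[0] for t in range(len(spec.tier_lengths))]
        expect = [l / spec.spacing - 1 for l in spec.tier_lengths]
        assert rows_of == expect

    def test_shoot_boundary_flags_respect_cell_files(self):
        rmap = build_root_map(default_spec(spacing=4.0))
        influx = set(rmap.shoot_influx_cols)
        efflux = set(rmap.shoot_efflux_cols)
        assert not influx & efflux
        nb, types = rmap.col_bounds, rmap.file_types_full
        for f, t in enumerate(types):
            cols = set(range(nb[f] + 1, nb[f + 1]))
            if t == EPIDERMIS:
                assert cols <= efflux and not cols & influx

    @pytest.mark.parametrize("bad", [
        dict(spacing=0.0),
        dict(mz_cell_length=7.0),                 # not a multiple of spacing
        dict(ez_cell_lengths=(16.0, 12.0)),       # decreasing
        dict(file_widths=(2.0,), file_types=("vascular",)),  # too thin
        dict(file_widths=(8.0, 8.0), file_types=("vascular",)),
    ])
    def test_untileable_geometry_rejected(self, bad):
        with pytest.raises(GeometryError):
            GridSpec(**bad)


class TestInterfaces:
    def test_single_cell_counts(self):
        # one mirrored file of width 6 um at 2 um: each cell is 2x2 cytosol
        rmap = build_root_map(
            minimal_spec(n_tiers=1, files=(("vascular", 6.0),), cell_length=6.0))
        faces = interfaces(rmap)
        assert rmap.n_cells == 2
        for cid in range(2):
            assert np.sum(faces.mem_cell == cid) == 8
        cells = rmap.cell_id.ravel()
        assert np.sum(cells[faces.cyt_a] == 0) == 4

    def test_counts_match_brute_force_scan(self, small_root_map):
        faces = interfaces(small_root_map)
        assert faces.counts() == brute_force_face_counts(small_root_map)

    def test_membrane_faces_pair_cytosol_with_wall(self, small_root_map):
        faces = interfaces(small_root_map)
        kind = small_root_map.point_kind.ravel()
        assert np.all(kind[faces.mem_cyt] == CYTOSOL)
        assert np.all(kind[faces.mem_wall] == WALL)
        assert np.all(
            faces.mem_cell == small_root_map.cell_id.ravel()[faces.mem_cyt])

    def test_membrane_face_count_equals_cell_perimeter(self, small_root_map):
        faces = interfaces(small_root_map)
        for cid in range(small_root_map.n_cells):
            r0, r1 = small_root_map.cell_rows(cid)
            c0, c1 = small_root_map.cell_cols(cid)
            perimeter = 2 * ((r1 - r0) + (c1 - c0))
            assert np.sum(faces.mem_cell == cid) == perimeter

    def test_shared_wall_between_cells_has_faces_to_both(self):
        rmap = build_root_map(minimal_spec(n_tiers=2, files=(("vascular", 8.0),)))
        faces = interfaces(rmap)
        shared_row = rmap.row_bounds[1]
        nc = rmap.dims[1]
        wall_pts = [shared_row * nc + c for c in range(1, 4)]
        for w in wall_pts:
            cells = faces.mem_cell[faces.mem_wall == w]
            assert set(cells) == {0, 2}  # tier 0 and tier 1 of the left file


class TestRegionMask:
    def test_cell_type_partition_recovers_cytosol(self, small_root_map):
        total = 0
        for t in ("epidermis", "outer", "pericycle", "vascular",
                  "columella", "qc"):
            total += region_mask(small_root_map, cell_types=(t,)).sum()
        assert total == small_root_map.cytosol_mask.sum()

    def test_central_selector_is_complement_of_outer(self, small_root_map):
        central = region_mask(small_root_map,
                              cell_types=("vascular", "pericycle"))
        rest = region_mask(
            small_root_map,
            cell_types=("epidermis", "outer", "columella", "qc"))
        assert not np.any(central & rest)
        assert (central | rest).sum() == small_root_map.cytosol_mask.sum()

    def test_tier_range_selects_inclusive_window(self, small_root_map):
        mask = region_mask(small_root_map, tiers=(2, 3))
        cids = np.unique(small_root_map.cell_id[mask])
        assert set(small_root_map.tier_index[cids]) == {2, 3}

    def test_unknown_selector_raises(self, small_root_map):
        with pytest.raises(KeyError):
            region_mask(small_root_map, cell_types=("phloem",))
        with pytest.raises(KeyError):
            region_mask(small_root_map, zones=("DZ",))


@settings(max_examples=15, deadline=None, derandomize=True)
@given(
    n_mz=st.integers(1, 4),
    widths=st.lists(st.sampled_from([6.0, 8.0, 12.0]), min_size=1, max_size=3),
    cap=st.booleans(),
)
def test_random_geometries_keep_invariants(n_mz, widths, cap):
    types = ["epidermis", "pericycle", "vascular"][-len(widths):]
    spec = GridSpec(
        spacing=2.0,
        file_widths=tuple(widths),
        file_types=tuple(types),
        columella_tier_lengths=(8.0,) if cap else (),
        qc_length=8.0 if cap else 0.0,
        mz_cell_length=8.0,
        mz_length=8.0 * n_mz,
        ez_cell_lengths=(),
    )
    rmap = build_root_map(spec)
    # mirror symmetry and the face oracle
    assert np.array_equal(rmap.point_kind, rmap.point_kind[:, ::-1])
    faces = interfaces(rmap)
    assert faces.counts() == brute_force_face_counts(rmap)
    # masks of all cell types partition the cytosol
    total = sum(
        region_mask(rmap, cell_types=(t,)).sum()
        for t in ("epidermis", "outer", "pericycle", "vascular",
                  "columella", "qc"))
    assert total == rmap.cytosol_mask.sum()
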