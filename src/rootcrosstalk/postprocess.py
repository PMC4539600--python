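"""Readouts of converged states: region averages, longitudinal profiles,
fold changes, colour maps and trend comparisons.

Concentration averages are arithmetic means over the cytosol points of a
region.  For the carrier proteins the membrane pools matter: the combined
species ``"pin_protein"`` and ``"aux1_protein"`` fold each membrane-face
pool into the cytosol side of the face, so averages count total carrier
protein per cytosol volume and are insensitive to cell shape (cell-tier
averaging additionally smooths the membrane/cytosol contrast).  Profiles can be normalized to their own maximum when
compared against image-derived response profiles, which are unitless.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import RootMap, region_mask
from .state import SpeciesState

COMBINED = {
    "pin_protein": ("pinp_cyt", "pinp_mem"),
    "aux1_protein": ("aux1p_cyt", "aux1p_mem"),
}


def _resolve(state: SpeciesState, species: str):
    """Return (grid field, include_walls) for a species name.

    Combined carrier species deposit each membrane-face pool onto the
    cytosol side of its face, so per-cell averages equal (cytosolic +
    membrane amount) / cytosol volume regardless of cell shape; bare
    membrane pools are shown on their wall points.
    """
    if species in COMBINED:
        cyt, mem = COMBINED[species]
        field = state.grid[cyt].copy()
        np.add.at(field.ravel(), state.faces.mem_cyt, state.mem[mem])
        return field, False
    if species in state.mem:
        return state.membrane_field(species), True
    return state.grid[species], False


def _state_of(result) -> SpeciesState:
    return result.state if hasattr(result, "state") else result


def region_average(result, species: str, **selector) -> float:
    """Mean concentration (uM) of a species over a region of cytosol points
    (plus owning wall points for membrane/carrier species)."""
    state = _state_of(result)
    field, with_walls = _resolve(state, species)
    selector.setdefault("include_walls", with_walls)
    mask = region_mask(state.rmap, **selector)
    if not mask.any():
        raise ValueError("empty region")
    return float(field[mask].mean())


@dataclass
class Profile:
    """A longitudinal concentration profile."""
    positions: np.ndarray    # um from the tip (row mode) or tier index
    values: np.ndarray
    species: str
    mode: str                # "row" or "tier"

    def __post_init__(self):
        self.positions = np.asarray(self.positions, float)
        self.values = np.asarray(self.values, float)
        if self.positions.size != self.values.size:
            raise ValueError("positions/values length mismatch")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    def normalized(self) -> "Profile":
        m = self.values.max()
        if m <= 0:
            raise ValueError("cannot normalize a nonpositive profile")
        return Profile(self.positions, self.values / m, self.species, self.mode)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.positions, "value": self.values})


def longitudinal_profile(result, species: str, mode: str = "row",
                         **selector) -> Profile:
    """Profile along the root axis.  ``mode="row"`` averages each
    cross-sectional grid row; ``mode="tier"`` averages all points of each
    cell tier (including walls for carrier species), which smooths the
    membrane/cytosol contrast."""
    state = _state_of(result)
    rmap = state.rmap
    field, with_walls = _resolve(state, species)
    selector.setdefault("include_walls", with_walls)
    base = region_mask(rmap, **selector)
    h = rmap.spacing

    if mode == "row":
        pos, vals = [], []
        for r in range(rmap.dims[0]):
            row_mask = base[r]
            if row_mask.any():
                pos.append(r * h)
                vals.append(field[r, row_mask].mean())
    elif mode == "tier":
        pos, vals = [], []
        n_tiers = len(rmap.spec.tier_lengths)
        for t in range(n_tiers):
            tmask = base & region_mask(
                rmap, tiers=(t + 1, t + 1),
                include_walls=selector.get("include_walls", False))
            if tmask.any():
                pos.append(t + 1)
                vals.append(field[tmask].mean())
    else:
        raise ValueError(f"unknown profile mode {mode!r}")
    return Profile(np.asarray(pos), np.asarray(vals), species, mode)


def fold_change(result_mut, result_wt, species: str, **selector) -> float:
    """Region-average ratio mutant / wild-type."""
    wt = region_average(result_wt, species, **selector)
    if wt == 0:
        raise ZeroDivisionError("wild-type average is zero")
    return region_average(result_mut, species, **selector) / wt


@dataclass
class TrendReport:
    spearman_rho: float
    argmax_position: float
    argmin_position: float
    increasing_fraction: float      # fraction of steps going up
    expected: str | None
    passed: bool | None

    def __str__(self):
        verdict = ("" if self.passed is None
                   else f" expected={self.expected} passed={self.passed}")
        return (f"trend(rho={self.spearman_rho:+.3f}, "
                f"argmax@{self.argmax_position:g},"
                f" up-fraction={self.increasing_fraction:.2f}{verdict})")


def trend_compare(profile: Profile, reference: Profile | None = None,
                  expected: str | None = None) -> TrendReport:
    """Monotonicity/extremum report of a profile, optionally correlated
    against a reference profile resampled to the same axis, and/or checked
    against a declared trend ("increasing" or "decreasing" shootwards)."""
    v = profile.values
    if np.allclose(v, v[0]):
        raise ValueError("degenerate (constant) profile")
    if reference is not None:
        ref = np.interp(profile.positions, reference.positions,
                        reference.values)
        rho = float(stats.spearmanr(v, ref).statistic)
    else:
        rho = float(stats.spearmanr(profile.positions, v).statistic)
    steps = np.diff(v)
    up = float(np.mean(steps > 0)) if steps.size else 0.0
    passed = None
    if expected is not None:
        if expected not in ("increasing", "decreasing"):
            raise ValueError(f"unknown expected trend {expected!r}")
        ok_rho = rho > 0 if expected == "increasing" else rho < 0
        passed = bool(ok_rho)
    return TrendReport(
        spearman_rho=rho,
        argmax_position=float(profile.positions[np.argmax(v)]),
        argmin_position=float(profile.positions[np.argmin(v)]),
        increasing_fraction=up,
        expected=expected,
        passed=passed,
    )


def load_reference_profile(name: str) -> Profile:
    """A shipped qualitative reference trend (synthetic, unitless).

    These curves are idealized response shapes - an auxin response peaking
    near the quiescent centre, a PLS response declining shootwards, an
    ethylene response rising shootwards - for use as ``trend_compare``
    references.  They are synthetic stand-ins, not digitized measurements,
    and are never used as numeric targets.
    """
    from importlib import resources

    ref = resources.files("rootcrosstalk.data") / "synthetic_reference_profiles.csv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, comment="#")
    sel = df[df["profile"] == name]
    if sel.empty:
        raise KeyError(f"unknown reference profile {name!r}; "
                       f"known: {sorted(df['profile'].unique())}")
    return Profile(sel["position_um"].to_numpy(float),
                   sel["value"].to_numpy(float), name, "row")


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def export_csv(result, species: str, path) -> None:
    """Write the full grid field of a species as CSV (rows x cols)."""
    state = _state_of(result)
    field, _ = _resolve(state, species)
    pd.DataFrame(field).to_csv(path, index=False)


def read_csv_field(path) -> np.ndarray:
    return pd.read_csv(path, float_precision="round_trip").to_numpy(dtype=float)


def export_colormap(result, species: str, path, vmin: float = 0.0,
                    vmax: float | None = None, dpi: int = 100) -> None:
    """Colour map of a species (uM) with the tip at the bottom.  The colour
    scale is fixed and printed on the bar so maps are comparable."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    state = _state_of(result)
    field, _ = _resolve(state, species)
    if vmax is None:
        vmax = float(field.max()) or 1.0
    fig, ax = plt.subplots(figsize=(3, 6))
    im = ax.imshow(field, origin="lower", vmin=vmin, vmax=vmax,
                   cmap="viridis", interpolation="nearest", aspect="auto")
    ax.set_xlabel("transverse (grid)")
    ax.set_ylabel("longitudinal (grid, tip at bottom)")
    ax.set_title(species)
    fig.colorbar(im, ax=ax, label="concentration (uM)")
    fig.savefig(path, dpi=dpi, metadata={"Software": "rootcrosstalk"})
    plt.close(fig)


def file_checksum(path) -> str:
    with open(path, "rb") as fh:
        return hashlib.sha256(fh.read()).hexdigest()
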