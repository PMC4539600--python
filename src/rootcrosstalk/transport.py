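"""Spatial fluxes: diffusion, membrane crossing and shoot-boundary exchange.

Flux conventions: a *face* joins two adjacent grid points; fluxes are
reported per unit face length (uM um / s), so the total through one face of
length ``h`` (the grid spacing) is ``h`` times larger.  Fluxes are
antisymmetric by construction.

Species rules (enforced by the operators the solver assembles):

* hormones diffuse within the cytosol and within the wall network;
* ethylene and cytokinin additionally cross membrane faces diffusively;
* auxin crosses membranes only through carriers: AUX1-mediated influx
  (wall -> cytosol) on every membrane face, PIN-mediated efflux
  (cytosol -> wall) only on the faces selected by the cell type's polarity
  pattern; an optional passive permeability is off by default;
* all other species stay within the cytosol of their cell.

PIN polarity (prescribed per cell type, magnitudes from the simulated
membrane pools): vascular and pericycle files pump rootward, epidermis and
the outer file pump shootward, columella and QC pump lateral-outward.
This closes the tip reflux loop: down the central tissues, out at the cap,
back up the outer layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    EPIDERMIS, OUTER, PERICYCLE, QC, VASCULAR, COLUMELLA,
    ROOTWARD, SHOOTWARD, LATERAL_IN, LATERAL_OUT,
    FaceSet, RootMap,
)
from .params import KineticParameters

PIN_POLARITY = {
    VASCULAR: (ROOTWARD,),
    PERICYCLE: (ROOTWARD,),
    EPIDERMIS: (SHOOTWARD,),
    OUTER: (SHOOTWARD,),
    COLUMELLA: (LATERAL_OUT,),
    QC: (LATERAL_OUT,),
}


def diffusive_flux(c_a, c_b, D, spacing):
    """Fickian face flux from a to b per unit face length (uM um/s)."""
    if np.any(np.asarray(D) < 0):
        raise ValueError("diffusion coefficient must be nonnegative")
    return D * (np.asarray(c_a, float) - np.asarray(c_b, float)) / spacing


def carrier_activity(mem_abundance, ref, cap):
    """Saturating scaling of carrier abundance: linear below the cap,
    normalized so the wild-type reference abundance gives 1."""
    return np.minimum(np.asarray(mem_abundance, float) / ref, cap)


def auxin_membrane_flux(auxin_cyt, auxin_wall, pin_mem, aux1_mem,
                        p: KineticParameters, pin_allowed=True):
    """Net carrier-mediated auxin flux into the cytosol per unit face length.

    influx = P_aux1 * g(aux1_mem) * auxin_wall; efflux (PIN faces only)
    = P_pin * g(pin_mem) * auxin_cyt.  With both carriers absent the flux
    is zero: there is no passive auxin crossing in the default model.
    """
    g_in = carrier_activity(aux1_mem, p.aux1_mem_ref, p.carrier_cap)
    g_out = carrier_activity(pin_mem, p.pin_mem_ref, p.carrier_cap)
    influx = p.P_aux1 * g_in * np.asarray(auxin_wall, float)
    efflux = p.P_pin * g_out * np.asarray(auxin_cyt, float)
    net = influx - np.where(pin_allowed, efflux, 0.0)
    if p.P_auxin_passive:
        net = net + p.P_auxin_passive * (
            np.asarray(auxin_wall, float) - np.asarray(auxin_cyt, float))
    return net


def gas_membrane_flux(c_cyt, c_wall, P_mem):
    """Diffusive membrane crossing for ethylene/cytokinin, per unit face
    length, positive into the cytosol."""
    if np.any(np.asarray(P_mem) < 0):
        raise ValueError("membrane permeability must be nonnegative")
    return P_mem * (np.asarray(c_wall, float) - np.asarray(c_cyt, float))


def pin_allowed_faces(rmap: RootMap, faces: FaceSet) -> np.ndarray:
    """Boolean mask over membrane faces where the cell's polarity pattern
    places PIN."""
    allowed = np.zeros(faces.n_membrane, dtype=bool)
    cell_types = rmap.cell_type[faces.mem_cell]
    for ctype, orients in PIN_POLARITY.items():
        sel = cell_types == ctype
        for o in orients:
            allowed |= sel & (faces.mem_orientation == o)
    return allowed


@dataclass
class FluxLedger:
    """Boundary and membrane flux bookkeeping of a converged state.

    Boundary entries are total fluxes per boundary point (uM um^2/s,
    positive into the root).  ``membrane_net_auxin`` is the net
    carrier-mediated auxin flux per membrane face (into the cytosol, per
    unit face length).
    """

    spacing: float
    influx_cols: np.ndarray
    efflux_cols: np.ndarray
    auxin_influx: np.ndarray        # per influx point, >= 0
    auxin_efflux: np.ndarray        # per efflux point, >= 0 (leaving the root)
    et_boundary_net: np.ndarray     # per gas point, signed
    ck_boundary_net: np.ndarray
    membrane_net_auxin: np.ndarray

    @property
    def total_influx(self) -> float:
        return float(self.auxin_influx.sum())

    @property
    def total_efflux(self) -> float:
        return float(self.auxin_efflux.sum())

    def totals(self) -> dict:
        return {
            "auxin_influx": self.total_influx,
            "auxin_efflux": self.total_efflux,
            "auxin_net": self.total_influx - self.total_efflux,
            "et_net": float(self.et_boundary_net.sum()),
            "ck_net": float(self.ck_boundary_net.sum()),
        }


def shoot_boundary_fluxes(state, p: KineticParameters, rmap: RootMap,
                          faces: FaceSet, pin_allowed=None) -> FluxLedger:
    """Evaluate shoot-boundary and membrane fluxes for a state.

    Auxin influx applies on the pericycle/vascular boundary points and is
    repressed by the local downstream ethylene signal X; auxin efflux
    applies on the epidermal boundary points, proportional to local wall
    auxin scaled by the membrane PIN of the face beneath; ethylene and
    cytokinin exchange diffusively against fixed shoot-side references.
    """
    h = rmap.spacing
    top = rmap.shoot_row
    auxin = state["auxin"]
    et, ck, x = state["et"], state["ck"], state["x"]

    icols = rmap.shoot_influx_cols
    x_near = x[top - 1, icols] if top >= 1 else np.zeros(icols.size)
    influx = (p.k_influx_shoot / (1.0 + x_near / p.K_x_influx)) * h

    ecols = rmap.shoot_efflux_cols
    pin_scale = _boundary_pin_scale(state, p, rmap, faces, ecols)
    efflux = p.k_efflux_shoot * pin_scale * auxin[top, ecols] * h

    gcols = rmap.shoot_gas_cols
    et_net = p.P_et_shoot * (p.et_shoot - et[top, gcols]) * h
    ck_net = p.P_ck_shoot * (p.ck_shoot - ck[top, gcols]) * h

    if pin_allowed is None:
        pin_allowed = pin_allowed_faces(rmap, faces)
    a_cyt = auxin.ravel()[faces.mem_cyt]
    a_wall = auxin.ravel()[faces.mem_wall]
    net_mem = auxin_membrane_flux(
        a_cyt, a_wall, state["pinp_mem"], state["aux1p_mem"], p, pin_allowed)

    return FluxLedger(
        spacing=h,
        influx_cols=icols, efflux_cols=ecols,
        auxin_influx=influx, auxin_efflux=efflux,
        et_boundary_net=et_net, ck_boundary_net=ck_net,
        membrane_net_auxin=net_mem,
    )


def _boundary_pin_scale(state, p, rmap, faces: FaceSet, ecols) -> np.ndarray:
    """Carrier scaling of the epidermal shoot-efflux points, from the
    membrane PIN of the shootward face directly beneath each point."""
    nr, nc = rmap.dims
    top = rmap.shoot_row
    wall_flat = (top * nc + ecols)
    scale = np.ones(ecols.size)
    sel = (faces.mem_orientation == SHOOTWARD)
    wall_of_face = faces.mem_wall[sel]
    pin_of_face = carrier_activity(
        state["pinp_mem"][sel], p.pin_mem_ref, p.carrier_cap)
    lookup = dict(zip(wall_of_face.tolist(), pin_of_face.tolist()))
    for i, w in enumerate(wall_flat.tolist()):
        scale[i] = lookup.get(w, 1.0)
    return scale


def total_rootward_flux(ledger: FluxLedger, gross: bool = False) -> float:
    """Shoot-to-root auxin flux: gross influx, or net of the epidermal
    root-to-shoot efflux (default)."""
    if gross:
        return ledger.total_influx
    return ledger.total_influx - ledger.total_efflux
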