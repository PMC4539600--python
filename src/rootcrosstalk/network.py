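"""Per-grid-point reaction kinetics of the hormonal crosstalk network.

One network per cell (evaluated at every cytosol point): synthesis and
first-order decay of the three hormones; the auxin and ethylene receptor
cascades (Ra/Ra*, ETR1 as Re/Re*, CTR1/CTR1* and the lumped downstream
ethylene signal X); and the expression modules for PLS, PIN and AUX1.

Functional forms are mass-action for receptor inter-conversions,
Michaelis-Menten (Hill coefficient 1) for activations, and saturating
``1/(1 + c/K)`` factors for repressions; repression factors that must not
vanish at saturation carry a residual floor.  The regulatory logic:

* auxin synthesis: basal + activated by ethylene signalling (X), inhibited
  by cytokinin (Nordstrom-type; a Jones-type activating variant is a
  config switch);
* cytokinin synthesis: restricted to the vascular/pericycle/columella/QC
  cells, inhibited by auxin;
* ethylene synthesis: basal + synergistic activation by auxin and cytokinin,
  independent of PLS;
* receptor cascade: auxin activates Ra->Ra*; ethylene binding deactivates
  Re* (ETR1) while the PLS peptide promotes the active pool; Re* activates
  CTR1->CTR1*, which represses production of X;
* PLS transcription: induced by auxin signalling (Ra*), weakly repressed by
  ethylene signalling (X);
* PIN transcription: promoted by auxin (Ra*) and ethylene signalling (X),
  repressed by cytokinin;
* AUX1 transcription: promoted by ethylene signalling (X).

All functions accept either scalars or numpy arrays; ``s`` is any mapping
from species name to concentration (a :class:`~rootcrosstalk.state.SpeciesState`
works, and so does a plain dict).
"""

from __future__ import annotations

import numpy as np

from .params import KineticParameters
from .geometry import CELL_TYPE_NAMES, COLUMELLA, PERICYCLE, QC, VASCULAR

CK_SYNTHESIS_TYPES = frozenset({PERICYCLE, VASCULAR})


def _check_nonneg(**kw):
    for name, v in kw.items():
        if np.any(np.asarray(v) < 0):
            raise ValueError(f"negative concentration for {name}")


# ---------------------------------------------------------------------------
# regulation factors
# ---------------------------------------------------------------------------

def ck_inhibition_of_auxin(ck, p: KineticParameters):
    """Saturating cytokinin factor on auxin synthesis.

    Nordstrom mode: falls from 1 to the residual ``rho_a``.
    Jones mode: rises from 1 to 2 (cytokinin activates auxin synthesis).
    """
    if p.ck_auxin_mode == "jones":
        return 1.0 + ck / (p.K_cka + ck)
    return p.rho_a + (1.0 - p.rho_a) / (1.0 + ck / p.K_cka)


def auxin_synthesis(x, ck, p: KineticParameters):
    return (p.k_a0 + p.k_ax * x / (p.K_xa + x)) * ck_inhibition_of_auxin(ck, p)


def pls_transcription(ras, x, p: KineticParameters):
    if p.pls_auxin_regulation:
        aux_factor = ras / (p.K_ras_pls + ras)
    else:
        aux_factor = p.ablation_aux_factor * np.ones_like(np.asarray(ras, float))
    rate = p.k_plsm * (p.f0_pls + aux_factor) / (1.0 + x / p.K_xpls)
    return p.pls_functional * (rate + p.k_plsm_ox)


def pin_transcription(ras, x, ck, p: KineticParameters):
    fa = p.f0a_pin + (1.0 - p.f0a_pin) * ras / (p.K_ras_pin + ras)
    fx = p.f0x_pin + (1.0 - p.f0x_pin) * x / (p.K_x_pin + x)
    fc = p.rho_pin + (1.0 - p.rho_pin) / (1.0 + ck / p.K_ck_pin)
    return p.k_pinm * fa * fx * fc


def aux1_transcription(x, p: KineticParameters):
    return p.k_aux1m * (p.f0_aux1 + (1.0 - p.f0_aux1) * x / (p.K_x_aux1 + x))


# ---------------------------------------------------------------------------
# per-species net rates (uM/s); the module surface used by tests and by the
# explicit integrator.  The implicit solver uses production_and_loss below.
# ---------------------------------------------------------------------------

def auxin_reaction_rate(s, p: KineticParameters, is_cytosol=True):
    """Net auxin reaction rate: synthesis (basal + X-activated, CK-inhibited)
    minus first-order decay.  Zero on wall points (no reactions there)."""
    _check_nonneg(auxin=s["auxin"], x=s["x"], ck=s["ck"])
    rate = auxin_synthesis(s["x"], s["ck"], p) - p.d_a * s["auxin"]
    return np.where(is_cytosol, rate, 0.0) if not np.all(is_cytosol) else rate


def cytokinin_reaction_rate(s, p: KineticParameters, cell_type):
    """Net cytokinin rate; synthesis only in vascular/pericycle files."""
    if isinstance(cell_type, str):
        cell_type = CELL_TYPE_NAMES[cell_type]
    synth = np.isin(cell_type, list(CK_SYNTHESIS_TYPES))
    prod = p.s_ck / (1.0 + s["auxin"] / p.K_ack)
    return np.where(synth, prod, 0.0) - p.d_ck * s["ck"]


def ethylene_reaction_rate(s, p: KineticParameters):
    """Net ethylene rate: basal + auxin/cytokinin synergistic synthesis minus
    decay; independent of PLS."""
    a, ck = s["auxin"], s["ck"]
    prod = p.k_e0 + p.k_es * (a / (p.K_ae + a)) * (ck / (p.K_cke + ck))
    return prod - p.d_et * s["et"]


def receptor_cascade_rates(s, p: KineticParameters) -> dict:
    """Rates of the seven cascade species.  The three pair sums (Ra+Ra*,
    Re+Re*, CTR1+CTR1*) are conserved by these terms."""
    a, et, plsp = s["auxin"], s["et"], s["plsp"]
    ra, ras = s["ra"], s["ras"]
    re, res = s["re"], s["res"]
    ctr, ctrs = s["ctr"], s["ctrs"]
    d_ras = p.k_ra_on * a * ra - p.k_ra_off * ras
    d_res = (p.k_re_off + p.k_re_pls * plsp) * re - p.k_re_et * et * res
    d_ctrs = p.k_ctr_on * res * ctr - p.k_ctr_off * ctrs
    d_x = p.k_x / (1.0 + ctrs / p.K_ctrx) - p.d_x * s["x"]
    return {
        "ra": -d_ras, "ras": d_ras,
        "re": -d_res, "res": d_res,
        "ctr": -d_ctrs, "ctrs": d_ctrs,
        "x": d_x,
    }


def pls_expression_rates(s, p: KineticParameters) -> tuple:
    """(d PLSm/dt, d PLSp/dt).  The pls genotype zeroes functional PLS
    production; PLSox adds a constitutive transcription term; the ablation
    switch replaces the Ra* factor with a constant."""
    d_plsm = pls_transcription(s["ras"], s["x"], p) - p.d_plsm * s["plsm"]
    d_plsp = p.pls_functional * p.k_pls_transl * s["plsm"] - p.d_plsp * s["plsp"]
    return d_plsm, d_plsp


def pin_expression_rates(s, p: KineticParameters) -> tuple:
    """(d PINm/dt, d PINp_cyt/dt) excluding the recycling exchange, which is
    handled with the membrane pools."""
    d_pinm = pin_transcription(s["ras"], s["x"], s["ck"], p) - p.d_pinm * s["pinm"]
    d_pinp = p.k_pin_transl * s["pinm"] - p.d_pinp * s["pinp_cyt"]
    return d_pinm, d_pinp


def aux1_expression_rates(s, p: KineticParameters) -> tuple:
    d_m = aux1_transcription(s["x"], p) - p.d_aux1m * s["aux1m"]
    d_p = p.k_aux1_transl * s["aux1m"] - p.d_aux1p * s["aux1p_cyt"]
    return d_m, d_p


# ---------------------------------------------------------------------------
# production / linear-loss split used by the implicit finite-volume solver
# ---------------------------------------------------------------------------

def production_and_loss(s, p: KineticParameters, ck_synth_mask) -> tuple:
    """Split every cytosolic reaction into (production, loss-coefficient)
    so that ``rate = production - loss * concentration`` with production and
    loss both nonnegative.  State-dependent conversion losses (e.g. ET
    binding of Re*) appear as loss coefficients evaluated at the current
    iterate, which keeps the implicit update an M-matrix and therefore
    positivity-preserving.
    """
    a, et, ck, x = s["auxin"], s["et"], s["ck"], s["x"]
    prod = {
        "auxin": auxin_synthesis(x, ck, p),
        "ck": np.where(ck_synth_mask, p.s_ck / (1.0 + a / p.K_ack), 0.0),
        "et": p.k_e0 + p.k_es * (a / (p.K_ae + a)) * (ck / (p.K_cke + ck)),
        "ras": p.k_ra_on * a * s["ra"],
        "ra": p.k_ra_off * s["ras"],
        "res": (p.k_re_off + p.k_re_pls * s["plsp"]) * s["re"],
        "re": p.k_re_et * et * s["res"],
        "ctrs": p.k_ctr_on * s["res"] * s["ctr"],
        "ctr": p.k_ctr_off * s["ctrs"],
        "x": p.k_x / (1.0 + s["ctrs"] / p.K_ctrx),
        "plsm": pls_transcription(s["ras"], x, p),
        "plsp": p.pls_functional * p.k_pls_transl * s["plsm"],
        "pinm": pin_transcription(s["ras"], x, ck, p),
        "pinp_cyt": p.k_pin_transl * s["pinm"],
        "aux1m": aux1_transcription(x, p),
        "aux1p_cyt": p.k_aux1_transl * s["aux1m"],
    }
    loss = {
        "auxin": p.d_a,
        "ck": p.d_ck,
        "et": p.d_et,
        "ras": p.k_ra_off,
        "ra": p.k_ra_on * a,
        "res": p.k_re_et * et,
        "re": p.k_re_off + p.k_re_pls * s["plsp"],
        "ctrs": p.k_ctr_off,
        "ctr": p.k_ctr_on * s["res"],
        "x": p.d_x,
        "plsm": p.d_plsm,
        "plsp": p.d_plsp,
        "pinm": p.d_pinm,
        "pinp_cyt": p.d_pinp,
        "aux1m": p.d_aux1m,
        "aux1p_cyt": p.d_aux1p,
    }
    return prod, loss
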