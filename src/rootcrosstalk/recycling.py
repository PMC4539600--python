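"""Exocytosis/endocytosis exchange of PIN and AUX1 between cytosolic and
membrane pools.

Exocytosis moves cytosolic carrier protein to the cell's membrane faces at
rate ``k_exo`` (first order in the cytosolic pool, distributed uniformly
over the faces permitted by the carrier's polarity pattern).  Endocytosis
returns membrane protein to the cytosol at rate ``k_endo``; for PIN this
rate is inhibited by the local wall-side auxin concentration,
``k_endo / (1 + auxin / K_endo_aux)`` (auxin stabilizes PIN at the
membrane).  AUX1 recycling is unregulated.  The exchange is conservative:
recycling alone never changes the total carrier protein of a cell.
"""

from __future__ import annotations

import numpy as np

from .params import KineticParameters


def pin_endocytosis_rate_constant(auxin_wall, p: KineticParameters):
    """Effective PIN endocytosis rate constant at a face (1/s)."""
    return p.k_pin_endo / (1.0 + auxin_wall / p.K_endo_aux)


def pin_recycling_rates(pin_cyt, pin_mem, auxin, p: KineticParameters):
    """(d pin_cyt/dt, d pin_mem/dt) from recycling alone, for one cytosol
    pool exchanging with one membrane pool.  The pair sums to zero."""
    _reject_negative(pin_cyt=pin_cyt, pin_mem=pin_mem, auxin=auxin)
    exo = p.k_pin_exo * np.asarray(pin_cyt, float)
    endo = pin_endocytosis_rate_constant(auxin, p) * np.asarray(pin_mem, float)
    return endo - exo, exo - endo


def aux1_recycling_rates(aux1_cyt, aux1_mem, p: KineticParameters):
    """Conservative first-order exchange; no auxin modulation."""
    _reject_negative(aux1_cyt=aux1_cyt, aux1_mem=aux1_mem)
    exo = p.k_aux1_exo * np.asarray(aux1_cyt, float)
    endo = p.k_aux1_endo * np.asarray(aux1_mem, float)
    return endo - exo, exo - endo


def pin_steady_membrane_ratio(auxin, p: KineticParameters):
    """Closed-form steady pin_mem/pin_cyt ratio under pure recycling."""
    return (p.k_pin_exo / p.k_pin_endo) * (1.0 + auxin / p.K_endo_aux)


def aux1_steady_membrane_ratio(p: KineticParameters):
    return p.k_aux1_exo / p.k_aux1_endo


def _reject_negative(**kw):
    for name, v in kw.items():
        if np.any(np.asarray(v) < 0):
            raise ValueError(f"negative input {name}")
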