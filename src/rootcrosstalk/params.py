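"""Kinetic, transport and boundary parameters of the crosstalk model.

Units: concentrations uM, time s, lengths um.  Diffusion coefficients are
um^2/s, membrane permeabilities um/s.  Values printed in the source
literature: auxin diffusion 220 um^2/s (Rutschow et al.), PIN efflux
permeability 0.5-5 um/s with median 2 (Kramer et al.), AUX1 influx
permeability 1.5 +/- 0.3 um/s (Rutschow et al.).  Receptor/CTR1 step rates
follow the mass-action convention of Diaz & Alvarez-Buylla-style cascade
models.  Remaining constants are fitting parameters calibrated once against
the model-fitting criteria (wild-type auxin maximum at the QC, predominantly
membrane-localized carriers, vascular/pericycle-restricted cytokinin
synthesis, and the wild-type/mutant trend set); see docs/methods.md.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources

import yaml

P_PIN_RANGE = (0.5, 5.0)
P_AUX1_RANGE = (1.2, 1.8)


@dataclass
class KineticParameters:
    # --- diffusion (um^2/s) ---------------------------------------------
    D_auxin: float = 220.0          # cytosol, literature value
    D_auxin_wall: float = 10.0      # apoplast, much slower than cytosol
    D_et: float = 300.0
    D_et_wall: float = 300.0
    D_ck: float = 220.0
    D_ck_wall: float = 110.0
    D_mrna: float = 1.0             # intracellular only
    D_protein: float = 3.0
    D_receptor: float = 1.0
    D_x: float = 20.0

    # --- membrane crossing (um/s) ---------------------------------------
    P_et_mem: float = 15.0          # ethylene crosses freely
    P_ck_mem: float = 3.0
    P_pin: float = 4.0              # PIN efflux permeability, within 0.5-5
    P_aux1: float = 1.8             # AUX1 influx permeability, within 1.5 +/- 0.3
    P_auxin_passive: float = 0.0    # optional non-carrier auxin leak
    pin_mem_ref: float = 1.0        # membrane abundance giving nominal P_pin (uM)
    aux1_mem_ref: float = 1.0
    carrier_cap: float = 8.0        # saturation cap of the abundance scaling

    # --- auxin kinetics --------------------------------------------------
    k_a0: float = 4.5e-4            # basal synthesis (uM/s)
    k_ax: float = 4.6e-3            # X-activated synthesis, max (uM/s)
    K_xa: float = 0.12               # X half-activation (uM)
    K_cka: float = 0.03              # CK inhibition constant (uM)
    rho_a: float = 0.05             # residual synthesis at saturating CK
    d_a: float = 6.0e-3             # decay (1/s)

    # --- cytokinin kinetics ---------------------------------------------
    s_ck: float = 8.0e-3            # synthesis in vascular/pericycle files (uM/s)
    K_ack: float = 0.04             # auxin inhibition constant (uM)
    d_ck: float = 5.0e-3

    # --- ethylene kinetics ----------------------------------------------
    k_e0: float = 5.0e-4            # basal synthesis (uM/s)
    k_es: float = 3.0e-4            # auxin+CK synergistic synthesis, max
    K_ae: float = 0.3
    K_cke: float = 0.5
    d_et: float = 2.0e-3

    # --- receptors and cascade ------------------------------------------
    ra_total: float = 1.0           # Ra + Ra* (uM)
    k_ra_on: float = 1.0            # auxin activation (1/(uM s))
    k_ra_off: float = 6.0
    re_total: float = 1.0           # Re + Re* (ETR1)
    k_re_et: float = 1.0            # ET binding deactivates Re* (1/(uM s))
    k_re_off: float = 0.02          # spontaneous reactivation
    k_re_pls: float = 6.0           # PLSp-promoted reactivation (1/(uM s))
    ctr_total: float = 1.0          # CTR1 + CTR1*
    k_ctr_on: float = 0.15           # Re*-driven activation (1/(uM s))
    k_ctr_off: float = 0.1
    k_x: float = 5.0e-3             # X production, max (uM/s)
    K_ctrx: float = 0.05            # CTR1* repression constant
    d_x: float = 1.0e-2

    # --- PLS expression --------------------------------------------------
    k_plsm: float = 1.2e-3          # transcription scale (uM/s)
    f0_pls: float = 0.01            # basal floor of the auxin factor
    K_ras_pls: float = 1.5          # Ra* half-activation
    K_xpls: float = 2.0             # weak ethylene repression
    d_plsm: float = 1.0e-3
    k_pls_transl: float = 1.0e-3
    d_plsp: float = 1.0e-3
    pls_functional: float = 1.0     # 0 in the pls mutant
    k_plsm_ox: float = 0.0          # constitutive transcription (PLSox)
    pls_auxin_regulation: float = 1.0   # 0 = ablate the Ra* dependence
    ablation_aux_factor: float = 0.5    # constant replacing the Ra* factor

    # --- PIN expression and recycling ------------------------------------
    k_pinm: float = 1.0e-3
    f0a_pin: float = 0.2            # auxin factor floor
    K_ras_pin: float = 0.05
    f0x_pin: float = 0.15           # ethylene-signalling factor floor
    K_x_pin: float = 0.08
    rho_pin: float = 0.1            # residual at saturating CK
    K_ck_pin: float = 0.8
    d_pinm: float = 1.0e-3
    k_pin_transl: float = 2.0e-3
    d_pinp: float = 4.0e-4          # decay of both PIN pools
    k_pin_exo: float = 5.0e-3       # exocytosis (1/s)
    k_pin_endo: float = 1.0e-3      # endocytosis, inhibited by wall auxin
    K_endo_aux: float = 0.5

    # --- AUX1 expression and recycling -----------------------------------
    k_aux1m: float = 1.0e-3
    f0_aux1: float = 0.3
    K_x_aux1: float = 0.08
    d_aux1m: float = 1.0e-3
    k_aux1_transl: float = 2.0e-3
    d_aux1p: float = 4.0e-4
    k_aux1_exo: float = 5.0e-3
    k_aux1_endo: float = 1.0e-3

    # --- shoot boundary ---------------------------------------------------
    k_influx_shoot: float = 5.5     # auxin loading, uM um/s per unit face
    K_x_influx: float = 0.075         # X repression of the loading
    k_efflux_shoot: float = 5.0     # epidermal unloading permeability (um/s)
    et_shoot: float = 3.0           # shoot-side reference concentrations (uM)
    ck_shoot: float = 0.2
    P_et_shoot: float = 15.0        # boundary exchange permeabilities (um/s)
    P_ck_shoot: float = 0.02

    # --- switches ---------------------------------------------------------
    ck_auxin_mode: str = "nordstrom"  # "nordstrom" (CK inhibits auxin synthesis)
                                      # or "jones" (CK activates it)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and v < 0:
                raise ValueError(f"parameter {f.name} is negative: {v}")
        if self.ck_auxin_mode not in ("nordstrom", "jones"):
            raise ValueError(f"unknown ck_auxin_mode {self.ck_auxin_mode!r}")

    def copy(self, **overrides) -> "KineticParameters":
        return dataclasses.replace(self, **overrides)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "KineticParameters":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        base = cls()
        return base.copy(**{k: v for k, v in data.items()})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    def check_carrier_ranges(self) -> None:
        """Warn-level check that carrier permeabilities sit in their
        experimentally measured windows (overridable by genotypes)."""
        if not (P_PIN_RANGE[0] <= self.P_pin <= P_PIN_RANGE[1]):
            raise ValueError(f"P_pin {self.P_pin} outside {P_PIN_RANGE}")
        if not (P_AUX1_RANGE[0] <= self.P_aux1 <= P_AUX1_RANGE[1]):
            raise ValueError(f"P_aux1 {self.P_aux1} outside {P_AUX1_RANGE}")


def default_parameters() -> KineticParameters:
    """Parameters shipped with the package (data/default_parameters.yaml)."""
    ref = resources.files("rootcrosstalk.data") / "default_parameters.yaml"
    with resources.as_file(ref) as path:
        return KineticParameters.from_yaml(path)
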