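"""Named genotype configurations: parameter-override sets for mutant lines.

Each genotype is a small set of overrides applied to the wild-type parameter
table:

* ``wt`` - no overrides.
* ``pls`` - loss of POLARIS function: production of functional PLS is zero.
* ``etr1`` - dominant ethylene-insensitive receptor: the ET-binding
  (receptor-deactivating) rate is strongly reduced, so the Re* -> CTR1* -> X
  arm stays active regardless of ethylene.
* ``pls_etr1`` - both of the above.
* ``plsox`` - PLS over-expression: an added constitutive transcription term.
* ``aux1`` - auxin-influx permeability halved (other LAX carriers remain).

An ablation scenario (``pls_no_auxin_regulation``) removes the auxin (Ra*)
dependence of PLS transcription while keeping everything else wild-type;
it is a model experiment, not a plant line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .params import KineticParameters

# fitted magnitudes of the genotype knobs (trend data only, no printed
# mutant constants): see docs/methods.md
ETR1_BINDING_FACTOR = 0.055
PLSOX_TRANSCRIPTION = 2.4e-3


@dataclass(frozen=True)
class Genotype:
    """A named set of parameter overrides.

    ``scale`` entries multiply the wild-type value; ``set`` entries replace
    it.  Keys must be existing :class:`KineticParameters` field names.
    """

    name: str
    scale: dict = field(default_factory=dict)
    set: dict = field(default_factory=dict)

    def describe(self) -> str:
        parts = [f"{k} x{v}" for k, v in self.scale.items()]
        parts += [f"{k}={v}" for k, v in self.set.items()]
        return f"{self.name}: " + (", ".join(parts) if parts else "wild-type")


GENOTYPES = {
    "wt": Genotype("wt"),
    "pls": Genotype("pls", set={"pls_functional": 0.0}),
    "etr1": Genotype("etr1", scale={"k_re_et": ETR1_BINDING_FACTOR}),
    "pls_etr1": Genotype(
        "pls_etr1",
        scale={"k_re_et": ETR1_BINDING_FACTOR},
        set={"pls_functional": 0.0},
    ),
    "plsox": Genotype("plsox", set={"k_plsm_ox": PLSOX_TRANSCRIPTION}),
    "aux1": Genotype("aux1", scale={"P_aux1": 0.5}),
    "pls_no_auxin_regulation": Genotype(
        "pls_no_auxin_regulation", set={"pls_auxin_regulation": 0.0}
    ),
}


def get_genotype(name: str) -> Genotype:
    key = name.lower().replace(" ", "_").replace("-", "_")
    if key not in GENOTYPES:
        raise KeyError(
            f"unknown genotype {name!r}; known: {sorted(GENOTYPES)}"
        )
    return GENOTYPES[key]


def apply_genotype(p: KineticParameters, g: Genotype | str) -> KineticParameters:
    """Return a parameter copy with the genotype's overrides applied."""
    if isinstance(g, str):
        g = get_genotype(g)
    valid = set(p.as_dict())
    for k in list(g.scale) + list(g.set):
        if k not in valid:
            raise KeyError(f"genotype {g.name!r} overrides unknown key {k!r}")
    out = {}
    for k, v in g.scale.items():
        out[k] = getattr(p, k) * v
    for k, v in g.set.items():
        out[k] = v
    return p.copy(**out)
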