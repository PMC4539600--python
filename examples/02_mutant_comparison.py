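"""Wild type against the pls mutant: hormone levels and auxin flux.

Losing the POLARIS peptide de-represses downstream ethylene signalling (X),
which throttles auxin loading at the shoot boundary.  Root auxin falls,
which in turn de-represses cytokinin biosynthesis; ethylene is unchanged.
"""
from rootcrosstalk import (Simulator, SolverSettings, apply_genotype,
                           build_root_map, default_parameters, default_spec,
                           fold_change, total_rootward_flux)

rmap = build_root_map(default_spec(spacing=4.0))
runs = {}
for g in ("wt", "pls"):
    p = apply_genotype(default_parameters(), g)
    runs[g] = Simulator(rmap, p, SolverSettings()).steady_state()

for sp in ("auxin", "ck", "et", "pin_protein"):
    f = fold_change(runs["pls"], runs["wt"], sp)
    print(f"{sp:12s} pls/wt fold change = {f:.2f}")
print("expected: auxin below 1, cytokinin near 1.9, ethylene near 1.0,")
print("PIN protein above 1")
for g, res in runs.items():
    print(f"net rootward auxin flux {g:4s}: "
          f"{total_rootward_flux(res.ledger):8.1f} uM um^2/s")
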