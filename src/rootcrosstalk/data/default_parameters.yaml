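# Default kinetic/transport parameter overrides.
#
# The full table with one entry per constant lives in
# rootcrosstalk.params.KineticParameters; this file records the
# literature-anchored values explicitly (they equal the coded defaults) and
# is the place to override any constant by name.  Units: uM, s, um.
#
# Literature-anchored values:
D_auxin: 220.0        # auxin diffusion coefficient, um^2/s (Rutschow et al.)
P_pin: 4.0            # PIN efflux permeability, um/s, within 0.5-5 (Kramer et al.)
P_aux1: 1.8           # AUX1 influx permeability, um/s, within 1.5 +/- 0.3 (Rutschow et al.)
# Receptor/CTR1 cascade rates follow mass-action forms in the style of
# Diaz & Alvarez-Buylla; remaining constants are fitted (docs/methods.md).
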