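"""POLARIS expression patterning and the auxin-regulation ablation.

Wild-type PLS protein peaks near the distal tip (auxin-induced) and
declines shootwards.  Removing the auxin (Ra*) dependence of PLS
transcription - a model experiment, not a plant line - flattens the
profile: the distal maximum disappears.
"""
import numpy as np

from rootcrosstalk import (Simulator, SolverSettings, apply_genotype,
                           build_root_map, default_parameters, default_spec,
                           longitudinal_profile)

rmap = build_root_map(default_spec(spacing=4.0))
for g in ("wt", "pls_no_auxin_regulation"):
    p = apply_genotype(default_parameters(), g)
    res = Simulator(rmap, p, SolverSettings()).steady_state()
    prof = longitudinal_profile(res, "plsp", mode="tier")
    n = len(prof.values)
    distal = prof.values[:n // 3].mean()
    proximal = prof.values[-n // 3:].mean()
    argmax = prof.positions[np.argmax(prof.values)]
    print(f"{g:25s} distal/proximal ratio = {distal / proximal:.2f}, "
          f"argmax at tier {argmax:.0f} of {n}")
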