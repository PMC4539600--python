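# Model and methods

`rootcrosstalk` simulates the steady-state levels and spatial patterning of
auxin, ethylene (ET) and cytokinin (CK), of the POLARIS (PLS) peptide, and
of the PIN and AUX1 auxin carriers in a two-dimensional multicellular model
of the *Arabidopsis thaliana* root tip.

## Spatial substrate

The root is a rectangle of square finite-volume elements (default
2 µm × 2 µm; all batch analyses in this package run at the reduced 4 µm
resolution). Each grid point is cytosol or wall; the wall layer is one
point thick and represents the merged cell wall + plasma membrane (the two
are deliberately not distinguished). Cells tile the rectangle in mirrored
files (epidermis, a cortex-like outer file, pericycle/border, vasculature,
from the outside in) and longitudinal tiers: a columella cap and a
quiescent-centre (QC) tier at the distal tip, meristematic-zone (MZ) cells
of constant 8 µm length, then elongation-zone (EZ) cells whose lengths ramp
from 12 µm to 68 µm shootwards. The default root is 1000 µm long and
216 µm wide (108 µm per side = 24 + 24 + 16 + 44), chosen so that every
cell dimension divides both the 2 µm and the 4 µm grid. Exact tissue
dimensions are not constrained by data and are fully configurable
(`GridSpec`).

The proximal (shoot-side) edge is the only open boundary: auxin is loaded
into the pericycle and vascular files at a rate repressed by the local
downstream ethylene signal X, auxin is unloaded from the epidermal files,
and ET/CK exchange diffusively with fixed shoot-side reference pools. All
other edges are closed.

## Species and reactions

Sixteen species live on the grid. Hormones (auxin, ET, CK) diffuse in
cytosol and wall; ET and CK additionally cross membranes diffusively, while
auxin crosses only through carriers. mRNAs, proteins, receptors and X
diffuse within the cytosol of their own cell only. PIN and AUX1 protein
each have an extra membrane-bound pool stored per membrane face.

Kinetics are mass-action for receptor inter-conversions, Michaelis–Menten
(Hill coefficient 1) for activations, and saturating `1/(1+c/K)` factors
for repressions (with a residual floor where a repression must not shut a
process off completely):

* **auxin**: synthesis = basal + X-activated, multiplied by a saturating CK
  inhibition (Nordström-type; a Jones-type activating variant is available
  via `ck_auxin_mode="jones"` and yields qualitatively similar behaviour);
  first-order decay.
* **CK**: synthesis restricted to the vascular and pericycle files,
  inhibited by auxin; first-order decay. The restriction is required to
  make central CK exceed epidermal CK.
* **ET**: basal synthesis plus a small synergistic term activated by auxin
  and CK together; independent of PLS, so the *pls* mutant leaves ET
  essentially unchanged.
* **receptor cascade**: auxin activates Ra→Ra*; ethylene binding
  deactivates the active ethylene receptor Re* (ETR1) while PLS protein
  promotes the active pool; Re* activates CTR1→CTR1*, which represses
  production of the lumped downstream signal X. Each pair conserves its
  total.
* **PLS**: transcription induced by Ra* and weakly repressed by X;
  translation and first-order decays. The *pls* genotype zeroes functional
  PLS production; PLSox adds a constitutive transcription term; an ablation
  switch replaces the Ra* factor with a constant (a model experiment used
  to show that auxin regulation creates the distal PLS maximum).
* **PIN**: transcription promoted by Ra* and X, repressed by CK;
  translation into a cytosolic pool that exchanges with the membrane pool
  by recycling.
* **AUX1**: transcription promoted by X; same recycling structure.

Carrier recycling is conservative first-order exchange: exocytosis
distributes cytosolic protein uniformly over the faces allowed by the
cell's polarity pattern; endocytosis returns it, for PIN at a rate
inhibited by wall-side auxin (auxin stabilizes PIN at the membrane).
Membrane pools therefore dominate at steady state
(`k_exo/k_endo = 5` before auxin stabilization).

PIN polarity is prescribed per cell type — vascular/pericycle rootward,
epidermis and outer file shootward, columella/QC lateral-outward — closing
the tip reflux loop; only the *amounts* on those faces are dynamic.
Carrier permeabilities scale linearly with local membrane abundance up to a
cap (`carrier_cap`), normalized so the reference abundance of 1 µM gives
the nominal permeability; the cap prevents runaway auxin→PIN→efflux
feedback.

## Parameters

Literature-anchored values: auxin diffusion 220 µm²/s; PIN efflux
permeability within 0.5–5 µm/s (4 µm/s used); AUX1 influx permeability
1.5 ± 0.3 µm/s (1.8 used, keeping effective influx at least the efflux so
no cell is depleted of auxin). All other constants are fitting parameters,
calibrated once against the model-fitting criteria — wild-type auxin
maximum at/near the QC, predominantly membrane-localized carriers, central
CK above epidermal CK, proximally increasing ET — and the wild-type/mutant
trend set, then frozen as the defaults in `params.py` (annotated copies in
`data/default_parameters.yaml`). Three calibration choices carry most of
the patterning behaviour and are worth knowing about:

1. **Ethylene decay length ≈ root length** (`d_et = 2e-3` s⁻¹,
   `D_et = 300` µm²/s, shoot reference 3 µM): shoot-supplied ET falls off
   over ~400 µm, so X rises proximally even deep in the meristem. This
   gradient, amplified by PLS suppression of X near the tip, is what makes
   wild-type PIN increase shootwards.
2. **`K_x_pin` sits between the wild-type and *pls* levels of X**
   (0.08 µM vs. ~0.1 and ~0.34): the PIN X-factor is sensitive in wild
   type but saturated in *pls*, so in *pls* the PIN profile follows the
   auxin maximum instead and the tier trend reverses sign.
3. **The etr1 binding-rate factor (0.055) places X(*pls etr1*) just below
   X(wild type)**: shoot auxin loading in the double mutant is then
   slightly above wild type (the flux ordering) while the loss of
   X-activated auxin synthesis keeps its mean auxin at or just below wild
   type (the concentration ordering). Both orderings are knife-edge in the
   data as well ("approximately recovers to wild type").

Genotypes are parameter-override sets: *pls* (functional PLS production
zero), *etr1* (ET-binding rate × 0.055, i.e. constitutive receptor
signalling), *pls etr1* (both), PLSox (constitutive transcription term
2.4e-3 µM/s), *aux1* (P_AUX1 × 0.5, other LAX influx carriers remaining),
plus the PLS auxin-regulation ablation.

## Numerics

Each grid point is a finite-volume element with one discrete mass-balance
equation per species. Steady states are reached by implicit pseudo-time
stepping with a geometrically growing step (5 s → 2000 s): every step
solves the nonlinear balance by Picard iteration to a relative tolerance of
1e-5, and the linear systems are solved by preconditioned Krylov iteration
to 1e-10. Diffusion, first-order losses, carrier-crossing losses, boundary
losses and the receptor inter-conversions are implicit; reaction sources,
carrier abundances and recycling returns are lagged to the previous Picard
iterate. The receptor pairs are solved through their conserved totals
(which obey pure intracellular diffusion) with the active form fully
implicit — lagging one member of a fast flip-flop against the other stalls
the fixed point at large steps.

The diffusive part of every system is symmetric positive definite, and a
Jacobi-preconditioned conjugate-gradient path is available
(`preconditioner="jacobi"`) and test-verified. The default path factorizes
each species' matrix once per pseudo-time step and reuses the factorization
as the preconditioner across Picard sweeps; because the reused
preconditioner is not symmetric with respect to the current matrix, BiCGStab
is used there (and always for auxin, whose carrier-crossing terms are
one-sided). Stationarity is declared when every pool's relative rate of
change falls below 1e-9 s⁻¹ (with a 1e-6 µM concentration floor so that
knocked-out, exponentially emptying pools terminate). Results are
insensitive to halving both tolerances (<0.1%), bit-identical across
repeat runs (no stochastic components), and agree with a long
explicit-Euler integration of the same right-hand side on a two-cell
fixture to far better than 0.1% — the explicit integrator (`integrate`) is
kept as a first-class verification path. Implicit updates are M-matrix
solves of nonnegative right-hand sides, so concentrations stay nonnegative
(tiny Krylov undershoots are clipped at zero).

Initial conditions are deterministic: hormones at 0.1 µM, receptor pairs
all-inactive at their 1 µM totals, everything else at 0.01 µM.

## Problem sizes

Default analyses (the genotype batch, the acceptance script, the examples)
run the full 1000 µm × 216 µm geometry at 4 µm spacing (13,805 grid
points, ~40 pseudo-time steps, tens of seconds per genotype). The 2 µm
grid is available through `default_spec(spacing=2.0)` and changes
region-averaged steady concentrations only within a few percent (grid
refinement on small fixtures is part of the test suite's cross-checks).
Unit and oracle tests use miniature roots (two to a few dozen cells) with
rescaled "fast" kinetics so explicit integration converges in seconds;
those rescaled parameter sets alter time scales, not model structure.

## What passing tests do and do not show

The synthetic study conditions reproduce *trends*: orderings between
genotypes, profile monotonicity, extremum locations, and one fold change
(whole-root CK in *pls* ≈ 1.7–1.9× wild type). Absolute concentrations are
not calibrated to measurements, experimental response profiles (GUS/GFP
intensities) are only trend references — the shipped reference curves are
synthetic idealizations, clearly labelled as such — and several known
discrepancies of this model class are inherited by design: modelled CK
*increases* shootwards (opposite to ARR5::GUS imaging), EZ auxin does not
match DII-VENUS imaging, and there is no lateral root cap, no growth, and
no 3-D tissue structure.

## Known limitations

* The trend orderings for *pls etr1* are intrinsically knife-edge (a few
  percent); they hold at the shipped defaults and the 4 µm grid but are not
  robust to arbitrary parameter perturbations — matching the biology, where
  the double mutant "approximately recovers" wild type.
* The whole-root CK fold change computes to ≈1.73 at the shipped defaults;
  pushing it closer to 1.9 destabilized the PIN patterning reversal, and
  the experimental median across CK species is itself 1.42.
* PIN1/PIN2 are lumped into a single PIN species; PIN3/PIN7 effects are
  assumed to cancel.
* Shoot-side reference concentrations stand in for the unmodelled shoot.
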