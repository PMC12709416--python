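# Methods

## The model

`slabsim` implements a one-bead-per-residue implicit-solvent model for
intrinsically disordered proteins, of the CALVADOS/HPS family. Each amino
acid is a single bead carrying a diameter σ (nm), a stickiness λ ∈ [0, 1],
a charge q (e), and a mass (g/mol). The potential energy has three terms:

- **Bonded.** Consecutive beads in a chain interact through a harmonic
  spring, U(r) = k/2 (r − l)², with k = 8368 kJ mol⁻¹ nm⁻² and
  l = 0.38 nm. Bonded pairs are excluded from the nonbonded sums.
- **Ashbaugh–Hatch.** All other pairs within r ≤ 2.0 nm interact through a
  Lennard-Jones potential (ε = 0.8368 kJ/mol) whose attractive branch is
  scaled by the pair stickiness: for r ≤ 2^{1/6}σᵢⱼ the energy is
  U_LJ + ε(1 − λᵢⱼ) (a λ-independent repulsive core), and beyond the
  minimum it is λᵢⱼ·U_LJ. Pair parameters combine by arithmetic mean.
- **Debye–Hückel.** Charged pairs interact through a screened Coulomb term
  f·qᵢqⱼ/(ε_r·r)·exp(−r/λ_D) with screening length λ_D = 1 nm, relative
  dielectric ε_r = 80 (physiological conditions), truncated at 4.0 nm. The
  molar Coulomb conversion constant f = 138.935 kJ mol⁻¹ nm e⁻² makes the
  expression dimensionally consistent in these units.

Both nonbonded terms are plainly truncated by default, following the
printed form of the model; a `shift_at_cutoff` option subtracts the cutoff
value for energy-conservation studies. Distances use the minimum-image
convention in orthorhombic boxes; the slab direction is the longest axis,
labeled z.

The packaged default parameter table carries the published CALVADOS2
σ/λ/charge/mass values (provenance label `"CALVADOS2"`). All quantitative
tests run on synthetic tables from `slabsim.synth`, so no result in the
test suite depends on the packaged file.

### Dynamics

Langevin dynamics uses a BAOAB splitting, chosen for its accurate
configurational sampling at the model's standard 10 fs timestep. The
friction coefficient is a thermostat parameter, not part of the physical
model (the model family does not prescribe one): the package default is
0.01 ps⁻¹ per bead for fast diffusive sampling; slab production runs in
`slabsim.studies` use 0.1 ps⁻¹ so the thermostat can absorb the potential
energy released during condensation, and thermostat-accuracy checks use
1.0 ps⁻¹, where the velocity autocorrelation is short enough for tight
statistics over 10⁶ steps. Integration is JIT-compiled (numba); a run
diverging to non-finite coordinates, or reaching a bead-bead separation
below the 10⁻³ nm positivity floor, aborts with the step index.

Randomly packed starting structures are relaxed by displacement-capped
steepest descent (cap 0.02 nm/iteration, stop at max force 10³ kJ/mol/nm)
before dynamics.

### Topology construction

Charges are assigned from the table; His defaults to 0 e (the model's
physiological-pH convention here; configurable) and termini default to
+1 e on the first and −1 e on the last bead of each chain (standard for
this model family; configurable). A single-residue chain carries both
terminal charges.

## Density and coexistence analysis

`z_density_profile` bins bead mass along z (default 1 nm bins) and converts
to mg/mL. Frames are first centered: the densest coarse bin provides a
provisional slab center, refined by the mass-weighted circular mean of
beads within a quarter box — this resolves slabs wrapped across the
periodic boundary. The SEM comes from block averaging over five equal
trajectory blocks. `radial_density_profile` is the shell-volume-normalized
analogue around the system's center of mass (default 1 nm = 10 Å bins).

`coexistence_densities` locates the dense region as the contiguous stretch
around the profile maximum above the midpoint of the extreme values, then
averages plateaus while excluding a 2 nm buffer on each side of each
interface (the interface-window width is not prescribed by the model
family; the buffer is configurable and recorded in the output metadata).
A profile whose max/min ratio falls below 2 is flagged as not phase
separated, with both densities set to the profile mean.

`fit_critical_point` fits the order parameter Δρ = ρ_h − ρ_l to
B(1 − T/T_c)^β with β fixed at 0.325 (3D Ising) by nonlinear least squares
with T_c bounded above the highest fitted temperature, then fits the
rectilinear diameter (ρ_h + ρ_l)/2 = ρ_c + C(T_c − T) linearly with T_c
held fixed. Temperatures flagged "no interface" are excluded. Tight solver
tolerances (1e−15) make noiseless round-trips exact to ~1e−10 relative.

## Contact analysis

`interchain_contact_map` marks a residue pair as in contact when its
distance (minimum over constituent particles, for multi-particle residues)
falls below the cutoff: per-pair 2^{1/6}σᵢⱼ under the `calvados` rule, or a
fixed distance (`6 Å` and `4.5 Å` are the conventional choices at
near-atomic and atomistic resolution). Contacts are averaged over all
ordered inter-chain pairs, then over frames; homotypic maps are
symmetrized and report the ordered pair count excluding self-pairs.
Reductions: 1D profiles (mean over the other axis), region blocks (mean of
the submatrix; overlapping or out-of-range regions are rejected), and
20×20 residue-type maps (sum over position pairs of each type combination,
optionally normalized by the number of such pairs; absent pairs are NaN,
never divided by zero).

`lambda_contact_correlation` computes the Pearson correlation between
normalized type-pair contact probabilities and a pair-stickiness score over
type pairs present in the sequences. The score defaults to the model's own
combination rule (λᵢ + λⱼ)/2; the alternative literal product form λᵢλⱼ/2
is available via `score="product_half"` and recorded in metadata — the two
orderings differ, so the choice is never silent.

## Interaction geometry

Detector thresholds (distances in nm, angles as cosines):

| interaction | gates |
|---|---|
| cation-π | \|N − ring COM\| < 0.6 and \|cos∠(N−COM, ring normal)\| > 0.8 |
| sp2-π | COM distance < 0.8, \|cos∠(normals)\| > 0.8, and < 0.4 between COMs elevated 0.15 along their normals |
| H-bond | D···A ≤ 0.35 and ∠(D–H···A) ≥ 150° |

Design choices where the criteria leave freedom: the "charged nitrogen" of
Arg is any of NH1/NH2/NE (charge is delocalized over the guanidinium; Lys
uses NZ; atom lists configurable); the sp2-π elevation displaces each plane
toward the other's COM (detecting stacked geometry; a fixed-normal variant
is exposed); plane-normal cosines are compared in absolute value because a
best-fit normal has no intrinsic sign; the H-bond criteria are the standard
MD geometric definition, with a heavy-atom-only fallback for structures
without hydrogens. The Tyr π group is the six phenol-ring carbons; the
guanidinium plane is CZ/NE/NH1/NH2; the H-bond acceptor is the Tyr backbone
carbonyl O. Percentages count (frame, pair) observations; the hydrogen-bond
percentage is conditional on the pair already forming the cation-π contact
and is undefined (NaN, flagged) when no such contact occurs.

Ion partitioning: each bin with net protein charge concentration
Δ = c⁺ − c⁻ (mM) in bulk salt c₀ satisfies local electroneutrality and a
fixed activity product, giving anion = (Δ + √(Δ² + 4c₀²))/2 and
cation = c₀²/anion; mobile-anion excess therefore tracks the sign of the
protein's net charge.

## Synthetic data

Every analysis stage has a generator with known ground truth, all
seed-deterministic:

- **Homopolymers** — single-letter chains with a complete 20-entry table so
  downstream type-maps work unchanged; fixtures carry their own tables.
- **Coexistence curves** — the scaling law inverted, with optional
  multiplicative noise; draws producing a negative dilute branch are
  rejected.
- **Slab trajectories** — bead counts per fine z-bin follow the target
  two-plateau (optionally sigmoidal-interface) profile using cumulative
  rounding, which keeps plateau averages at their targets even below one
  expected bead per bin.
- **Contact trajectories** — per frame, each residue of chain B draws a
  partner in chain A from the categorical distribution given by its column
  of the target matrix, and is placed inside that partner's cutoff and
  outside all others'. Marginal contact probabilities are then exactly
  p_ij. Fully independent per-pair draws are not realizable as 3D geometry
  for arbitrary matrices (one bead cannot sit within the cutoff of two
  well-separated partners at once), so matrices must have column sums ≤ 1;
  the all-ones matrix is realized exactly by co-location.
- **π-geometry fixtures** — ideal hexagonal rings, guanidinium planes and
  donor/H/acceptor triples at stated separations/tilts/offsets, labeled by
  closed-form geometry; plus a scripted multi-frame Arg(Lys)/Tyr system
  with exact per-frame interaction status for the conditional statistic.

What the generators do *not* emulate: real force-field trajectories,
sequence-specific conformational ensembles, solvent and ion dynamics, or
finite sampling correlations of MD data. Passing tests therefore
demonstrate the correctness of the analysis operations and the internal
consistency of the simulation engine at desk scale — not the accuracy of
the physical model for any real protein.

## Desk-scale study protocols

`slabsim.studies` fixes the package's small-system conditions: 10 chains ×
50 beads in an 8 × 8 × 24 nm slab, 40 000–60 000 steps at 10 fs, friction
0.1 ps⁻¹, analysis on the second half of each run. These sizes were chosen
as the largest runs that keep the full phase-behavior study in the minutes
range on one CPU; the model's full-scale protocol (100 chains,
20 × 20 × 280 nm, 10 μs) uses the same code path and is documented as a
cluster-sized computation.

Two protocols differ in initialization:

- **Condensation** (random start): sticky chains (λ = 1.0) collapse into a
  dense cluster; nearly athermal chains (λ = 0.1) stay a dispersed coil
  gas. The diagnostic is `peak_local_density_ratio`: the peak density of
  *other-chain* beads within a 2 nm sphere, relative to the box mean of
  other-chain beads, median over the last five saved frames. Excluding
  same-chain beads prevents a single collapsed coil from registering as a
  dense phase; sticky systems reach ratios above 10, dispersed systems
  stay near 3.
- **Evaporation** (slab start): chains begin confined to the central
  quarter of the box, and the dilute phase fills by escape. This
  approaches coexistence from below and preserves the physical
  monotonicity of the dilute-phase density in temperature even on runs too
  short for full equilibration — with a random start, slow cluster-capture
  kinetics at low temperature can invert the apparent trend. The
  temperature scan uses λ = 0.7 with 20 chains of 25 beads between 260 and
  320 K: at fixed bead count, more and shorter chains shrink the per-chain
  density quantum of the dilute phase (a single escaped 50-mer already
  reads as ~13 mg/mL), which keeps the trend resolvable at desk scale.

## Numerical notes and limitations

- Plain truncation makes the energy discontinuous at the cutoffs; force vs.
  numerical-gradient checks therefore avoid configurations with pair
  distances within 10⁻³ nm of a cutoff.
- Energies and forces are all-pairs O(N²) kernels — appropriate for
  desk-scale systems (≤ ~10³ beads); no cell list is implemented.
- Kinetic temperature counts 3N degrees of freedom (the Langevin thermostat
  acts on all of them; no COM-motion removal).
- The bonded-dimer equipartition check targets k_B·T/2 = 1.247 kJ/mol at
  300 K for the radial bond mode; the Jacobian of the radial coordinate
  shifts the true mean upward by ~0.01 kJ/mol at this stiffness, well
  inside the test tolerance.
- The critical-point fit performs no finite-size-scaling correction, and β
  is never fitted.
- The coexistence analysis assumes a single dominant dense region; systems
  with several long-lived clusters (common early in condensation) bias ρ_h
  downward and ρ_l upward.
- FFR region boundaries: the working definition is residues 773–944 (the
  simulated and purified construct); the alternative 773–945 found in part
  of the literature ships as region `"FFR_945"`.
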