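# slabsim

Residue-level coarse-grained slab simulations and condensate analysis for
disordered-protein phase separation.

Many scaffold proteins of membraneless organelles — such as MUT-16, which
builds the Mutator foci that drive RNA silencing in *C. elegans* — phase
separate through their intrinsically disordered regions and recruit client
proteins (MUT-8) through specific residue contacts. `slabsim` provides the
computational pipeline for studying this at desk scale, for structural
bioinformaticians and molecular modelers:

- a **one-bead-per-residue implicit-solvent model** (harmonic bonds,
  Ashbaugh–Hatch stickiness-scaled Lennard-Jones with per-residue λ,
  Debye–Hückel electrostatics with λ_D = 1 nm and ε_r = 80) integrated by
  BAOAB Langevin dynamics in periodic slab geometry, with the published
  CALVADOS2 parameter set packaged as the default table;
- **phase analysis**: z/radial density profiles, dense/dilute coexistence
  densities, and critical-point fits Δρ = B(1 − T/T_c)^β (β = 0.325) with
  the rectilinear-diameter law for ρ_c;
- **contact statistics**: inter-chain contact maps under a pair-specific
  2^{1/6}σᵢⱼ or fixed-distance cutoff, 1D/region/residue-type reductions,
  and the contact-vs-stickiness Pearson correlation;
- **interaction geometry**: cation-π, sp2-π, and hydrogen-bond detectors
  with the standard distance/cosine gates, conditional percentage
  statistics, and Donnan-style ion-partitioning prediction;
- **synthetic data** with known ground truth for every stage, so the whole
  pipeline is testable without downloads.

## Worked example

Fit a critical point from a noisy synthetic coexistence curve
(`examples/03_critical_point_fit.py`):

```python
import numpy as np
from slabsim import fit_critical_point
from slabsim.synth import gen_coexistence_data

temps = np.linspace(240.0, 293.0, 10)
noisy = gen_coexistence_data(Tc=296.0, B=900.0, rho_c=310.0, C=2.5,
                             temps=temps, noise_rel=0.02, seed=1)
fit = fit_critical_point(noisy)
print(fit.Tc, fit.B, fit.rho_c, fit.C)
```

Output:

```
noiseless: Tc =  296.00 K  B =  900.0  rho_c =  310.0  C =  2.50
2% noise : Tc =  295.77 K  B =  898.3  rho_c =  309.1  C =  2.54
truth    : Tc =  296.00 K  B =  900.0  rho_c =  310.0  C =  2.50
```

The noiseless fit inverts the generating law to machine precision; with 2%
multiplicative noise on the branch densities, the fitted critical
temperature lands within ~1 K of the truth. The other scripts in
`examples/` walk through sequence composition, homopolymer condensation,
contact maps, the interaction detectors, and ion partitioning, each
printing the numbers it computes and what they mean.

A thin CLI wraps the same stages for shell use:

```sh
slabsim synth --kind coexistence --seed 7 --out out/
slabsim phasediag --curve out/coexistence.tsv --out fit/
slabsim simulate --n-chains 10 --n-res 50 --lam 1.0 --n-steps 40000 --out sim/
```

Every run writes a `manifest.json` with the configuration, seed, package
version, and input checksums.

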