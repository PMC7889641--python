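# cgphase

Residue-level coarse-grained simulation and analysis of salt-dependent
protein liquid–liquid phase separation (LLPS).

Many proteins that form biomolecular condensates at low salt (FUS being
the canonical example) re-enter a phase-separated state at molar salt,
where electrostatics are screened out and hydrophobic/non-ionic
interactions dominate.  `cgphase` provides a tested, reusable pipeline
for studying this reentrant behaviour in silico at one bead per amino
acid:

* a hydrophobicity-scale (HPS-style) force field — Ashbaugh–Hatch pair
  term Φ(r) = LJ(r) + (1−λij)ε for r ≤ 2^{1/6}σij, λij·LJ(r) beyond,
  with λij = h·(λi+λj)/2 — plus Debye–Hückel screened electrostatics
  scaled by a salt-regime parameter χ and an optional cation–π well on
  {R,K}×{F,W,Y} pairs;
* salt-regime presets: low (χ=4, cation–π on), moderate (χ=2), high
  (χ=1 with the hydrophobic term raised 10% for FUS-like sequences or
  30% for Arg–Pro repeat peptides);
* BAOAB Langevin dynamics and direct-coexistence slab simulations in
  elongated periodic boxes;
* slab analysis: recentred axial density profiles, double-tanh
  coexistence densities, LLPS classification (dense/dilute ratio ≥ 10),
  and critical-point fits Δρ = A(1−T/Tc)^0.325 with the law of
  rectilinear diameters and bootstrap confidence intervals;
* WHAM reconstruction of pair potentials of mean force from umbrella
  windows, with Bayesian-bootstrap error bands and well-depth
  extraction;
* condensate metrics: inter-chain contact maps (0.65 nm cutoff) and
  droplet morphology (area, perimeter, circularity = 4πA/P²);
* synthetic-data generators for every analysis: salt-trend toy pair
  potentials, Metropolis umbrella samplers, critical-scaling
  coexistence curves, labeled droplet masks, and the study sequences
  (PR25 = 13 Arg / 12 Pro alternating, FUS domains from a user FASTA).

## Worked example

Classify the salt-regime phase behaviour of a reduced Arg–Pro repeat
system (20 PR25 peptides, 500 beads) at low and high salt:

```python
import cgphase as cg
from cgphase.dynamics import run_direct_coexistence
from cgphase.slab import density_profile, coexistence_densities, classify_llps

params = cg.load_residue_params()
topo = cg.build_topology(cg.make_sequence("PR25"), name="PR25")

for regime in ("low", "high"):
    trajs = run_direct_coexistence(
        topo, 20, params, regime, [140.0], protein_class="pr_like",
        n_steps=80_000, thin=2_500, slab_fraction=0.35,
        slab_density_mg_ml=350.0, friction_time_ps=50.0, rng_seed=1,
    )
    prof = density_profile(trajs[140.0], equil_fraction=0.6, n_bins=40)
    pt = coexistence_densities(prof, 140.0)
    print(f"{regime}: rho_dilute={pt.rho_dilute:.1f} mg/mL, "
          f"rho_dense={pt.rho_dense:.1f} mg/mL, llps={classify_llps(pt)}")
```

Output (about two minutes on one CPU):

```
low: rho_dilute=119.4 mg/mL, rho_dense=128.2 mg/mL, llps=False
high: rho_dilute=0.0 mg/mL, rho_dense=755.1 mg/mL, llps=True
```

At low salt the χ=4 Coulomb repulsion between the 13 arginines
disperses the initial slab into a nearly uniform solution
(dense/dilute ratio ≈ 1, no LLPS); at high salt the screened charges
plus the 30% hydrophobic boost hold a ~755 mg/mL condensate against an
essentially empty dilute phase.

The same machinery exposes a CLI (`cgphase simulate`, `analyze-slab`,
`fit-critical`, `phase-scan`, `wham`, `contacts`, `droplets`,
`synth ...`); see `cgphase --help`.

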