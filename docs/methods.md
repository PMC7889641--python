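# Methods

`cgphase` simulates and analyses salt-dependent liquid–liquid phase
separation (LLPS) of proteins with a residue-level coarse-grained model,
and provides the analysis layer that normally accompanies such studies:
direct-coexistence density profiles, critical-point fits, weighted-
histogram (WHAM) reconstruction of pair potentials of mean force, contact
statistics and droplet morphology.  This note records the model, its
parameters, the numerical choices, and what the reduced desk-scale study
conditions do and do not demonstrate.

## Units

Lengths nm, energies kJ/mol, masses Da, times ps, charges in elementary
units, temperatures K.  kB = R/1000 = 8.31446×10⁻³ kJ mol⁻¹ K⁻¹; the
Coulomb prefactor e²N_A/(4πε₀) = 138.935 kJ nm mol⁻¹.

## The energy model

One bead per residue.  Each residue carries mass, signed charge (Arg and
Lys +1, Asp and Glu −1, His neutral by default with a +1 switch), a bead
diameter σ and a hydrophobicity λ ∈ [0, 1] from the bundled
Kapcha–Rossky-derived hydrophobicity-scale table (the standard parameter
set of this model family; the table ships as a TSV and is fully
replaceable by the user).

Nonbonded pair energy between beads i and j at distance r:

* **Ashbaugh–Hatch hydrophobic term.**  With LJ(r) = 4ε[(σij/r)¹² −
  (σij/r)⁶], σij = (σi+σj)/2 and λij = h·(λi+λj)/2 (h is the regime's
  hydrophobic scale; each residue's λ is multiplied by 0.7 when it sits
  in a globular region, accounting for burial):

      Φ(r) = LJ(r) + (1 − λij)·ε   for r ≤ 2^{1/6} σij
      Φ(r) = λij·LJ(r)             otherwise

  so λij = 0 leaves a purely repulsive core and λij = 1 the full LJ
  well.  ε = 0.8368 kJ/mol (0.2 kcal/mol), the standard choice.
* **Screened electrostatics.**  χ·qiqj e²/(4πε₀εr r)·exp(−r/λD), with
  relative permittivity εr = 80 and Debye length λD.  χ is the
  salt-regime multiplier (below).  λD defaults to 1.0 nm in every
  regime: the salt dependence is carried by χ, not by λD, because
  Debye–Hückel theory is not meaningful at molar ionic strength — which
  is exactly why the regime mapping scales the Coulomb term instead.
  `debye_length(I, T, εr)` provides the physical κ⁻¹ for users who want
  it (0.793 nm at 0.15 M, 298 K, εr 80).
* **Cation–π enhancement.**  An extra Lennard-Jones well of depth
  `cation_pi_eps` at σij, applied only to {R,K}×{F,W,Y} pairs.  This
  stands in for the enhanced cation–aromatic attraction at low salt.
  The exact strength is not derivable from first principles at this
  resolution; it is a calibration knob (default 3.0 kJ/mol) chosen so
  that the low-salt regime of aromatic/arginine-bearing sequences
  phase-separates robustly in the reduced study systems.

All pair terms are truncated and shifted to zero at their cutoffs
(hydrophobic and cation–π at 2.0 nm; electrostatics at 3.5·λD capped at
3.5 nm and further reduced when the periodic box is too small for the
minimum-image convention).  Forces are the exact negative gradient of
the shifted energy; a finite-difference check to 10⁻⁵ relative accuracy
is part of the test suite.

Bonded terms: consecutive residues are joined by harmonic springs
(r₀ = 0.38 nm, k = 1000 kJ mol⁻¹ nm⁻², both configurable).  Globular
regions (annotated as 1-based inclusive ranges) additionally receive a
stiff elastic network: springs (k = 500 kJ mol⁻¹ nm⁻²) between region
residues within 0.9 nm of the bind-time configuration.  This
approximates rigid-body behaviour while keeping one integrator for the
whole chain; it preserves the energetic role of compact domains but not
their exact rigid kinematics.

## Salt regimes

The mapping from salt concentration to interaction scaling:

| regime   | χ | hydrophobic scale      | cation–π | Debye length |
|----------|---|------------------------|----------|--------------|
| low      | 4 | 1.0                    | on       | 1.0 nm       |
| moderate | 2 | 1.0                    | off      | 1.0 nm       |
| high     | 1 | 1.1 (FUS-like) / 1.3 (Arg–Pro repeat) | off (subsumed by the hydrophobic up-scaling) | 0.3 nm |

The χ = 4 reference makes electrostatics matter at low salt; χ = 2
approximates molar salt; χ = 1 plus a 10–30% hydrophobic increase
represents the >3 M salting-out regime.  The high-salt preset also
shortens the Debye length to a molar-regime 0.3 nm: the defining
physics of that regime is that electrostatics are screened out, and for
densely charged sequences (PR25 carries +13 per 25 residues) a χ = 1
Coulomb term with a dilute-regime screening length would instead leave
the residual arginine repulsion dominant and suppress the
experimentally observed high-salt condensation entirely.  All regime
fields remain configurable.

## Dynamics

BAOAB-split Langevin integration (exact Ornstein–Uhlenbeck substep),
chosen for its configurational accuracy at large time steps.  Default
dt = 10 fs and friction relaxation 5 ps; dt is validated against the
stiffest spring (dt ≤ 0.1·2π/ω_max).  Verlet pair lists (skin 0.3 nm,
one list for short-range terms, one over charged beads for
electrostatics) are rebuilt when any bead has moved half a skin;
center-of-mass momentum is re-zeroed at rebuilds.  Trajectories are
exactly reproducible for a fixed seed (single-threaded kernels).  An
instability detector aborts when any bead moves more than half the
smallest bead diameter in one step or the energy becomes non-finite.

Slab construction places chains as self-avoiding random walks inside
the central fraction of an elongated box (aspect 4:1), with inter-bead
separations above 0.7 of the smallest σ, followed by a capped
steepest-descent relaxation.  The slab is built directly at the target
dense density (350 mg/mL by default); a Berendsen weak-coupling
barostat (isotropic, compressibility 0.2 bar⁻¹ — deliberately large, as
only κ/τp sets the weak-coupling relaxation rate) is available as an
optional NPT pre-equilibration stage but is not needed on the direct
route.

## Slab analysis

Density profiles along the long axis are computed per frame after
recentring the dense slab: the mass-weighted circular mean of the axial
coordinate is shifted to the box center, which prevents interface
smearing from slab drift.  The profile integral equals the total system
mass identically.  Coexistence densities come from a symmetric
double-tanh fit; the reported values are plateau averages excluding
bins within 2.5 (dense side) and 4 (dilute side) interface widths of
the interfaces, with a central/outer-bin fallback when the fit fails
(flagged).  LLPS classification: dense/dilute ratio ≥ 10 (inclusive),
with a 10⁻³ mg/mL dilute floor.

Critical points: simultaneous least squares of Δρ = A(1 − T/Tc)^β with
the 3D Ising exponent β = 0.325 (fixed) and the law of rectilinear
diameters.  For fixed Tc both sub-fits are linear, so the optimisation
is one-dimensional in Tc (bounded scalar minimisation).  The Tc
confidence interval is a basic (reverse-percentile) bootstrap over
coexistence points; the basic interval was chosen over the raw
percentile interval because the Tc estimator is skewed and
bias-prone at small point counts, and the basic interval is the better
calibrated of the two there.

## WHAM

Standard self-consistent WHAM on a uniform grid (default 0.005 nm
spacing over the union of window supports), iterated in log space with
`scipy.special.logsumexp` until the window free energies change by less
than 10⁻⁷ kJ/mol (max 10⁵ iterations).  The first 10% of each window's
samples are dropped as equilibration.  Bins with fewer than 5 total
counts are masked (NaN): they carry no usable free-energy information
and would otherwise produce spurious minima at the support edges.  The
PMF is zeroed over the largest 10% of the grid.  No Jacobian/entropic
correction is applied to the 1-D coordinate (appropriate when lateral
motion is restrained, which is the convention the window format
assumes).  Non-overlapping window groups (islands) are detected and
rejected.  Errors: Bayesian bootstrap — whole windows reweighted by
flat Dirichlet weights, WHAM re-solved per replicate (default 200), the
band being the pointwise standard deviation.  `well_depth` reports
min − reference-mean; an optional search range confines the minimum to
the physical contact region, away from the noisier support edges.

## Synthetic generators

* **Toy pair potentials** encode only the *directional* salt trends of
  atomistic pair PMFs — they are deliberately not fits to any published
  curve.  U(r) = r⁻¹² core + screened Coulomb (physical Debye length
  for the given molarity) + Gaussian well whose depth grows linearly
  with salt (salting-out).  Classes: `charged_opposite` (attraction
  that screening removes; no salting-out term so the weakening is
  strictly monotone), `charged_like_pi` (Arg–Arg-like: repulsive at
  0 M, attractive by 3 M), `hydrophobic` (monotone deepening),
  `cation_pi_hybrid` (strong at both extremes, dip in between
  permitted).  Well magnitudes sit in the −2 to −14 kJ/mol regime.
* **Umbrella sampler**: 1-D Metropolis on a 4001-point piecewise-linear
  tabulation of the potential, default protocol 31 windows at 0.05 nm
  spacing from 0.1 to 1.6 nm with bias constant 6000 kJ mol⁻¹ nm⁻²,
  thinned ×10 after a 2000-step burn-in; step size 1.5·sqrt(kT/k_bias).
  Acceptance is monitored; zero acceptance raises.
* **Sequences**: the 25-mer Arg–Pro repeat (13 R / 12 P, Arg at both
  termini); the first 163 residues of a user-supplied full-length FUS
  FASTA; homopolymers; and `PLD_like`, a deterministic 100-residue
  prion-like-domain caricature used by the reduced phase scans (below).
* **Coexistence curves**: exact points on Δρ = A(1 − T/Tc)^β split
  around a linear rectilinear diameter, with optional multiplicative
  Gaussian noise — the oracle for the critical-point fit.
* **Droplet masks**: labeled rasters of disks with an optional smooth
  low-order Fourier boundary perturbation, with the analytic
  areas/circularities returned alongside.

## Condensate metrics

Contacts: beads on different chains within 0.65 nm (minimum image)
count as a contact; frequencies are per-frame averages on the
residue-pair level (symmetric, intra-chain excluded), coarsened to
domain blocks on request.  Periodic neighbour queries use a KD-tree.

Droplet morphology: per label, area = pixel count × pixel size²;
perimeter and the circularity numerator use the marching-squares
contour simplified by Douglas–Peucker (tolerance 1 px), which removes
the half-pixel staircase that inflates smooth perimeters by ~6% while
leaving true polygon corners untouched.  Calibration on analytic
shapes: rasterized disks of radius ≥ 10 px score 0.95–0.99 (dispersion
±0.02, the raster floor ε_raster of this estimator) and axis-aligned
squares score π/4 within 0.02.  Circularity is clipped at 1.

## Reduced (desk-scale) study conditions

The production-scale version of the salt-regime scan — hundreds of
chains, microseconds — is far beyond a single CPU.  The shipped scan
(`cgphase.studies`) therefore uses reduced systems chosen once:

* FUS-like: 10 chains of a 60-residue aromatic-rich, slightly
  net-positive sequence (the first 60 residues of `PLD_like`: a
  Tyr/Gly/Ser repeat carrying one Arg per 20 residues), scanned at
  330 K.  The net positive charge makes χ a genuinely repulsive lever,
  which is what separates the melting points of the moderate (χ = 2)
  and high (χ = 1 + 10%) conditions at this scale; with a
  charge-balanced sequence the two effects nearly cancel and the
  regimes are indistinguishable in desk-scale runs.
* PR25: 20 peptides at 140 K (its critical point sits far below the
  FUS-like one in this parameterization, mirroring the large critical-
  temperature separation of the two systems at production scale).
* Elongated boxes (aspect 4).  The FUS-like scan starts from a loose
  slab (250 mg/mL over 45% of the long axis): conditions that should
  not phase-separate then melt within the run instead of lingering in a
  metastable dense slab, while condensing conditions compact quickly.
  The PR25 scan starts from a regular dense slab (350 mg/mL over 35%):
  its non-condensing condition melts by outright Coulomb repulsion, and
  a loose start at 140 K would risk freezing multi-droplet
  configurations.
* 120 000 steps (80 000 for PR25) of 10 fs at a Langevin relaxation of
  50 ps.  The weak coupling accelerates configurational sampling (chain
  diffusion, slab evaporation) several-fold relative to the 5 ps
  production default without changing the sampled ensemble; the scan
  measures equilibrium densities, not transport.
* Scan temperatures sit between the melting points of the conditions
  that must and must not phase-separate, estimated from preliminary
  temperature ladders of the same reduced systems (the standard
  direct-coexistence practice of simulating just below the critical
  point).
* Each condition is a majority vote over 3 independent seeds;
  single-run calls are flagged low-confidence.  The moderate-salt
  FUS-like condition sits closest to its melting point and is the
  noisiest call at this scale.

What passing shows: the *sign structure* of the salt-regime mapping —
electrostatic melting at reduced χ, reentrance from a 10% hydrophobic
boost, charge-repulsion suppression of the Arg–Pro peptide at low salt
and its salting-out condensation at high salt — survives at reduced
scale.  What it does not show: quantitative coexistence densities,
critical temperatures or interface properties of any real protein; the
reduced chains are shorter, the boxes smaller and the runs orders of
magnitude briefer than production simulations, and finite-size noise in
the dilute phase is substantial.

## Known limitations

* Globular regions are elastic-network-restrained, not rigid bodies.
* No explicit ions or solvent; permittivity is temperature-independent.
* The 10–30% hydrophobic up-scaling is applied uniformly to every
  λij; per-pair masks are left to configuration.
* WHAM assumes decorrelated samples (no autocorrelation-aware effective
  sample sizes); the synthetic sampler thins accordingly.
* The droplet perimeter estimator's ±0.02 raster dispersion sets the
  resolution floor for circularity comparisons.
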