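# Methods

`membind` implements, at desk scale, the computational framework used to
study how the conformational state of a membrane-binding peptide segment
(the α-synuclein 65–97 region over a synaptic-like DOPE:DOPS:DOPC
bilayer) controls its membrane affinity. The framework has three
computational pillars — conformational restraint potentials, contact-
index melting-curve analysis, and umbrella-sampling/WHAM free energies —
plus a synthetic-data layer that replaces μs-scale coarse-grained MD
with generators and a toy Langevin engine whose ground truth is known
exactly, so every stage is verifiable.

## Conformational restraints

A peptide is a chain of backbone beads, one per residue. Two
conformational states are imposed through Gaussian restraints on the
angle θ of each consecutive bead triplet and the dihedral φ of each
consecutive quadruplet:

    V(x) = −K · exp(−(x − x_min)² / σ),   x ∈ {θ, φ} in degrees.

σ sits in the exponent un-squared and therefore carries units of
degrees² — this literal form is kept deliberately. The restraint is a
well of depth K, not a harmonic spring: far from the target geometry the
chain is free, which is what lets a "helical" chain melt rather than be
clamped.

Forces are fully analytic: F = −dV/dx · dx/dr, with dV/dx evaluated per
degree and the geometric gradients dθ/dr, dφ/dr in radians/nm (the
180/π conversion is applied once in the prefactor). The dihedral is the
standard four-quadrant atan2 construction (cis = 0°, trans = 180°,
mirror symmetry negates φ), and the dihedral deviation is wrapped into
(−180°, 180°] before squaring so the well is periodic with no cliff at
±180°. The arccos gradient is guarded at 1e-12 on its argument so
near-collinear geometries degrade gracefully instead of overflowing.

Numeric defaults (helical: θ_min = 96°, φ_min = −120°; extended:
θ_min = 127°, φ_min = 180°; K = 10 kJ/mol, σ = 200 deg² for both terms)
are documented placeholders: the original parameterisation lives in
prior work and is not reproduced here. Every entry point takes explicit
parameters; the defaults exist so examples run.

## Toy simulation engine

The engine is overdamped (Brownian) Euler–Maruyama dynamics,

    x(t+dt) = x(t) + F·dt/γ + √(2 kB T dt/γ) · N(0,1),

whose stationary law is the Boltzmann distribution of the potential.
That is the only property the engine must deliver — the study's
analyses are equilibrium averages — so inertia, thermostats and
barostats are deliberately absent. kB = 0.0083145 kJ/mol/K; coordinates
nm, energies kJ/mol, time ps; γ defaults to 1 kJ·ps/mol/nm².

The membrane is implicit: an attractive Gaussian well in z of depth
`well_depth_per_bead` and width `well_width` centred on the mean
phosphate plane, plus a static square lattice of explicit phosphate
beads on that plane so contact analysis consumes the same data model as
real trajectories. The box is periodic in xy and reflecting in z. The
well can couple to each bead (default) or to the chain's centre of
mass; the latter makes the COM z-marginal exactly Boltzmann in the well
potential, independent of the chain's internal interactions.

The inner loop is a numba kernel duplicating the force expressions; the
pure-numpy module is the reference and a test asserts agreement to
1e-10. Time steps must satisfy dt·k_max/γ ≲ 0.1 where k_max is the
stiffest curvature present (bonds, restraints, or well bottom
depth/width²); the tests use dt between 5e-5 and 1e-3 ps accordingly.
The Euler scheme inflates positional variance by ~dt·k/2γ, so
equilibrium checks keep that product below ~0.06.

## Contact analysis and melting curves

A residue is "in contact" in a frame if its backbone bead lies within
1 nm of the nearest phosphate bead (both leaflets included; xy distances
minimum-image, z plain — slab geometry). "Cα atoms" of the source
analysis map to backbone beads, one per residue. The per-residue contact
index is the fraction of frames in contact; the global contact index is
the unweighted mean over residues (per-residue first, then averaged —
identical to the frame-first order at equal frame counts). Frames are
weighted equally with no burn-in by default (a burn-in fraction is
configurable), matching an analysis of whole trajectories.

The melting curve is the global contact index versus the ladder
temperature (310–450 K in 10 K steps, 15 rungs, in the reference
protocol). The melting temperature is extracted by least squares as the
inflection point of a four-parameter logistic

    c(T) = c_low + (c_high − c_low) / (1 + exp((T − Tm)/w)),

with Tm constrained to the sampled range, initial values taken from the
data, and a low-confidence flag when the curve spans < 0.2 in global
index. The estimator is a deliberate design choice — the extraction
method is not specified in the source analysis; a logistic inflection
is standard melting-curve practice and comes with standard errors from
the fit covariance.

Convergence is assessed by splitting a run into consecutive equal
segments (default 3; remainder frames dropped from the end) and taking
the maximum absolute per-residue contact-index difference over segment
pairs.

## Umbrella sampling and WHAM

The reaction coordinate ξ is the peptide–bilayer COM distance. Windows
are harmonic, w_i(ξ) = k/2 (ξ−ξ_i)², k = 1000 kJ/mol/nm² by default
(the printed "1,000 kJ/mol" is read as kJ/mol/nm² by dimensional
necessity); the reference protocol uses 11 windows over a 1.2 nm path.
Histograms share one grid (default bin width 0.02 nm, which puts ≥2
bins per biased-sample standard deviation √(kBT/k) ≈ 0.05 nm at 300 K).
WHAM iterates

    p(b) = Σ_i n_i(b) / Σ_i N_i exp((F_i − w_i(b))/kBT)
    F_i  = −kBT ln Σ_b p(b) exp(−w_i(b)/kBT)

until max|ΔF_i| < tol·kBT (tol = 1e-7), with F_1 ≡ 0. Adjacent-window
overlap Σ_b min(p̂_i, p̂_{i+1}) is the sampling diagnostic: zero overlap
is an error naming the gap, < 0.05 a warning.

The PMF is G(ξ) = −kBT ln p(ξ), zeroed on the detached plateau (default:
the last 0.2 nm of the grid, overridable); empty bins stay NaN, never
interpolated. The binding free energy is the plateau mean minus the
bound-region minimum, reported positive-favourable in kcal/mol
(4.184 kJ/kcal). No Jacobian (2 kBT ln ξ) correction is applied to the
1-D distance coordinate — a known limitation, consistent with default
g_wham-style analysis. Uncertainty, when requested, comes from a
case-resampling bootstrap over each window's samples (default 50
resamples, seeded); an integrated-basin ΔG variant was considered and
left out in favour of the simpler minimum-to-plateau definition.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of their seeds and embed their ground
truth in each object's metadata.

- **Two-state Markov trajectories** emulate bound/unbound contact
  dynamics: each residue's z toggles between a bound height (< 1 nm
  above the plane) and an unbound height (> 1 nm) with per-frame rates
  chosen so the stationary occupancy is prescribed; k_on + k_off
  defaults to 0.5/frame, giving mild frame-to-frame correlation.
  Residues sit at fixed xy lattice positions directly above phosphate
  beads, so the contact criterion depends on z alone.
- **Melting ensembles** place a logistic occupancy law
  occ(T) = 1/(1+exp((T−Tm)/width)) on the ladder; width defaults to
  15 K, a slope comparable to the reference melting curves.
- **Umbrella windows** are drawn by inverse-CDF sampling (1e-4 nm grid)
  from exp(−(U+bias)/kBT) for analytic PMFs (harmonic, smoothed square
  well, double well, Morse-like). The draws are independent, so WHAM
  recovery error is purely statistical — deliberately more favourable
  than correlated MD samples.
- **Bilayer patches** reproduce the 167-lipid-per-leaflet,
  84:50:33 DOPE:DOPS:DOPC composition on a jittered lattice
  (~0.64 nm²/lipid); lipid identity affects labels only.
- **Peptide chains** are built bead-by-bead at exactly θ_min/φ_min
  (so the chain restraint energy is exactly its global minimum,
  −(n−2)K_θ − (n−3)K_φ) with the COM placed 4 nm above the plane.

None of this emulates lipid diffusion, realistic binding kinetics,
specific lipid chemistry, or the nonbonded energetics of a real
coarse-grained force field. Passing tests therefore demonstrate that the
*estimators and analysis machinery* are correct and well-calibrated,
not that the toy dynamics reproduce any particular membrane's physics.

## Problem sizes and verification design

The test-suite and acceptance runs use sizes chosen to give comfortable
statistical margins: 100 random geometries for force/finite-difference
agreement (< 1e-5 relative); ~1e5 saved samples for Boltzmann fidelity
(KS < 0.02 against the quadrature CDF; harmonic variance within 5% of
kBT/k); 1e4-frame trajectories for occupancy recovery (±0.02) with a
1e3/1e4/1e5 scaling check of the n^(−1/2) law; 2e4 frames per rung for
melting recovery (±2 K at midpoints 352/372/393/413 K); 2e4 samples per
window for WHAM (PMF RMSE < 0.3 kJ/mol on bins with ≥100 counts; well
depths 11 and 7.5 kcal/mol recovered within ±0.3, their difference
within 3.5 ± 0.4).

The end-to-end check (generate → simulate → contacts → melt) runs the
33-bead chain over the implicit membrane with internal interactions
switched off (bond_k = 0, no restraints). Each bead is then an
independent single-particle system whose contact probability is an
exact Boltzmann integral — a 1-D z-quadrature times the xy unit-cell
contact fraction of the phosphate lattice — so the reference melting
curve is computed to quadrature accuracy and fitted with the same
logistic estimator as the simulation. A non-cooperative single-bead
binder melts over a far wider temperature interval than a 33-residue
cooperative binder (its transition width is set by ln of a 1-D volume
ratio, which is small), so this check uses a wide 100–800 K ladder on
which both plateaus of the curve are visible and the logistic midpoint
is well conditioned. Bonded/restrained chain physics is verified
separately (equipartition, Boltzmann fidelity, restraint-effect and
kernel-consistency tests); melting of a sharp, cooperative two-state
system is covered by the Markov-ensemble recovery tests, where the
midpoint is prescribed exactly.

## Known limitations

- The restraint parameter defaults are placeholders, not a published
  parameterisation.
- The implicit membrane has no lateral structure, no leaflet asymmetry
  and immobile phosphates.
- Overdamped dynamics carry no kinetic information; only equilibrium
  quantities are meaningful.
- The WHAM PMF omits the distance-coordinate Jacobian correction.
- Melting temperatures from the toy engine have "relative physical
  meaning" only: they characterise the model, not an absolute
  experimental scale.
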