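# membind

Coarse-grained analysis of how a peptide's conformational state controls
its membrane affinity, built around the three computational pillars of
conformationally restrained peptide–membrane studies (the motivating
system is the central 65–97 segment of α-synuclein over a synaptic-like
DOPE:DOPS:DOPC bilayer):

1. **Conformational restraints** — Gaussian well potentials
   `V(x) = −K·exp(−(x−x_min)²/σ)` on backbone angles θ and four-quadrant
   dihedrals φ, with analytic forces, defining a helix-locked and an
   extended-disordered state.
2. **Contact-index melting curves** — per-residue membrane contact
   probability (backbone bead within 1 nm of the nearest lipid phosphate
   bead), averaged into a global contact index, traced over a
   temperature ladder and fitted with a logistic to extract the melting
   temperature Tm of membrane binding.
3. **Umbrella sampling / WHAM** — harmonic-window reaction-coordinate
   histograms combined by the weighted histogram analysis method,
   `p(ξ_b) = Σ_i n_i(b) / Σ_i N_i e^{(F_i − w_i(b))/k_BT}`,
   `F_i = −k_BT ln Σ_b p(b) e^{−w_i(b)/k_BT}`, giving the potential of
   mean force `G(ξ) = −k_BT ln p(ξ)` and the membrane-binding free
   energy ΔG (bound minimum to detached plateau, kcal/mol).

Because the original evidence comes from μs-scale simulations that are
not reproducible at desk scale, the package ships a first-class
synthetic-data layer: a toy overdamped Langevin engine for bead chains
near an implicit membrane slab, two-state Markov contact trajectories,
logistic melting ensembles, and exact inverse-CDF umbrella samples from
analytic PMFs — all with embedded ground truth, so every estimator is
testable against known answers. See `docs/methods.md` for the model
details and design choices.

Intended users: people building or validating membrane-binding analysis
pipelines (contact statistics, melting-curve fits, WHAM) who need
verifiable components rather than a production MD engine.

## Worked example

```python
import numpy as np
from membind import *

# 1. a melting ensemble with a designed midpoint of 372 K
trajs = gen_melting_ensemble(Tm=372.0, width=15.0, n_frames=8000, seed=11)
curve = melting_curve([contact_profile(t) for t in trajs])
tm, width, diag = fit_melting_temperature(curve)
print(f"fitted Tm = {tm:.1f} K (width {width:.1f} K, "
      f"rms residual {diag['rms_residual']:.4f})")

# 2. umbrella sampling of a 7.5 kcal/mol binding well, WHAM, free energy
pmf_true = AnalyticPMF("square_well",
                       {"depth_kcal": 7.5, "location": 1.0,
                        "half_width": 0.1, "softness": 0.15},
                       (0.7, 2.4))
windows = gen_umbrella_samples(pmf_true, centers=np.linspace(1.0, 2.2, 11),
                               n_per_window=20000, seed=12)
pmf = compute_pmf(windows, temperature=300.0, plateau_window=(2.0, 2.3))
dg = binding_free_energy(pmf, bound_window=(0.8, 1.4),
                         plateau_window=(2.0, 2.3))
print(f"binding free energy = {dg:.2f} kcal/mol")
ov = window_overlap(build_histograms(windows))
print(f"adjacent window overlap: min {ov.min():.2f}, max {ov.max():.2f}")
```

Output:

```
fitted Tm = 372.0 K (width 15.0 K, rms residual 0.0008)
binding free energy = 7.51 kcal/mol
adjacent window overlap: min 0.10, max 0.46
```

The fitted Tm recovers the designed melting midpoint from the sampled
contact statistics alone; the WHAM free energy recovers the designed
well depth (7.5 kcal/mol) from biased window samples; the overlap
diagnostic confirms adjacent umbrella windows share enough histogram
mass for the reweighting to be conditioned.

## Command-line pipeline

The same stages are exposed as a CLI (`membind --help`): `generate`
(synthetic scenarios from YAML), `simulate` (the toy Langevin engine
from a run config), `contacts`, `melt`, `wham`, and `report`
(aggregation). All outputs are plain text (GRO, a documented multi-frame
XYZ dialect, two-column umbrella series tolerant of `#`/`@` comments,
TSV/JSON with provenance headers); identical config + seed reproduces
identical bytes.

Trajectory dialect grammar (one frame, repeated):

```
<n_beads>\n
frame=<int> time=<ps> temperature=<K> box=<Lx>,<Ly>,<Lz> n_peptide=<R>\n
BB<resid> <x> <y> <z>\n   # R peptide lines, nm
PO4 <x> <y> <z>\n          # n_beads - R phosphate lines, nm
```

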