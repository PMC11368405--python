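# memraft

Analysis toolkit for lipid–protein organization in membrane-protein MD
trajectories, built around the measurements used to study how cholesterol
glues aquaporin-0 (AQP0) tetramers into two-dimensional membrane arrays:

- **Cholesterol insertion depth and orientation.** The signed depth
  *d* = *z*(O3) − ⟨*z*(P)⟩ of the sterol hydroxyl oxygen below the
  extracellular sphingomyelin phosphate plane (recomputed every frame from
  the P atoms within 0.8 nm of the protein, or 3.0 nm of the monitored lipid
  in protein-free bilayers), and the tilt *θ* = arccos(*v̂*·*ẑ*) of the
  C17→C3 sterol ring axis against the membrane normal, reported unfolded in
  [0°, 180°] so leaflet flip-flops appear as excursions past 90°.
- **Time-averaged localization densities.** Atoms spread onto a regular grid
  (0.1 nm default) as sums of per-element Gaussians, accumulated per protein
  monomer after least-squares rigid-body fitting onto a reference monomer,
  summed, σ-thresholded (e.g. 9σ) and masked to within 1 nm of the protein.
  Writers for OpenDX and CCP4/MRC.
- **Inter-protein contact statistics.** Residue pairs of two groups are in
  contact when their minimum-image minimum atom distance ≤ 0.6 nm; per pair
  the occupancy *T*ᵢⱼ ∈ [0, 1], between-condition differences
  Δ*T*ᵢⱼ = *T*ᵢⱼ(A) − *T*ᵢⱼ(B) in percentage points (|Δ*T*| < 1 point
  discarded), and mean contact lifetimes ⟨τ⟩ᵢⱼ from maximal runs of
  contact frames; plus per-frame *d*_CM and *d*_tet-tet distances.
- **Lipid–protein surface complementarity.** Shrake–Rupley SASA (probe
  0.14 nm, 960 points/atom, Bondi-style radii) and the buried-area identity
  *A*_Contact,i,m = ½(*A*_Tet,m + *A*_Lipid,i − *A*_Tet,m+Lipid,i); the
  ratio *A*_Contact/*A*_Lipid runs from 0 (no contact) to 1 (lipid fully
  buried between the two proteins).
- **Detachment forces from force-probe pulling.** Gaussian smoothing
  (σ = 100 ps), detachment force as the highest smoothed force before the
  center-of-mass separation first exceeds 7.3 nm, the phenomenological fit
  *F*_detach = *A* + *B*·log *V*_pull, Mann–Whitney U per velocity and
  two-way ANOVA across velocities.
- **Rigid-body PCA.** After fitting each frame on one tetramer's Cα atoms,
  the covariance of the other group's coordinates is diagonalized into
  relative-motion modes with eigenvalues, variance fractions and projections.
- **Synthetic data with ground truth.** A generator producing membranes with
  labeled anchor atoms whose depth/tilt follow stationary Ornstein–Uhlenbeck
  laws, two-state Markov contact series, force-ramp traces with planted
  detachment events, and sphere clusters with closed-form surface areas —
  so every stage is testable without running MD.

Static-structure measurements (leaflet spacing from P/amide-N marker planes,
Cα RMSD between deposited models, B-factor summaries) are included for
crystallographic coordinates and report in Å; trajectory quantities use nm/ps.

## Worked example

The end-to-end demo generates a synthetic membrane (42 SM + 22 cholesterol
per leaflet around a static fourfold protein, depth −0.60 ± 0.16 nm, tilt
20°), measures depth/tilt, contact statistics against the Markov ground
truth, and detachment forces over the 0.004/0.02/0.1 m/s velocity grid with
a planted force law *F* = 2164 + 232·log₁₀ *V*:

```sh
memraft demo --seed 7 --out demo_out
```

prints (abridged):

```json
{
  "depth_mean_nm": -0.6204712458422551,
  "depth_sd_nm": 0.15998190248184554,
  "tilt_mean_deg": 20.076896751253926,
  "contact_occupancy_mean": 0.31235833333333324,
  "contact_occupancy_expected": 0.33333333333333337,
  "contact_lifetime_ps": 95.46586892682481,
  "contact_lifetime_expected_ps": 100.50083333194499,
  "detach_fit_A": 2151.801744580887,
  "detach_fit_B": 207.91797811456743
}
```

The measured insertion depth (−0.62 ± 0.16 nm) and tilt (20.1°) recover the
generator's stationary law within sampling error at 400 frames; occupancy
and lifetime sit within a few percent of the two-state Markov expectations;
and the log-velocity fit recovers the planted coefficients from 9 noisy
pulling traces. Re-running with the same seed reproduces every byte.

Other subcommands (`depth`, `density`, `contacts`, `complementarity`,
`thickness`, `rmsd`, `detach`, `pca`, `bfactor`, `gen`) operate on files —
multi-model PDB/GRO/XTC trajectories, PDB structures, force-trace TSVs —
and write TSV tables with JSON metadata sidecars; see `memraft <cmd> --help`.

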