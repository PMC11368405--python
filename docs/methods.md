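# Methods

This note documents the models, conventions and numerical choices behind
each analysis stage, what the synthetic-data generator does and does not
emulate, and the design decisions taken where more than one reasonable
convention exists.

## Units and conventions

Internal lengths are nanometers and times picoseconds; PDB input (Å) is
converted at the boundary and crystallographic reporting helpers
(`leaflet_spacing`, `ca_rmsd`, B-factors) emit Å. Forces are kJ/mol/nm
(1 kJ/mol/nm = 1.6606 pN). Boxes are orthorhombic only; triclinic input is
rejected with a clear error, and all periodic distances use the
minimum-image convention componentwise. Atom indices are 0-based internally;
residue identity is (chain, author resid), 1-based, as in the PDB standard.
Atom-name conventions (cholesterol hydroxyl oxygen `O3`, ring atoms
`C3`/`C17`, sphingomyelin phosphorus `P`, amide nitrogen `N`) are defaults,
not assumptions — every operation takes explicit selections, because
force fields differ in naming.

## Cholesterol insertion depth and orientation

Depth is *d* = *z*(O3) − ⟨*z*(P)⟩ where the reference plane is the mean *z*
of extracellular-leaflet sphingomyelin phosphorus atoms passing a proximity
filter, recomputed every frame (the membrane drifts; a static plane would
alias that drift into *d*). The filter keeps P atoms within 0.8 nm of any
protein atom (`near_protein`) or within 3.0 nm of the monitored lipid's
oxygen (`near_lipid`, for protein-free bilayers). Negative *d* means the
hydroxyl sits below the plane, toward the membrane center. Leaflets are
assigned by *z* relative to the selection midplane at a chosen frame
(`select_leaflet`, invertible); sphingomyelin flip-flop is not modeled, so
a static assignment suffices. Frames whose filtered reference set is empty
yield NaN with a warning rather than aborting — transient empty sets occur
legitimately in small boxes.

Orientation is the angle between the C17→C3 ring-axis vector and +*z*,
reported unfolded in [0°, 180°]: a lipid that flips to the other leaflet
reads > 90° rather than being folded back, which is what makes flip-flop
events visible as tilt excursions (~135–160°). `count_flip_flops` counts
hysteretic transitions between a low zone (≤ 30°) and a high zone (≥ 150°);
the dead band prevents tilt noise near a single threshold from
double-counting. Coincident C17/C3 atoms are an error (zero-length axis).

## Localization density maps

Each selected atom contributes a linear combination of Gaussians
Σᵢ Aᵢ exp(−r²/2wᵢ²) evaluated on voxels within 4 widths of its center;
the accumulated grid is divided by the frame count. The shipped per-element
four-Gaussian table is generic (amplitudes scaling with electron count,
widths 0.04–0.26 nm) and is meant to be overridden with coefficients
appropriate to the user's scattering model; a single-Gaussian mode exists
for analytic work. Truncation at 4 widths bounds the omitted mass below
~10⁻³ of an atom's integral; comparisons of maps computed from slightly
different float paths should use exp(−8) of the peak amplitude as the
tolerance, because a boundary voxel can enter or leave the window on a
one-ulp coordinate difference.

Atoms are wrapped into the primary cell before spreading; the spread itself
does not wrap across the boundary (maps are visual/statistical objects and
the protein is kept centered). σ is defined as the standard deviation over
*all* voxels of the box-spanning grid, zeros included, computed **before**
any masking — the source convention is unstated, so this choice is fixed
here and `threshold_and_mask` documents it; thresholds like 9σ/10σ and the
1 nm protein-proximity mask are parameters. Per-monomer accumulation fits
each monomer's atoms onto one common reference monomer (proper rotations
only; degenerate planar sets get a proper-rotation correction with a
warning) and applies the same transform to the density-target atoms. With
an exactly fourfold protein the four fit transforms are exact 90° rotations,
so the summed map is fourfold symmetric up to grid discretization — the
basis of the symmetry test.

## Contacts

A residue pair is in contact at a frame iff the minimum-image minimum
atom–atom distance is ≤ 0.6 nm, all atoms included (hydrogens too, when
present; `heavy_only` excludes them) — the cutoff convention of standard
minimum-distance tools. Occupancy is the contact-frame fraction; ΔT is
reported in percentage points with |ΔT| < 1 point discarded and pairs
absent from one condition counted as T = 0 there. Lifetimes are means of
maximal runs of consecutive contact frames × dt; runs truncated by the
trajectory ends are *included* (the alternative biases short trajectories
toward long-lived contacts disappearing entirely), which slightly
underestimates true lifetimes — the conservation identity
Σ runs × dt = T × n_frames × dt holds regardless and is tested. Group
distances use unweighted centroids by default (optional masses); groups are
assumed compact within the cell, and the center-center distance is
minimum-imaged.

## Surface areas and complementarity

SASA uses the Shrake–Rupley rolling-probe construction (probe 0.14 nm,
960 mesh points per atom, Bondi-style element radii with per-atom
overrides), delegated to a mesh implementation with per-atom radii.
Determinism holds for fixed parameters; the mesh discretization error is
~0.3% at 960 points (tested against a Monte-Carlo surface-sampling oracle
and closed forms for one and two spheres). Absolute areas depend strongly
on the radius table — cross-study comparisons must state radii and probe.

Contact area uses the buried-area identity
*A*_C,i,m = ½(*A*_Tet,m + *A*_Lipid,i − *A*_Tet,m+Lipid,i), which averages
the lipid surface buried by the protein and the protein surface buried by
the lipid. Two clamps keep the complementarity ratio an honest *covered
lipid fraction* in [0, 1]: small negative *A*_C from mesh sampling are set
to 0, and the total *A*_C,1 + *A*_C,2 is capped at *A*_Lipid — a strongly
concave protein pocket can bury more of its own surface than the lipid has,
which would otherwise push the ratio above 1 (the engulfed-lipid limit
reaches ~1.16 uncapped). Both clamps set a `clamped` flag.

Leaflet spacing is |⟨z⟩_upper − ⟨z⟩_lower| of the marker atoms (P or amide
N); the defining phrase "average distance between the atoms in the two
leaflets" is ambiguous between this and the mean pairwise separation, so
both modes exist (identical for the plane interpretation with equal-size
leaflets). Cα RMSD matches residues by (chain, resid) intersection and
optionally applies a proper-rotation Kabsch fit first.

## Force-probe analysis

Smoothing is an order-0 Gaussian filter, σ = 100 ps, kernel truncated at
4σ, with the truncated kernel *renormalized* at the trace ends rather than
zero-padded — detachment often happens near the end of a trace, and
zero-padding would suppress exactly the peak being measured. The
detachment force is the maximum of the smoothed force over frames at which
the smoothed *d*_COM is below the cutoff (7.3 nm default) and strictly
before its first crossing; "the force when separation starts" is
operationalized as this pre-crossing window. Ties take the earliest frame;
traces that never cross return the whole-trace maximum flagged
`crossed=False`; a trace already beyond the cutoff at *t* = 0 is an error.
Taking the maximum of a smoothed noisy series is positively biased by the
noise floor (≈ +2σ_smoothed in the generator's conditions, ~2% of the
planted forces); this is a property of the estimator, not removable without
changing the definition.

`fit_log_velocity` is ordinary least squares of *F* on log *V*; the log
base is a required, recorded parameter because the convention is not
universal (the shipped examples use base 10). Mann–Whitney U uses the exact
null distribution for min(n, m) ≤ 8 without ties and the tie-corrected
normal approximation otherwise, with the method recorded; the two-sided
exact p follows the standard 2·min(P(U ≤ u), P(U ≥ u)) convention capped
at 1. The two-way ANOVA (force ~ interface + velocity) uses type-II sums
of squares, appropriate for unbalanced designs without interaction; an
interaction flag switches to the crossed model.

## Rigid-body PCA

Each frame is superposed by a proper-rotation least-squares fit of the fit
selection (typically one group's Cα atoms) onto reference coordinates and
the transform applied to all atoms, so the residual motion of the other
group is its motion relative to the fitted one. The covariance of the
flattened 3N analysis coordinates about their time mean is diagonalized;
eigenvalues are clipped at 0 and sorted descending, variance fractions are
λ_k/Σλ, and eigenvector signs follow the largest-coefficient-positive
convention so repeated runs are bit-identical. No mass weighting. A
trajectory whose total variance is at rounding level relative to the
coordinate magnitude is flagged degenerate (fractions undefined) instead of
dividing by ~0. Projections are dot products of mean-centered coordinates
with the eigenvectors; projecting the PCA's own trajectory reproduces the
eigenvalues as projection variances (Parseval), which is tested to 1e-8.

## Synthetic data: what it emulates, and what it does not

The membrane generator emulates the *statistical structure* of a
sphingomyelin/cholesterol bilayer around a membrane protein, not its
physics: a static cylinder of pseudo-atoms (optionally exactly fourfold
symmetric — rounding the bead count to a multiple of 4), sphingomyelin as
P/N marker-atom pairs pinned to leaflet planes at ±1.84 nm (P) and
∓0.25 nm inside them (amide N, giving the 36.8/31.8 Å marker spacings of a
thick, cholesterol-rich bilayer), and cholesterol as O3/C3/C17 triplets
whose depth and tilt follow exactly-discretized stationary
Ornstein–Uhlenbeck processes (defaults −0.60 ± 0.16 nm and 20° ± 8°,
relaxation 100 ps) with lateral diffusion 10⁻⁵ nm²/ps as a periodic random
walk. Default composition is 42 SM + 22 cholesterol per leaflet (128
lipids, ~2:1) in a 10 × 10 × 9 nm box at 100 ps/frame. Flip-flop events
are injectable as explicit state switches (depth mirrored through the
midplane, tilt → 180° − θ). Packing below 0.45 nm lattice spacing is
rejected. Deliberately absent: lipid–lipid interactions, acyl chains,
protein flexibility, membrane undulations, realistic force-field
energetics. Passing tests therefore demonstrate that the *measurement
operators* are correct and unbiased under known laws — not that real
membranes behave like the generator.

The force-trace generator ramps the force at the effective loading rate
k_s·V_pull (spring 500 kJ/mol/nm², velocities 0.004–0.1 m/s) with AR(1)
noise (sd 50 kJ/mol/nm, correlation 50 ps), enforces
F_true = loading rate × t_det, relaxes exponentially after detachment, and
makes d_COM cross the cutoff exactly `cutoff_crossing_delay` (200 ps) after
t_det. Noiseless traces are flagged pre-smoothed so the detector recovers
F_true exactly. Planted velocity laws in the examples use
F = 2164 + 232·log₁₀V, spanning ~1600–1930 kJ/mol/nm across the grid.
Contact series are independent two-state Markov chains with exact
per-step transition probabilities 1 − e^(−k·dt), initialized from the
stationary law.

All generators consume a single named RNG per call, seeded from the spec;
identical specs give byte-identical output, and seeds are recorded in the
ground-truth records and output metadata.

## Problem sizes

The shipped tests and the acceptance script run at desk scale by design:
membranes of ~130 lipids over 10²–5·10³ frames, contact ensembles of 100
chains × 10⁴ steps, 20 pulling replicas per velocity, Monte-Carlo SASA
oracles at 10⁶ samples per cluster, and density grids of ≤ 10⁶ voxels.
These sizes put the stochastic recovery checks at 3-standard-error
resolution while keeping the full suite under a minute of compute per
module; the statistical conclusions do not change with longer runs, only
their error bars tighten.

## Known limitations

- SASA absolute values inherit the radius table; only relative and
  oracle-checked quantities are radius-robust.
- Lifetime estimates include end-truncated runs (documented bias toward
  shorter means on short trajectories).
- The detachment estimator's noise-floor bias (above) is inherent to
  max-of-smoothed-trace definitions.
- Density maps do not wrap the Gaussian spread across periodic boundaries;
  lipids within 4 widths of the box edge lose a sliver of mass.
- The selection mini-language covers resname/name/resid/chain boolean
  algebra only; positional selections are done in code.
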