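# Methods

## Scope and model

The package implements the trajectory-analysis layer of a receptor
conformational-ensemble study: given frames of a class-A GPCR (optionally
with a bound ligand and an intracellular mini-Gq construct), it reduces
each frame to a vector of interpretable degrees of freedom (DOFs), pools
the per-simulation time series, and maps the resulting landscape with PCA,
kernel densities and discrete state labels.  It does not prepare systems
or run dynamics; frames are taken as given (whole molecules, membrane
normal along z).

## Descriptors

* **Torsions.** χ1 is N–CA–CB–CG, χ2 is CA–CB–CG–CD1 (CD1 for both Trp
  and Phe, the IUPAC reference branch), signed by the standard convention
  (cis = 0°, range (−180°, 180°]).  The implementation agrees with an
  independent atan2-of-normals oracle and with MDAnalysis'
  `calc_dihedrals` on random quadruples to 1e-9.
* **Centroid distances.** Wherever a DOF addresses "a residue" or a
  residue range, the unweighted centroid of its non-hydrogen atoms is
  used; selectors can narrow to named atoms (e.g. hydroxyl oxygens for
  the Tyr5x58–Tyr7x53 distance, indole NE1 and amide OD1 for the
  W6x48–N7x49 hydrogen-bond distance).
* **Ligand contacts.** Minimum distance over all polar heavy-atom pairs
  (polar = N, O, S) between ligand and residue.
* **Motif RMSD.** Least-squares superposition on a fit selection (default
  receptor Cα) restricted to proper rotations (Kabsch with determinant
  correction, so mirror images are never matched), then RMSD over the
  motif selection without re-fitting.  Whether the fit set should be all
  Cα or transmembrane-only is genuinely open; it is a selector in config,
  defaulting to all Cα.
* **Construct coupling.** Z-distance is the signed z gap between the
  receptor TM-bundle centroid and the construct interface-helix centroid
  (receptor minus construct); Z-angle is `arcsin(Δz/|v|)` of the vector
  from the interface centroid to the tail centroid.  Both assume the
  membrane normal is the z axis, which is the convention of
  membrane-builder outputs.

Residues are addressed by Ballesteros–Weinstein code through a
configurable map.  The shipped 5-HT2A default contains only positions
whose sequence numbers are anchored in the literature narrative
(e.g. 6x48 → 336, 7x53 → 380); positions without an anchored number
(6x30, 3x50, 3x46, 6x37, 5x44, 3x36, 6x55) must be supplied by the user,
because inventing residue numbers would be worse than failing loudly.

## Preparation

Each simulation is truncated at its discard cutoff (explicit nanoseconds
per simulation id; or an automatic rule — the first 100-frame window of
the receptor-Cα RMSD series whose fitted slope magnitude drops below
0.001 Å/ns).  The remainder is evenly subsampled to 3,000 frames per
system (floor-rounded linear index ramp including first and last frame;
strictly increasing whenever rows exceed the target, so no duplicates).
Order is always discard first, then subsample.

## Pooled PCA

DOFs mix Å and degrees, so the pooled matrix is z-scored per column
(population SD) and the eigendecomposition is of the correlation matrix;
eigenvalues then sum to the number of DOFs and explained-variance ratios
are eigenvalue / DOF-count.  Determinism: eigenvalues sorted
non-increasing; each loading vector is oriented so its
largest-magnitude weight is positive.

Angular columns are re-centered before standardization: the branch cut is
moved to the antimode of a smoothed (~15° window) circular histogram,
tie-broken to the emptiest bin farthest from the mode, so a rotamer basin
straddling ±180° stays contiguous on one branch.  The per-column cut is
stored in the model and re-applied when projecting new data or reference
structures.

The ligand-aware second analysis excludes apo simulations (their presence
is an error, not a warning) and requires the five ligand-distance columns
in every retained matrix; otherwise its contract is identical.

## Landscapes

Densities are product-Gaussian kernel estimates evaluated directly on
fixed grids: 0.2 Å bins for distances, 1° for angles.  Angular axes use a
wrapped kernel (±360° images) on a full-circle grid, and the bandwidth on
those axes uses the circular standard deviation.  A separable product
kernel with per-axis bandwidths is evaluated in place of
`scipy.stats.gaussian_kde` because a single shared covariance factor
cannot mix a linear Å axis with a toroidal degree axis; on purely linear
data the two agree (cross-checked in the tests).

Bandwidth per axis is Scott's rule times an oversmoothing factor of 2
(`bw_scale`, configurable).  The maps are read for basin locations: with
unimodal Gaussian-like basins, widening the kernel leaves the mode
unbiased while roughly halving its sampling scatter, which keeps mode
estimates within one grid bin at the ensemble sizes used here
(10,000–20,000 frames).  Basins closer than ~3 combined SDs would merge
earlier under this factor; set `bw_scale=1.0` for plain Scott behaviour.

Boltzmann inversion writes `F = −kB·T·ln(p/p_max)` in kcal/mol at
303.15 K by default (kB = 0.0019872041 kcal/mol/K), so the mode sits at
F = 0 and a half-maximum cell at ln 2 · kB·T ≈ 0.418 kcal/mol.  These are
population-derived maps of whatever the input ensemble sampled — the API
deliberately does not call them free-energy surfaces.  Unsampled cells
are stored as +∞.  The highest-density region accumulates cells in
descending probability until the target mass (default 50 %) is reached,
with row-major order breaking exact ties; this is the smallest cell set
reaching the mass under that tie rule, and regions are nested in the
target mass by construction.

## State classification

* Toggle switch: "alternative" iff χ1 ∈ [30°, 60°] (the window reported
  for the rotated-indole state), taking precedence over the χ2 split;
  otherwise nearest of on (50°) / off (120°) by circular distance.  The
  literature gives basin modes, not a classifier; the precedence rule is
  this package's design, chosen because the alternative state is defined
  by χ1, orthogonal to the χ2 on/off axis.
* F6x44: "anti" iff circular distance to 180° ≤ 60° (boundary inclusive
  on the anti side), else "gauche".
* Hydrogen bond: heavy-atom donor–acceptor distance ≤ 3.5 Å, no angular
  term — trajectories may lack consistent hydrogens and the distance
  distribution is the observable of record.
* Activation coordinate: signed projection of a frame's (TM2–6, TM3–7)
  point onto the unit axis from the inactive anchor to the active anchor
  (defaults (14, 19) → (21, 14) Å, the synthetic presets' anchor basins;
  in real use the anchors should come from experimental reference
  structures).  Labels split the anchor-to-anchor length into thirds —
  an explicit package choice, since no cutoffs are published.

## Restraints

Flat-bottom harmonic: zero inside `[lo, hi]`, `½k(d − bound)²` outside
(the ½ convention is declared, and config requires explicit force-constant
units because MD engines disagree).  Energy is continuous and once
differentiable at the boundaries and convex in the CV.  Coupling
monitoring reports per-frame CV values, restraint energies and
Z-distance/Z-angle, and flags decoupling when the Z-distance moving
average (20-frame window) departs more than 2 Å from its initial value.

## Synthetic ground truth

`sample_features` draws frames from named Gaussian basins — wrapped
Gaussians for angles (SDs ≤ 30° keep wrap distortion negligible; the
default angular SD is 10°) — with optional per-step Markov switching
between basins and an optional deterministic linear drift (used by the
decoupling preset).  Defaults are 0.8 Å / 10° SDs, chosen so basins
reported ~3 Å or ~70° apart are well separated (≥ 6 SD) without being
trivial.  Preset basin centres encode the reported conformational states:
β-arrestin-ideal at TM3–7 = 15 Å / TM2–6 = 18 Å, G-protein-ideal at
TM2–6 = 21 Å (its TM3–7 is set to 14 Å, slightly below the β-arrestin
value, as no number is published), toggle basins at χ2 = 50° / 120° with
a symmetric 0.01-per-step transition matrix.  Values without any
published anchor (lock distances, Z geometry, the inactive basin) are
fixture choices documented in `synthetic.py`.

`build_structure` realizes a feature vector as a toy structure in which
every DOF is carried by a minimal dedicated atom group: helix-end
centroid pairs for the TM distances, internal-coordinate (NeRF) side
chains for exact torsions, marker atoms at exact pair distances, and a
two-centroid construct placed at the exact Z-distance/Z-angle.  These
fixtures are deliberately not physical receptors — groups are spread ~50 Å
apart so DOFs never interfere — which is what makes
`extract_features(build_structure(f)) = f` hold to 1e-6 and lets every
pipeline stage be tested against exact ground truth.  What synthetic
passes do **not** show: correlated multi-switch kinetics, anharmonic or
multimodal basins within a state, solvent/membrane coupling, or
force-field realism; conclusions about real trajectories rest on the
geometry oracles, not on the basin statistics.

## Problem sizes and numerics

Statistical tests run at 10,000–20,000 frames (feature level) and 50–400
frames (structure level); the basin-recovery script uses 20,000 frames
for distance basins and 10,000 for the toggle ensemble, sizes at which
mode scatter is comfortably below one grid bin.  Statistical assertions
use 3-standard-error bounds, with Markov-chain occupancy SEs inflated by
(1+ρ)/(1−ρ) for chain autocorrelation ρ.  Degenerate inputs fail loudly:
empty selections, collinear dihedral points, constant DOF columns
(unless explicitly tolerated, in which case they standardize to zeros
with a warning), all-zero densities, and discard cutoffs that would
remove every frame.  Density-mode ties return the lowest row-major cell
with a warning.

## Known limitations

DCD/XTC reading loads trajectories fully into memory (fine at the
3,000-frame analysis scale; streaming is out of scope).  2D densities
support periodic axes, but the pipeline currently only exercises the
linear (TM2–6, TM3–7) pair.  The plateau-based discard rule is a
convenience, not a convergence diagnostic — no autocorrelation-time or
block-averaging analysis is provided.
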