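# gpcrswitch

Microswitch and macroswitch analysis of GPCR conformational ensembles,
built around the serotonin-2A receptor (5-HT2A), a class-A GPCR whose
activation involves a small set of coupled conformational switches:
the E/DRY ionic lock (E6x30–R3x50), the hydrophobic lock (I3x46–L6x37),
the tryptophan toggle switch (W6x48, read out through its χ1/χ2 side-chain
torsions), the PIF-motif phenylalanine (F6x44), the NPxxY motif on TM7,
the TM5 bulge at S5x46, and — on the macroscopic scale — the distances
between the intracellular ends of TM2–TM6 and TM3–TM7 that shape the
G-protein binding surface.

The package is for structural/computational pharmacologists who have MD
trajectories (or want controlled synthetic stand-ins) and need the standard
trajectory-analysis layer for this problem:

* **descriptor extraction** — distances, non-hydrogen-centroid distances,
  χ1 (N–CA–CB–CG) and χ2 (CA–CB–CG–CD1) torsions, minimum polar heavy-atom
  ligand–residue distances, motif RMSD after global Cα superposition
  (proper-rotation Kabsch), and the Z-distance / Z-angle that monitor an
  intracellular mini-Gq construct, with residues addressed by
  Ballesteros–Weinstein (BW) codes through a configurable map;
* **preparation** — per-simulation discard of the unequilibrated head
  (explicit ns or an RMSD-plateau rule), then even subsampling
  (default 3,000 frames per system);
* **pooled PCA** — correlation-matrix PCA (each DOF z-scored so Å and
  degrees are commensurate; for standardized input the eigenvalues sum to
  the number of DOFs), with deterministic loading signs, loadings reports,
  projection of trajectories and reference structures, and a second,
  ligand-aware analysis that excludes apo runs and appends five
  ligand–residue distances;
* **population landscapes** — Gaussian-kernel densities on fixed grids
  (0.2 Å / 1° bins), Boltzmann inversion
  `F = -kB·T·ln(p/p_max)` (kcal/mol, 303.15 K default), highest-density
  ("50 % most sampled") regions, and mode extraction;
* **state classification** — toggle rotamer on (χ2 ≈ 50°) / off
  (χ2 ≈ 120°) / alternative (χ1 ∈ [30°, 60°]), F6x44 gauche/anti, a 3.5 Å
  heavy-atom H-bond criterion, and a scalar coordinate along the
  (TM2–6, TM3–7) activation axis;
* **restraint monitoring** — flat-bottom harmonic CV restraints
  (`E = ½k·x²` outside `[lo, hi]`) and construct-coupling drift detection;
* **synthetic ground truth** — named Gaussian-basin ensembles with Markov
  rotamer switching, and a toy structure builder whose extracted
  descriptors reproduce any requested feature vector to 1e-6, so the whole
  pipeline is testable end to end against known answers.

## Worked example

Two synthetic ensembles — an inactive apo-like receptor and an active
Gq-coupled one — through the full pipeline:

```python
from gpcrswitch.pipeline import validate_config, run_pipeline

cfg = validate_config({
    "seed": 1, "subsample_n": 3000,
    "simulations": [
        {"id": "apo_unbound", "preset": "inactive_apo",     "n_frames": 6000},
        {"id": "gq_coupled",  "preset": "active_g_protein", "n_frames": 6000},
    ],
})
manifest = run_pipeline(cfg, "demo_out")
```

This prints/records (same numbers on every rerun with this seed):

```
eigenvalues: [7.94, 1.04, 1.01, 0.99]
evr:         [0.611, 0.08, 0.078, 0.076]
pooled rows: 6000
density mode (tm26, tm37): [13.9, 19.1]
               toggle_on  toggle_off  activation_active  activation_inactive
apo_unbound          0.0         1.0                0.0                  1.0
gq_coupled           1.0         0.0                1.0                  0.0
```

Reading: 6,000 of 12,000 frames enter the pooled PCA (3,000 per system
after even subsampling).  PC1 carries eigenvalue 7.94 of the 13 z-scored
DOFs (61 % of variance) and cleanly separates the unbound from the
G-protein-coupled ensemble, as expected when every switch flips together;
the remaining eigenvalues sit near 1, i.e. uncorrelated noise.  The pooled
2D (TM2–6, TM3–7) density peaks at (13.9, 19.1) Å — the deeper inactive
basin — and the occupancy table shows the coupled ensemble fully in the
toggle-on, active-labelled state.

The same stages run from the shell:

```sh
gpcrswitch simulate --preset beta_arrestin_ideal --n-frames 200 --seed 1 --out fx/
gpcrswitch run --config run.yaml --out out/
```

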