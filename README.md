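# groovescope

Analysis toolkit for molecular-dynamics trajectories of **tail-anchored (TA)
protein targeting complexes** — a TRC40/Get3/ArsA-family ATPase dimer holding
a single transmembrane helix in its hydrophobic groove — together with the
**NADH-coupled ATPase assay** analysis used to characterize these enzymes
biochemically.

TA proteins carry a single C-terminal transmembrane helix and are inserted
into membranes post-translationally; a cytosolic ATPase chaperone shields the
hydrophobic helix in transit. Two questions dominate the trajectory analysis
of such complexes: *how does the carrier reorient around the bound helix*,
and *how well does it shield the helix termini from water*. groovescope
computes the observables that answer them and the population statistics that
summarize long trajectories into a handful of conformational states.

## What it computes

Given a multi-model PDB trajectory (topology + frames) and a per-atom
parameter table:

- **Helical rotation** θ(t): after superposing each frame onto frame 0 via
  the ligand backbone (Kabsch), with ligand helix axis **a** (top
  eigenvector of the backbone covariance, oriented N→C) and
  v_t = COM(carrier) − COM(ligand backbone),

  θ(t) = ∠( p₀, p_t ),  p_t = v_t − (v_t·a)a  ∈ [0°, 180°]

  i.e. the angle the carrier has revolved about the helix axis since t = 0.
- **Terminal hydration shell**: number of water oxygens within 5 Å
  (minimum image) of any heavy atom of the first and last two ligand
  residues — each water counted once.
- **Contact series**: minimum heavy-atom distance between a probe residue's
  side chain and a pocket atom set, thresholded at 4.5 Å.
- **Backbone RMSD** series and plateau/convergence detection.
- **2-D population maps**: paired observables binned (2° × 1 water by
  default); bins ≥ 10% of the maximum count form 8-connected clusters,
  indexed chronologically, with occupancy percentages and dwell intervals;
  per-cluster average structures after ligand-backbone superposition.
- **Per-cluster interaction enthalpies**: a pairwise generalized-Born
  screened-Coulomb + Lennard-Jones surrogate,
  E = Σ k_e q_i q_j [1/(ε_p r) − (1/ε_p − 1/ε_w)/f_GB] + Σ 4ε_ij[(σ_ij/r)¹² − (σ_ij/r)⁶],
  f_GB = √(r² + R_i R_j e^(−r²/4R_iR_j)), averaged over cluster members.
- **ATPase kinetics**: initial rates from A340 traces (ATP turnover is
  coupled 1:1 to NADH oxidation), specific activities in nmol·min⁻¹·mg⁻¹
  via activity = |slope|/(ε·ℓ) · V · 60 · 10⁹ / m, and relative-Vmax tables
  for oxyanion (arsenite/antimonite) response.

A **synthetic-data generator** builds carrier–ligand–water trajectories with
exactly known ground truth (rotation schedules, per-frame hydration counts,
contact schedules) and NADH-decay traces at prescribed activities, so every
stage is testable end to end.

## Worked example

Generate a four-state synthetic complex emulating a carrier that drifts to a
~39° rotation while its groove closes around the helix, and analyze it:

```
$ groovescope demo arsa2_pep12_like --out demo_out --seed 1
arsa2_pep12_like: 4 clusters
  cluster 1: occupancy 7.50%, centroid (1.0, 12.5)
  cluster 2: occupancy 30.94%, centroid (19.0, 7.5)
  cluster 3: occupancy 30.31%, centroid (39.0, 9.5)
  cluster 4: occupancy 31.25%, centroid (39.0, 2.5)
```

Each centroid is (rotation °, hydration count). Cluster 1 is the initial
state (no rotation, fully hydrated termini), cluster 2 the rearrangement
state, and the dominant cluster (31.25% of frames) combines high rotation
with a collapsed terminal hydration shell — the closed, shielded groove.
`demo_out/` contains the full series (`rotation.tsv`, `hydration.tsv`,
`rmsd.tsv`), the binned map (`heatmap.tsv`), `clusters.json` with dwell
intervals, per-cluster average structures (`cluster_<k>_avg.pdb`),
per-cluster interaction enthalpies (`energies.json`) and a `manifest.json`
with input checksums.

The same analyses run on real data via `groovescope run --config cfg.json`,
or piecewise (`groovescope rotation`, `hydration`, `contacts`, `popmap`,
`energy`, `assay`); `groovescope simulate-traj` / `simulate-assay` emit
synthetic inputs with ground-truth sidecars.

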