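# Methods

This note documents the models, conventions and numerical choices behind
groovescope, and what the synthetic-data validation does and does not show.

## Coordinate conventions

Coordinates are Angstrom, times nanoseconds, residue numbering 1-based per
PDB, selection `resid` ranges inclusive. The reference trajectory format is
multi-model PDB (one MODEL block per frame); PDB stores no times, so frame
times are `index × dt` with `dt` configurable (default 0.1 ns/frame, i.e.
1600 snapshots over 160 ns). Waters are recognized by residue name
HOH/WAT/SOL and represented, for counting purposes, by their oxygen atom
(O/OW/OH2). "Heavy atom" means any element other than hydrogen. Periodic
boundaries are orthorhombic-only; distances use the minimum-image convention
when a box is present and raw distances otherwise, so stripped or unboxed
trajectories analyze cleanly. Distance thresholds are inclusive (d ≤ cutoff
counts) — a convention that had to be fixed one way and is tested both ways
round.

## Helical rotation

The metric reports how far the carrier has revolved about the bound helix
since the start of the trajectory. Per frame: (1) superpose onto frame 0
using the ligand backbone (mass-weighted Kabsch; the optimal rotation is
computed by `scipy.spatial.transform.Rotation.align_vectors`, which handles
the reflection branch); (2) project the carrier→ligand COM-difference
vector off the helix axis; (3) take the angle to the frame-0 projection via
atan2, range [0°, 180°], with θ(0) ≡ 0.

Choices worth noting:

- **Axis at frame 0 only.** After alignment all frames share the ligand
  frame; a per-frame axis would re-absorb ligand flexing into the metric.
  The axis is the top eigenvector of the (unweighted) backbone coordinate
  covariance; a relative eigengap below 1e-6 raises an error rather than
  returning an arbitrary direction. The sign points from the first selected
  residue to the last (N→C).
- **Unsigned by default.** No handedness convention is imposed; a signed
  variant (about +a, range (−180°, 180°]) is available via `signed=True`.
- **Ligand COM over backbone atoms only**, matching the alignment
  selection, for internal consistency.
- Frames whose off-axis carrier COM component is shorter than 0.5 Å have no
  defined azimuth and raise an error naming the frame.
- The carrier selection defaults to the whole carrier (both chains); which
  COM a given study used (whole protein vs groove helices) is configurable.

## Convergence detection

`convergence_time` defines the plateau as the mean of the final 20% of the
series and returns the earliest time from which every full running-window
mean (default window 5 ns) stays within ± tolerance of it. This is a
deliberate, simple construction — published convergence times rarely state
their criterion — and its two free parameters (window, tolerance) are
exposed.

## Hydration and contacts

Terminal hydration counts distinct water oxygens within 5 Å of ANY heavy
atom of the first and last two ligand residues; a water near both termini
counts once. Hydrogens are excluded from the reference set (standard
water-shell semantics; an all-atom variant would only shift counts
upward). Contacts use the probe residue's side-chain heavy atoms (backbone
N/CA/C/O excluded; a glycine-like probe is an error) against an arbitrary
pocket selection, reporting both the minimum distance and the thresholded
0/1 series (default 4.5 Å).

Distances are computed by vectorised numpy broadcasting with minimum-image
wrapping. At the system sizes this package targets (10²–10⁴ atoms,
10²–10³ frames) this is faster and simpler than cell lists; the test suite
pins it against an independent pure-Python all-pairs oracle, including
across-boundary cases.

## Population analysis

2-D histograms use half-open bins [edge, edge + width) with edges anchored
at floor(min/width)·width, so identical data always falls on the same grid.
Default widths: 2° (rotation), 1 (hydration counts), 0.25 Å (distances) —
chosen to match the visual granularity of typical published heat maps; no
automatic bin-width selection is attempted.

Bins holding at least 10% of the maximum bin count (configurable) are
"significant"; significant bins form clusters by 8-connectivity
(4-connectivity fragments diagonal ridges). Clusters are indexed
chronologically — cluster 1 is the one visited first — matching the
convention that cluster 1 is the initial state. Frames in non-significant
bins stay unassigned rather than being forced into a nearest cluster, so
cluster occupancies sum to ≤ 100%. Dwell intervals are maximal runs of
consecutive assigned frames; a cluster revisited later therefore owns
several intervals, which accommodates trajectories that alternate between
overlapping states. Average structures superpose all member frames onto the
first member (mass-weighted, over a configurable alignment selection,
ligand backbone by default) and take the unweighted coordinate mean.

## Interaction enthalpies

The per-cluster energy is a **pairwise generalized-Born interaction
surrogate**, not a full MM-GBSA: no SASA/nonpolar term, no per-snapshot
effective-radius recomputation — Born radii come fixed from the parameter
table. The electrostatic term per pair is
k_e q_i q_j [1/(ε_p r) − (1/ε_p − 1/ε_w)/f_GB] with
f_GB = √(r² + R_iR_j exp(−r²/4R_iR_j)) (f_GB → r as radii → 0, recovering
the fully screened 1/(ε_w r) limit; `use_gb=False` gives vacuum Coulomb);
k_e = 332.0636 kcal·Å/(mol·e²), ε_p = 1, ε_w = 78.5 by default. The van der
Waals term is 12-6 Lennard-Jones with Lorentz–Berthelot combining. Favorable
energies are negative; reports also carry |E| since published enthalpy signs
are not always consistent. No distance cutoff is applied by default
(desk-scale systems); an optional cutoff uses a shifted potential so the
energy is continuous (zero) at the boundary. Pairs closer than 0.1 Å raise a
clash error naming the atoms. The surrogate preserves *comparative*
per-cluster analysis (which state binds tighter); its absolute numbers are
not comparable to any specific force-field MM-GBSA.

Ions, when present, are treated as solvent unless explicitly grouped.

## ATPase kinetics

In the coupled assay, ATP hydrolysis regenerates via pyruvate
kinase/lactate dehydrogenase so each turnover oxidizes one NADH; the A340
slope therefore reports the hydrolysis rate directly. Defaults:
ε₃₄₀(NADH) = 6220 M⁻¹cm⁻¹; path length 0.55 cm, the effective liquid
height of a 200 µL reaction in a 96-well plate; initial NADH 0.3 mM. All are
configurable. Initial rates are ordinary least squares over a manual
window, with an automatic option that takes the longest window from t₀
keeping r² ≥ 0.99. Specific activity is
|slope|/(ε·ℓ) [M/s] × V [L] × 60 × 10⁹ / m [mg]; relative Vmax is the ratio
to the basal (no-oxyanion) condition, with ratio uncertainties propagated
as r·√((σ_a/a)² + (σ_b/b)²). Rounding to printed precision happens only at
report time. Michaelis–Menten fitting and coupling-lag modeling are out of
scope (only Vmax is analyzed).

## Synthetic-data generator

The generator emulates the *statistical structure* of carrier–TA
trajectories, not their physics: no force field, thermostat or dynamics.

- **Ligand**: ideal 20-residue α-helix backbone (1.5 Å rise, 100°/residue;
  N/CA/C/O on concentric helices), chain L, axis ≈ z, plus one mobile
  side-chain pseudo-atom (CB) on the last residue serving as the contact
  probe. The ligand is held literally fixed: it defines the ground-truth
  reference frame in which the rotation schedule is prescribed, so thermal
  jitter applies to the carrier only. (Jittering the reference frame itself
  would fold frame-alignment noise — ~0.45°/frame at σ = 0.1 Å for a helix
  of 2 Å cross-section — into every recovered observable.)
- **Carrier**: two rigid pseudo-atom arcs (chain A spanning 120°, chain B
  40°, radius 11 Å, five z-levels) around the ligand. The asymmetry puts the
  carrier COM ~6 Å off the helix axis, giving the rotation metric a healthy
  lever arm. Four atoms on chain A (res names LYS/MET/ASP/ILE) near the
  ligand C-terminus form the "induced pocket". Each frame the carrier is
  rigid-rotated about the ligand backbone's principal axis through its COM —
  exactly the axis the analysis measures about — by the schedule angle, then
  jittered per-atom with N(0, σ²) (σ = `noise_sigma`).
- **Waters**: oxygen-only pseudo-residues. Per frame, exactly
  `hydration_schedule[f]` oxygens are placed 3.0–4.7 Å from terminal-residue
  backbone atoms (inside the 5 Å shell with margin for jitter) and the rest
  of a fixed pool (≥ 50) in bulk, rejection-sampled to stay > 7.5 Å
  (minimum image) from every terminal heavy atom — so the recovered count
  equals the schedule exactly at any jitter level, because placement is
  relative to the jittered anchors.
- **Contacts**: when on, the CB probe sits 4.4 Å above the pocket ring
  centroid along the helix axis (3.5–3.9 Å from every pocket atom, near the
  LJ minimum, inside the 4.5 Å cutoff); when off, 10 Å above (> 8 Å from
  all pocket atoms).
- **Box**: 80 Å cube with the system centered, exercising minimum-image
  code without wrapping artifacts.
- Everything is driven by one `numpy.random.default_rng(seed)`: fixed seed ⇒
  bit-identical output.

`make_cluster_schedule` turns ordered, contiguous dwell segments
((rotation°, hydration), start, end) into per-frame schedules with uniform
within-state rotation jitter (default ± 0.4°, below half the 2° bin width)
and integer hydration (no jitter — any jitter crosses a count bin).
Because rotation is measured relative to frame 0, schedules meant for exact
population recovery should start at 0°; states at odd-degree values then
stay strictly inside single bins.

The assay generator produces A340(t) = ε·ℓ·[NADH]₀ − ε·ℓ·rate·t + N(0, σ²),
with the rate implied by the prescribed specific activity; prescriptions
that would deplete 0.3 mM NADH before the trace ends are rejected.

**What passing these tests shows — and not.** Recovery of schedules proves
the analysis chain (alignment, projection, counting, binning, clustering,
unit conversion) is correct and self-consistent, with exactly known ground
truth. It does not validate behavior on real MD data, where the ligand
flexes (adding alignment noise the generator deliberately excludes),
hydration is diffusive rather than placed, states are not box-shaped in
observable space, and force-field energetics bear no relation to the GB
surrogate's absolute values.

## Demo profiles

Three literature-style profiles (320 frames, dt 0.5 ns, σ = 0.05 Å) exercise
the full pipeline: `get3_like` — one state (low rotation, dry termini) →
a single 100% cluster; `arsa2_pep12_like` — initial, rearrangement, and two
rotated states, the low-hydration one dominant at exactly 31.25% of frames
(500-of-1600-style occupancy); `arsa2_sec61b_like` — a high-torsion
meta-stable state, a rotated-back state, and a final probe-docked state,
mapped as rotation × contact flag → three clusters.

## Problem sizes

The shipped tests and the acceptance script use 60–320-frame trajectories
of ~350 atoms, 50-frame brute-force comparisons on ≤ 500-atom systems, and
100-seed Monte-Carlo loops for kinetics — sizes chosen so the full suite
runs in seconds while every statistical claim still has comfortable margin
(e.g. rotation recovery errors run ~0.2° against the 0.5° bound; kinetics
recovery hits 100/100 seeds against a ≥ 95 criterion).

## Known limitations

- Orthorhombic boxes only; no triclinic minimum image.
- No RMSF, dihedral, secondary-structure or water-residence analysis;
  helix-formation events must be assessed by other tools.
- The GB surrogate's absolute energies are not MM-GBSA numbers.
- PDB is the only trajectory format (binary formats would need adapters);
  PDBx/mmCIF and AMBER prmtop are not parsed.
- The selection grammar covers chain/resid/resname/name/backbone/water with
  boolean algebra — no distance-based or sequence-based selections.
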