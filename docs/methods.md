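# Methods

## Data model and units

Coordinates are angstroms, charges elementary charges, masses amu, dipoles
Debye (1 e·Å = 4.803205 D), fields MV/cm (the Coulomb field of 1 e at 1 Å is
14.39964 V/Å = 1439.964 MV/cm). Indices are 0-based internally and 1-based in
reports. PDB carries no partial charges, so charges, masses and the
auxiliary-site flag come from a sidecar table keyed by
(atom name, residue name). Auxiliary sites — fixed point charges standing in
for lone-pair or Drude particles — are ordinary atoms flagged `is_auxiliary`:
they enter every charge sum (dipoles, fields) and are excluded from
mass-weighted geometry and heavy-atom selections. Minimum-image distances are
used exactly where a box is present; no box means open boundaries. Binary
trajectory formats go through mdtraj's low-level readers; DCD round trips are
good to ~1e-6 Å, PDB to the format's 1e-3 Å.

## Synthetic builder

The builder exists so that every analysis has exact, force-field-independent
ground truth.

**Rings.** Six ring atoms are placed on a regular hexagon (projected radius
1.45 Å, giving ring bonds within 1.45–1.60 Å for amplitudes up to ~0.6 Å)
with out-of-plane displacements obtained by inverting the Cremer–Pople
projection: z_j = √(2/6)·q₂·cos(φ₂ + 4πj/6) + √(1/6)·q₃·(−1)^j, with
q₂ = Q sin θ, q₃ = Q cos θ. The hexagon is traversed clockwise viewed from
+z so the mean-plane normal (from the sine/cosine-weighted lattice vectors)
is +z and the supplied z values are exactly the measured puckering
displacements; the round trip is exact to machine precision. Default pucker
is the ⁴C₁ chair at Q = 0.57 Å, a typical glucopyranose amplitude.

**Chains.** Residues are rigid glucose templates (equatorial O2/O3/O4 and
C6; anomeric oxygen axial for α, equatorial for β; exocyclic torsion
ω = 60° by default). Chain assembly is z-matrix style: residue i's C1 is
placed by natural-extension (NeRF) with torsion Ψᵢ about the previous
residue's C5–C4–O4 frame, its O5 by torsion Φᵢ, and the rest of the template
is mapped by an exact three-point rigid fit onto (C1, O5, O4ₚᵣₑᵥ). Because
the anchor triangle in the template is congruent to the placed one, measured
Φ/Ψ equal the targets to machine precision — the ±1° tolerances quoted in
tests are slack, not error. Fixed internal coordinates: C–C 1.52 Å, C–O
1.42 Å, glycosidic C1–O4 1.41 Å at a 116° C–O–C angle, O–H 0.96 Å.
Constant (Φ, Ψ) at every linkage realizes the restrained-helix case;
per-linkage lists support alternating-pair targets, cycled starting at
linkage 1. Non-bonded heavy atoms closer than 1.0 Å trigger seeded redraws
of the non-target exocyclic/hydroxyl torsions (≤50), then an error; the
default helix targets never need a redraw, so building is deterministic.

**Charges.** Glucose atoms carry a synthetic neutral charge set (hydroxyl
O −0.65 / H +0.42, ether oxygens −0.36, carbons balancing to zero per
interior residue; the terminal O1/HO1 and HO4 pairs keep the whole chain
neutral). These are plausible magnitudes for testing electrostatics, not a
force field.

**Waters.** Rigid 3-site geometry (O–H 0.9572 Å, H–O–H 104.52°) with charges
O −0.834 / H +0.417 e gives the classic fixed ~2.35 D dipole. The
`3-site+aux` variant moves −0.4 e from O to a massless satellite 0.24 Å
along the H–O–H bisector (toward the hydrogens, M-site-like), preserving net
charge; it exists to exercise auxiliary-site handling, not to model
polarization dynamics. Placement modes: `shell` (2.6–3.4 Å from random
solute hydroxyl oxygens), `cavity` (uniform in a cylinder about the chain's
principal axis, within its axial extent, with a reduced 1.6 Å exclusion
because confined waters sit close to the wall), `bulk` (uniform in a box
with a 2.4 Å solute exclusion). All placement is rejection sampling from a
seeded generator — identical seeds give identical coordinates.

**Ensembles.** Frames are drawn i.i.d. from a discrete mixture of built
conformations (seeded multinomial) and perturbed by isotropic Gaussian noise
of standard deviation σ per coordinate. This emulates a two-state
conformational equilibrium with thermal jitter. It deliberately does *not*
reproduce the time correlation, anharmonic fluctuations, solvent friction or
force-field physics of real MD; passing recovery tests demonstrates the
*estimators* are correct, not that any force field behaves a particular way.

## Analysis conventions and numerical choices

* Dihedrals: IUPAC sign, half-open range [−180°, 180°); trans is reported as
  −180° so the ±180 ambiguity never arises.
* Cremer–Pople: atom order O5→C1→C2→C3→C4→C5 with O5 as index origin; θ ∈
  [0°, 180°] from atan2(q₂, q₃); rings with Q < 1e-6 Å report θ/φ undefined.
  The φ phase depends on the origin convention, which is why it is pinned.
* Superposition: Kabsch SVD with the determinant correction (proper rotations
  only). RMSF uses a two-pass iteratively superposed mean structure as
  reference and averages heavy-atom fluctuations within residues.
* R_ee endpoints are C1 of residue 1 (reducing end) and C4 of residue N —
  the carbons flanking the glycosidic backbone; "termini" has no unique atom
  definition otherwise.
* Free-energy surfaces: 72×72 bins (5°) by default, T = 298 K,
  F = −k_BT ln(P/P_max) so the global minimum is exactly 0; empty bins are
  masked (NaN) rather than capped.
* RDF: bin width 0.05 Å, r_max 10 Å (must be ≤ half the smallest box edge);
  normalization by the mean target density in the box.
* H-bonds: d(D···A) ≤ 3.5 Å and ∠D–H···A ≥ 150°. The geometric criterion and
  both cutoffs are configuration-exposed since conventions vary.
  First-shell cutoff 3.5 Å (a typical hydroxyl–water first RDF minimum);
  cavity radius 4.0 Å (V-type amylose channel scale); water residues
  recognized by name {HOH, TIP3, SWM4, WAT, SOL}.
* Axis alignment: per frame, the gyration-tensor eigenvector of largest
  eigenvalue maps to +x with a deterministic roll; polarity is fixed so the
  reducing end has smaller x. A warning fires when the top two eigenvalues
  are within 5% (poorly defined axis).
* Field profile: sources default to the chain's own atoms (the field the
  chain exerts), solvent excluded unless requested; 2 blocks × 12 equidistant
  points spanning each block's heavy-atom axial extent, endpoints included,
  recomputed per frame. An alternative reading of the 24-point scheme — one
  span with 24 points — is available by passing `n_blocks=1,
  points_per_block=24`. Reported statistics are the mean of per-frame |E⃗|
  with a normal-approximation 95% CI (no autocorrelation correction; the
  synthetic ensembles are i.i.d. by construction, and this is noted in the
  output metadata for real trajectories).
* Clustering: features are superposed flattened coordinates, so Euclidean
  distance/√n approximates RMSD while keeping centroid arithmetic exact.
  Initialization ranks frames by mean distance to their 10 nearest neighbors
  (densest first) and accepts greedily subject to exceeding the 1/k distance
  quantile from already-chosen seeds — deterministic, density-led, diverse.
  Lloyd iterations stop at centroid shift < 1e-6 or 500 iterations. Model
  selection minimizes the Davies–Bouldin index (ties → smallest k); an
  optional elbow criterion (maximum second difference of the DB curve) is
  available but off by default. Representatives are the frames nearest each
  centroid.

## Problem sizes

Tests and the demo pipeline run on 6–12-residue chains, tens of waters and
25–200 frames; the isotropic-noise RMSF check uses 2000 frames because the
σ√3 closed form needs that sampling to hold within 5%, and the uniform-fluid
RDF check uses 125 reference points × 5000 ideal-gas targets × 20 frames with
0.2 Å bins so the ±0.05 flatness band tests the normalization rather than
shot noise. These sizes are the package's chosen defaults for exercising the
estimators; all scale linearly in frames and atoms.

## Known limitations

* The builder's geometry is idealized (fixed bond lengths/angles, no
  hydrogens on carbons, no energy minimization); it is a measurement ground
  truth, not a physical model.
* Polarization is emulated by *fixed* auxiliary charges; no induced-dipole
  self-consistency, Ewald summation or dielectric screening anywhere.
* Clustering distance is the flattened-coordinate approximation to RMSD, not
  exact per-pair superposition; the discrepancy is bounded in tests (row
  distance vs direct pairwise RMSD correlation > 0.99).
* Orthorhombic boxes only; no triclinic support, no PSF/TOP parsing, no
  velocities.
* H-bond kinetics (lifetimes, autocorrelation) are out of scope.
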