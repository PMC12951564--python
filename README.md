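# glycotraj

Analysis toolkit for molecular-dynamics trajectories of polysaccharides —
amylose-like α(1→4) and cellulose-like β(1→4) glucans — covering the full
descriptor battery used in comparative force-field studies of these chains:

* **conformation** — Kabsch-superposed RMSD and per-residue RMSF, radius of
  gyration *R*g, end-to-end distance *R*ee, glycosidic torsions
  Φ = O5ᵢ–C1ᵢ–O4ᵢ₋₁–C4ᵢ₋₁ and Ψ = C1ᵢ–O4ᵢ₋₁–C4ᵢ₋₁–C5ᵢ₋₁, Cremer–Pople ring
  puckering (Q, θ, φ), and Boltzmann-inverted 2D Φ/Ψ free-energy surfaces
  F = −k_BT ln(P/P_max);
* **hydration** — per-oxygen-type radial distribution functions g(r),
  geometric hydrogen-bond detection (d(D···A) ≤ 3.5 Å, ∠D–H···A ≥ 150°)
  classified as intra-chain / inter-chain / chain–water, first-hydration-shell
  and helix-cavity-confined water selection;
* **electrostatics** — group dipole moments μ⃗ = Σ qᵢ(r⃗ᵢ − r⃗_ref) in Debye
  (auxiliary lone-pair/Drude-style charge sites included as point charges),
  helix-axis alignment to +x, axis-decomposed water dipole components, and the
  Coulomb electric-field profile E⃗ = Σᵢ k Qᵢ r̂/r² (MV/cm) evaluated at 24
  dynamic points along the chain axis (two 6-residue blocks × 12 equidistant
  points, point 1 nearest the reducing end);
* **clustering** — deterministic density-diversity-seeded k-means over
  superposed heavy-atom coordinates with Davies–Bouldin model selection,
  cluster populations and nearest-to-centroid representative frames.

Because real glucan trajectories require an MD engine, the package ships a
**synthetic builder** that constructs idealized chains from internal
coordinates with *exact* glycosidic torsions and ring puckers, places rigid
3-site waters (shell / cavity / bulk modes, optional auxiliary charge site),
and draws frame ensembles from discrete conformational mixtures with Gaussian
noise. Every analysis stage is therefore testable against known ground truth.

## Worked example

Build a 12-residue restrained amylose helix (Φ = 103°, Ψ = 115°), measure its
torsions, pucker and end-to-end distance:

```python
import numpy as np
from glycotraj import builder, conformation as conf
from glycotraj.model import Trajectory

spec = builder.ChainSpec(n_residues=12, linkage="alpha-1-4",
                         phi_deg=103.0, psi_deg=115.0)
top, frame = builder.build_chain(spec)
traj = Trajectory(topology=top, frames=[frame])

tors = conf.glycosidic_torsions(traj, "A")[0]
print(len(tors), np.mean([t.phi_deg for t in tors]), np.mean([t.psi_deg for t in tors]))
# 11 103.0 114.99999999999999

pucker = conf.ring_pucker_series(traj, "A")[0][0]
print(round(pucker.Q, 2), round(pucker.theta_deg, 1))
# 0.57 0.0

print(round(conf.end_to_end(frame, top, "A"), 2))
# 32.51
```

All 11 linkages measure exactly the targets (the builder is an
internal-coordinate construction, not a minimization), every ring is a ⁴C₁
chair (θ = 0°), and the constant-(Φ,Ψ) helix is compact — 32.5 Å end to end,
versus 50.9 Å for the same targets built with a cellulose-like β(1→4)
linkage, whose equatorial anomeric geometry extends the chain.

The same analyses run from the shell on files (PDB/DCD/XTC plus a sidecar
charge table, since PDB carries no charges):

```sh
glycotraj build --n-residues 12 --n-waters 20 --water-mode cavity --out helix
glycotraj conform --traj helix.pdb --top helix.pdb --charges helix.charges --out out
glycotraj run --config run.yml     # configuration-driven multi-stage run
```

Outputs are tidy TSV per stage plus a JSON manifest (version, parameters,
seed, input hashes) that makes any run reproducible.

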