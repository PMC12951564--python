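"""Structural descriptors for glucan chains.

Covers superposition-based RMSD/RMSF, radius of gyration, end-to-end
distance, glycosidic torsions, Cremer-Pople ring puckering and 2D torsional
free-energy surfaces.

Conventions used throughout:

* dihedrals follow the IUPAC sign rule and live in the half-open range
  [-180, 180) degrees (trans is reported as -180);
* the glycosidic torsions of a 1->4 glucan are
  Phi = O5(i)-C1(i)-O4(i-1)-C4(i-1) and Psi = C1(i)-O4(i-1)-C4(i-1)-C5(i-1),
  with residue i the one nearer the nonreducing end;
* Cremer-Pople puckering uses the atom order O5, C1, C2, C3, C4, C5 with O5
  as the index origin, so theta = 0 is the 4C1 chair, theta = 180 the 1C4
  chair and theta = 90 the boat/twist-boat equator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Frame, Topology, Trajectory

KB_KCAL = 0.0019872041  # Boltzmann constant, kcal/mol/K

RING_ATOM_ORDER = ("O5", "C1", "C2", "C3", "C4", "C5")


# ---------------------------------------------------------------------------
# dihedral primitive

def measure_dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle p1-p2-p3-p4 in degrees, in [-180, 180).

    Positive when, looking from p2 towards p3, the far bond p3->p4 is rotated
    clockwise from the near bond p2->p1 (IUPAC convention).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    for a, b in ((p1, p2), (p2, p3), (p3, p4)):
        if np.linalg.norm(b - a) < 1e-10:
            raise ValueError("degenerate dihedral: consecutive points coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("degenerate dihedral: three consecutive points collinear")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2) / np.linalg.norm(b2)
    angle = np.degrees(np.arctan2(y, x))
    return float(angle if angle < 180.0 else angle - 360.0)


def wrap_angle(angle_deg: float | np.ndarray) -> float | np.ndarray:
    """Wrap angle(s) into [-180, 180)."""
    return (np.asarray(angle_deg) + 180.0) % 360.0 - 180.0


# ---------------------------------------------------------------------------
# glycosidic torsions

@dataclass
class GlycosidicTorsion:
    linkage_index: int  # 0-based, linkage i joins residue i and residue i+1
    phi_deg: float
    psi_deg: float


def glycosidic_torsions(traj: Trajectory, chain_id: str) -> list[list[GlycosidicTorsion]]:
    """Per-frame Phi/Psi for every glycosidic linkage of a chain.

    Returns a list (one entry per frame) of ``n_residues - 1`` torsions each,
    ordered from the reducing end.
    """
    top = traj.topology
    residues = top.residues(chain_id)
    if len(residues) < 2:
        raise ValueError(f"chain {chain_id!r} has {len(residues)} residue(s); need >= 2 for a linkage")
    quads = []  # (phi atom indices, psi atom indices) per linkage
    for k in range(len(residues) - 1):
        prev_idx, _ = residues[k]
        next_idx, _ = residues[k + 1]
        o5 = top.find_atom(chain_id, next_idx, "O5").index
        c1 = top.find_atom(chain_id, next_idx, "C1").index
        o4 = top.find_atom(chain_id, prev_idx, "O4").index
        c4 = top.find_atom(chain_id, prev_idx, "C4").index
        c5 = top.find_atom(chain_id, prev_idx, "C5").index
        quads.append(((o5, c1, o4, c4), (c1, o4, c4, c5)))
    out = []
    for frame in traj.frames:
        xyz = frame.coordinates
        per_frame = []
        for k, (phi_q, psi_q) in enumerate(quads):
            phi = measure_dihedral(*(xyz[i] for i in phi_q))
            psi = measure_dihedral(*(xyz[i] for i in psi_q))
            per_frame.append(GlycosidicTorsion(k, phi, psi))
        out.append(per_frame)
    return out


# ---------------------------------------------------------------------------
# Cremer-Pople puckering

@dataclass
class PuckerState:
    """Cremer-Pople puckering amplitude and angles for a six-membered ring.

    theta/phi are undefined (None) for an essentially planar ring (Q < 1e-6 A).
    """

    Q: float
    theta_deg: float | None
    phi_deg: float | None

    @property
    def is_planar(self) -> bool:
        return self.theta_deg is None


def cremer_pople(ring_coords: np.ndarray) -> PuckerState:
    """Cremer-Pople (Q, theta, phi) for six ring atoms ordered O5,C1,...,C5.

    The mean plane is defined by the sine- and cosine-weighted lattice vectors
    of the centered coordinates; out-of-plane displacements z_j then give the
    puckering coordinates q2, phi2 (phase) and q3 (alternating-sign chair
    mode), with Q = sqrt(q2^2 + q3^2) and theta = atan2(q2, q3) in [0, 180].
    """
    r = np.asarray(ring_coords, dtype=float)
    if r.shape != (6, 3):
        raise ValueError("expected six 3-vectors")
    N = 6
    r = r - r.mean(axis=0)
    j = np.arange(N)
    r_sin = (r * np.sin(2 * np.pi * j / N)[:, None]).sum(axis=0)
    r_cos = (r * np.cos(2 * np.pi * j / N)[:, None]).sum(axis=0)
    normal = np.cross(r_sin, r_cos)
    norm = np.linalg.norm(normal)
    if norm < 1e-12:
        raise ValueError("degenerate ring geometry: cannot define a mean plane")
    normal /= norm
    z = r @ normal
    q2_cos = np.sqrt(2.0 / N) * (z * np.cos(4 * np.pi * j / N)).sum()
    q2_sin = -np.sqrt(2.0 / N) * (z * np.sin(4 * np.pi * j / N)).sum()
    q3 = np.sqrt(1.0 / N) * (z * (-1.0) ** j).sum()
    q2 = np.hypot(q2_cos, q2_sin)
    Q = float(np.hypot(q2, q3))
    if Q < 1e-6:
        return PuckerState(Q=Q, theta_deg=None, phi_deg=None)
    theta = float(np.degrees(np.arctan2(q2, q3)))
    phi2 = float(np.degrees(np.arctan2(q2_sin, q2_cos))) % 360.0
    return PuckerState(Q=Q, theta_deg=theta, phi_deg=phi2)


def ring_pucker_series(traj: Trajectory, chain_id: str) -> list[list[PuckerState]]:
    """Cremer-Pople state per residue per frame for a glucan chain."""
    top = traj.topology
    rings = []
    for res_idx, _ in top.residues(chain_id):
        rings.append([top.find_atom(chain_id, res_idx, n).index for n in RING_ATOM_ORDER])
    return [
        [cremer_pople(frame.coordinates[idx]) for idx in rings] for frame in traj.frames
    ]


# ---------------------------------------------------------------------------
# superposition and RMSD/RMSF

def superpose(
    mobile: Frame | np.ndarray,
    reference: Frame | np.ndarray,
    selection: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Kabsch least-squares superposition of mobile onto reference.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits the reference over the
    selected atoms; the RMSD is the global minimum over rigid transforms.
    """
    xm = mobile.coordinates if isinstance(mobile, Frame) else np.asarray(mobile, float)
    xr = reference.coordinates if isinstance(reference, Frame) else np.asarray(reference, float)
    if xm.shape != xr.shape:
        raise ValueError(f"coordinate shape mismatch: {xm.shape} vs {xr.shape}")
    sel = np.arange(xm.shape[0]) if selection is None else np.asarray(selection, int)
    if sel.size < 3:
        raise ValueError("superposition needs at least 3 selected atoms")
    a = xm[sel] - xm[sel].mean(axis=0)
    b = xr[sel] - xr[sel].mean(axis=0)
    if np.linalg.matrix_rank(np.vstack([a, b])) < 2:
        raise ValueError("selected atoms are collinear; superposition is ill-defined")
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = xr[sel].mean(axis=0) - xm[sel].mean(axis=0) @ rot.T
    fitted = xm[sel] @ rot.T + trans
    rmsd = float(np.sqrt(((fitted - xr[sel]) ** 2).sum(axis=1).mean()))
    return rot, trans, rmsd


def apply_transform(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    return coords @ rotation.T + translation


def rmsd_series(
    traj: Trajectory,
    reference: Frame | None = None,
    selection: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame minimum RMSD to a reference (default: the first frame)."""
    ref = traj.frames[0] if reference is None else reference
    return np.array([superpose(f, ref, selection)[2] for f in traj.frames])


def mean_structure(traj: Trajectory, selection: np.ndarray | None = None, passes: int = 2) -> np.ndarray:
    """Iteratively superposed mean coordinates (all atoms), used as RMSF reference."""
    coords = traj.coordinates_array()
    mean = coords[0]
    for _ in range(passes):
        fitted = []
        for x in coords:
            rot, trans, _ = superpose(x, mean, selection)
            fitted.append(apply_transform(x, rot, trans))
        mean = np.mean(fitted, axis=0)
    return mean


def rmsf_per_residue(
    traj: Trajectory, chain_id: str | None = None, heavy_only: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Root-mean-square fluctuation averaged over heavy atoms of each residue.

    Frames are first superposed onto the iterative mean structure (heavy-atom
    fit), then per-atom fluctuations about the mean are averaged (RMS) within
    residues.  Returns ``(residue_indices, rmsf)`` ordered from the reducing
    end.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    top = traj.topology
    sel = top.select(heavy=heavy_only or None, chain_id=chain_id)
    if sel.size == 0:
        raise ValueError("empty selection for RMSF")
    mean = mean_structure(traj, sel)
    coords = traj.coordinates_array()
    sq_disp = np.zeros(top.n_atoms)
    for x in coords:
        rot, trans, _ = superpose(x, mean, sel)
        fitted = apply_transform(x, rot, trans)
        sq_disp += ((fitted - mean) ** 2).sum(axis=1)
    msf = sq_disp / traj.n_frames
    res_ids, values = [], []
    for res_idx, atoms in top.residues(chain_id):
        idx = [a.index for a in atoms if (a.is_heavy or not heavy_only)]
        if not idx:
            continue
        res_ids.append(res_idx)
        values.append(np.sqrt(msf[idx].mean()))
    return np.array(res_ids), np.array(values)


# ---------------------------------------------------------------------------
# size and extension

def radius_of_gyration(
    frame: Frame, topology: Topology, selection: np.ndarray, mass_weighted: bool = True
) -> float:
    """RMS distance of the selected atoms from their (mass-weighted) center."""
    sel = np.asarray(selection, int)
    if sel.size == 0:
        raise ValueError("empty selection for radius of gyration")
    x = frame.coordinates[sel]
    if mass_weighted:
        m = topology.masses()[sel]
        if m.sum() <= 0:
            raise ValueError("mass-weighted Rg requires positive masses")
    else:
        m = np.ones(sel.size)
    center = (m[:, None] * x).sum(axis=0) / m.sum()
    return float(np.sqrt((m * ((x - center) ** 2).sum(axis=1)).sum() / m.sum()))


def end_to_end(frame: Frame, topology: Topology, chain_id: str) -> float:
    """Distance from C1 of residue 1 (reducing end) to C4 of the last residue.

    These carbons flank the glycosidic backbone, giving a well-defined
    "terminus" on both ends of a 1->4 glucan.
    """
    residues = topology.residues(chain_id)
    if len(residues) < 2:
        raise ValueError("end-to-end distance needs a chain of >= 2 residues")
    first_res, _ = residues[0]
    last_res, _ = residues[-1]
    a = topology.find_atom(chain_id, first_res, "C1")
    b = topology.find_atom(chain_id, last_res, "C4")
    return float(np.linalg.norm(frame.coordinates[a.index] - frame.coordinates[b.index]))


# ---------------------------------------------------------------------------
# free-energy surface

@dataclass
class FesGrid:
    phi_edges: np.ndarray
    psi_edges: np.ndarray
    free_energy: np.ndarray  # kcal/mol, masked bins hold nan
    mask: np.ndarray  # True where no samples fell
    counts: np.ndarray
    temperature_K: float


def fes_2d(
    phi_deg: np.ndarray,
    psi_deg: np.ndarray,
    bins: int = 72,
    temperature_K: float = 298.0,
) -> FesGrid:
    """Boltzmann-inverted 2D free-energy surface over (Phi, Psi).

    F = -kB T ln(P / P_max) per bin, so the most populated bin is exactly 0;
    empty bins are masked (nan) rather than capped.  Binning is periodic over
    [-180, 180).
    """
    if bins < 2:
        raise ValueError("need at least 2 bins per axis")
    phi = np.asarray(wrap_angle(np.asarray(phi_deg, float).ravel()))
    psi = np.asarray(wrap_angle(np.asarray(psi_deg, float).ravel()))
    if phi.size == 0:
        raise ValueError("no torsion samples given")
    edges = np.linspace(-180.0, 180.0, bins + 1)
    counts, _, _ = np.histogram2d(phi, psi, bins=[edges, edges])
    mask = counts == 0
    free = np.full_like(counts, np.nan)
    pmax = counts.max()
    free[~mask] = -KB_KCAL * temperature_K * np.log(counts[~mask] / pmax)
    return FesGrid(
        phi_edges=edges, psi_edges=edges, free_energy=free, mask=mask,
        counts=counts, temperature_K=temperature_K,
    )
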