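"""Hydration structure: per-oxygen radial distribution functions,
hydrogen-bond detection/classification, and selection of first-shell and
cavity-confined waters.

Hydrogen bonds use the common geometric MD criterion, donor-acceptor
distance <= 3.5 A and D-H...A angle >= 150 deg (both configurable; the
criterion is reported alongside results).  Bonds are classified by the chain
membership of donor and acceptor: within one solute chain (intra_chain),
between two solute chains (inter_chain), or between solute and water
(chain_water).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model import Frame, Topology, Trajectory, minimum_image


@dataclass
class RdfResult:
    reference_label: str
    bin_centers: np.ndarray  # A
    g_of_r: np.ndarray
    raw_counts: np.ndarray
    bulk_density: float  # target atoms per A^3


def rdf(
    traj: Trajectory,
    reference_atoms: np.ndarray,
    target_atoms: np.ndarray,
    r_max: float = 10.0,
    bin_width: float = 0.05,
    label: str = "",
) -> RdfResult:
    """Radial distribution function g(r) of targets around references.

    g(r) = <counts(r)> / (n_ref * 4 pi r^2 dr * rho_target), with
    minimum-image distances and rho_target the mean target density in the
    box.  Requires a box (normalization needs a bulk density); shared atoms
    between the two selections are self-excluded.
    """
    ref = np.asarray(reference_atoms, int)
    tgt = np.asarray(target_atoms, int)
    if ref.size == 0 or tgt.size == 0:
        raise ValueError("empty reference or target selection for RDF")
    box = traj.frames[0].box
    if box is None:
        raise ValueError("RDF normalization requires a periodic box")
    if r_max > box.min() / 2.0:
        raise ValueError(
            f"r_max {r_max} A exceeds half the smallest box edge ({box.min() / 2:.2f} A)"
        )
    nbins = int(round(r_max / bin_width))
    edges = np.linspace(0.0, r_max, nbins + 1)
    counts = np.zeros(nbins)
    shared = np.intersect1d(ref, tgt)
    for frame in traj.frames:
        d = frame.coordinates[ref][:, None, :] - frame.coordinates[tgt][None, :, :]
        d = minimum_image(d, frame.box)
        r = np.linalg.norm(d, axis=2)
        if shared.size:
            for i, a in enumerate(ref):
                mask = tgt == a
                r[i, mask] = np.inf
        counts += np.histogram(r.ravel(), bins=edges)[0]
    volume = float(np.prod(box))
    rho = tgt.size / volume
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell_vol = 4.0 * np.pi * centers**2 * bin_width
    norm = ref.size * traj.n_frames * shell_vol * rho
    return RdfResult(
        reference_label=label, bin_centers=centers,
        g_of_r=counts / norm, raw_counts=counts, bulk_density=rho,
    )


def rdf_per_oxygen_type(
    traj: Trajectory, chain_id: str, r_max: float = 10.0, bin_width: float = 0.05
) -> dict[str, RdfResult]:
    """RDF of water oxygens around each sugar oxygen type O1..O6."""
    top = traj.topology
    water_o = np.array([a.index for a in top.atoms if a.is_water and a.element == "O"])
    out = {}
    for otype in ("O1", "O2", "O3", "O4", "O5", "O6"):
        ref = top.select(chain_id=chain_id, names=(otype,))
        if ref.size == 0:
            continue
        out[otype] = rdf(traj, ref, water_o, r_max, bin_width, label=otype)
    return out


# ---------------------------------------------------------------------------
# hydrogen bonds

@dataclass
class HBondRecord:
    donor_atom: int
    hydrogen_atom: int
    acceptor_atom: int
    frame: int
    d_DA: float
    angle_DHA: float
    category: str  # intra_chain | inter_chain | chain_water | water_water


def _categorize(top: Topology, donor: int, acceptor: int) -> str:
    d, a = top.atoms[donor], top.atoms[acceptor]
    if d.is_water and a.is_water:
        return "water_water"
    if d.is_water or a.is_water:
        return "chain_water"
    return "intra_chain" if d.chain_id == a.chain_id else "inter_chain"


def detect_hbonds(
    traj: Trajectory,
    d_cut: float = 3.5,
    angle_cut_deg: float = 150.0,
    include_water_water: bool = False,
) -> list[HBondRecord]:
    """Geometric hydrogen-bond detection over all frames.

    Donors are oxygens with at least one bonded hydrogen (oxygens with none
    are skipped with a warning the first time); acceptors are all oxygens.  A
    record is produced for every (frame, D, H, A) with d(D...A) <= d_cut and
    angle(D-H...A) >= angle_cut.  Minimum-image distances when a box is
    present.
    """
    top = traj.topology
    oxygens = np.array([a.index for a in top.atoms if a.element == "O"])
    donors: list[tuple[int, list[int]]] = []
    warned = False
    for i in oxygens:
        hs = top.bonded_hydrogens(int(i))
        if hs:
            donors.append((int(i), hs))
        elif top.atoms[i].name in ("O2", "O3", "O6", "O1") and not warned:
            warnings.warn(f"hydroxyl oxygen {i} has no bonded hydrogen; skipped as donor", stacklevel=2)
            warned = True
    records: list[HBondRecord] = []
    for k, frame in enumerate(traj.frames):
        xyz = frame.coordinates
        box = frame.box
        for d_idx, hs in donors:
            dv = xyz[oxygens] - xyz[d_idx]
            dv = minimum_image(dv, box)
            dist = np.linalg.norm(dv, axis=1)
            near = np.where((dist <= d_cut) & (dist > 1e-6))[0]
            for j in near:
                a_idx = int(oxygens[j])
                if a_idx == d_idx:
                    continue
                cat = _categorize(top, d_idx, a_idx)
                if cat == "water_water" and not include_water_water:
                    continue
                for h_idx in hs:
                    hd = minimum_image(xyz[d_idx] - xyz[h_idx], box)
                    ha = minimum_image(xyz[a_idx] - xyz[h_idx], box)
                    cosang = (hd @ ha) / (np.linalg.norm(hd) * np.linalg.norm(ha))
                    ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
                    if ang >= angle_cut_deg:
                        records.append(
                            HBondRecord(
                                donor_atom=d_idx, hydrogen_atom=h_idx, acceptor_atom=a_idx,
                                frame=k, d_DA=float(dist[j]), angle_DHA=ang, category=cat,
                            )
                        )
    return records


def hbond_counts_by_oxygen(records: list[HBondRecord], topology: Topology, n_frames: int) -> pd.DataFrame:
    """Mean H-bond count per frame, by sugar oxygen type and category.

    Every record involving the solute is attributed to exactly one solute
    oxygen (the donor's if the donor is solute, else the acceptor's).  Ether
    oxygens O4/O5 can only ever appear as acceptors.
    """
    rows = []
    known = ("O1", "O2", "O3", "O4", "O5", "O6")
    for rec in records:
        d, a = topology.atoms[rec.donor_atom], topology.atoms[rec.acceptor_atom]
        solute_atom = d if not d.is_water else a
        if solute_atom.is_water:
            continue
        name = solute_atom.name
        if name not in known:
            warnings.warn(f"unknown solute oxygen name {name!r}; bucketed as 'other'", stacklevel=2)
            name = "other"
        rows.append({"oxygen": name, "category": rec.category})
    if not rows:
        return pd.DataFrame(columns=["oxygen", "category", "mean_per_frame"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["oxygen", "category"]).size().rename("mean_per_frame") / n_frames
    ).reset_index()
    return out


# ---------------------------------------------------------------------------
# water selections

def first_shell_waters(
    frame: Frame, topology: Topology, solute_selection: np.ndarray, cutoff: float = 3.5
) -> list[int]:
    """Water residues whose oxygen lies within ``cutoff`` of any solute heavy
    atom (inclusive boundary)."""
    solute = np.asarray(solute_selection, int)
    water_o = [(a.residue_index, a.index) for a in topology.atoms if a.is_water and a.element == "O"]
    if cutoff <= 0 or not water_o or solute.size == 0:
        return []
    tree = cKDTree(frame.coordinates[solute])
    out = []
    for res, idx in water_o:
        d, _ = tree.query(frame.coordinates[idx])
        if d <= cutoff:
            out.append(res)
    return sorted(set(out))


def confined_waters(
    frame: Frame, topology: Topology, helix_chain: str, cavity_radius: float = 4.0
) -> list[int]:
    """Water residues confined inside the helix cavity.

    A water is confined when its oxygen lies within ``cavity_radius`` of the
    chain's principal axis AND within the chain's axial extent.
    """
    from .electrostatics import principal_axis

    sel = topology.select(heavy=True, chain_id=helix_chain)
    if sel.size < 3:
        raise ValueError("cavity selection: helix axis undefined")
    axis, origin = principal_axis(frame.coordinates[sel])
    proj = (frame.coordinates[sel] - origin) @ axis
    lo, hi = proj.min(), proj.max()
    out = []
    for a in topology.atoms:
        if not (a.is_water and a.element == "O"):
            continue
        v = frame.coordinates[a.index] - origin
        s = float(v @ axis)
        radial = float(np.linalg.norm(v - s * axis))
        if radial <= cavity_radius and lo <= s <= hi:
            out.append(a.residue_index)
    return sorted(set(out))
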