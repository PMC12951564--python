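"""Synthetic glucan and water builder with exact, known ground truth.

Chains are assembled residue-by-residue from internal coordinates (z-matrix
style) with fixed idealized bond lengths and angles, so the only degrees of
freedom are the glycosidic torsions (Phi, Psi) and the per-residue ring
pucker.  A chain built with given targets therefore measures back exactly to
those targets, independent of any force field — which is what makes the
analysis battery testable without MD.

Waters are rigid 3-site molecules (O-H 0.9572 A, H-O-H 104.52 deg, charges
O -0.834 e / H +0.417 e, dipole ~2.35 D).  The ``3-site+aux`` variant moves
-0.4 e from the oxygen to a massless satellite site 0.24 A along the H-O-H
bisector, mimicking lone-pair/Drude charge displacement without polarization
dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conformation import PuckerState, cremer_pople, RING_ATOM_ORDER
from .model import Atom, Frame, Topology, Trajectory

# idealized internal coordinates (angstrom, degrees)
BOND_CC = 1.52
BOND_CO = 1.42
BOND_GLYCOSIDIC = 1.41
BOND_OH = 0.96
ANGLE_COC_LINK = 116.0  # C4-O4-C1 glycosidic angle
RING_RADIUS = 1.45  # projected hexagon radius; ring bonds land in 1.45-1.60 A
DEFAULT_Q = 0.57  # chair amplitude typical of glucopyranose

CHAIR_4C1 = PuckerState(Q=DEFAULT_Q, theta_deg=0.0, phi_deg=0.0)

MASSES = {"C": 12.011, "O": 15.999, "H": 1.008, "X": 0.0}

#: per-atom partial charges for a glucose residue; interior residues are
#: exactly neutral, the terminal hydroxyl pairs (O1/HO1, O4/HO4) keep the
#: whole chain neutral.
GLC_CHARGES = {
    "C1": 0.39, "C2": 0.19, "C3": 0.19, "C4": 0.25, "C5": 0.26, "C6": 0.13,
    "O5": -0.36, "O4": -0.36, "O2": -0.65, "O3": -0.65, "O6": -0.65,
    "HO2": 0.42, "HO3": 0.42, "HO6": 0.42,
    "O1": -0.78, "HO1": 0.42, "HO4": 0.36,
}

WATER_OH = 0.9572
WATER_HOH = 104.52
WATER_CHARGES = {"O": -0.834, "H": 0.417}
AUX_CHARGE = -0.4
AUX_OFFSET = 0.24


# ---------------------------------------------------------------------------
# geometric primitives

def place_nerf(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D on chain a-b-c with |c-d| = bond, angle(b,c,d) and
    torsion(a,b,c,d) as given (natural extension reference frame)."""
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-bond * np.cos(theta), bond * np.sin(theta) * np.cos(chi), bond * np.sin(theta) * np.sin(chi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def ideal_ring_coords(z: np.ndarray, radius: float = RING_RADIUS) -> np.ndarray:
    """Six ring atoms on a regular hexagon with prescribed out-of-plane z.

    The hexagon is traversed clockwise when viewed from +z, which makes the
    Cremer-Pople mean-plane normal +z, so the supplied z values ARE the
    puckering displacements (e.g. z_j = (-1)^j z0 gives the theta = 0 chair).
    """
    z = np.asarray(z, float)
    if z.shape != (6,):
        raise ValueError("need exactly six z displacements")
    j = np.arange(6)
    ang = -2.0 * np.pi * j / 6.0
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang), z])


def pucker_displacements(pucker: PuckerState) -> np.ndarray:
    """Out-of-plane z_j realizing the given (Q, theta, phi), inverse of the
    Cremer-Pople projection."""
    if pucker.Q < 0:
        raise ValueError("puckering amplitude Q must be >= 0")
    theta = np.radians(pucker.theta_deg if pucker.theta_deg is not None else 0.0)
    phi2 = np.radians(pucker.phi_deg if pucker.phi_deg is not None else 0.0)
    q2 = pucker.Q * np.sin(theta)
    q3 = pucker.Q * np.cos(theta)
    j = np.arange(6)
    return np.sqrt(2.0 / 6.0) * q2 * np.cos(phi2 + 4 * np.pi * j / 6.0) + np.sqrt(
        1.0 / 6.0
    ) * q3 * (-1.0) ** j


def _tetrahedral_directions(r_c, r_prev, r_next) -> tuple[np.ndarray, np.ndarray]:
    """The two open substituent directions at a ring atom, (axial-ish, equatorial-ish)
    classified by |projection| on the local ring normal."""
    v1 = r_prev - r_c
    v1 /= np.linalg.norm(v1)
    v2 = r_next - r_c
    v2 /= np.linalg.norm(v2)
    bis = -(v1 + v2)
    bis /= np.linalg.norm(bis)
    n = np.cross(v1, v2)
    n /= np.linalg.norm(n)
    delta = np.radians(54.75)
    d_plus = np.cos(delta) * bis + np.sin(delta) * n
    d_minus = np.cos(delta) * bis - np.sin(delta) * n
    if abs(d_plus @ n) >= abs(d_minus @ n):
        return d_plus, d_minus
    return d_minus, d_plus


@dataclass
class _Residue:
    """A rigid residue template: named coordinates plus intra-residue bonds."""

    coords: dict[str, np.ndarray]
    bonds: list[tuple[str, str]]


def _glucose_template(
    pucker: PuckerState,
    linkage: str,
    omega_deg: float = 60.0,
    hydroxyl_torsions: dict[str, float] | None = None,
) -> _Residue:
    """Idealized glucopyranose with ring pucker exactly as requested.

    ``OLINK`` marks the glycosidic-oxygen direction at C1 (axial for
    alpha-1-4, equatorial for beta-1-4); it is replaced by the previous
    residue's O4 during chain assembly, or renamed O1 at the reducing end.
    """
    ht = hydroxyl_torsions or {}
    z = pucker_displacements(pucker)
    ring = ideal_ring_coords(z)
    names = list(RING_ATOM_ORDER)  # O5, C1, C2, C3, C4, C5
    coords = {n: ring[i] for i, n in enumerate(names)}
    normal = np.array([0.0, 0.0, 1.0])
    bonds = [("O5", "C1"), ("C1", "C2"), ("C2", "C3"), ("C3", "C4"), ("C4", "C5"), ("C5", "O5")]

    ring_cycle = names
    def neighbors(name: str) -> tuple[np.ndarray, np.ndarray]:
        i = ring_cycle.index(name)
        return coords[ring_cycle[i - 1]], coords[ring_cycle[(i + 1) % 6]]

    # equatorial hydroxyls O2, O3, O4 (glucose stereochemistry)
    for carbon, oxy in (("C2", "O2"), ("C3", "O3"), ("C4", "O4")):
        p, n_ = neighbors(carbon)
        _, eq = _tetrahedral_directions(coords[carbon], p, n_)
        coords[oxy] = coords[carbon] + BOND_CO * eq
        bonds.append((carbon, oxy))
    # exocyclic C6 equatorial on C5, then O6 set by the omega torsion
    p, n_ = neighbors("C5")
    _, eq = _tetrahedral_directions(coords["C5"], p, n_)
    coords["C6"] = coords["C5"] + BOND_CC * eq
    bonds.append(("C5", "C6"))
    coords["O6"] = place_nerf(coords["C4"], coords["C5"], coords["C6"], BOND_CO, 110.0, omega_deg)
    bonds.append(("C6", "O6"))
    # anomeric oxygen direction: axial (alpha) or equatorial (beta) at C1
    p, n_ = neighbors("C1")
    ax, eq = _tetrahedral_directions(coords["C1"], p, n_)
    d = ax if linkage == "alpha-1-4" else eq
    coords["OLINK"] = coords["C1"] + BOND_GLYCOSIDIC * d
    # hydroxyl hydrogens (O4's only at the nonreducing terminus; added later)
    for parent_c, oxy, h in (("C2", "O2", "HO2"), ("C3", "O3", "HO3"), ("C6", "O6", "HO6")):
        grand = {"C2": "C1", "C3": "C2", "C6": "C5"}[parent_c]
        coords[h] = place_nerf(
            coords[grand], coords[parent_c], coords[oxy], BOND_OH, 108.0, ht.get(h, 180.0)
        )
        bonds.append((oxy, h))
    _ = normal
    return _Residue(coords=coords, bonds=bonds)


# ---------------------------------------------------------------------------
# public build operations

def build_ring(pucker: PuckerState) -> tuple[Topology, Frame]:
    """One glucopyranose residue (ring, substituent oxygens, hydroxyl H).

    Cremer-Pople analysis of the returned ring atoms reproduces the requested
    (Q, theta, phi) to machine precision.
    """
    tpl = _glucose_template(pucker, "alpha-1-4")
    tpl.coords["O1"] = tpl.coords.pop("OLINK")
    tpl.bonds.append(("C1", "O1"))
    tpl.coords["HO1"] = place_nerf(
        tpl.coords["O5"], tpl.coords["C1"], tpl.coords["O1"], BOND_OH, 108.0, 180.0
    )
    tpl.bonds.append(("O1", "HO1"))
    tpl.coords["HO4"] = place_nerf(
        tpl.coords["C3"], tpl.coords["C4"], tpl.coords["O4"], BOND_OH, 108.0, 180.0
    )
    tpl.bonds.append(("O4", "HO4"))
    return _residues_to_system([tpl], chain_id="A")


@dataclass
class ChainSpec:
    """Target geometry for one glucan chain.

    ``phi_deg``/``psi_deg`` may be scalars (applied to every linkage — the
    restrained-helix case) or per-linkage sequences of length
    ``n_residues - 1``; alternating pairs are given as e.g. ``[85, 92]``
    cycled in order starting at linkage 1.
    """

    n_residues: int
    linkage: str = "alpha-1-4"
    phi_deg: float | list[float] = 103.0
    psi_deg: float | list[float] = 115.0
    pucker: PuckerState | list[PuckerState] = field(default_factory=lambda: CHAIR_4C1)

    def __post_init__(self) -> None:
        if self.n_residues < 2:
            raise ValueError("a chain needs at least 2 residues (no linkage otherwise)")
        if self.linkage not in ("alpha-1-4", "beta-1-4"):
            raise ValueError(f"unknown linkage {self.linkage!r}")

    def _cycle(self, value, n: int) -> list:
        if isinstance(value, (int, float, PuckerState)):
            return [value] * n
        return [value[i % len(value)] for i in range(n)]

    @property
    def linkage_phis(self) -> list[float]:
        return self._cycle(self.phi_deg, self.n_residues - 1)

    @property
    def linkage_psis(self) -> list[float]:
        return self._cycle(self.psi_deg, self.n_residues - 1)

    @property
    def puckers(self) -> list[PuckerState]:
        return self._cycle(self.pucker, self.n_residues)


def _residues_to_system(
    residues: list[_Residue], chain_id: str = "A", resname: str = "GLC"
) -> tuple[Topology, Frame]:
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    bonds: list[tuple[int, int]] = []
    index_of: dict[tuple[int, str], int] = {}
    for ri, res in enumerate(residues):
        for name, xyz in res.coords.items():
            element = "H" if name.startswith("H") else name[0]
            idx = len(atoms)
            index_of[(ri, name)] = idx
            atoms.append(
                Atom(
                    index=idx, name=name, element=element, residue_index=ri,
                    residue_name=resname, chain_id=chain_id,
                    charge=GLC_CHARGES.get(name, 0.0), mass=MASSES[element],
                )
            )
            coords.append(xyz)
        for a, b in res.bonds:
            bonds.append((index_of[(ri, a)], index_of[(ri, b)]))
    top = Topology(atoms=atoms, bonds=bonds)
    return top, Frame(np.array(coords))


def build_chain(spec: ChainSpec, seed: int = 0, max_redraws: int = 50) -> tuple[Topology, Frame]:
    """Assemble an idealized 1->4 glucan with exact glycosidic torsions.

    Residue 1 is the reducing end.  Each subsequent residue is positioned by
    natural-extension placement of its C1 (sets Psi) and O5 (sets Phi),
    followed by an exact rigid fit of the residue template onto those anchor
    atoms — the measured torsions therefore equal the targets to machine
    precision.  Heavy-atom clashes below 1.0 A among non-bonded atoms trigger
    redraws of the non-target exocyclic torsions (up to ``max_redraws``,
    seeded, hence deterministic) and finally an error.
    """
    rng = np.random.default_rng(seed)
    phis, psis, puckers = spec.linkage_phis, spec.linkage_psis, spec.puckers

    for attempt in range(max_redraws + 1):
        if attempt == 0:
            omegas = [60.0] * spec.n_residues
            ho_torsions = [dict()] * spec.n_residues
        else:
            omegas = list(rng.choice([60.0, -60.0, 180.0], size=spec.n_residues))
            ho_torsions = [
                {h: float(rng.uniform(-180, 180)) for h in ("HO2", "HO3", "HO6")}
                for _ in range(spec.n_residues)
            ]
        residues: list[_Residue] = []
        for i in range(spec.n_residues):
            tpl = _glucose_template(puckers[i], spec.linkage, omegas[i], ho_torsions[i])
            if i == 0:
                tpl.coords["O1"] = tpl.coords.pop("OLINK")
                tpl.bonds.append(("C1", "O1"))
                tpl.coords["HO1"] = place_nerf(
                    tpl.coords["O5"], tpl.coords["C1"], tpl.coords["O1"], BOND_OH, 108.0, 180.0
                )
                tpl.bonds.append(("O1", "HO1"))
                residues.append(tpl)
                continue
            prev = residues[i - 1]
            # anchor placement: Psi fixes C1, Phi fixes O5
            c1 = place_nerf(
                prev.coords["C5"], prev.coords["C4"], prev.coords["O4"],
                BOND_GLYCOSIDIC, ANGLE_COC_LINK, psis[i - 1],
            )
            t_c1, t_o5, t_ol = tpl.coords["C1"], tpl.coords["O5"], tpl.coords["OLINK"]
            d_c1o5 = float(np.linalg.norm(t_o5 - t_c1))
            v1 = t_ol - t_c1
            v2 = t_o5 - t_c1
            ang = float(np.degrees(np.arccos(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))))
            o5 = place_nerf(prev.coords["C4"], prev.coords["O4"], c1, d_c1o5, ang, phis[i - 1])
            rot, trans = _fit_three_points(
                np.array([t_c1, t_o5, t_ol]),
                np.array([c1, o5, prev.coords["O4"]]),
            )
            placed = {n: xyz @ rot.T + trans for n, xyz in tpl.coords.items() if n != "OLINK"}
            bonds = [(a, b) for a, b in tpl.bonds]
            if i == spec.n_residues - 1:
                placed["HO4"] = place_nerf(
                    placed["C3"], placed["C4"], placed["O4"], BOND_OH, 108.0, 180.0
                )
                bonds.append(("O4", "HO4"))
            residues.append(_Residue(coords=placed, bonds=bonds))
        top, frame = _residues_to_system(residues, chain_id="A")
        # inter-residue glycosidic bonds
        for i in range(1, spec.n_residues):
            o4_prev = top.find_atom("A", i - 1, "O4").index
            c1_i = top.find_atom("A", i, "C1").index
            top.bonds.append((o4_prev, c1_i))
        if not _has_clash(top, frame, threshold=1.0):
            return top, frame
    raise ValueError(
        "persistent steric clash while building chain; the requested (Phi, Psi) "
        "targets are sterically impossible at idealized geometry — change the angles"
    )


def _fit_three_points(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Proper rigid transform mapping three congruent points exactly."""
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    h = (src - sc).T @ (dst - dc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, dc - sc @ rot.T


def _has_clash(top: Topology, frame: Frame, threshold: float = 1.0) -> bool:
    from scipy.spatial import cKDTree

    heavy = top.select(heavy=True)
    bonded = {tuple(sorted(b)) for b in top.bonds}
    tree = cKDTree(frame.coordinates[heavy])
    for i_loc, j_loc in tree.query_pairs(threshold):
        i, j = int(heavy[i_loc]), int(heavy[j_loc])
        if tuple(sorted((i, j))) not in bonded:
            return True
    return False


# ---------------------------------------------------------------------------
# waters

def _water_coords(origin: np.ndarray, rotation: np.ndarray) -> np.ndarray:
    """Rigid water: O at origin, H's in the canonical geometry, rotated."""
    half = np.radians(WATER_HOH / 2.0)
    local = np.array(
        [
            [0.0, 0.0, 0.0],
            [WATER_OH * np.sin(half), WATER_OH * np.cos(half), 0.0],
            [-WATER_OH * np.sin(half), WATER_OH * np.cos(half), 0.0],
        ]
    )
    return local @ rotation.T + origin


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a random unit quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def place_waters(
    solute: tuple[Topology, Frame],
    n_waters: int,
    mode: str = "shell",
    water_model: str = "3-site",
    seed: int = 0,
    cavity_radius: float = 3.0,
    box: np.ndarray | None = None,
) -> tuple[Topology, Frame]:
    """Add rigid waters around (or inside) a solute.

    ``shell``  — oxygens 2.6-3.4 A from randomly chosen solute hydroxyl oxygens;
    ``cavity`` — oxygens inside the helix-cavity cylinder around the chain's
                 principal axis, within its axial extent;
    ``bulk``   — uniform in the box, outside a 2.4 A solute exclusion zone.
    Same seed => identical coordinates.
    """
    if n_waters < 0:
        raise ValueError("n_waters must be >= 0")
    top, frame = solute
    if n_waters == 0:
        return top, frame
    rng = np.random.default_rng(seed)
    solute_heavy = top.select(heavy=True)
    solute_xyz = frame.coordinates[solute_heavy]

    if mode == "shell":
        hydroxyl = top.select(names=("O1", "O2", "O3", "O6"))
        if hydroxyl.size == 0:
            raise ValueError("shell mode needs solute hydroxyl oxygens (O1/O2/O3/O6)")
    elif mode == "cavity":
        from .electrostatics import principal_axis

        chain0 = top.chains[0]
        sel = top.select(heavy=True, chain_id=chain0)
        if sel.size < 3:
            raise ValueError("cavity mode: helix axis undefined for this solute")
        axis, origin = principal_axis(frame.coordinates[sel])
        proj = (frame.coordinates[sel] - origin) @ axis
        axial_lo, axial_hi = proj.min(), proj.max()
        # orthonormal frame perpendicular to the axis
        perp1 = np.cross(axis, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp1) < 1e-6:
            perp1 = np.cross(axis, [0.0, 1.0, 0.0])
        perp1 /= np.linalg.norm(perp1)
        perp2 = np.cross(axis, perp1)
    elif mode == "bulk":
        if box is None:
            lo, hi = solute_xyz.min(axis=0), solute_xyz.max(axis=0)
            box = (hi - lo) + 16.0
            box_origin = lo - 8.0
        else:
            box = np.asarray(box, float)
            box_origin = solute_xyz.mean(axis=0) - box / 2.0
    else:
        raise ValueError(f"unknown water placement mode {mode!r}")

    exclusion = 1.6 if mode == "cavity" else 2.4
    placed_o: list[np.ndarray] = []
    max_attempts = 5000 * n_waters
    attempts = 0
    while len(placed_o) < n_waters:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(f"could not place {n_waters} waters in mode {mode!r}")
        if mode == "shell":
            anchor = frame.coordinates[rng.choice(hydroxyl)]
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            pos = anchor + rng.uniform(2.6, 3.4) * u
        elif mode == "cavity":
            s = rng.uniform(axial_lo, axial_hi)
            r = cavity_radius * np.sqrt(rng.uniform())
            ang = rng.uniform(0, 2 * np.pi)
            pos = origin + s * axis + r * (np.cos(ang) * perp1 + np.sin(ang) * perp2)
        else:
            pos = box_origin + rng.uniform(size=3) * box
        if np.min(np.linalg.norm(solute_xyz - pos, axis=1)) < exclusion:
            continue
        if placed_o and np.min(np.linalg.norm(np.array(placed_o) - pos, axis=1)) < 2.4:
            continue
        placed_o.append(pos)

    atoms = list(top.atoms)
    coords = [frame.coordinates]
    bonds = list(top.bonds)
    with_aux = water_model == "3-site+aux"
    if water_model not in ("3-site", "3-site+aux"):
        raise ValueError(f"unknown water model {water_model!r}")
    next_res = max(a.residue_index for a in atoms) + 1
    for w, opos in enumerate(placed_o):
        wxyz = _water_coords(opos, _random_rotation(rng))
        o_charge = WATER_CHARGES["O"] - AUX_CHARGE if with_aux else WATER_CHARGES["O"]
        idx0 = len(atoms)
        spec = [("O", "O", o_charge, False, wxyz[0]), ("H1", "H", WATER_CHARGES["H"], False, wxyz[1]),
                ("H2", "H", WATER_CHARGES["H"], False, wxyz[2])]
        if with_aux:
            bis = (wxyz[1] + wxyz[2]) / 2.0 - wxyz[0]
            bis /= np.linalg.norm(bis)
            spec.append(("MW", "X", AUX_CHARGE, True, wxyz[0] + AUX_OFFSET * bis))
        for k, (name, elem, q, aux, xyz) in enumerate(spec):
            atoms.append(
                Atom(
                    index=idx0 + k, name=name, element=elem, residue_index=next_res + w,
                    residue_name="HOH", chain_id="W", charge=q, mass=MASSES[elem],
                    is_auxiliary=aux,
                )
            )
            coords.append(xyz[None, :])
        bonds.extend([(idx0, idx0 + 1), (idx0, idx0 + 2)])
        if with_aux:
            bonds.append((idx0, idx0 + 3))
    new_top = Topology(atoms=atoms, bonds=bonds)
    return new_top, Frame(np.vstack(coords), frame.box)


# ---------------------------------------------------------------------------
# ensembles

@dataclass
class EnsembleSpec:
    """A frame ensemble drawn from a mixture of discrete conformational states
    plus isotropic Gaussian coordinate noise."""

    n_frames: int
    noise_sigma_A: float = 0.0
    state_mixture: list[tuple[ChainSpec, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not self.state_mixture:
            raise ValueError("state_mixture must contain at least one state")
        total = sum(f for _, f in self.state_mixture)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"state fractions must sum to 1 (got {total})")
        if self.noise_sigma_A < 0:
            raise ValueError("noise_sigma_A must be >= 0")


def make_ensemble(spec: EnsembleSpec) -> tuple[Trajectory, np.ndarray]:
    """Draw frames from the state mixture and perturb with Gaussian noise.

    Returns the trajectory and the per-frame state labels (ground-truth
    provenance, written to a sidecar file by the pipeline).  All states must
    share one topology (same residue count and linkage).
    """
    rng = np.random.default_rng(spec.seed)
    templates = []
    top0: Topology | None = None
    for chain_spec, _ in spec.state_mixture:
        top, frame = build_chain(chain_spec)
        if top0 is None:
            top0 = top
        elif top.n_atoms != top0.n_atoms:
            raise ValueError("all mixture states must share one topology")
        templates.append(frame.coordinates)
    fractions = np.array([f for _, f in spec.state_mixture])
    labels = rng.choice(len(templates), size=spec.n_frames, p=fractions)
    frames = []
    for lab in labels:
        xyz = templates[lab].copy()
        if spec.noise_sigma_A > 0:
            xyz = xyz + rng.normal(scale=spec.noise_sigma_A, size=xyz.shape)
        frames.append(Frame(xyz))
    assert top0 is not None
    return Trajectory(topology=top0, frames=frames), labels


def verify_ring_roundtrip(pucker: PuckerState) -> PuckerState:
    """Convenience: build a ring and re-measure its pucker (used in tests)."""
    top, frame = build_ring(pucker)
    ring_idx = [top.find_atom("A", 0, n).index for n in RING_ATOM_ORDER]
    return cremer_pople(frame.coordinates[ring_idx])
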