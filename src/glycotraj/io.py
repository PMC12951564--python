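"""Reading and writing topologies, charge tables and trajectories.

PDB carries names and coordinates but no partial charges, so charges (and
masses, and the auxiliary-site flag) come from a sidecar whitespace-delimited
table keyed by ``(atom_name, residue_name)``::

    # atom_name  residue_name  charge  mass  [aux_flag]
    OH2  HOH  -0.834  15.999
    H1   HOH   0.417   1.008

Binary trajectory formats (DCD, XTC) are handled through mdtraj's low-level
format readers/writers; PDB is parsed here directly so that malformed records
can be reported with their line numbers.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .model import Atom, Frame, Topology, Trajectory

# covalent radii (angstrom) for geometric bond inference
_COVALENT_RADII = {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "X": 0.3}


class PDBParseError(ValueError):
    pass


def _guess_element(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    if stripped[0] in "HDT" or (len(name) > 1 and name[0].isdigit() and stripped[0] == "H"):
        return "H"
    return stripped[0].upper()


def _parse_atom_line(line: str, lineno: int) -> dict:
    if len(line.rstrip("\n")) < 54:
        raise PDBParseError(f"line {lineno}: truncated ATOM/HETATM record: {line.rstrip()!r}")
    try:
        return {
            "name": line[12:16].strip(),
            "resname": line[17:21].strip(),
            "chain": line[21].strip() or "A",
            "resseq": int(line[22:26]),
            "xyz": (float(line[30:38]), float(line[38:46]), float(line[46:54])),
            "element": line[76:78].strip() if len(line) >= 78 else "",
        }
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: malformed ATOM/HETATM record: {exc}") from exc


def _read_pdb_models(path: str | Path) -> tuple[list[dict], list[np.ndarray], np.ndarray | None]:
    """Parse a (multi-model) PDB into atom records and per-model coordinates."""
    records: list[dict] = []
    models: list[list[tuple[float, float, float]]] = []
    current: list[tuple[float, float, float]] = []
    box = None
    in_first_model = True
    text = Path(path).read_text()
    if not text.strip():
        raise PDBParseError(f"{path}: empty file")
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "CRYST1":
            edges = np.array([float(line[6:15]), float(line[15:24]), float(line[24:33])])
            if np.all(edges > 1.0):  # PDB convention uses 1x1x1 for "no box"
                box = edges
        elif rec in ("ATOM", "HETATM"):
            parsed = _parse_atom_line(line, lineno)
            if in_first_model:
                records.append(parsed)
            current.append(parsed["xyz"])
        elif rec == "ENDMDL":
            if current:
                models.append(current)
            current = []
            in_first_model = False
    if current:
        models.append(current)
    if not records:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")
    coords = []
    for k, model in enumerate(models):
        arr = np.array(model)
        if arr.shape[0] != len(records):
            raise PDBParseError(
                f"{path}: model {k + 1} has {arr.shape[0]} atoms, expected {len(records)}"
            )
        coords.append(arr)
    return records, coords, box


def read_charge_table(path: str | Path) -> dict[tuple[str, str], tuple[float, float, bool]]:
    """Parse the sidecar charge table into {(atom_name, residue_name): (q, m, aux)}."""
    table: dict[tuple[str, str], tuple[float, float, bool]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) not in (4, 5):
            raise ValueError(f"{path} line {lineno}: expected 4 or 5 fields, got {len(parts)}")
        name, resname = parts[0], parts[1]
        charge, mass = float(parts[2]), float(parts[3])
        aux = len(parts) == 5 and parts[4].lower() in ("1", "true", "aux", "yes")
        table[(name, resname)] = (charge, mass, aux)
    return table


def write_charge_table(topology: Topology, path: str | Path) -> None:
    seen: dict[tuple[str, str], tuple[float, float, bool]] = {}
    for a in topology.atoms:
        seen.setdefault((a.name, a.residue_name), (a.charge, a.mass, a.is_auxiliary))
    with open(path, "w") as fh:
        fh.write("# atom_name residue_name charge mass aux_flag\n")
        for (name, resname), (q, m, aux) in seen.items():
            fh.write(f"{name:6s} {resname:5s} {q: .6f} {m:10.5f} {int(aux)}\n")


def infer_bonds(topology: Topology, frame: Frame, tolerance: float = 1.25) -> list[tuple[int, int]]:
    """Geometric bond inference: pairs closer than tolerance x sum of covalent radii.

    Hydrogens bond only to their single nearest heavy atom; heavy-heavy bonds
    use the radius criterion.  Used when a file format carries no connectivity.
    """
    coords = frame.coordinates
    heavy = [a for a in topology.atoms if not a.is_hydrogen and not a.is_auxiliary]
    if not heavy:
        return []
    heavy_idx = np.array([a.index for a in heavy])
    tree = cKDTree(coords[heavy_idx])
    bonds: set[tuple[int, int]] = set()
    for a in topology.atoms:
        if a.is_auxiliary:
            continue
        ra = _COVALENT_RADII.get(a.element, 0.77)
        if a.is_hydrogen:
            d, j = tree.query(coords[a.index])
            if d < tolerance * (ra + 0.77):
                bonds.add(tuple(sorted((a.index, int(heavy_idx[j])))))
        else:
            rmax = tolerance * (ra + max(_COVALENT_RADII.values()))
            for j in tree.query_ball_point(coords[a.index], rmax):
                b = topology.atoms[heavy_idx[j]]
                if b.index <= a.index:
                    continue
                rb = _COVALENT_RADII.get(b.element, 0.77)
                d = np.linalg.norm(coords[a.index] - coords[b.index])
                if d < tolerance * (ra + rb):
                    bonds.add((a.index, b.index))
    return sorted(bonds)


def read_structure(
    path: str | Path, charge_table: str | Path | None = None
) -> tuple[Topology, Frame]:
    """Read a PDB file (first model) and optionally attach charges/masses.

    Returns the topology, with geometrically inferred bonds, and the first
    coordinate frame.  Without a charge table all charges are zero.
    """
    records, coords, box = _read_pdb_models(path)
    table = read_charge_table(charge_table) if charge_table is not None else None

    atoms = []
    resmap: dict[tuple[str, int], int] = {}
    for i, rec in enumerate(records):
        key = (rec["chain"], rec["resseq"])
        if key not in resmap:
            resmap[key] = len(resmap)
        element = rec["element"] or _guess_element(rec["name"])
        charge, mass, aux = 0.0, 0.0, False
        if table is not None:
            entry = table.get((rec["name"], rec["resname"]))
            if entry is None:
                raise ValueError(
                    f"no charge-table entry for atom {rec['name']!r} in residue "
                    f"{rec['resname']!r} (table given, so every atom needs one)"
                )
            charge, mass, aux = entry
        atoms.append(
            Atom(
                index=i,
                name=rec["name"],
                element="X" if aux else element,
                residue_index=resmap[key],
                residue_name=rec["resname"],
                chain_id=rec["chain"],
                charge=charge,
                mass=mass,
                is_auxiliary=aux,
            )
        )
    if table is not None:
        used = {(a.name, a.residue_name) for a in atoms}
        for key in table:
            if key not in used:
                warnings.warn(f"charge-table entry {key} matches no atom", stacklevel=2)
    frame = Frame(coords[0], box)
    topology = Topology(atoms=atoms)
    topology.bonds = infer_bonds(topology, frame)
    return topology, frame


def read_trajectory(path: str | Path, topology: Topology) -> Trajectory:
    """Read a multi-model PDB, DCD or XTC trajectory against a known topology."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".pdb", ".ent"):
        _, coords, box = _read_pdb_models(path)
        frames = [Frame(c, box) for c in coords]
    elif suffix == ".dcd":
        from mdtraj.formats import DCDTrajectoryFile

        with DCDTrajectoryFile(str(path)) as fh:
            xyz, cell_lengths, _ = fh.read()
        if xyz is None or len(xyz) == 0:
            raise ValueError(f"{path}: no frames in DCD file")
        frames = [
            Frame(xyz[k], None if cell_lengths is None or np.all(cell_lengths[k] <= 1) else cell_lengths[k])
            for k in range(len(xyz))
        ]
    elif suffix == ".xtc":
        from mdtraj.formats import XTCTrajectoryFile

        with XTCTrajectoryFile(str(path)) as fh:
            xyz, _, _, boxvecs = fh.read()
        if xyz is None or len(xyz) == 0:
            raise ValueError(f"{path}: no frames in XTC file")
        frames = []
        for k in range(len(xyz)):
            box = None
            if boxvecs is not None:
                edges = np.diag(boxvecs[k]) * 10.0
                if np.all(edges > 0):
                    box = edges
            frames.append(Frame(xyz[k] * 10.0, box))  # nm -> angstrom
    else:
        raise ValueError(f"unsupported trajectory format: {suffix!r}")
    n = topology.n_atoms
    for k, f in enumerate(frames):
        if f.n_atoms != n:
            raise ValueError(
                f"frame {k}: trajectory has {f.n_atoms} atoms but topology has {n}"
            )
    return Trajectory(topology=topology, frames=frames)


def _format_pdb_atom(serial: int, atom: Atom, xyz: np.ndarray) -> str:
    name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
    return (
        f"ATOM  {min(serial, 99999):5d} {name:4s} {atom.residue_name:<4s}"
        f"{atom.chain_id[:1]}{(atom.residue_index % 9999) + 1:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00          "
        f"{atom.element:>2s}\n"
    )


def write_pdb(topology: Topology, frames: list[Frame] | Frame, path: str | Path) -> None:
    """Write one or more frames as a (multi-model) PDB file."""
    if isinstance(frames, Frame):
        frames = [frames]
    with open(path, "w") as fh:
        if frames[0].box is not None:
            a, b, c = frames[0].box
            fh.write(f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}  90.00  90.00  90.00 P 1           1\n")
        multi = len(frames) > 1
        for m, frame in enumerate(frames, start=1):
            if multi:
                fh.write(f"MODEL     {m:4d}\n")
            prev_chain = None
            serial = 0
            for atom in topology.atoms:
                if prev_chain is not None and atom.chain_id != prev_chain:
                    fh.write("TER\n")
                prev_chain = atom.chain_id
                serial += 1
                fh.write(_format_pdb_atom(serial, atom, frame.coordinates[atom.index]))
            fh.write("TER\n")
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def write_trajectory(traj: Trajectory, path: str | Path, format: str = "multi-model-PDB") -> None:
    """Write a trajectory as multi-model PDB or DCD.

    Round-tripping through either format preserves coordinates to better than
    1e-3 angstrom (PDB is fixed to 3 decimals; DCD is single precision).
    """
    path = Path(path)
    if format.lower() in ("multi-model-pdb", "pdb"):
        write_pdb(traj.topology, traj.frames, path)
    elif format.lower() == "dcd":
        from mdtraj.formats import DCDTrajectoryFile

        xyz = traj.coordinates_array().astype(np.float32)
        boxes = None
        if traj.frames[0].box is not None:
            boxes = np.stack([f.box for f in traj.frames]).astype(np.float32)
        with DCDTrajectoryFile(str(path), "w") as fh:
            if boxes is not None:
                fh.write(xyz, cell_lengths=boxes, cell_angles=np.full((len(xyz), 3), 90.0))
            else:
                fh.write(xyz)
    else:
        raise ValueError(f"unsupported output format: {format!r} (use multi-model-PDB or DCD)")
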