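"""Internal data model shared by every analysis stage.

Coordinates are stored in angstroms, charges in elementary-charge units and
masses in amu.  Atom and residue indices are 0-based internally; report
writers convert to 1-based labels.  Auxiliary sites (Drude-particle or
lone-pair stand-ins) are ordinary atoms flagged ``is_auxiliary``: they carry
charge and participate in every electrostatic sum, but are excluded from
mass-weighted geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

#: residue names recognised as water (config-extensible at call sites)
WATER_RESNAMES = ("HOH", "TIP3", "SWM4", "WAT", "SOL")


@dataclass
class Atom:
    index: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    charge: float = 0.0
    mass: float = 0.0
    is_auxiliary: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("atom name must be nonempty")
        if not np.isfinite(self.charge):
            raise ValueError(f"atom {self.index}: charge must be finite")
        if self.mass < 0:
            raise ValueError(f"atom {self.index}: mass must be >= 0")
        if self.mass == 0 and not self.is_auxiliary and self.element != "X":
            # massless real atoms are suspicious but tolerated for plumbing;
            # auxiliary sites are the intended massless case
            pass

    @property
    def is_water(self) -> bool:
        return self.residue_name in WATER_RESNAMES

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"

    @property
    def is_heavy(self) -> bool:
        return self.element != "H" and not self.is_auxiliary


@dataclass
class Topology:
    """Ordered atom list plus covalent bonds and chain bookkeeping."""

    atoms: list[Atom] = field(default_factory=list)
    bonds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, a in enumerate(self.atoms):
            if a.index != i:
                raise ValueError(f"atom indices must be contiguous (atom {i} has index {a.index})")
        n = len(self.atoms)
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) references missing atom")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def chains(self) -> list[str]:
        seen: list[str] = []
        for a in self.atoms:
            if a.chain_id not in seen:
                seen.append(a.chain_id)
        return seen

    def chain_atoms(self, chain_id: str) -> np.ndarray:
        idx = np.array([a.index for a in self.atoms if a.chain_id == chain_id], dtype=int)
        if idx.size == 0:
            raise KeyError(f"chain {chain_id!r} not found in topology")
        return idx

    def residues(self, chain_id: str | None = None) -> list[tuple[int, list[Atom]]]:
        """Residues in order of first appearance as (residue_index, atoms)."""
        out: dict[int, list[Atom]] = {}
        for a in self.atoms:
            if chain_id is not None and a.chain_id != chain_id:
                continue
            out.setdefault(a.residue_index, []).append(a)
        return sorted(out.items())

    def select(
        self,
        *,
        heavy: bool = False,
        chain_id: str | None = None,
        water: bool | None = None,
        names: Sequence[str] | None = None,
    ) -> np.ndarray:
        """Index array for a simple attribute-based selection."""
        keep = []
        for a in self.atoms:
            if heavy and not a.is_heavy:
                continue
            if chain_id is not None and a.chain_id != chain_id:
                continue
            if water is not None and a.is_water != water:
                continue
            if names is not None and a.name not in names:
                continue
            keep.append(a.index)
        return np.array(keep, dtype=int)

    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    def bonded_hydrogens(self, heavy_index: int) -> list[int]:
        out = []
        for i, j in self.bonds:
            if i == heavy_index and self.atoms[j].is_hydrogen:
                out.append(j)
            elif j == heavy_index and self.atoms[i].is_hydrogen:
                out.append(i)
        return out

    def find_atom(self, chain_id: str, residue_index: int, name: str) -> Atom:
        for a in self.atoms:
            if a.chain_id == chain_id and a.residue_index == residue_index and a.name == name:
                return a
        raise KeyError(
            f"atom {name!r} not found in residue {residue_index} of chain {chain_id!r}"
        )


@dataclass
class Frame:
    """One set of coordinates (angstrom), with an optional orthorhombic box."""

    coordinates: np.ndarray
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be an (n_atoms, 3) array")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or np.any(self.box <= 0):
                raise ValueError("box must be three positive edge lengths")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]

    def copy(self) -> "Frame":
        return Frame(self.coordinates.copy(), None if self.box is None else self.box.copy())


@dataclass
class Trajectory:
    topology: Topology
    frames: list[Frame]
    timestep_ps: float | None = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        n = self.topology.n_atoms
        for k, f in enumerate(self.frames):
            if f.n_atoms != n:
                raise ValueError(
                    f"frame {k} has {f.n_atoms} atoms but topology has {n}"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def coordinates_array(self) -> np.ndarray:
        """Stacked (n_frames, n_atoms, 3) coordinate array."""
        return np.stack([f.coordinates for f in self.frames])


def minimum_image(vectors: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors.

    With no box, vectors are returned unchanged (open boundaries).
    """
    if box is None:
        return vectors
    return vectors - box * np.round(vectors / box)
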