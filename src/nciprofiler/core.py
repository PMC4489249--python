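"""Core domain model: atoms, residues, structures and binding sites.

The model is deliberately small: coordinates live in numpy arrays, chemistry
annotations (bonds, element, hydrogen flags) are plain attributes, and all
perception logic lives in the other modules. A :class:`Structure` holds the
residues of one PDB model; a :class:`BindingSite` is one ligand (possibly a
composite of several covalently linked HET residues) plus the protein
residues and waters within a distance envelope of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

#: Three-letter codes of the 20 standard amino acids.
STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Residue codes treated as water.
WATER_CODES = frozenset({"HOH", "DOD", "WAT"})

#: Covalent radii in Angstrom, used for distance-based bond inference.
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39, "B": 0.84, "SE": 1.20,
}

HALOGENS = frozenset({"F", "CL", "BR", "I"})

#: Residue kinds.
KIND_PROTEIN = "protein"
KIND_WATER = "water"
KIND_LIGAND_CANDIDATE = "ligand-candidate"
KIND_EXCLUDED = "excluded"


@dataclass
class Atom:
    """One atom of a PDB model, with connectivity.

    ``coords`` is a length-3 float array in Angstrom.  ``parent`` is the key
    of the residue the atom belongs to ("chain:number:icode").
    ``bonded_serials`` is kept symmetric by the parser/hydrogenator.
    """

    serial: int
    name: str
    element: str
    coords: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0
    parent: str = ""
    bonded_serials: list[int] = field(default_factory=list)
    is_hydrogen: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: coords must be 3 finite numbers")
        self.element = self.element.upper()
        self.is_hydrogen = self.element in ("H", "D")

    def __repr__(self) -> str:  # compact; full dataclass repr is noisy
        x, y, z = self.coords
        return f"<Atom {self.serial} {self.name} {self.element} ({x:.2f},{y:.2f},{z:.2f})>"


@dataclass
class Residue:
    """A residue: one chain/number/icode triple with its atoms and a kind."""

    chain: str
    number: int
    icode: str
    code: str
    atoms: list[Atom] = field(default_factory=list)
    kind: str = KIND_LIGAND_CANDIDATE
    exclusion_reason: str = ""

    @property
    def key(self) -> str:
        return f"{self.chain}:{self.number}:{self.icode}"

    @property
    def label(self) -> str:
        """Human-facing label, e.g. ``ARG-A-120``."""
        return f"{self.code}-{self.chain}-{self.number}{self.icode}"

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def __repr__(self) -> str:
        return f"<Residue {self.code} {self.key} kind={self.kind} n_atoms={len(self.atoms)}>"


@dataclass
class Structure:
    """One model of a parsed PDB entry."""

    identifier: str
    residues: list[Residue] = field(default_factory=list)
    model_index: int = 1

    def __post_init__(self) -> None:
        self._by_serial: dict[int, Atom] = {}
        self.reindex()

    def reindex(self) -> None:
        """Rebuild the serial -> Atom lookup; raises on duplicate serials."""
        self._by_serial = {}
        for res in self.residues:
            for atom in res.atoms:
                if atom.serial in self._by_serial:
                    raise ValueError(f"duplicate atom serial {atom.serial} in model {self.model_index}")
                self._by_serial[atom.serial] = atom
                atom.parent = res.key

    def atoms(self) -> Iterator[Atom]:
        for res in self.residues:
            yield from res.atoms

    def atom_by_serial(self, serial: int) -> Atom:
        return self._by_serial[serial]

    def residue_by_key(self, key: str) -> Residue | None:
        for res in self.residues:
            if res.key == key:
                return res
        return None

    def neighbors(self, atom: Atom) -> list[Atom]:
        return [self._by_serial[s] for s in atom.bonded_serials if s in self._by_serial]

    def heavy_neighbors(self, atom: Atom) -> list[Atom]:
        return [a for a in self.neighbors(atom) if not a.is_hydrogen]

    def hydrogens_of(self, atom: Atom) -> list[Atom]:
        return [a for a in self.neighbors(atom) if a.is_hydrogen]

    def next_serial(self) -> int:
        return max(self._by_serial, default=0) + 1

    def add_atom(self, residue: Residue, atom: Atom) -> None:
        residue.atoms.append(atom)
        atom.parent = residue.key
        self._by_serial[atom.serial] = atom

    def add_bond(self, a: Atom, b: Atom) -> None:
        if b.serial not in a.bonded_serials:
            a.bonded_serials.append(b.serial)
        if a.serial not in b.bonded_serials:
            b.bonded_serials.append(a.serial)


@dataclass
class BindingSite:
    """One ligand plus the protein residues and waters around it."""

    ligand: list[Residue]
    site_id: str
    protein_residues: list[Residue] = field(default_factory=list)
    waters: list[Residue] = field(default_factory=list)
    structure: Structure | None = None
    isolated: bool = False

    def ligand_atoms(self) -> list[Atom]:
        return [a for r in self.ligand for a in r.atoms]

    def ligand_heavy_atoms(self) -> list[Atom]:
        return [a for r in self.ligand for a in r.heavy_atoms()]

    def protein_atoms(self) -> list[Atom]:
        return [a for r in self.protein_residues for a in r.atoms]

    def water_oxygens(self) -> list[Atom]:
        return [a for r in self.waters for a in r.atoms if a.element == "O"]

    def side_of(self, atom: Atom) -> str:
        """'ligand', 'protein' or 'water' for an atom of this site."""
        keys_l = {r.key for r in self.ligand}
        keys_w = {r.key for r in self.waters}
        if atom.parent in keys_l:
            return "ligand"
        if atom.parent in keys_w:
            return "water"
        return "protein"
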