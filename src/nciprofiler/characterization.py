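"""Functional characterization of binding partners.

Perceives, on both sides of the interface, the feature sets the detectors
match against each other: hydrophobic carbons, hydrogen-bond donors and
acceptors, halogen-bond donors and acceptors, aromatic rings and formal
charge centers.

Perception is a function of topology (the bond graph) plus, for rings, the
planarity of the actual coordinates. Protein features come from residue
templates; ligand features from element/connectivity patterns on the bond
graph. Ligand rings are 5/6-cycles of sp2-capable atoms whose fitted plane
has RMSD below a tolerance — a geometric criterion that needs no bond
orders (PDB CONECT records carry none).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .core import HALOGENS, Atom, BindingSite, Residue
from .geometry import Plane, fit_plane

__all__ = [
    "HydrophobicAtom",
    "HBondDonor",
    "HBondAcceptor",
    "HalogenDonor",
    "HalogenAcceptor",
    "AromaticRing",
    "ChargeCenter",
    "SiteFeatures",
    "find_hydrophobic_atoms",
    "find_hbond_partners",
    "find_halogen_partners",
    "find_aromatic_rings",
    "find_charge_centers",
    "characterize",
]

RING_PLANARITY_TOL = 0.25  # Angstrom RMSD for the geometric aromaticity fallback

# aromatic ring atom names per residue template
_PROTEIN_RINGS = {
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TRP": [
        ("CG", "CD1", "NE1", "CE2", "CD2"),
        ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"),
    ],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
}


@dataclass(frozen=True)
class HydrophobicAtom:
    atom: Atom
    side: str  # protein | ligand


@dataclass(frozen=True)
class HBondDonor:
    heavy: Atom
    hydrogens: tuple[Atom, ...]
    side: str


@dataclass(frozen=True)
class HBondAcceptor:
    heavy: Atom
    side: str


@dataclass(frozen=True)
class HalogenDonor:
    halogen: Atom
    carbon: Atom
    side: str


@dataclass(frozen=True)
class HalogenAcceptor:
    acceptor: Atom
    neighbors: tuple[Atom, ...]  # Y atoms defining candidate Y-A axes
    side: str


@dataclass(frozen=True)
class AromaticRing:
    atoms: tuple[Atom, ...]
    plane: Plane
    residue: str
    side: str


@dataclass(frozen=True)
class ChargeCenter:
    sign: int  # +1 or -1
    atoms: tuple[Atom, ...]
    centroid: np.ndarray
    group: str
    side: str


@dataclass
class SiteFeatures:
    """All perceived features of one binding site."""

    hydrophobic: list[HydrophobicAtom] = field(default_factory=list)
    hbond_donors: list[HBondDonor] = field(default_factory=list)
    hbond_acceptors: list[HBondAcceptor] = field(default_factory=list)
    halogen_donors: list[HalogenDonor] = field(default_factory=list)
    halogen_acceptors: list[HalogenAcceptor] = field(default_factory=list)
    rings: list[AromaticRing] = field(default_factory=list)
    charges: list[ChargeCenter] = field(default_factory=list)
    waters: list[Atom] = field(default_factory=list)  # water oxygens


def _site_residues(site: BindingSite):
    for res in site.protein_residues:
        yield res, "protein"
    for res in site.ligand:
        yield res, "ligand"


def find_hydrophobic_atoms(site: BindingSite) -> list[HydrophobicAtom]:
    """Carbons whose bonded heavy neighbors are exclusively carbon."""
    st = site.structure
    out = []
    for res, side in _site_residues(site):
        for atom in res.heavy_atoms():
            if atom.element != "C":
                continue
            if all(n.element == "C" for n in st.heavy_neighbors(atom)):
                out.append(HydrophobicAtom(atom=atom, side=side))
    return out


def _is_acceptor(st, atom: Atom) -> bool:
    if atom.element == "O":
        return True
    if atom.element == "N":
        # lone pair available: no hydrogens, not quaternary/protonated
        n_h = len(st.hydrogens_of(atom))
        n_heavy = len(st.heavy_neighbors(atom))
        return n_h == 0 and n_heavy + n_h < 4
    if atom.element == "S":
        return len(st.heavy_neighbors(atom)) <= 2
    return False


def find_hbond_partners(site: BindingSite) -> tuple[list[HBondDonor], list[HBondAcceptor]]:
    """Hydrogen-bond donors (N/O/S with bound H) and acceptors (N/O/S with
    a free lone pair) on both sides. Waters are handled by the water-bridge
    detector and excluded here."""
    st = site.structure
    donors, acceptors = [], []
    for res, side in _site_residues(site):
        for atom in res.heavy_atoms():
            if atom.element not in ("N", "O", "S"):
                continue
            hs = st.hydrogens_of(atom)
            if hs:
                donors.append(HBondDonor(heavy=atom, hydrogens=tuple(hs), side=side))
            if _is_acceptor(st, atom):
                acceptors.append(HBondAcceptor(heavy=atom, side=side))
    return donors, acceptors


def find_halogen_partners(
    site: BindingSite, protein_donors: bool = False
) -> tuple[list[HalogenDonor], list[HalogenAcceptor]]:
    """C-X units as halogen donors (ligand side by default) and O/N/S atoms
    with a heavy neighbor as acceptors on both sides."""
    st = site.structure
    donors, acceptors = [], []
    for res, side in _site_residues(site):
        for atom in res.heavy_atoms():
            if atom.element in HALOGENS and (side == "ligand" or protein_donors):
                nbrs = st.heavy_neighbors(atom)
                if len(nbrs) == 1 and nbrs[0].element == "C":
                    donors.append(HalogenDonor(halogen=atom, carbon=nbrs[0], side=side))
            if atom.element in ("O", "N", "S"):
                nbrs = st.heavy_neighbors(atom)
                if nbrs:
                    acceptors.append(
                        HalogenAcceptor(acceptor=atom, neighbors=tuple(nbrs), side=side)
                    )
    return donors, acceptors


def _ligand_rings(st, res: Residue) -> list[tuple[Atom, ...]]:
    serials = {a.serial: a for a in res.heavy_atoms()}
    g = nx.Graph()
    g.add_nodes_from(serials)
    for a in res.heavy_atoms():
        for s in a.bonded_serials:
            if s in serials:
                g.add_edge(a.serial, s)
    rings = []
    for cycle in nx.minimum_cycle_basis(g):
        if len(cycle) not in (5, 6):
            continue
        atoms = [serials[s] for s in cycle]
        if any(a.element not in ("C", "N", "O", "S") for a in atoms):
            continue
        # sp2-capable: no ring atom with 4 heavy neighbors
        if any(len(st.heavy_neighbors(a)) > 3 for a in atoms):
            continue
        rings.append(_order_cycle(g, cycle, serials))
    return rings


def _order_cycle(g, cycle, serials) -> tuple[Atom, ...]:
    # walk the cycle so consecutive atoms are bonded
    start = min(cycle)
    order = [start]
    prev = None
    while len(order) < len(cycle):
        nxt = [n for n in g.neighbors(order[-1]) if n in cycle and n != prev and n not in order]
        if not nxt:
            break
        prev = order[-1]
        order.append(min(nxt))
    return tuple(serials[s] for s in order)


def find_aromatic_rings(site: BindingSite) -> list[AromaticRing]:
    """Aromatic rings: Phe/Tyr/Trp/His side chains by template; ligand
    5/6-cycles of sp2-capable atoms passing the planarity criterion."""
    st = site.structure
    out = []
    for res in site.protein_residues:
        for names in _PROTEIN_RINGS.get(res.code, []):
            atoms = [res.atom(n) for n in names]
            if any(a is None for a in atoms):
                continue
            plane = fit_plane([a.coords for a in atoms])
            if plane.planarity_rmsd <= RING_PLANARITY_TOL:
                out.append(AromaticRing(atoms=tuple(atoms), plane=plane, residue=res.key, side="protein"))
    for res in site.ligand:
        for atoms in _ligand_rings(st, res):
            plane = fit_plane([a.coords for a in atoms])
            if plane.planarity_rmsd <= RING_PLANARITY_TOL:
                out.append(AromaticRing(atoms=atoms, plane=plane, residue=res.key, side="ligand"))
    return out


def _center(atoms) -> np.ndarray:
    return np.mean([a.coords for a in atoms], axis=0)


def _protein_charges(st, res: Residue) -> list[ChargeCenter]:
    out = []
    if res.code == "ARG":
        atoms = [res.atom(n) for n in ("CZ", "NH1", "NH2")]
        if all(atoms):
            out.append(ChargeCenter(+1, tuple(atoms), _center(atoms), "guanidinium", "protein"))
    elif res.code == "LYS":
        nz = res.atom("NZ")
        if nz is not None:
            out.append(ChargeCenter(+1, (nz,), nz.coords.copy(), "ammonium", "protein"))
    elif res.code == "HIS":
        nd1, ne2 = res.atom("ND1"), res.atom("NE2")
        if nd1 is not None and ne2 is not None:
            if st.hydrogens_of(nd1) and st.hydrogens_of(ne2):  # doubly protonated only
                ring = [res.atom(n) for n in ("CG", "ND1", "CD2", "CE1", "NE2")]
                if all(ring):
                    out.append(ChargeCenter(+1, tuple(ring), _center(ring), "imidazolium", "protein"))
    elif res.code in ("ASP", "GLU"):
        names = ("OD1", "OD2") if res.code == "ASP" else ("OE1", "OE2")
        atoms = [res.atom(n) for n in names]
        if all(atoms):
            out.append(ChargeCenter(-1, tuple(atoms), _center(atoms), "carboxylate", "protein"))
    return out


def _ligand_charges(st, res: Residue) -> list[ChargeCenter]:
    out = []
    claimed: set[int] = set()
    for atom in res.heavy_atoms():
        nbrs = st.heavy_neighbors(atom)
        terminal_o = [
            n for n in nbrs if n.element == "O" and len(st.heavy_neighbors(n)) == 1
        ]
        if atom.element == "C" and len(terminal_o) == 2 and len(nbrs) <= 3:
            out.append(ChargeCenter(-1, tuple(terminal_o), _center(terminal_o), "carboxylate", "ligand"))
            claimed.update(o.serial for o in terminal_o)
        elif atom.element == "P" and len(terminal_o) >= 2:
            out.append(ChargeCenter(-1, tuple(terminal_o), _center(terminal_o), "phosphate", "ligand"))
            claimed.update(o.serial for o in terminal_o)
        elif atom.element == "S" and len(terminal_o) >= 2 and len(nbrs) >= 3:
            out.append(ChargeCenter(-1, tuple(terminal_o), _center(terminal_o), "sulfonate", "ligand"))
            claimed.update(o.serial for o in terminal_o)
    for atom in res.heavy_atoms():
        if atom.element != "N":
            continue
        nbrs = st.heavy_neighbors(atom)
        n_h = len(st.hydrogens_of(atom))
        if len(nbrs) == 4:
            out.append(ChargeCenter(+1, (atom,), atom.coords.copy(), "quaternary-amine", "ligand"))
        elif len(nbrs) == 1 and n_h >= 3:
            out.append(ChargeCenter(+1, (atom,), atom.coords.copy(), "ammonium", "ligand"))
    # guanidine: C bonded to exactly three N and nothing else heavy
    for atom in res.heavy_atoms():
        if atom.element != "C":
            continue
        nbrs = st.heavy_neighbors(atom)
        if len(nbrs) == 3 and all(n.element == "N" for n in nbrs):
            group = (atom, *nbrs)
            out.append(ChargeCenter(+1, group, _center(group), "guanidinium", "ligand"))
    return out


def find_charge_centers(site: BindingSite) -> list[ChargeCenter]:
    """Formal charge centers: Arg/Lys/His(+)/Asp/Glu(-) by template on the
    protein side; carboxylate, phosphate, sulfonate, ammonium, quaternary
    amine and guanidinium patterns on the ligand side."""
    st = site.structure
    out = []
    for res in site.protein_residues:
        out.extend(_protein_charges(st, res))
    for res in site.ligand:
        out.extend(_ligand_charges(st, res))
    return out


def characterize(site: BindingSite) -> SiteFeatures:
    """Run all perception steps for one binding site."""
    donors, acceptors = find_hbond_partners(site)
    hal_donors, hal_acceptors = find_halogen_partners(site)
    return SiteFeatures(
        hydrophobic=find_hydrophobic_atoms(site),
        hbond_donors=donors,
        hbond_acceptors=acceptors,
        halogen_donors=hal_donors,
        halogen_acceptors=hal_acceptors,
        rings=find_aromatic_rings(site),
        charges=find_charge_centers(site),
        waters=site.water_oxygens(),
    )
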