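"""Synthetic protein-ligand complexes with exactly controlled geometry.

Each builder places a minimal protein fragment (real residue and atom
nomenclature, so template-based perception fires) and a small HET ligand
(fictitious code ``LG1``, absent from the blacklist) such that one target
interaction holds with the requested distances/angles exactly. Decoy
variants place the same groups outside the thresholds by a clear margin
(>= 0.2 A / >= 5 deg), so a correct pipeline reports nothing.

A seed-derived rigid rotation + translation is applied to every fixture:
it exercises the orientation-independence of the pipeline while leaving
every internal distance and angle untouched, and the same seed always
yields byte-identical PDB text.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .core import (
    KIND_LIGAND_CANDIDATE,
    KIND_PROTEIN,
    KIND_WATER,
    Atom,
    Residue,
    Structure,
)
from .detectors import INTERACTION_TYPES
from .geometry import rotation_matrix
from .structure_io import write_pdb

__all__ = ["FixtureSpec", "GalleryCase", "build_fixture", "build_structure", "build_gallery", "build_combined"]

_RANGE = (0.5, 20.0)  # physically sensible override window, Angstrom


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic complex."""

    interaction_type: str
    overrides: dict = field(default_factory=dict)
    decoy: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.interaction_type not in INTERACTION_TYPES:
            raise ValueError(f"unknown interaction type {self.interaction_type!r}")
        for key, value in self.overrides.items():
            if key.endswith(("dist", "_l", "_p")) or key in ("d",):
                if not (_RANGE[0] <= value <= _RANGE[1]):
                    raise ValueError(f"override {key}={value} outside sensible range {_RANGE}")


@dataclass(frozen=True)
class GalleryCase:
    name: str
    spec: FixtureSpec
    pdb: str
    expected: dict[str, int]  # ground-truth inventory, type -> count


class _Builder:
    """Accumulates residues/atoms with sequential serials."""

    def __init__(self) -> None:
        self.residues: list[Residue] = []
        self._serial = 0
        self._bonds: list[tuple[Atom, Atom]] = []

    def residue(self, code: str, chain: str, number: int, kind: str) -> Residue:
        res = Residue(chain=chain, number=number, icode="", code=code, kind=kind)
        self.residues.append(res)
        return res

    def atom(self, res: Residue, name: str, element: str, xyz) -> Atom:
        self._serial += 1
        a = Atom(serial=self._serial, name=name, element=element, coords=np.asarray(xyz, float))
        res.atoms.append(a)
        return a

    def bond(self, a: Atom, b: Atom) -> None:
        self._bonds.append((a, b))

    def structure(self, identifier: str) -> Structure:
        st = Structure(identifier=identifier, residues=self.residues)
        for a, b in self._bonds:
            st.add_bond(a, b)
        return st


def _hex_ring(center, radius: float = 1.39, normal="z", phase_deg: float = 0.0):
    """Vertices of a regular hexagon; normal 'z' puts it in the xy plane,
    'y' in the xz plane."""
    center = np.asarray(center, float)
    pts = []
    for k in range(6):
        t = math.radians(phase_deg + 60.0 * k)
        if normal == "z":
            offset = np.array([radius * math.cos(t), radius * math.sin(t), 0.0])
        else:  # normal along y: ring spans x and z
            offset = np.array([radius * math.sin(t), 0.0, radius * math.cos(t)])
        pts.append(center + offset)
    return pts


def _add_benzene(b: _Builder, res: Residue, center, normal="z", phase_deg: float = 0.0):
    atoms = [
        b.atom(res, f"C{k + 1}", "C", p)
        for k, p in enumerate(_hex_ring(center, normal=normal, phase_deg=phase_deg))
    ]
    for k in range(6):
        b.bond(atoms[k], atoms[(k + 1) % 6])
    return atoms


# ---------------------------------------------------------------------------
# per-type builders; defaults are the "ideal textbook" geometry of each type


def _build_hydrophobic(ov: dict) -> _Builder:
    d = ov.get("dist", 3.6)
    b = _Builder()
    leu = b.residue("LEU", "A", 1, KIND_PROTEIN)
    b.atom(leu, "CB", "C", (-1.53, 0, 0))
    b.atom(leu, "CG", "C", (0, 0, 0))
    b.atom(leu, "CD1", "C", (1.53, 0, 0))
    lig = b.residue("LG1", "L", 1, KIND_LIGAND_CANDIDATE)
    c1 = b.atom(lig, "C1", "C", (1.53 + d, 0, 0))
    c2 = b.atom(lig, "C2", "C", (1.53 + d + 1.53, 0, 0))
    b.bond(c1, c2)
    return b


def _hbond_h_position(og: np.ndarray, o1: np.ndarray, target_angle: float) -> np.ndarray:
    """Place H at 0.96 A from ``og`` in the xy plane so the O-H...O angle
    at H equals ``target_angle`` degrees (donor on the -x side)."""
    if target_angle >= 179.9:
        return og + 0.96 * (o1 - og) / np.linalg.norm(o1 - og)

    def f(alpha: float) -> float:
        h = og + 0.96 * np.array([math.cos(math.radians(alpha)), math.sin(math.radians(alpha)), 0.0])
        v1, v2 = og - h, o1 - h
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        return math.degrees(math.acos(max(-1.0, min(1.0, cosang)))) - target_angle

    alpha = brentq(f, 1e-3, 179.0)
    return og + 0.96 * np.array([math.cos(math.radians(alpha)), math.sin(math.radians(alpha)), 0.0])


def _build_hbond(ov: dict) -> _Builder:
    d = ov.get("dist", 2.9)
    don_angle = ov.get("don_angle", 180.0)
    b = _Builder()
    ser = b.residue("SER", "A", 1, KIND_PROTEIN)
    b.atom(ser, "CB", "C", (0, 0, 0))
    og = b.atom(ser, "OG", "O", (1.42, 0, 0))
    o1_pos = np.array([1.42 + d, 0.0, 0.0])
    h = b.atom(ser, "HG", "H", _hbond_h_position(og.coords, o1_pos, don_angle))
    b.bond(og, h)
    lig = b.residue("LG1", "L", 1, KIND_LIGAND_CANDIDATE)
    o1 = b.atom(lig, "O1", "O", o1_pos)
    c1 = b.atom(lig, "C1", "C", o1_pos + 1.23 * np.array([0.5, math.sqrt(3) / 2, 0.0]))
    c2 = b.atom(lig, "C2", "C", c1.coords + 1.52 * np.array([1.0, 0.0, 0.0]))
    c3 = b.atom(lig, "C3", "C", c1.coords + 1.52 * np.array([-0.5, math.sqrt(3) / 2, 0.0]))
    b.bond(o1, c1)
    b.bond(c1, c2)
    b.bond(c1, c3)
    return b


def _build_waterbridge(ov: dict) -> _Builder:
    leg_p = ov.get("dist_p", 2.8)
    leg_l = ov.get("dist_l", 2.8)
    omega = ov.get("omega", 110.0)
    b = _Builder()
    ser = b.residue("SER", "A", 1, KIND_PROTEIN)
    b.atom(ser, "CB", "C", (0, 0, 0))
    b.atom(ser, "OG", "O", (1.42, 0, 0))
    w_pos = np.array([1.42 + leg_p, 0.0, 0.0])
    wat = b.residue("HOH", "W", 1, KIND_WATER)
    b.atom(wat, "O", "O", w_pos)
    t = math.radians(180.0 - omega)
    v = np.array([math.cos(t), math.sin(t), 0.0])
    lig = b.residue("LG1", "L", 1, KIND_LIGAND_CANDIDATE)
    o1 = b.atom(lig, "O1", "O", w_pos + leg_l * v)
    c1 = b.atom(lig, "C1", "C", o1.coords + 1.43 * v)
    b.bond(o1, c1)
    return b


def _build_saltbridge(ov: dict) -> _Builder:
    d = ov.get("dist", 4.0)
    b = _Builder()
    arg = b.residue("ARG", "A", 1, KIND_PROTEIN)
    b.atom(arg, "NE", "N", (0, 0, 0))
    b.atom(arg, "CZ", "C", (1.33, 0, 0))
    b.atom(arg, "NH1", "N", (1.33 + 1.33 * 0.5, 1.33 * math.sqrt(3) / 2, 0))
    b.atom(arg, "NH2", "N", (1.33 + 1.33 * 0.5, -1.33 * math.sqrt(3) / 2, 0))
    pos_centroid = np.array([(1.33 + 2 * (1.33 + 0.665)) / 3.0, 0.0, 0.0])
    neg_centroid = pos_centroid + np.array([d, 0.0, 0.0])
    half = math.radians(63.0)  # half the O-C-O angle
    c2_pos = neg_centroid + np.array([1.25 * math.cos(half), 0.0, 0.0])
    lig = b.residue("LG1", "L", 1, KIND_LIGAND_CANDIDATE)
    c2 = b.atom(lig, "C2", "C", c2_pos)
    o1 = b.atom(lig, "O1", "O", c2_pos + 1.25 * np.array([-math.cos(half), math.sin(half), 0.0]))
    o2 = b.atom(lig, "O2", "O", c2_pos + 1.25 * np.array([-math.cos(half), -math.sin(half), 0.0]))
    c1 = b.atom(lig, "C1", "C", c2_pos + 1.52 * np.array([1.0, 0.0, 0.0]))
    b.bond(c2, o1)
    b.bond(c2, o2)
    b.bond(c2, c1)
    return b


def _build_pistack(ov: dict) -> _Builder:
    ang = ov.get("angle", 0.0)
    d = ov.get("dist", 5.3 if ang > 45 else 4.3)
    b = _Builder()
    phe = b.residue("PHE", "A", 1, KIND_PROTEIN)
    ring_pts = _hex_ring((0, 0, 0))
    names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    for name, p in zip(names, ring_pts):
        b.atom(phe, name, "C", p)
    b.atom(phe, "CB", "C", (1.39 + 1.52, 0, 0))
    lig = b.residue("LG1", "L", 1, KIND_LIGAND_CANDIDATE)
    if ang > 45:  # T-shaped: ligand ring plane contains the stacking axis
        _add_benzene(b, lig, (0, 0, d), normal="y", phase_deg=30.0)
    else:  # parallel sandwich, staggered 30 deg to keep C...C above 4 A
        _add_benzene(b, lig, (0, 0, d), normal="z", phase_deg=30.0)
    return b


def _build_pication(ov: dict) -> _Builder:
    d = ov.get("dist", 4.0)
    b = _Builder()
    lys = b.residue("LYS", "A", 1, KIND_PROTEIN)
    b.atom(lys, "CE", "C", (0, 0, d + 1.49))
    b.atom(lys, "NZ", "N", (0, 0, d))
    lig = b.residue("LG1", "L", 1, KIND_LIGAND_CANDIDATE)
    _add_benzene(b, lig, (0, 0, 0))
    return b


def _build_halogen(ov: dict) -> _Builder:
    d = ov.get("dist", 3.3)
    don = ov.get("don_angle", 175.0)
    acc = ov.get("acc_angle", 120.0)
    b = _Builder()
    gly = b.residue("GLY", "A", 1, KIND_PROTEIN)
    b.atom(gly, "CA", "C", (-1.52 * 0.5, 1.52 * math.sqrt(3) / 2, 0))
    b.atom(gly, "C", "C", (0, 0, 0))
    o = b.atom(gly, "O", "O", (1.23, 0, 0))
    t = math.radians(180.0 - acc)
    v = np.array([math.cos(t), -math.sin(t), 0.0])  # O->X, acc deg from O->C
    x_pos = o.coords + d * v
    c1_dir = rotation_matrix([0, 0, 1], 180.0 - don) @ v
    lig = b.residue("LG1", "L", 1, KIND_LIGAND_CANDIDATE)
    cl = b.atom(lig, "CL1", "CL", x_pos)
    c1 = b.atom(lig, "C1", "C", x_pos + 1.77 * c1_dir)
    b.bond(cl, c1)
    return b


_BUILDERS = {
    "hydrophobic": _build_hydrophobic,
    "hbond": _build_hbond,
    "waterbridge": _build_waterbridge,
    "saltbridge": _build_saltbridge,
    "pistack": _build_pistack,
    "pication": _build_pication,
    "halogen": _build_halogen,
}

# decoy geometry: clearly outside the default thresholds
_DECOY_OVERRIDES = {
    "hydrophobic": {"dist": 4.5},
    "hbond": {"don_angle": 70.0},
    "waterbridge": {"dist_l": 4.3},
    "saltbridge": {"dist": 6.5},
    "pistack": {"dist": 7.0},
    "pication": {"dist": 8.0},
    "halogen": {"don_angle": 120.0},
}


def _seed_transform(structure: Structure, seed: int) -> None:
    """Apply a seed-derived rigid rotation + translation to all atoms.

    Seed 0 keeps the canonical axis-aligned frame (so key distances fall on
    coordinate axes and survive the 3-decimal PDB rounding essentially
    exactly); any other seed yields a reproducible random rigid motion.
    """
    if seed == 0:
        return
    rng = np.random.default_rng(seed)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    rot = rotation_matrix(axis, float(rng.uniform(0, 360)))
    shift = rng.uniform(-5, 5, size=3)
    for atom in structure.atoms():
        atom.coords = rot @ atom.coords + shift


def build_structure(spec: FixtureSpec) -> Structure:
    """Build the fixture as a live Structure (bonds included)."""
    overrides = dict(spec.overrides)
    if spec.decoy:
        merged = dict(_DECOY_OVERRIDES[spec.interaction_type])
        merged.update(overrides)
        overrides = merged
    builder = _BUILDERS[spec.interaction_type](overrides)
    tag = "decoy" if spec.decoy else "pos"
    st = builder.structure(f"{spec.interaction_type}_{tag}")
    _seed_transform(st, spec.seed)
    return st


def build_fixture(spec: FixtureSpec) -> str:
    """Render the fixture as PDB text (parseable by :func:`parse_pdb`)."""
    return write_pdb(build_structure(spec))


def build_gallery(seed: int = 0) -> list[GalleryCase]:
    """One positive and one decoy case per interaction type (plus a
    T-shaped stacking positive), each with its ground-truth inventory."""
    cases: list[GalleryCase] = []
    for itype in INTERACTION_TYPES:
        spec = FixtureSpec(interaction_type=itype, seed=seed)
        cases.append(GalleryCase(
            name=f"{itype}_pos",
            spec=spec,
            pdb=build_fixture(spec),
            expected={itype: 1},
        ))
        dspec = FixtureSpec(interaction_type=itype, decoy=True, seed=seed)
        cases.append(GalleryCase(
            name=f"{itype}_decoy",
            spec=dspec,
            pdb=build_fixture(dspec),
            expected={},
        ))
    tspec = FixtureSpec(interaction_type="pistack", overrides={"angle": 90.0}, seed=seed)
    cases.append(GalleryCase(
        name="pistack_pos_T",
        spec=tspec,
        pdb=build_fixture(tspec),
        expected={"pistack": 1},
    ))
    return cases


def build_combined(seed: int = 0) -> str:
    """One PDB containing all seven positive cases, spaced 30 A apart so
    the binding sites stay independent. The union of reported types over
    the sites is the full seven-type taxonomy."""
    merged = _Builder()
    for idx, itype in enumerate(INTERACTION_TYPES):
        builder = _BUILDERS[itype]({})
        shift = np.array([30.0 * idx, 0.0, 0.0])
        remap: dict[int, Atom] = {}
        for res in builder.residues:
            nres = merged.residue(res.code, res.chain, idx + 1, res.kind)
            for atom in res.atoms:
                remap[atom.serial] = merged.atom(nres, atom.name, atom.element, atom.coords + shift)
        for a, b in builder._bonds:
            merged.bond(remap[a.serial], remap[b.serial])
    st = merged.structure("combined")
    _seed_transform(st, seed)
    return write_pdb(st)
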