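"""Structure preparation: PDB parsing, polar hydrogen placement, ligand
filtering and binding-site extraction.

Parsing is delegated to gemmi (fixed-column wwPDB v3.3, MODEL/ENDMDL,
altlocs, CONECT); this module resolves alternate locations (highest
occupancy wins, ties broken by altloc letter), classifies residues,
completes the bond graph with a covalent-radius distance rule and exposes
the domain model of :mod:`nciprofiler.core`.

Hydrogenation is an explicit rule-based policy at pH 7: Arg/Lys protonated,
Asp/Glu deprotonated, His neutral (tau tautomer). Hydrogens already present
in the input are preserved; heavy-atom coordinates are never touched.
Rotatable polar hydrogens (hydroxyl, thiol, ammonium) are oriented toward
the nearest plausible acceptor so that donor-angle criteria operate on
optimally oriented hydrogens, mirroring the behaviour of optimizing
protonation toolkits while staying deterministic.
"""

from __future__ import annotations

import io
import math
import os
from importlib import resources

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .core import (
    COVALENT_RADII,
    KIND_EXCLUDED,
    KIND_LIGAND_CANDIDATE,
    KIND_PROTEIN,
    KIND_WATER,
    WATER_CODES,
    Atom,
    BindingSite,
    Residue,
    Structure,
)

__all__ = [
    "PDBParseError",
    "ModelNotFoundError",
    "parse_pdb",
    "write_pdb",
    "hydrogenate",
    "filter_ligands",
    "extract_binding_sites",
    "load_blacklist",
    "default_blacklist",
]

BOND_TOLERANCE = 0.45  # added to the sum of covalent radii
MIN_BOND_DIST = 0.4
SITE_CUTOFF_DEFAULT = 7.5  # Angstrom envelope around ligand heavy atoms

# X-H bond lengths used when placing hydrogens
XH_BOND = {"N": 1.01, "O": 0.96, "S": 1.34}


class PDBParseError(ValueError):
    pass


class ModelNotFoundError(ValueError):
    pass


# ---------------------------------------------------------------------------
# parsing


def _read_text(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    text = str(source)
    if "\n" not in text and (os.path.exists(text) or text.lower().endswith(".pdb")):
        with open(text) as fh:
            return fh.read()
    return text


def _prevalidate(text: str) -> None:
    n_records = 0
    for i, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            n_records += 1
            if len(line) < 54:
                raise PDBParseError(f"line {i}: truncated coordinate record")
            try:
                float(line[30:38]), float(line[38:46]), float(line[46:54])
            except ValueError:
                raise PDBParseError(f"line {i}: cannot parse coordinates") from None
    if n_records == 0:
        raise PDBParseError("no ATOM or HETATM records found in input")


def parse_pdb(source, model: int = 1, identifier: str | None = None) -> Structure:
    """Parse one model of a PDB file into a :class:`Structure`.

    ``source`` may be a path, a file object or PDB text. Altloc conflicts
    are resolved by keeping the highest-occupancy conformer (ties broken by
    altloc letter order). CONECT records seed the bond graph; remaining
    bonds are inferred from a covalent-radius distance rule.
    """
    text = _read_text(source)
    _prevalidate(text)
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:  # gemmi names the offending line
        raise PDBParseError(f"PDB parse failed: {exc}") from None

    models = {m.num: m for m in st}
    if model not in models:
        raise ModelNotFoundError(
            f"model {model} not present; available models: {sorted(models)}"
        )
    gmodel = models[model]

    if identifier is None:
        identifier = st.name if st.name and st.name != "unknown" else "structure"

    residues: list[Residue] = []
    kept_serials: set[int] = set()
    for chain in gmodel:
        for gres in chain:
            code = gres.name.strip()
            if code in WATER_CODES:
                kind = KIND_WATER
            elif gres.het_flag == "A":
                kind = KIND_PROTEIN
            else:
                kind = KIND_LIGAND_CANDIDATE
            res = Residue(
                chain=chain.name,
                number=gres.seqid.num,
                icode=(gres.seqid.icode or "").strip(),
                code=code,
                kind=kind,
            )
            # altloc resolution: group by atom name, keep best conformer
            by_name: dict[str, list[gemmi.Atom]] = {}
            for ga in gres:
                by_name.setdefault(ga.name, []).append(ga)
            for name in by_name:
                group = by_name[name]
                best = min(group, key=lambda ga: (-ga.occ, ga.altloc or "~"))
                altloc = (best.altloc or "\x00").replace("\x00", "").strip()
                atom = Atom(
                    serial=best.serial,
                    name=name.strip(),
                    element=best.element.name,
                    coords=np.array([best.pos.x, best.pos.y, best.pos.z]),
                    altloc=altloc,
                    occupancy=best.occ,
                )
                res.atoms.append(atom)
                kept_serials.add(best.serial)
            res.atoms.sort(key=lambda a: a.serial)
            residues.append(res)

    structure = Structure(identifier=identifier, residues=residues, model_index=model)

    # bonds from CONECT (pruned to kept conformers), then distance inference
    for serial, partners in st.conect_map.items():
        if serial not in kept_serials:
            continue
        a = structure.atom_by_serial(serial)
        for p in partners:
            if p in kept_serials:
                structure.add_bond(a, structure.atom_by_serial(p))
    _infer_bonds(structure)
    return structure


def _infer_bonds(structure: Structure) -> None:
    """Complete the bond graph with a covalent-radius distance rule.

    Elements without a tabulated covalent radius (metals) are never bonded;
    a hydrogen is bonded only to its nearest heavy atom.
    """
    atoms = [a for a in structure.atoms() if a.element in COVALENT_RADII]
    if len(atoms) < 2:
        return
    coords = np.array([a.coords for a in atoms])
    tree = cKDTree(coords)
    max_reach = 2 * max(COVALENT_RADII.values()) + BOND_TOLERANCE
    for i, j in tree.query_pairs(r=max_reach):
        a, b = atoms[i], atoms[j]
        if a.is_hydrogen and b.is_hydrogen:
            continue
        d = float(np.linalg.norm(a.coords - b.coords))
        if not (MIN_BOND_DIST <= d <= COVALENT_RADII[a.element] + COVALENT_RADII[b.element] + BOND_TOLERANCE):
            continue
        structure.add_bond(a, b)
    # a hydrogen keeps only its closest heavy partner
    for a in atoms:
        if not a.is_hydrogen or len(a.bonded_serials) <= 1:
            continue
        partners = [structure.atom_by_serial(s) for s in a.bonded_serials]
        best = min(partners, key=lambda p: float(np.linalg.norm(a.coords - p.coords)))
        for p in partners:
            if p is not best:
                p.bonded_serials.remove(a.serial)
        a.bonded_serials = [best.serial]


# ---------------------------------------------------------------------------
# writing


def _format_atom_line(record: str, atom: Atom, res: Residue) -> str:
    name = atom.name
    if len(atom.element) == 1 and len(name) < 4:
        name = f" {name}"
    x, y, z = atom.coords
    return (
        f"{record:<6}{atom.serial:>5} {name:<4}{atom.altloc or ' ':1}"
        f"{res.code:>3} {res.chain[:1] or 'A':1}{res.number:>4}{res.icode or ' ':1}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}          "
        f"{atom.element:>2}"
    )


def write_pdb(structure: Structure) -> str:
    """Serialize a Structure back to fixed-column PDB text.

    Protein residues are written as ATOM records, everything else as
    HETATM. CONECT records are emitted for bonds that involve at least one
    HETATM atom (protein-internal bonds are recoverable by distance).
    """
    lines: list[str] = []
    het_serials: set[int] = set()
    for res in structure.residues:
        record = "ATOM" if res.kind == KIND_PROTEIN else "HETATM"
        for atom in sorted(res.atoms, key=lambda a: a.serial):
            lines.append(_format_atom_line(record, atom, res))
            if record == "HETATM":
                het_serials.add(atom.serial)
    for res in structure.residues:
        for atom in sorted(res.atoms, key=lambda a: a.serial):
            partners = sorted(
                s for s in atom.bonded_serials
                if atom.serial in het_serials or s in het_serials
            )
            if partners:
                for k in range(0, len(partners), 4):
                    chunk = "".join(f"{p:>5}" for p in partners[k : k + 4])
                    lines.append(f"CONECT{atom.serial:>5}{chunk}")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# hydrogenation

# side-chain donors: residue -> atom name -> (hydrogen count, placement mode)
_SIDECHAIN_DONORS = {
    "SER": {"OG": (1, "rot")},
    "THR": {"OG1": (1, "rot")},
    "TYR": {"OH": (1, "rot")},
    "CYS": {"SG": (1, "rot")},
    "LYS": {"NZ": (3, "rot")},
    "ARG": {"NE": (1, "sp2"), "NH1": (2, "sp2"), "NH2": (2, "sp2")},
    "HIS": {"NE2": (1, "sp2")},  # neutral tau tautomer at pH 7
    "TRP": {"NE1": (1, "sp2")},
    "ASN": {"ND2": (2, "sp2")},
    "GLN": {"NE2": (2, "sp2")},
}


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 1e-12 else v


def _acceptor_candidates(structure: Structure) -> list[Atom]:
    return [
        a for a in structure.atoms()
        if not a.is_hydrogen and a.element in ("N", "O", "S")
    ]


def _rot_directions(d: Atom, heavy_nbrs: list[Atom], n_h: int, candidates: list[Atom]) -> list[np.ndarray]:
    """Hydrogen directions for a rotatable donor (hydroxyl/thiol/ammonium)."""
    target = None
    for c in sorted(candidates, key=lambda c: float(np.linalg.norm(c.coords - d.coords))):
        if c.parent == d.parent or c is d:
            continue
        dist = float(np.linalg.norm(c.coords - d.coords))
        if dist > 4.5:
            break
        if heavy_nbrs:
            v1 = _unit(heavy_nbrs[0].coords - d.coords)
            v2 = _unit(c.coords - d.coords)
            if np.degrees(np.arccos(np.clip(np.dot(v1, v2), -1, 1))) < 60:
                continue  # acceptor hides behind the existing bond
        target = c
        break
    if not heavy_nbrs:
        base = np.array([1.0, 0.0, 0.0])
        if target is not None:
            base = _unit(target.coords - d.coords)
        return [base] * min(n_h, 1)
    axis = _unit(d.coords - heavy_nbrs[0].coords)  # anti direction
    if target is not None:
        tv = target.coords - d.coords
        perp = tv - np.dot(tv, axis) * axis
    else:
        perp = np.cross(axis, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(axis, [0.0, 1.0, 0.0])
    perp = _unit(perp) if np.linalg.norm(perp) > 1e-6 else _unit(np.cross(axis, [0.0, 0.0, 1.0]))
    perp2 = np.cross(axis, perp)
    if n_h == 1:
        if target is not None:
            return [_unit(target.coords - d.coords)]
        return [axis]
    # tetrahedral fan: 109.5 deg from the X-D bond
    tilt = math.radians(180.0 - 109.5)
    dirs = []
    for k in range(n_h):
        phi = math.radians(120.0 * k)
        dirs.append(
            math.cos(tilt) * axis
            + math.sin(tilt) * (math.cos(phi) * perp + math.sin(phi) * perp2)
        )
    return dirs


def _sp2_directions(structure: Structure, d: Atom, heavy_nbrs: list[Atom], n_h: int) -> list[np.ndarray]:
    """Hydrogen directions for planar (sp2) donors such as amide N."""
    if len(heavy_nbrs) >= 2:
        s = sum((_unit(n.coords - d.coords) for n in heavy_nbrs), np.zeros(3))
        return [-_unit(s)] * min(n_h, 1)
    if len(heavy_nbrs) == 1:
        c = heavy_nbrs[0]
        others = [n for n in structure.heavy_neighbors(c) if n is not d]
        v = _unit(c.coords - d.coords)
        if others:
            ref = _unit(others[0].coords - c.coords)
            normal = np.cross(v, ref)
            if np.linalg.norm(normal) < 1e-6:
                normal = np.cross(v, [1.0, 0.0, 0.0])
        else:
            normal = np.cross(v, [1.0, 0.0, 0.0])
            if np.linalg.norm(normal) < 1e-6:
                normal = np.cross(v, [0.0, 1.0, 0.0])
        normal = _unit(normal)
        from .geometry import rotation_matrix

        dirs = [rotation_matrix(normal, 120.0) @ v, rotation_matrix(normal, -120.0) @ v]
        return dirs[:n_h]
    return []


def _ligand_ring_members(structure: Structure, residue: Residue) -> set[int]:
    import networkx as nx

    g = nx.Graph()
    serials = {a.serial for a in residue.heavy_atoms()}
    g.add_nodes_from(serials)
    for a in residue.heavy_atoms():
        for s in a.bonded_serials:
            if s in serials:
                g.add_edge(a.serial, s)
    members: set[int] = set()
    for cycle in nx.cycle_basis(g):
        members.update(cycle)
    return members


def _is_carbonyl_like(structure: Structure, o: Atom) -> bool:
    """Terminal O on C/P/S with short bond or sibling terminal oxygens.

    Disambiguates C=O from C-OH without bond orders: a carbonyl C-O bond is
    ~1.23 A vs ~1.43 A for an alcohol; carboxylate/phosphate/sulfonate
    oxygens are recognized by sibling terminal oxygens on the same center
    and left deprotonated (pH 7 policy).
    """
    nbrs = structure.heavy_neighbors(o)
    if len(nbrs) != 1:
        return False
    center = nbrs[0]
    d = float(np.linalg.norm(o.coords - center.coords))
    if d < 1.30:
        return True
    if center.element in ("P", "S"):
        return True  # terminal O on P/S: (de)protonated oxyanion policy
    terminal_os = [
        n for n in structure.heavy_neighbors(center)
        if n.element == "O" and len(structure.heavy_neighbors(n)) == 1
    ]
    return len(terminal_os) >= 2  # carboxylate


def _ligand_h_plan(structure: Structure, residue: Residue) -> dict[int, tuple[int, str]]:
    """Hydrogen counts for ligand N/O/S atoms, from valence bookkeeping."""
    plan: dict[int, tuple[int, str]] = {}
    ring = _ligand_ring_members(structure, residue)
    for a in residue.heavy_atoms():
        nbrs = structure.heavy_neighbors(a)
        deg = len(nbrs)
        if a.element == "O":
            if deg == 1 and not _is_carbonyl_like(structure, a):
                plan[a.serial] = (1, "rot")
        elif a.element == "S":
            if deg == 1:
                plan[a.serial] = (1, "rot")
        elif a.element == "N":
            if deg == 1:
                carbon = nbrs[0]
                aromatic_attach = carbon.serial in ring
                plan[a.serial] = (2, "sp2") if aromatic_attach else (3, "rot")
            elif deg == 2 and a.serial not in ring:
                plan[a.serial] = (1, "sp2")
            # ring N (pyridine-like) and tertiary N: no hydrogen
    return plan


def hydrogenate(structure: Structure) -> Structure:
    """Add polar hydrogens at idealized geometry (pH 7 policy), in place.

    Pre-existing hydrogens are preserved and counted toward each donor's
    quota; heavy atoms are never moved. Waters are left bare — the
    water-bridge detector treats the water oxygen symmetrically. Returns
    the same Structure for chaining.
    """
    candidates = _acceptor_candidates(structure)
    todo: list[tuple[Residue, Atom, int, str]] = []
    for res in structure.residues:
        if res.kind == KIND_PROTEIN:
            for atom in res.atoms:
                if atom.name == "N" and res.code != "PRO" and atom.element == "N":
                    todo.append((res, atom, 1, "sp2"))
            for name, (n_h, mode) in _SIDECHAIN_DONORS.get(res.code, {}).items():
                atom = res.atom(name)
                if atom is not None:
                    todo.append((res, atom, n_h, mode))
        elif res.kind in (KIND_LIGAND_CANDIDATE, KIND_EXCLUDED):
            plan = _ligand_h_plan(structure, res)
            for serial, (n_h, mode) in plan.items():
                todo.append((res, structure.atom_by_serial(serial), n_h, mode))

    for res, donor, n_h, mode in todo:
        missing = n_h - len(structure.hydrogens_of(donor))
        if missing <= 0:
            continue
        heavy_nbrs = structure.heavy_neighbors(donor)
        if mode == "sp2":
            dirs = _sp2_directions(structure, donor, heavy_nbrs, n_h)
        else:
            dirs = _rot_directions(donor, heavy_nbrs, n_h, candidates)
        length = XH_BOND.get(donor.element, 1.0)
        existing = len(structure.hydrogens_of(donor))
        for direction in dirs[existing : existing + missing]:
            serial = structure.next_serial()
            h = Atom(
                serial=serial,
                name=f"H{len([a for a in res.atoms if a.is_hydrogen]) + 1}",
                element="H",
                coords=donor.coords + length * _unit(direction),
            )
            structure.add_atom(res, h)
            structure.add_bond(donor, h)
    return structure


# ---------------------------------------------------------------------------
# ligand filtering and binding sites


def default_blacklist() -> set[str]:
    """Residue codes shipped as the default ligand blacklist."""
    text = resources.files("nciprofiler.data").joinpath("blacklist.txt").read_text()
    return _parse_blacklist(io.StringIO(text))


def load_blacklist(path) -> set[str]:
    """Read a blacklist file: one residue code per line, '#' comments."""
    with open(path) as fh:
        return _parse_blacklist(fh)


def _parse_blacklist(fh) -> set[str]:
    codes = set()
    for line in fh:
        line = line.split("#", 1)[0].strip().upper()
        if line:
            codes.add(line)
    return codes


def filter_ligands(structure: Structure, blacklist: set[str] | None = None) -> list[Residue]:
    """Return ligand-candidate residues that survive the blacklist and the
    covalent-modification filter.

    A candidate is excluded if its code is blacklisted, if it is a water,
    or if it is covalently bonded into a polymer chain (bond from any of
    its atoms to a protein backbone atom), the connectivity signature of a
    modified residue. Excluded residues are marked kind='excluded' with a
    reason.
    """
    if blacklist is None:
        blacklist = default_blacklist()
    blacklist = {c.upper() for c in blacklist}
    backbone_serials = {
        a.serial
        for res in structure.residues
        if res.kind == KIND_PROTEIN
        for a in res.atoms
        if a.name in ("N", "CA", "C")
    }
    kept: list[Residue] = []
    for res in structure.residues:
        if res.kind not in (KIND_LIGAND_CANDIDATE, KIND_EXCLUDED):
            continue
        if res.code.upper() in blacklist:
            res.kind = KIND_EXCLUDED
            res.exclusion_reason = "blacklisted"
            continue
        linked = any(
            s in backbone_serials for a in res.atoms for s in a.bonded_serials
        )
        if linked:
            res.kind = KIND_EXCLUDED
            res.exclusion_reason = "covalently bound into polymer chain"
            continue
        res.kind = KIND_LIGAND_CANDIDATE
        res.exclusion_reason = ""
        kept.append(res)
    return kept


def _composite_groups(structure: Structure, ligands: list[Residue]) -> list[list[Residue]]:
    """Group ligand residues linked by covalent bonds (e.g. saccharides)."""
    key_to_res = {r.key: r for r in ligands}
    parent = {r.key: r.key for r in ligands}

    def find(k: str) -> str:
        while parent[k] != k:
            parent[k] = parent[parent[k]]
            k = parent[k]
        return k

    for res in ligands:
        for atom in res.atoms:
            for s in atom.bonded_serials:
                other = structure.atom_by_serial(s).parent
                if other in key_to_res and other != res.key:
                    parent[find(other)] = find(res.key)
    groups: dict[str, list[Residue]] = {}
    for res in ligands:
        groups.setdefault(find(res.key), []).append(res)
    return [sorted(g, key=lambda r: (r.chain, r.number, r.icode)) for g in groups.values()]


def extract_binding_sites(
    structure: Structure,
    ligands: list[Residue],
    cutoff: float = SITE_CUTOFF_DEFAULT,
) -> list[BindingSite]:
    """One BindingSite per (composite) ligand: protein residues and waters
    with any atom within ``cutoff`` of any ligand heavy atom."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    sites: list[BindingSite] = []
    for group in _composite_groups(structure, ligands):
        lig_heavy = np.array([a.coords for r in group for a in r.heavy_atoms()])
        if lig_heavy.size == 0:
            continue
        tree = cKDTree(lig_heavy)
        prot: list[Residue] = []
        waters: list[Residue] = []
        group_keys = {r.key for r in group}
        for res in structure.residues:
            if res.key in group_keys or not res.atoms:
                continue
            coords = np.array([a.coords for a in res.atoms])
            if not (tree.query(coords, k=1)[0] < cutoff).any():
                continue
            if res.kind == KIND_PROTEIN:
                prot.append(res)
            elif res.kind == KIND_WATER:
                waters.append(res)
        first = group[0]
        sites.append(
            BindingSite(
                ligand=group,
                site_id=f"{first.code}:{first.chain}:{first.number}",
                protein_residues=prot,
                waters=waters,
                structure=structure,
                isolated=not prot,
            )
        )
    sites.sort(key=lambda s: s.site_id)
    return sites
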