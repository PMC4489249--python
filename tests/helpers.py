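"""Shared test utilities: random feature scenes and independent
brute-force oracles for every detector.

The oracles deliberately avoid the package's geometry helpers: distances,
angles and projections are recomputed here with plain Python/math so that
detector results are checked against an independent statement of the same
inequalities. Ring normals come from Newell's method rather than the SVD
plane fit used by the implementation.
"""

from __future__ import annotations

import math

import numpy as np

from nciprofiler.characterization import (
    AromaticRing,
    ChargeCenter,
    HalogenAcceptor,
    HalogenDonor,
    HBondAcceptor,
    HBondDonor,
    HydrophobicAtom,
    SiteFeatures,
)
from nciprofiler.core import (
    KIND_LIGAND_CANDIDATE,
    KIND_PROTEIN,
    KIND_WATER,
    Atom,
    BindingSite,
    Residue,
    Structure,
)
from nciprofiler.geometry import fit_plane


# ---------------------------------------------------------------------------
# random scenes


class SceneBuilder:
    def __init__(self) -> None:
        self.serial = 0
        self.prot = Residue("A", 1, "", "UNK", kind=KIND_PROTEIN)
        self.lig = Residue("L", 1, "", "LG1", kind=KIND_LIGAND_CANDIDATE)
        self.wat = Residue("W", 1, "", "HOH", kind=KIND_WATER)

    def atom(self, side: str, element: str, xyz) -> Atom:
        self.serial += 1
        a = Atom(serial=self.serial, name=f"{element}{self.serial}", element=element,
                 coords=np.asarray(xyz, float))
        res = {"protein": self.prot, "ligand": self.lig, "water": self.wat}[side]
        res.atoms.append(a)
        return a

    def finish(self) -> BindingSite:
        st = Structure(identifier="scene", residues=[self.prot, self.lig, self.wat])
        return BindingSite(
            ligand=[self.lig], site_id="LG1:L:1", protein_residues=[self.prot],
            waters=[self.wat], structure=st,
        )


def random_scene(seed: int, box: float = 12.0) -> tuple[BindingSite, SiteFeatures]:
    """A random ~130-atom scene exercising every detector."""
    rng = np.random.default_rng(seed)
    b = SceneBuilder()
    f = SiteFeatures()

    def pos():
        return rng.uniform(0, box, size=3)

    def unit():
        v = rng.normal(size=3)
        return v / np.linalg.norm(v)

    for side, n in (("protein", 15), ("ligand", 15)):
        for _ in range(n):
            f.hydrophobic.append(HydrophobicAtom(atom=b.atom(side, "C", pos()), side=side))
    for side in ("protein", "ligand"):
        for _ in range(6):
            heavy = b.atom(side, "O", pos())
            h = b.atom(side, "H", heavy.coords + 0.96 * unit())
            f.hbond_donors.append(HBondDonor(heavy=heavy, hydrogens=(h,), side=side))
        for _ in range(6):
            f.hbond_acceptors.append(HBondAcceptor(heavy=b.atom(side, "O", pos()), side=side))
    for _ in range(5):
        f.waters.append(b.atom("water", "O", pos()))
    for side in ("protein", "ligand"):
        for _ in range(2):
            center, normal = pos(), unit()
            ref = np.cross(normal, [1.0, 0.0, 0.0])
            if np.linalg.norm(ref) < 1e-6:
                ref = np.cross(normal, [0.0, 1.0, 0.0])
            ref /= np.linalg.norm(ref)
            ref2 = np.cross(normal, ref)
            atoms = []
            for k in range(6):
                t = math.radians(60.0 * k)
                p = center + 1.39 * (math.cos(t) * ref + math.sin(t) * ref2)
                atoms.append(b.atom(side, "C", p))
            f.rings.append(AromaticRing(
                atoms=tuple(atoms), plane=fit_plane([a.coords for a in atoms]),
                residue=f"ring-{side}", side=side,
            ))
        for sign in (1, 1, -1, -1):
            atoms = tuple(b.atom(side, "N" if sign > 0 else "O", pos())
                          for _ in range(int(rng.integers(1, 4))))
            centroid = np.mean([a.coords for a in atoms], axis=0)
            f.charges.append(ChargeCenter(
                sign=sign, atoms=atoms, centroid=centroid,
                group="ammonium" if sign > 0 else "carboxylate", side=side,
            ))
    for _ in range(4):
        x = b.atom("ligand", "CL", pos())
        c = b.atom("ligand", "C", x.coords + 1.77 * unit())
        f.halogen_donors.append(HalogenDonor(halogen=x, carbon=c, side="ligand"))
    for _ in range(4):
        a = b.atom("protein", "O", pos())
        y = b.atom("protein", "C", a.coords + 1.23 * unit())
        f.halogen_acceptors.append(HalogenAcceptor(acceptor=a, neighbors=(y,), side="protein"))
    return b.finish(), f


# ---------------------------------------------------------------------------
# independent math


def odist(p, q) -> float:
    return math.sqrt(sum((a - c) ** 2 for a, c in zip(p, q)))


def oangle(a, v, c) -> float:
    v1 = [a[i] - v[i] for i in range(3)]
    v2 = [c[i] - v[i] for i in range(3)]
    dot = sum(x * y for x, y in zip(v1, v2))
    n1 = math.sqrt(sum(x * x for x in v1))
    n2 = math.sqrt(sum(x * x for x in v2))
    return math.degrees(math.acos(max(-1.0, min(1.0, dot / (n1 * n2)))))


def newell_normal(points):
    nx = ny = nz = 0.0
    m = len(points)
    for i in range(m):
        p, q = points[i], points[(i + 1) % m]
        nx += (p[1] - q[1]) * (p[2] + q[2])
        ny += (p[2] - q[2]) * (p[0] + q[0])
        nz += (p[0] - q[0]) * (p[1] + q[1])
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return (nx / norm, ny / norm, nz / norm)


def ring_centroid(ring):
    pts = [a.coords for a in ring.atoms]
    return [sum(p[i] for p in pts) / len(pts) for i in range(3)]


def lateral_offset(ring, point) -> float:
    c = ring_centroid(ring)
    n = newell_normal([a.coords for a in ring.atoms])
    v = [point[i] - c[i] for i in range(3)]
    along = sum(v[i] * n[i] for i in range(3))
    perp = [v[i] - along * n[i] for i in range(3)]
    return math.sqrt(sum(x * x for x in perp))


# ---------------------------------------------------------------------------
# brute-force oracles: each returns a set of hashable keys


def oracle_hydrophobic(f: SiteFeatures, cfg) -> set:
    return {
        (p.atom.serial, l.atom.serial)
        for p in f.hydrophobic if p.side == "protein"
        for l in f.hydrophobic if l.side == "ligand"
        if odist(p.atom.coords, l.atom.coords) <= cfg.hydrophobic_dist_max
    }


def oracle_hbond(f: SiteFeatures, cfg) -> set:
    out = set()
    for don in f.hbond_donors:
        for acc in f.hbond_acceptors:
            if don.side == acc.side or don.heavy is acc.heavy:
                continue
            if odist(don.heavy.coords, acc.heavy.coords) > cfg.hbond_dist_max:
                continue
            best = max(oangle(don.heavy.coords, h.coords, acc.heavy.coords)
                       for h in don.hydrogens)
            if best >= cfg.hbond_don_angle_min:
                out.add((don.heavy.serial, acc.heavy.serial))
    return out


def oracle_waterbridge(f: SiteFeatures, cfg) -> set:
    def polar(side):
        m = {}
        for d in f.hbond_donors:
            if d.side == side:
                m[d.heavy.serial] = (d.heavy, d.hydrogens, False)
        for a in f.hbond_acceptors:
            if a.side == side:
                atom, hs, _ = m.get(a.heavy.serial, (a.heavy, (), False))
                m[a.heavy.serial] = (atom, hs, True)
        return m

    def leg(atom, hs, acc, w):
        d = odist(atom.coords, w.coords)
        if not (cfg.waterbridge_mindist <= d <= cfg.waterbridge_maxdist):
            return False
        as_donor = bool(hs) and max(
            oangle(atom.coords, h.coords, w.coords) for h in hs
        ) >= cfg.waterbridge_theta_min
        return as_donor or acc

    out = set()
    for w in f.waters:
        for la, lh, lacc in polar("ligand").values():
            if not leg(la, lh, lacc, w):
                continue
            for pa, ph, pacc in polar("protein").values():
                if not leg(pa, ph, pacc, w):
                    continue
                om = oangle(la.coords, w.coords, pa.coords)
                if cfg.waterbridge_omega_min <= om <= cfg.waterbridge_omega_max:
                    out.add((la.serial, w.serial, pa.serial))
    return out


def oracle_saltbridge(f: SiteFeatures, cfg) -> set:
    out = set()
    for p in f.charges:
        for n in f.charges:
            if p.sign != 1 or n.sign != -1 or p.side == n.side:
                continue
            cp = [sum(a.coords[i] for a in p.atoms) / len(p.atoms) for i in range(3)]
            cn = [sum(a.coords[i] for a in n.atoms) / len(n.atoms) for i in range(3)]
            if odist(cp, cn) <= cfg.saltbridge_dist_max:
                prot, lig = (p, n) if p.side == "protein" else (n, p)
                out.add((frozenset(a.serial for a in prot.atoms),
                         frozenset(a.serial for a in lig.atoms)))
    return out


def oracle_pistack(f: SiteFeatures, cfg) -> set:
    out = set()
    for pr in f.rings:
        for lr in f.rings:
            if pr.side != "protein" or lr.side != "ligand":
                continue
            cp, cl = ring_centroid(pr), ring_centroid(lr)
            if odist(cp, cl) > cfg.pistack_dist_max:
                continue
            np_, nl = newell_normal([a.coords for a in pr.atoms]), newell_normal(
                [a.coords for a in lr.atoms])
            cosang = abs(sum(x * y for x, y in zip(np_, nl)))
            ang = math.degrees(math.acos(min(1.0, cosang)))
            if ang <= cfg.pistack_ang_dev:
                subtype = "P"
            elif abs(ang - 90.0) <= cfg.pistack_ang_dev:
                subtype = "T"
            else:
                continue
            if min(lateral_offset(pr, cl), lateral_offset(lr, cp)) > cfg.pistack_offset_max:
                continue
            out.add((frozenset(a.serial for a in pr.atoms),
                     frozenset(a.serial for a in lr.atoms), subtype))
    return out


def oracle_pication(f: SiteFeatures, cfg) -> set:
    out = set()
    for ring in f.rings:
        for ch in f.charges:
            if ch.sign != 1 or ch.side == ring.side:
                continue
            centroid = [sum(a.coords[i] for a in ch.atoms) / len(ch.atoms) for i in range(3)]
            if odist(ring_centroid(ring), centroid) > cfg.pication_dist_max:
                continue
            if lateral_offset(ring, centroid) > cfg.pistack_offset_max:
                continue
            ring_set = frozenset(a.serial for a in ring.atoms)
            charge_set = frozenset(a.serial for a in ch.atoms)
            if ring.side == "protein":
                out.add((ring_set, charge_set))
            else:
                out.add((charge_set, ring_set))
    return out


def oracle_halogen(f: SiteFeatures, cfg) -> set:
    out = set()
    for don in f.halogen_donors:
        for acc in f.halogen_acceptors:
            if don.side == acc.side:
                continue
            if odist(don.halogen.coords, acc.acceptor.coords) > cfg.halogen_dist_max:
                continue
            da = oangle(don.carbon.coords, don.halogen.coords, acc.acceptor.coords)
            if abs(da - cfg.halogen_don_angle) > cfg.halogen_angle_dev:
                continue
            angles = [oangle(y.coords, acc.acceptor.coords, don.halogen.coords)
                      for y in acc.neighbors]
            aa = min(angles, key=lambda a: abs(a - cfg.halogen_acc_angle))
            if abs(aa - cfg.halogen_acc_angle) > cfg.halogen_angle_dev:
                continue
            out.add((don.halogen.serial, acc.acceptor.serial))
    return out


# keys extracted from detector output, matching the oracle key shapes


def detector_keys(kind: str, interactions) -> set:
    if kind == "hydrophobic":
        return {(i.protein_atoms[0].serial, i.ligand_atoms[0].serial) for i in interactions}
    if kind == "hbond":
        out = set()
        for i in interactions:
            don, acc = (
                (i.protein_atoms[0], i.ligand_atoms[0])
                if i.donor_side == "protein"
                else (i.ligand_atoms[0], i.protein_atoms[0])
            )
            out.add((don.serial, acc.serial))
        return out
    if kind == "waterbridge":
        return {(i.ligand_atoms[0].serial, i.water.serial, i.protein_atoms[0].serial)
                for i in interactions}
    if kind in ("saltbridge", "pication"):
        return {(frozenset(a.serial for a in i.protein_atoms),
                 frozenset(a.serial for a in i.ligand_atoms))
                for i in interactions}
    if kind == "pistack":
        return {(frozenset(a.serial for a in i.protein_atoms),
                 frozenset(a.serial for a in i.ligand_atoms), i.subtype)
                for i in interactions}
    if kind == "halogen":
        out = set()
        for i in interactions:
            x = next(a for a in i.ligand_atoms if a.element in ("F", "CL", "BR", "I"))
            out.add((x.serial, i.protein_atoms[0].serial))
        return out
    raise KeyError(kind)


ORACLES = {
    "hydrophobic": oracle_hydrophobic,
    "hbond": oracle_hbond,
    "waterbridge": oracle_waterbridge,
    "saltbridge": oracle_saltbridge,
    "pistack": oracle_pistack,
    "pication": oracle_pication,
    "halogen": oracle_halogen,
}
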