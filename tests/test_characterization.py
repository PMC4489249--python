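"""Functional perception: hydrophobic carbons, donors/acceptors, rings,
charge centers."""

import math

import numpy as np
import pytest

from nciprofiler import extract_binding_sites, filter_ligands, hydrogenate, parse_pdb
from nciprofiler.characterization import (
    characterize,
    find_aromatic_rings,
    find_charge_centers,
    find_halogen_partners,
    find_hbond_partners,
    find_hydrophobic_atoms,
)
from nciprofiler.fixtures import FixtureSpec, build_fixture
from nciprofiler.geometry import fit_plane


def site_from_text(text):
    st = hydrogenate(parse_pdb(text))
    sites = extract_binding_sites(st, filter_ligands(st), cutoff=10.0)
    assert len(sites) == 1
    return sites[0]


def site_from_fixture(itype, **kw):
    return site_from_text(build_fixture(FixtureSpec(interaction_type=itype, **kw)))


LEU_WITH_LIG = """\
ATOM      1  CB  LEU A   1       0.000   0.000   0.000  1.00  1.00           C
ATOM      2  CG  LEU A   1       1.530   0.000   0.000  1.00  1.00           C
ATOM      3  CD1 LEU A   1       2.040   1.440   0.000  1.00  1.00           C
ATOM      4  CD2 LEU A   1       2.040  -1.440   0.000  1.00  1.00           C
HETATM    5  C1  LG1 L   1       5.500   0.000   0.000  1.00  1.00           C
END
"""

SER_WITH_LIG = """\
ATOM      1  CB  SER A   1       0.000   0.000   0.000  1.00  1.00           C
ATOM      2  OG  SER A   1       1.420   0.000   0.000  1.00  1.00           O
HETATM    3  C1  LG1 L   1       5.500   0.000   0.000  1.00  1.00           C
END
"""


def test_leucine_side_chain_is_hydrophobic():
    site = site_from_text(LEU_WITH_LIG)
    protein_names = {
        h.atom.name for h in find_hydrophobic_atoms(site) if h.side == "protein"
    }
    assert protein_names == {"CB", "CG", "CD1", "CD2"}


def test_serine_cb_is_not_hydrophobic():
    site = site_from_text(SER_WITH_LIG)
    assert all(
        h.atom.name != "CB" for h in find_hydrophobic_atoms(site) if h.side == "protein"
    )


def test_fatty_acid_chain_hydrophobic_except_carboxyl_carbon():
    lines = []
    for i in range(8):  # C1..C8 chain
        lines.append(
            f"HETATM{i + 1:>5}  C{i + 1}  LG1 L   1    {i * 1.52:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  1.00           C"
        )
    x = 7 * 1.52
    lines.append(f"HETATM    9  O1  LG1 L   1    {x + 0.6:8.3f}{1.1:8.3f}{0.0:8.3f}  1.00  1.00           O")
    lines.append(f"HETATM   10  O2  LG1 L   1    {x + 0.6:8.3f}{-1.1:8.3f}{0.0:8.3f}  1.00  1.00           O")
    lines.append("CONECT    8    9\nCONECT    8   10")
    lines.append("ATOM     11  CA  GLY A   1       0.000   8.000   0.000  1.00  1.00           C")
    lines.append("END")
    site = site_from_text("\n".join(lines) + "\n")
    names = {h.atom.name for h in find_hydrophobic_atoms(site) if h.side == "ligand"}
    assert names == {f"C{i + 1}" for i in range(7)}  # C8 bears the oxygens
    charges = find_charge_centers(site)
    assert [c.sign for c in charges if c.side == "ligand"] == [-1]


def test_tyrosine_hydroxyl_is_donor_and_acceptor():
    text = (
        "ATOM      1  CZ  TYR A   1       0.000   0.000   0.000  1.00  1.00           C\n"
        "ATOM      2  OH  TYR A   1       1.360   0.000   0.000  1.00  1.00           O\n"
        "HETATM    3  C1  LG1 L   1       5.500   0.000   0.000  1.00  1.00           C\n"
        "END\n"
    )
    site = site_from_text(text)
    donors, acceptors = find_hbond_partners(site)
    assert any(d.heavy.name == "OH" for d in donors)
    assert any(a.heavy.name == "OH" for a in acceptors)


def test_carboxylate_oxygen_is_acceptor_only():
    site = site_from_fixture("saltbridge")
    donors, acceptors = find_hbond_partners(site)
    lig_donors = {d.heavy.name for d in donors if d.side == "ligand"}
    lig_acceptors = {a.heavy.name for a in acceptors if a.side == "ligand"}
    assert lig_donors == set()
    assert {"O1", "O2"} <= lig_acceptors


def test_halogen_partner_perception():
    site = site_from_fixture("halogen")
    donors, acceptors = find_halogen_partners(site)
    assert len(donors) == 1 and donors[0].halogen.element == "CL"
    assert donors[0].carbon.element == "C"
    prot_acc = [a for a in acceptors if a.side == "protein"]
    assert any(a.acceptor.name == "O" for a in prot_acc)  # backbone carbonyl


def test_lone_chloride_ion_is_not_a_halogen_donor():
    text = (
        "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  1.00           C\n"
        "HETATM    2 CL   XCL L   1       4.000   0.000   0.000  1.00  1.00          CL\n"
        "END\n"
    )
    site = site_from_text(text)
    donors, _ = find_halogen_partners(site)
    assert donors == []


def test_phenylalanine_has_one_ring_tryptophan_two():
    phe_site = site_from_fixture("pistack")
    prot_rings = [r for r in find_aromatic_rings(phe_site) if r.side == "protein"]
    assert len(prot_rings) == 1 and len(prot_rings[0].atoms) == 6

    # idealized TRP bicyclic system (planar, correct names)
    coords = {
        "CG": (0.0, 0.0), "CD1": (1.09, 0.84), "NE1": (0.63, 2.13),
        "CE2": (-0.76, 2.19), "CD2": (-1.16, 0.85), "CE3": (-2.48, 0.40),
        "CZ3": (-3.44, 1.36), "CH2": (-3.11, 2.72), "CZ2": (-1.77, 3.17),
    }
    lines = [
        f"ATOM  {i + 1:>5}  {name:<3} TRP A   1    {x:8.3f}{y:8.3f}{0.0:8.3f}  1.00  1.00           "
        f"{name[0]}"
        for i, (name, (x, y)) in enumerate(coords.items())
    ]
    lines.append("HETATM   99  C1  LG1 L   1       0.000   0.000   4.000  1.00  1.00           C")
    lines.append("END")
    site = site_from_text("\n".join(lines) + "\n")
    rings = [r for r in find_aromatic_rings(site) if r.side == "protein"]
    assert sorted(len(r.atoms) for r in rings) == [5, 6]


def test_cyclohexane_chair_fails_planarity():
    """An ideal chair (tetrahedral angles, C-C 1.54) has point-plane RMSD
    just above the 0.25 A tolerance and must not count as aromatic."""
    r = 1.54 / math.sqrt(1.125)
    d = r / (4 * math.sqrt(2))
    lines = []
    pts = []
    for k in range(6):
        t = math.radians(60 * k)
        x, y, z = r * math.cos(t), r * math.sin(t), d * (-1) ** k
        pts.append((x, y, z))
        lines.append(
            f"HETATM{k + 1:>5}  C{k + 1}  LG1 L   1    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  1.00           C"
        )
    for k in range(6):
        lines.append(f"CONECT{k + 1:>5}{(k + 1) % 6 + 1:>5}")
    lines.append("ATOM     11  CA  GLY A   1       0.000   0.000   5.000  1.00  1.00           C")
    lines.append("END")
    assert fit_plane(pts).planarity_rmsd > 0.25  # oracle on the raw coordinates
    site = site_from_text("\n".join(lines) + "\n")
    assert [r for r in find_aromatic_rings(site) if r.side == "ligand"] == []


def test_benzene_ring_agrees_with_rdkit_aromaticity():
    """Independent cross-check: RDKit perceives the fixture benzene as
    aromatic; our geometric perception finds the same six atoms."""
    rdkit = pytest.importorskip("rdkit")
    from rdkit import Chem

    site = site_from_fixture("pication")
    ours = [r for r in find_aromatic_rings(site) if r.side == "ligand"]
    assert len(ours) == 1

    mol = Chem.RWMol()
    lig = site.ligand[0]
    idx = {}
    conf_pos = []
    for a in lig.heavy_atoms():
        idx[a.serial] = mol.AddAtom(Chem.Atom(a.element.capitalize()))
        conf_pos.append(a.coords)
    seen = set()
    for a in lig.heavy_atoms():
        for s in a.bonded_serials:
            if s in idx and (s, a.serial) not in seen:
                mol.AddBond(idx[a.serial], idx[s], Chem.BondType.SINGLE)
                seen.add((a.serial, s))
    m = mol.GetMol()
    Chem.SanitizeMol(m, Chem.SanitizeFlags.SANITIZE_ALL ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE)
    Chem.SetAromaticity(m)
    ri = m.GetRingInfo()
    assert ri.NumRings() == 1 and len(ri.AtomRings()[0]) == 6


def test_arginine_guanidinium_centroid():
    site = site_from_fixture("saltbridge")
    pos = [c for c in find_charge_centers(site) if c.side == "protein"]
    assert len(pos) == 1 and pos[0].sign == 1 and pos[0].group == "guanidinium"
    arg = site.protein_residues[0]
    expected = np.mean(
        [arg.atom(n).coords for n in ("CZ", "NH1", "NH2")], axis=0
    )
    assert np.allclose(pos[0].centroid, expected, atol=1e-9)


def test_alanine_has_no_charge_center():
    text = (
        "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  1.00           C\n"
        "ATOM      2  CB  ALA A   1       1.520   0.000   0.000  1.00  1.00           C\n"
        "HETATM    3  C1  LG1 L   1       5.000   0.000   0.000  1.00  1.00           C\n"
        "END\n"
    )
    site = site_from_text(text)
    assert [c for c in find_charge_centers(site) if c.side == "protein"] == []


def test_histidine_neutral_by_default():
    coords = {"CG": (0.0, 0.0), "ND1": (1.19, 0.71), "CD2": (-0.14, 1.36),
              "CE1": (2.06, -0.31), "NE2": (1.09, 2.05)}
    lines = [
        f"ATOM  {i + 1:>5}  {n:<3} HIS A   1    {x:8.3f}{y:8.3f}{0.0:8.3f}  1.00  1.00           {n[0]}"
        for i, (n, (x, y)) in enumerate(coords.items())
    ]
    lines.append("HETATM    9  C1  LG1 L   1       0.000   0.000   4.000  1.00  1.00           C")
    lines.append("END")
    site = site_from_text("\n".join(lines) + "\n")
    assert [c for c in find_charge_centers(site) if c.side == "protein"] == []


def test_no_atom_in_opposite_sign_centers():
    for itype in ("saltbridge", "pication", "hbond"):
        site = site_from_fixture(itype)
        charges = find_charge_centers(site)
        pos = {a.serial for c in charges if c.sign == 1 for a in c.atoms}
        neg = {a.serial for c in charges if c.sign == -1 for a in c.atoms}
        assert not (pos & neg)


def test_perception_invariant_under_rigid_motion():
    def summary(seed):
        site = site_from_fixture("saltbridge", seed=seed)
        feats = characterize(site)
        return (
            sorted(h.atom.name for h in feats.hydrophobic),
            sorted(d.heavy.name for d in feats.hbond_donors),
            sorted((c.sign, c.group) for c in feats.charges),
        )

    assert summary(0) == summary(5) == summary(9)


def test_rings_satisfy_their_own_planarity_invariant():
    for itype in ("pistack", "pication"):
        site = site_from_fixture(itype)
        for ring in find_aromatic_rings(site):
            refit = fit_plane([a.coords for a in ring.atoms])
            assert refit.planarity_rmsd <= 0.25
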