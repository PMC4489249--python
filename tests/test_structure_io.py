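"""Structure preparation: parsing, altloc policy, hydrogenation rules,
ligand filtering and binding-site extraction."""

import numpy as np
import pytest

from nciprofiler import (
    extract_binding_sites,
    filter_ligands,
    hydrogenate,
    parse_pdb,
    write_pdb,
)
from nciprofiler.core import KIND_EXCLUDED, KIND_PROTEIN, KIND_WATER
from nciprofiler.fixtures import FixtureSpec, build_fixture
from nciprofiler.structure_io import ModelNotFoundError, PDBParseError, default_blacklist

GLYCINE = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  1.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  1.00           C
ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  1.00           C
ATOM      4  O   GLY A   1       1.251   2.390   0.000  1.00  1.00           O
END
"""

WATER_LINE = "HETATM    9  O   HOH B   1       8.000   0.000   0.000  1.00  1.00           O\n"


def test_parse_minimal_glycine():
    st = parse_pdb(GLYCINE)
    assert len(st.residues) == 1
    res = st.residues[0]
    assert res.kind == KIND_PROTEIN and res.code == "GLY"
    assert [a.name for a in res.atoms] == ["N", "CA", "C", "O"]
    # peptide-style bonds inferred from covalent radii
    ca = res.atom("CA")
    assert set(ca.bonded_serials) == {1, 3}


def test_water_residue_kind():
    st = parse_pdb(GLYCINE.replace("END\n", WATER_LINE + "END\n"))
    water = [r for r in st.residues if r.code == "HOH"]
    assert len(water) == 1 and water[0].kind == KIND_WATER


def test_altloc_keeps_highest_occupancy():
    text = (
        "ATOM      1  N  AGLY A   1       0.000   0.000   0.000  0.60  1.00           N\n"
        "ATOM      2  N  BGLY A   1       0.500   0.000   0.000  0.40  1.00           N\n"
        "END\n"
    )
    st = parse_pdb(text)
    atoms = list(st.atoms())
    assert len(atoms) == 1
    assert atoms[0].serial == 1 and atoms[0].coords[0] == pytest.approx(0.0)


def test_altloc_tie_breaks_by_letter():
    text = (
        "ATOM      1  N  BGLY A   1       0.500   0.000   0.000  0.50  1.00           N\n"
        "ATOM      2  N  AGLY A   1       0.000   0.000   0.000  0.50  1.00           N\n"
        "END\n"
    )
    st = parse_pdb(text)
    assert list(st.atoms())[0].altloc == "A"


def test_parse_errors():
    with pytest.raises(PDBParseError):
        parse_pdb("REMARK nothing here\n")
    garbled = "ATOM      1  N   GLY A   1       x.000   0.000   0.000  1.00  1.00\n"
    with pytest.raises(PDBParseError, match="line 1"):
        parse_pdb(garbled)
    with pytest.raises(ModelNotFoundError, match=r"\[1\]"):
        parse_pdb(GLYCINE, model=3)


def test_multi_model_selection():
    text = (
        "MODEL        1\n"
        + GLYCINE.replace("END\n", "ENDMDL\nMODEL        2\n")
        + GLYCINE.replace("   0.000   0.000   0.000", "   9.000   0.000   0.000").replace("END\n", "ENDMDL\nEND\n")
    )
    st1 = parse_pdb(text, model=1)
    st2 = parse_pdb(text, model=2)
    assert st1.residues[0].atom("N").coords[0] == pytest.approx(0.0)
    assert st2.residues[0].atom("N").coords[0] == pytest.approx(9.0)


def test_write_parse_roundtrip_coordinates():
    spec = FixtureSpec(interaction_type="saltbridge", seed=3)
    st = parse_pdb(build_fixture(spec))
    reparsed = parse_pdb(write_pdb(st))
    a1 = sorted(st.atoms(), key=lambda a: a.serial)
    a2 = sorted(reparsed.atoms(), key=lambda a: a.serial)
    assert len(a1) == len(a2)
    for x, y in zip(a1, a2):
        assert np.allclose(x.coords, y.coords, atol=5e-4)  # 3-decimal PDB precision


# ---------------------------------------------------------------------------
# hydrogenation


SERINE = """\
ATOM      1  CB  SER A   1       0.000   0.000   0.000  1.00  1.00           C
ATOM      2  OG  SER A   1       1.420   0.000   0.000  1.00  1.00           O
END
"""


def test_serine_gains_exactly_one_hydroxyl_hydrogen():
    st = hydrogenate(parse_pdb(SERINE))
    og = st.residues[0].atom("OG")
    hs = st.hydrogens_of(og)
    assert len(hs) == 1
    assert np.linalg.norm(hs[0].coords - og.coords) == pytest.approx(0.96, abs=1e-6)


def test_hydrogenate_is_idempotent():
    st = hydrogenate(parse_pdb(SERINE))
    n = sum(1 for _ in st.atoms())
    hydrogenate(st)
    assert sum(1 for _ in st.atoms()) == n


def test_carboxylate_stays_deprotonated():
    """pH-7 policy: neither acetate oxygen receives a hydrogen."""
    st = hydrogenate(parse_pdb(build_fixture(FixtureSpec(interaction_type="saltbridge"))))
    lig = next(r for r in st.residues if r.code == "LG1")
    for name in ("O1", "O2"):
        assert st.hydrogens_of(lig.atom(name)) == []


def test_heavy_atoms_never_move():
    st = parse_pdb(build_fixture(FixtureSpec(interaction_type="waterbridge")))
    before = {a.serial: a.coords.copy() for a in st.atoms() if not a.is_hydrogen}
    hydrogenate(st)
    for serial, coords in before.items():
        assert np.array_equal(st.atom_by_serial(serial).coords, coords)


def test_proline_backbone_not_protonated():
    text = (
        "ATOM      1  N   PRO A   1       0.000   0.000   0.000  1.00  1.00           N\n"
        "ATOM      2  CA  PRO A   1       1.470   0.000   0.000  1.00  1.00           C\n"
        "ATOM      3  CD  PRO A   1      -0.700   1.280   0.000  1.00  1.00           C\n"
        "END\n"
    )
    st = hydrogenate(parse_pdb(text))
    assert st.hydrogens_of(st.residues[0].atom("N")) == []


# ---------------------------------------------------------------------------
# ligand filtering


def test_blacklist_excludes_solvent_and_ions():
    """A fatty-acid-like HET plus glycerol and sulfate: only the fatty
    acid survives the blacklist."""
    lines = []
    serial = 1
    # short fatty-acid chain with carboxylate (code PLM kept)
    for i in range(4):
        lines.append(
            f"HETATM{serial:>5}  C{i + 1}  PLM A 101    {i * 1.52:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  1.00           C"
        )
        serial += 1
    lines.append(f"HETATM{serial:>5}  C5  GOL A 102    {0.0:8.3f}{8.0:8.3f}{0.0:8.3f}  1.00  1.00           C")
    serial += 1
    lines.append(f"HETATM{serial:>5}  S   SO4 A 103    {8.0:8.3f}{8.0:8.3f}{0.0:8.3f}  1.00  1.00           S")
    lines.append("END")
    st = parse_pdb("\n".join(lines) + "\n")
    kept = filter_ligands(st)
    assert [r.code for r in kept] == ["PLM"]
    excluded = {r.code: r.exclusion_reason for r in st.residues if r.kind == KIND_EXCLUDED}
    assert set(excluded) == {"GOL", "SO4"}


def test_only_solvent_yields_empty_list():
    text = (
        "HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  1.00           O\n"
        "HETATM    2 NA    NA A   2       5.000   0.000   0.000  1.00  1.00          NA\n"
        "END\n"
    )
    assert filter_ligands(parse_pdb(text)) == []


def test_covalently_linked_het_is_excluded():
    text = (
        "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  1.00           C\n"
        "ATOM      2  C   GLY A   1       1.520   0.000   0.000  1.00  1.00           C\n"
        "HETATM    3  N1  ABC A   2       2.850   0.000   0.000  1.00  1.00           N\n"
        "HETATM    4  C1  ABC A   2       3.500   1.300   0.000  1.00  1.00           C\n"
        "CONECT    2    3\nCONECT    3    2    4\n"
        "END\n"
    )
    st = parse_pdb(text)
    assert filter_ligands(st) == []
    abc = next(r for r in st.residues if r.code == "ABC")
    assert abc.kind == KIND_EXCLUDED and "covalent" in abc.exclusion_reason


def test_blacklist_is_monotone():
    st = parse_pdb(build_fixture(FixtureSpec(interaction_type="hbond")))
    small = filter_ligands(st, blacklist=set())
    large = filter_ligands(st, blacklist={"LG1"})
    assert {r.key for r in large} <= {r.key for r in small}


# ---------------------------------------------------------------------------
# binding sites


def _two_residue_structure(dist):
    text = (
        "ATOM      1  CA  GLY A   1    " + f"{dist:8.3f}{0.0:8.3f}{0.0:8.3f}" + "  1.00  1.00           C\n"
        "HETATM    2  C1  LG1 B   1       0.000   0.000   0.000  1.00  1.00           C\n"
        "END\n"
    )
    st = parse_pdb(text)
    return st, filter_ligands(st)


def test_site_membership_boundary():
    st, ligs = _two_residue_structure(7.4)
    sites = extract_binding_sites(st, ligs, cutoff=7.5)
    assert len(sites[0].protein_residues) == 1
    st, ligs = _two_residue_structure(8.5)
    sites = extract_binding_sites(st, ligs, cutoff=7.5)
    assert sites[0].protein_residues == [] and sites[0].isolated


def test_two_ligand_copies_give_two_sites():
    text = (
        "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  1.00           C\n"
        "HETATM    2  C1  LG1 A   9       3.000   0.000   0.000  1.00  1.00           C\n"
        "HETATM    3  C1  LG1 B   9      -3.000   0.000   0.000  1.00  1.00           C\n"
        "END\n"
    )
    st = parse_pdb(text)
    sites = extract_binding_sites(st, filter_ligands(st), cutoff=7.5)
    assert sorted(s.site_id for s in sites) == ["LG1:A:9", "LG1:B:9"]


def test_conect_linked_ligand_residues_merge_into_one_site():
    text = (
        "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  1.00           C\n"
        "HETATM    2  C1  SUG A   9       3.000   0.000   0.000  1.00  1.00           C\n"
        "HETATM    3  C1  SUG A  10       4.400   0.000   0.000  1.00  1.00           C\n"
        "CONECT    2    3\nCONECT    3    2\n"
        "END\n"
    )
    st = parse_pdb(text)
    sites = extract_binding_sites(st, filter_ligands(st), cutoff=7.5)
    assert len(sites) == 1 and len(sites[0].ligand) == 2


def test_site_membership_rigid_motion_invariant():
    spec0 = FixtureSpec(interaction_type="saltbridge", seed=0)
    spec1 = FixtureSpec(interaction_type="saltbridge", seed=11)

    def members(spec):
        st = parse_pdb(build_fixture(spec))
        sites = extract_binding_sites(st, filter_ligands(st))
        return {r.key for s in sites for r in s.protein_residues}

    assert members(spec0) == members(spec1)


def test_default_blacklist_contents():
    bl = default_blacklist()
    assert {"HOH", "GOL", "SO4", "NA"} <= bl
    assert "LG1" not in bl
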