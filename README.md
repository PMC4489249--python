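# nciprofiler

Rule-based profiling of **non-covalent protein–ligand interactions** in 3D
structures. Given a protein–ligand complex in PDB format — a crystal
structure, a docking pose or an MD snapshot — `nciprofiler` reports, at
single-atom detail, contacts of seven types:

hydrogen bonds, hydrophobic contacts, π-stacking, π-cation interactions,
salt bridges, water bridges and halogen bonds.

It is aimed at structural bioinformaticians and medicinal chemists who need
parsable interaction inventories (e.g. for pose inspection, fingerprinting,
or high-throughput post-processing of docking runs) without manual
structure preparation.

## How it works

The pipeline has four stages:

1. **Structure preparation** — parse the PDB file (altloc conflicts
   resolved by highest occupancy), place polar hydrogens with an explicit
   pH-7 rule set, exclude solvents/ions/buffer artifacts via an editable
   blacklist plus a covalent-linkage check, and extract one binding site
   per ligand (all protein residues and waters within 7.5 Å of any ligand
   heavy atom).
2. **Functional characterization** — perceive hydrophobic carbons (all
   heavy neighbors carbon), hydrogen-/halogen-bond donors and acceptors,
   aromatic rings (residue templates for Phe/Tyr/Trp/His; planarity-checked
   5/6-cycles for ligands) and formal charge centers (Arg/Lys/His⁺,
   Asp/Glu⁻; carboxylate, phosphate, sulfonate, ammonium, guanidinium and
   quaternary-amine patterns on the ligand).
3. **Geometric matching** — one detector per interaction type applies
   distance/angle inequalities between protein-side and ligand-side
   features. For example a hydrogen bond requires d(D···A) ≤ 4.1 Å and
   ∠(D–H···A) ≥ 100°; a halogen bond requires d(X···A) ≤ 4.0 Å with
   ∠(C–X···A) = 165° ± 30° (σ-hole directionality) and
   ∠(Y–A···X) = 120° ± 30°. All thresholds are configurable
   (`ThresholdConfig`, `--threshold KEY=VALUE`).
4. **Refinement** — redundant records are filtered: hydrophobic contacts
   are reduced to the shortest contact per atom neighbourhood, a hydrogen
   bond inside a reported salt bridge is dropped in favour of the salt
   bridge, and a water bridge duplicating a direct hydrogen bond is pruned.

Results serialize to a stable XML schema (`docs/report-schema.md`), a
flat `|`-delimited text table, and a plain-text PyMOL command script.

## Worked example

Generate a guanidinium/carboxylate complex with the built-in fixture
generator and profile it:

```
python -c "
from nciprofiler.fixtures import FixtureSpec, build_fixture
open('saltbridge.pdb','w').write(build_fixture(FixtureSpec(interaction_type='saltbridge')))"
nciprof -i saltbridge.pdb --out out
```

prints

```
saltbridge.pdb LG1:L:1: 1 interactions (saltbridge:1)
```

and `out/saltbridge/report.txt` contains

```
Binding site LG1:L:1
------------------------------------------------------------
** saltbridge (1) **
| RESIDUE | PROT_ATOMS | LIG_ATOMS | WATER | DONOR | SUBTYPE                 | DIST |
| ARG-A-1 | 2+3+4      | 6+7       | -     | n/a   | guanidinium/carboxylate | 4.00 |
```

The arginine-like guanidinium center (atoms CZ/NH1/NH2, serials 2–4) and
the ligand carboxylate oxygens (serials 6–7) sit 4.00 Å apart — inside the
5.5 Å salt-bridge cutoff. The N–H···O hydrogen bonds that co-occur with
the salt bridge were detected and then removed by the refinement stage:
only the salt bridge is reported for that atom pairing.

The same result is available from Python:

```python
from nciprofiler import profile
result = profile("saltbridge.pdb")
print(result.inventory("LG1:L:1"))   # {'saltbridge': 1}
```

## Layout

- `src/nciprofiler/` — library: `structure_io`, `geometry`,
  `characterization`, `detectors`, `refinement`, `report`, `fixtures`,
  `pipeline`, `cli`.
- `docs/methods.md` — model, perception rules, thresholds and limitations.
- `tests/` — unit, property and end-to-end acceptance tests.
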