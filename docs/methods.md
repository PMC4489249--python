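# Methods

This note documents the models, rules and numeric choices behind
`nciprofiler`, the assumptions they rest on, and what the synthetic test
fixtures do and do not demonstrate.

## Scope and model

The package treats interaction detection as a *rule-based geometric
classification* problem: given the atoms of a protein–ligand interface and
a perception of their chemistry (donors, acceptors, rings, charges), an
interaction of a given type exists iff a fixed set of distance/angle
inequalities holds. No energies are computed; the output is a discrete
inventory, not a score. This matches how interaction profiles are consumed
in practice (pose triage, fingerprints, figures), and it makes every
reported record auditable: each one carries the measured geometry that
satisfied its thresholds.

## Structure preparation

**Parsing.** Fixed-column PDB parsing is delegated to gemmi; one model is
analyzed at a time (default: the first). Alternate locations are collapsed
to a single conformer by highest occupancy, ties broken by altloc letter —
a deterministic single-conformer policy. CONECT records seed the bond
graph; remaining bonds are inferred when the interatomic distance is below
the sum of covalent radii + 0.45 Å (hydrogens keep only their nearest
heavy partner; elements without a tabulated radius, i.e. metals, are never
bonded).

**Hydrogenation.** Many PDB files carry no hydrogens, but donor-angle
criteria need them. Polar hydrogens are placed by explicit rules at a pH-7
protonation policy: Arg and Lys protonated, Asp/Glu deprotonated, His
neutral (tau tautomer: H on NE2 only). Fixed sp2 hydrogens (backbone and
side-chain amides, guanidinium, ring NH) are placed in the plane of their
heavy-atom frame at idealized 120° geometry. Rotatable hydrogens
(hydroxyl, thiol, ammonium) are oriented toward the nearest plausible
acceptor within 4.5 Å — the deterministic analogue of the
protonation-optimization step performed by preparation toolkits — or anti
to their heavy neighbour when no acceptor is in range. Pre-existing
hydrogens always count toward a donor's quota, so hydrogenation is
idempotent and never moves heavy atoms.

For ligands (whose PDB records carry no bond orders) the hydrogen count is
derived from connectivity plus one geometric disambiguation: a terminal
oxygen with a C–O bond shorter than 1.30 Å is treated as a carbonyl
(1.23 Å typical) rather than a hydroxyl (1.43 Å). Carboxylate, phosphate
and sulfonate oxygens are left deprotonated; terminal amines on aliphatic
carbon are protonated (ammonium), those on ring carbons left neutral
(aniline-like); ring nitrogens of degree 2 are treated as pyridine-like
acceptors. These rules are a documented superset that can misassign exotic
HET chemistry; they are intentionally simple and testable.

**Ligand filtering.** Candidates are HETATM residues. A residue is
rejected if (a) its code is on the blacklist (waters, monoatomic ions,
cryoprotectants/buffers; shipped as an editable text file), or (b) it is
covalently bonded to a protein backbone atom — the connectivity signature
of a modified residue sitting inside a polymer chain. Both mechanisms run,
since published blacklists do not state which one they rely on. Ligand
residues linked to each other by CONECT (saccharide chains) merge into one
composite ligand and one binding site.

**Binding sites.** One site per (composite) ligand: every protein residue
or water with any atom within 7.5 Å of any ligand heavy atom. The cutoff
is a generous envelope exceeding the largest detector cutoff (6.0 Å), so
no detector can miss a partner; it is configurable.

## Functional characterization

- *Hydrophobic atoms*: carbons whose bonded heavy neighbours are all
  carbon.
- *H-bond donors*: N/O/S bearing ≥ 1 hydrogen after hydrogenation.
  *Acceptors*: any O; N without hydrogens and fewer than four connections
  (pyridine, tertiary amine — not amide or ammonium); S with ≤ 2 heavy
  neighbours (Met thioether allowed, no special weighting). Waters are
  excluded from both lists; the water-bridge detector owns them.
- *Halogen donors*: ligand C–X units (X = F/Cl/Br/I, singly bonded to
  carbon). Fluorine is kept as a weak donor. Protein-side halogen donors
  are off by default (no halogenated standard residues) but can be enabled
  for modified residues. *Acceptors*: O/N/S with at least one heavy
  neighbour (the Y atom defining the Y–A axis; with several neighbours the
  one closest to the target acceptor angle is scored).
- *Aromatic rings*: Phe/Tyr/Trp/His side chains by residue template;
  ligand rings are 5/6-cycles (minimum cycle basis of the ligand bond
  graph) of sp2-capable atoms (C/N/O/S, ≤ 3 heavy neighbours) whose
  least-squares plane has RMSD ≤ 0.25 Å. The geometric route is primary
  because PDB connectivity carries no bond orders, so toolkit aromaticity
  perception on raw HET records is unreliable; RDKit aromaticity serves as
  an independent cross-check in the test suite. The 0.25 Å tolerance
  rejects an ideal cyclohexane chair (RMSD 0.257 Å) while accepting
  slightly distorted aromatic rings.
- *Charge centers*: protein — Arg guanidinium (+, centroid of CZ/NH1/NH2),
  Lys NZ (+), His (+ only if both ring nitrogens are protonated, which the
  default tautomer policy avoids), Asp/Glu carboxylate (−, centroid of the
  two O). Ligand — carboxylate/phosphate/sulfonate (−, centroid of the
  terminal oxygens), ammonium, quaternary N, guanidine (+). Centroids are
  unweighted means.

## Detector thresholds

All values live in `ThresholdConfig`, are echoed into every report, and
can be overridden per run. The defaults are permissive, literature-style
values — chosen to tolerate moderate coordinate error rather than to
maximize precision:

| quantity | default |
|---|---|
| hydrophobic C···C | ≤ 4.0 Å |
| H-bond D···A / ∠D–H···A | ≤ 4.1 Å / ≥ 100° |
| π-stack centroid dist / angle dev / offset | ≤ 5.5 Å / 30° / ≤ 2.0 Å |
| π-cation centroid dist | ≤ 6.0 Å |
| salt-bridge centroid dist | ≤ 5.5 Å |
| halogen X···A / ∠C–X···A / ∠Y–A···X | ≤ 4.0 Å / 165°±30° / 120°±30° |
| water-bridge legs / ω at water / θ donor | 2.5–4.1 Å / 75–140° / ≥ 100° |

π-stacking classifies parallel (plane angle ≤ 30°) and T-shaped
(90° ± 30°) subtypes; the lateral offset is the smaller of the two
centroid projections. A water-bridge leg qualifies if the polar atom can
act as an acceptor, or as a donor whose best D–H···O(water) angle clears
θ; the water oxygen itself needs no hydrogens (most depositions lack
them), only the ω window at the oxygen. Intra-molecular pairs are never
reported. Per-ring records are pairs, not cliques: a ligand ring stacking
with two protein rings yields two records.

## Refinement

Detectors over-report by design; refinement thins deterministically:

1. *Hydrophobic reduction*: keep the nearest protein partner per ligand
   atom, then the nearest ligand partner per surviving protein atom
   (≤ 1 contact per atom on each side). Tie-break: lower protein, then
   ligand, serial. The two-pass order is fixed for reproducibility.
2. *Salt-bridge precedence*: an H-bond whose donor and acceptor both lie
   inside one salt bridge's atom sets is removed. The same rule drops the
   rare H-bond duplicating a π-cation pairing (logged).
3. *Water-bridge vs direct H-bond*: a bridge duplicating the exact
   ligand/protein polar pairing of a direct H-bond is dropped — the direct
   bond is the more parsimonious reading of the density. π-stacking and
   π-cation co-occurrence is kept (both recorded), since thinning it is a
   judgment call better left to the consumer.

Refinement never adds records, never edits measurements, and is
idempotent; the test suite asserts all three plus the no-pair-in-two-types
invariant.

## Synthetic fixtures: what they show

The fixture generator builds minimal complexes — one or two real protein
residues with correct atom nomenclature plus a small fictitious `LG1`
ligand — placed so one target interaction holds with exact geometry
(e.g. the salt-bridge centroids at exactly 4.00 Å), while every other
detector stays silent by construction spacing (e.g. stacked rings are kept
staggered at 4.3 Å so no C···C pair enters the 4.0 Å hydrophobic cutoff).
Decoys place the same groups outside the thresholds by ≥ 0.2 Å / ≥ 5°.
A seed-derived rigid motion is applied to the whole complex (seed 0 keeps
the canonical axis-aligned frame); this exercises orientation independence
without touching internal geometry, and fixtures are byte-reproducible per
seed.

These fixtures validate the *rules* — perception, inequalities,
refinement, serialization — under ideal chemistry. They do not emulate
coordinate noise, missing atoms, ambiguous protonation, bad HET
connectivity or crystal-contact artifacts, so passing them bounds
correctness of the logic, not robustness on poor real-world structures.
The permissive thresholds and the fallback perception paths are the
mitigations for those, and real-structure spot checks remain the user's
responsibility.

## Numerical choices and degenerate inputs

- Angles in degrees everywhere; distances in Å; reports fixed to two
  decimals (PDB precision bounds meaningful digits).
- Plane fitting is SVD least-squares; the normal sign convention (positive
  z, ties by y then x) makes serialized geometry bit-reproducible.
  Collinear inputs and zero-length angle arms raise
  `DegenerateGeometryError` rather than returning junk.
- Problem sizes: oracle-equivalence checks run 100 random ~130-atom scenes
  (700 detector/oracle comparisons); rigid-motion checks run 20 random
  frames per fixture type. Both complete in seconds and the scene size
  comfortably covers the densities seen in real binding sites.
- The acceptance script derives all randomness from `--seed` and keeps
  derived seeds below 2³¹.

## Known limitations

- No metal coordination, amide-π, or cation-π subtype distinctions beyond
  donor-side labelling; no pKa prediction or partial charges.
- Ligand protonation/charge rules are connectivity heuristics; unusual
  tautomers or charged heterocycles may be missed (configurable thresholds
  and the permissive acceptor rules soften, but do not remove, this).
- mmCIF input, symmetry expansion and multi-model ensemble analysis are
  out of scope; only one model is profiled per run.
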