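"""Redundancy filtering of detected interactions (pipeline step D).

Detectors deliberately over-report: any close apolar carbon pair is a
hydrophobic candidate, and a salt bridge usually doubles as one or more
hydrogen bonds between the same charged groups. This module thins the raw
lists to the most relevant records:

* hydrophobic contacts are reduced to at most one contact per ligand atom
  and one per protein atom, keeping the shortest distance in each
  neighbourhood;
* a hydrogen bond whose donor and acceptor both belong to the atom sets of
  one reported salt bridge is dropped (the salt bridge is reported);
* a water bridge that duplicates the ligand/protein pairing of a reported
  direct hydrogen bond is dropped (the direct bond is the more
  parsimonious explanation).

All operations are pure: they never add records, never edit measurements,
and are idempotent.
"""

from __future__ import annotations

import logging

from .detectors import INTERACTION_TYPES, Interaction

__all__ = ["reduce_hydrophobic", "dedup_saltbridge_hbond", "dedup_waterbridge_hbond", "refine"]

logger = logging.getLogger(__name__)


def reduce_hydrophobic(contacts: list[Interaction]) -> list[Interaction]:
    """Keep the most relevant hydrophobic contacts: the nearest protein
    partner per ligand atom, then the nearest ligand partner per surviving
    protein atom. Ties break toward the lower protein (then ligand) atom
    serial for determinism."""
    if any(c.type != "hydrophobic" for c in contacts):
        raise ValueError("reduce_hydrophobic expects only hydrophobic interactions")

    def keep_best(pool: list[Interaction], key_side: str) -> list[Interaction]:
        best: dict[int, Interaction] = {}
        for c in pool:
            key_atom = (c.ligand_atoms if key_side == "ligand" else c.protein_atoms)[0]
            rank = (
                c.measurement("dist"),
                c.protein_atoms[0].serial,
                c.ligand_atoms[0].serial,
            )
            cur = best.get(key_atom.serial)
            if cur is None or rank < (
                cur.measurement("dist"),
                cur.protein_atoms[0].serial,
                cur.ligand_atoms[0].serial,
            ):
                best[key_atom.serial] = c
        return [c for c in pool if best[
            (c.ligand_atoms if key_side == "ligand" else c.protein_atoms)[0].serial
        ] is c]

    survivors = keep_best(contacts, "ligand")
    return keep_best(survivors, "protein")


def _serials(atoms) -> frozenset[int]:
    return frozenset(a.serial for a in atoms)


def dedup_saltbridge_hbond(interactions: dict[str, list[Interaction]]) -> dict[str, list[Interaction]]:
    """Salt-bridge precedence: remove hydrogen bonds whose donor and
    acceptor heavy atoms are both members of one reported salt bridge.
    Analogously, a hydrogen bond from a cation nitrogen to a ring atom of
    a reported pi-cation partner is dropped (rare; logged)."""
    out = dict(interactions)
    bridges = [
        (_serials(sb.protein_atoms), _serials(sb.ligand_atoms))
        for sb in interactions.get("saltbridge", [])
    ]
    pications = [
        (_serials(pc.protein_atoms), _serials(pc.ligand_atoms))
        for pc in interactions.get("pication", [])
    ]

    def subsumed(hb: Interaction) -> bool:
        p, l = hb.protein_atoms[0].serial, hb.ligand_atoms[0].serial
        for prot_set, lig_set in bridges:
            if p in prot_set and l in lig_set:
                return True
        for prot_set, lig_set in pications:
            if p in prot_set and l in lig_set:
                logger.info("hbond %s subsumed by pi-cation record", hb.residue_label)
                return True
        return False

    out["hbond"] = [hb for hb in interactions.get("hbond", []) if not subsumed(hb)]
    return out


def dedup_waterbridge_hbond(interactions: dict[str, list[Interaction]]) -> dict[str, list[Interaction]]:
    """Drop water bridges that duplicate the exact ligand-polar/protein-polar
    pairing of a reported direct hydrogen bond. One water may still carry
    several distinct bridges."""
    out = dict(interactions)
    direct = {
        (hb.protein_atoms[0].serial, hb.ligand_atoms[0].serial)
        for hb in interactions.get("hbond", [])
    }
    out["waterbridge"] = [
        wb for wb in interactions.get("waterbridge", [])
        if (wb.protein_atoms[0].serial, wb.ligand_atoms[0].serial) not in direct
    ]
    return out


def refine(interactions: dict[str, list[Interaction]]) -> dict[str, list[Interaction]]:
    """Apply all refinement steps; returns a new mapping with the same
    seven keys."""
    out = dict(interactions)
    out["hydrophobic"] = reduce_hydrophobic(list(out.get("hydrophobic", [])))
    out = dedup_saltbridge_hbond(out)
    out = dedup_waterbridge_hbond(out)
    return {t: list(out.get(t, [])) for t in INTERACTION_TYPES}
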