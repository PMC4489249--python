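"""Rule-based geometric matching: the seven interaction detectors.

Each detector pairs protein-side features with ligand-side features and
keeps a candidate when its measured geometry satisfies the distance/angle
inequalities of :class:`ThresholdConfig`. Detectors only ever *measure and
compare*; redundancy between types is resolved afterwards by
:mod:`nciprofiler.refinement`.

Default thresholds are permissive literature-style values and are fully
configurable; they are documented with units in :class:`ThresholdConfig`.
Intra-molecular pairs (protein-protein, ligand-ligand) are never reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

from .core import Atom, BindingSite
from .characterization import SiteFeatures
from .geometry import angle, distance, plane_angle, projected_offset

__all__ = [
    "ThresholdConfig",
    "Interaction",
    "INTERACTION_TYPES",
    "detect_hydrophobic",
    "detect_hbonds",
    "detect_waterbridges",
    "detect_saltbridges",
    "detect_pistacking",
    "detect_pication",
    "detect_halogenbonds",
    "run_all_detectors",
]

#: Canonical order of the seven interaction types.
INTERACTION_TYPES = (
    "hydrophobic",
    "hbond",
    "waterbridge",
    "saltbridge",
    "pistack",
    "pication",
    "halogen",
)


@dataclass(frozen=True)
class ThresholdConfig:
    """Geometric thresholds for all detectors. Distances in Angstrom,
    angles in degrees."""

    hydrophobic_dist_max: float = 4.0    # C...C contact distance
    hbond_dist_max: float = 4.1          # donor-acceptor heavy-atom distance
    hbond_don_angle_min: float = 100.0   # D-H...A angle floor
    pistack_dist_max: float = 5.5        # ring centroid-centroid distance
    pistack_ang_dev: float = 30.0        # allowed deviation from 0 (P) / 90 (T)
    pistack_offset_max: float = 2.0      # lateral ring-center offset
    pication_dist_max: float = 6.0       # ring centroid to charge centroid
    saltbridge_dist_max: float = 5.5     # charge centroid-centroid distance
    halogen_dist_max: float = 4.0        # X...acceptor distance
    halogen_don_angle: float = 165.0     # target C-X...A angle (sigma hole)
    halogen_acc_angle: float = 120.0     # target Y-A...X angle
    halogen_angle_dev: float = 30.0      # tolerance on both halogen angles
    waterbridge_mindist: float = 2.5     # polar-to-water leg, lower bound
    waterbridge_maxdist: float = 4.1     # polar-to-water leg, upper bound
    waterbridge_omega_min: float = 75.0  # angle at the water oxygen
    waterbridge_omega_max: float = 140.0
    waterbridge_theta_min: float = 100.0  # donor-angle floor on donor legs

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"threshold {f.name} must be positive")
        if self.waterbridge_mindist >= self.waterbridge_maxdist:
            raise ValueError("waterbridge_mindist must be < waterbridge_maxdist")
        for name in (
            "hbond_don_angle_min", "pistack_ang_dev", "halogen_don_angle",
            "halogen_acc_angle", "halogen_angle_dev",
            "waterbridge_omega_min", "waterbridge_omega_max", "waterbridge_theta_min",
        ):
            if not 0 < getattr(self, name) <= 180:
                raise ValueError(f"angle threshold {name} must be in (0, 180]")

    def with_overrides(self, **overrides: float) -> "ThresholdConfig":
        unknown = set(overrides) - {f.name for f in fields(self)}
        if unknown:
            raise KeyError(f"unknown threshold key(s): {', '.join(sorted(unknown))}")
        return replace(self, **overrides)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_file(cls, path) -> "ThresholdConfig":
        """Read a flat key-value file (``key = value`` or ``key: value``,
        '#' comments)."""
        overrides: dict[str, float] = {}
        with open(path) as fh:
            for raw in fh:
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                for sep in ("=", ":"):
                    if sep in line:
                        key, _, val = line.partition(sep)
                        break
                else:
                    raise ValueError(f"cannot parse config line: {raw.rstrip()}")
                overrides[key.strip()] = float(val.strip())
        return cls().with_overrides(**overrides)


@dataclass(eq=False)  # identity semantics: each record is a distinct event
class Interaction:
    """One detected interaction at single-atom detail.

    ``measurements`` maps a named geometric quantity to ``(value, unit)``.
    """

    type: str
    protein_atoms: list[Atom]
    ligand_atoms: list[Atom]
    residue_label: str
    measurements: dict[str, tuple[float, str]]
    donor_side: str = "n/a"  # protein | ligand | n/a
    subtype: str = ""
    water: Atom | None = None

    def measurement(self, name: str) -> float:
        return self.measurements[name][0]


def _label(site: BindingSite, protein_atom: Atom) -> str:
    res = site.structure.residue_by_key(protein_atom.parent)
    if res is None:
        return protein_atom.parent
    return f"{res.code}-{res.chain}-{res.number}{res.icode}"


def detect_hydrophobic(site: BindingSite, features: SiteFeatures, cfg: ThresholdConfig) -> list[Interaction]:
    """Hydrophobic contacts: apolar carbon pairs across the interface
    within ``hydrophobic_dist_max``."""
    prot = [h.atom for h in features.hydrophobic if h.side == "protein"]
    lig = [h.atom for h in features.hydrophobic if h.side == "ligand"]
    out = []
    for p in prot:
        for l in lig:
            d = distance(p.coords, l.coords)
            if d <= cfg.hydrophobic_dist_max:
                out.append(Interaction(
                    type="hydrophobic",
                    protein_atoms=[p],
                    ligand_atoms=[l],
                    residue_label=_label(site, p),
                    measurements={"dist": (d, "A")},
                ))
    return out


def _best_donor_angle(donor, acceptor_pos: np.ndarray) -> float:
    """Largest D-H...A angle over the donor's hydrogens."""
    return max(
        angle(donor.heavy.coords, h.coords, acceptor_pos) for h in donor.hydrogens
    )


def detect_hbonds(site: BindingSite, features: SiteFeatures, cfg: ThresholdConfig) -> list[Interaction]:
    """Hydrogen bonds: D-H...A with heavy-atom distance and donor-angle
    constraints; the best-oriented hydrogen is scored per donor."""
    out = []
    for donor in features.hbond_donors:
        for acc in features.hbond_acceptors:
            if donor.side == acc.side or donor.heavy is acc.heavy:
                continue
            d = distance(donor.heavy.coords, acc.heavy.coords)
            if d > cfg.hbond_dist_max:
                continue
            don_angle = _best_donor_angle(donor, acc.heavy.coords)
            if don_angle < cfg.hbond_don_angle_min:
                continue
            p_atom, l_atom = (
                (donor.heavy, acc.heavy) if donor.side == "protein" else (acc.heavy, donor.heavy)
            )
            out.append(Interaction(
                type="hbond",
                protein_atoms=[p_atom],
                ligand_atoms=[l_atom],
                residue_label=_label(site, p_atom),
                measurements={"dist_d-a": (d, "A"), "don_angle": (don_angle, "deg")},
                donor_side=donor.side,
            ))
    return out


def _polar_map(features: SiteFeatures, side: str) -> dict[int, tuple[Atom, tuple, bool]]:
    """serial -> (atom, hydrogens-if-donor, is_acceptor) for one side."""
    polar: dict[int, tuple[Atom, tuple, bool]] = {}
    for don in features.hbond_donors:
        if don.side == side:
            polar[don.heavy.serial] = (don.heavy, don.hydrogens, False)
    for acc in features.hbond_acceptors:
        if acc.side == side:
            atom, hs, _ = polar.get(acc.heavy.serial, (acc.heavy, (), False))
            polar[acc.heavy.serial] = (atom, hs, True)
    return polar


def detect_waterbridges(site: BindingSite, features: SiteFeatures, cfg: ThresholdConfig) -> list[Interaction]:
    """Water bridges: ligand-polar ... water-O ... protein-polar triples.

    Each leg must fall in the water-bridge distance window and be plausible
    as half of a double hydrogen bond: a polar atom participates either as
    an acceptor, or as a donor whose best D-H...O(water) angle clears
    ``waterbridge_theta_min``. The angle at the water oxygen (omega) must
    lie in the configured window.
    """
    lig_polar = _polar_map(features, "ligand")
    prot_polar = _polar_map(features, "protein")
    out = []

    def leg_ok(atom, hydrogens, is_acc, w):
        d = distance(atom.coords, w.coords)
        if not (cfg.waterbridge_mindist <= d <= cfg.waterbridge_maxdist):
            return None, False
        as_donor = bool(hydrogens) and (
            max(angle(atom.coords, h.coords, w.coords) for h in hydrogens)
            >= cfg.waterbridge_theta_min
        )
        return d, (as_donor or is_acc)

    for w in features.waters:
        for l_atom, l_hs, l_acc in lig_polar.values():
            d_lw, ok_l = leg_ok(l_atom, l_hs, l_acc, w)
            if not ok_l:
                continue
            for p_atom, p_hs, p_acc in prot_polar.values():
                d_pw, ok_p = leg_ok(p_atom, p_hs, p_acc, w)
                if not ok_p:
                    continue
                omega = angle(l_atom.coords, w.coords, p_atom.coords)
                if not (cfg.waterbridge_omega_min <= omega <= cfg.waterbridge_omega_max):
                    continue
                donor_side = "ligand" if l_hs else ("protein" if p_hs else "n/a")
                out.append(Interaction(
                    type="waterbridge",
                    protein_atoms=[p_atom],
                    ligand_atoms=[l_atom],
                    residue_label=_label(site, p_atom),
                    measurements={
                        "dist_l-w": (d_lw, "A"),
                        "dist_p-w": (d_pw, "A"),
                        "omega": (omega, "deg"),
                    },
                    donor_side=donor_side,
                    water=w,
                ))
    return out


def detect_saltbridges(site: BindingSite, features: SiteFeatures, cfg: ThresholdConfig) -> list[Interaction]:
    """Salt bridges: opposite formal charges across the interface within
    ``saltbridge_dist_max`` (centroid to centroid)."""
    out = []
    for pos in features.charges:
        if pos.sign != 1:
            continue
        for neg in features.charges:
            if neg.sign != -1 or pos.side == neg.side:
                continue
            d = distance(pos.centroid, neg.centroid)
            if d > cfg.saltbridge_dist_max:
                continue
            p_center, l_center = (pos, neg) if pos.side == "protein" else (neg, pos)
            out.append(Interaction(
                type="saltbridge",
                protein_atoms=list(p_center.atoms),
                ligand_atoms=list(l_center.atoms),
                residue_label=_label(site, p_center.atoms[0]),
                measurements={"dist": (d, "A")},
                subtype=f"{pos.group}/{neg.group}",
            ))
    return out


def detect_pistacking(site: BindingSite, features: SiteFeatures, cfg: ThresholdConfig) -> list[Interaction]:
    """Pi-stacking: ring pairs in parallel (P) or T-shaped (T) arrangement
    within centroid-distance, plane-angle and lateral-offset limits."""
    prot = [r for r in features.rings if r.side == "protein"]
    lig = [r for r in features.rings if r.side == "ligand"]
    out = []
    for pr in prot:
        for lr in lig:
            d = distance(pr.plane.centroid, lr.plane.centroid)
            if d > cfg.pistack_dist_max:
                continue
            ang = plane_angle(pr.plane, lr.plane)
            if ang <= cfg.pistack_ang_dev:
                subtype = "P"
            elif abs(ang - 90.0) <= cfg.pistack_ang_dev:
                subtype = "T"
            else:
                continue
            offset = min(
                projected_offset(pr.plane, lr.plane.centroid),
                projected_offset(lr.plane, pr.plane.centroid),
            )
            if offset > cfg.pistack_offset_max:
                continue
            out.append(Interaction(
                type="pistack",
                protein_atoms=list(pr.atoms),
                ligand_atoms=list(lr.atoms),
                residue_label=_label(site, pr.atoms[0]),
                measurements={
                    "centdist": (d, "A"),
                    "angle": (ang, "deg"),
                    "offset": (offset, "A"),
                },
                subtype=subtype,
            ))
    return out


def detect_pication(site: BindingSite, features: SiteFeatures, cfg: ThresholdConfig) -> list[Interaction]:
    """Pi-cation: positive charge center over an aromatic ring face."""
    out = []
    for ring in features.rings:
        for charge in features.charges:
            if charge.sign != 1 or charge.side == ring.side:
                continue
            d = distance(ring.plane.centroid, charge.centroid)
            if d > cfg.pication_dist_max:
                continue
            offset = projected_offset(ring.plane, charge.centroid)
            if offset > cfg.pistack_offset_max:
                continue
            if ring.side == "protein":
                p_atoms, l_atoms = list(ring.atoms), list(charge.atoms)
            else:
                p_atoms, l_atoms = list(charge.atoms), list(ring.atoms)
            out.append(Interaction(
                type="pication",
                protein_atoms=p_atoms,
                ligand_atoms=l_atoms,
                residue_label=_label(site, p_atoms[0]),
                measurements={"dist": (d, "A"), "offset": (offset, "A")},
                subtype=charge.group,
            ))
    return out


def detect_halogenbonds(site: BindingSite, features: SiteFeatures, cfg: ThresholdConfig) -> list[Interaction]:
    """Halogen bonds: C-X...A contacts with near-linear donor angle (sigma
    hole) and a Y-A...X acceptor angle near the lone-pair direction."""
    out = []
    don_lo = cfg.halogen_don_angle - cfg.halogen_angle_dev
    don_hi = cfg.halogen_don_angle + cfg.halogen_angle_dev
    acc_lo = cfg.halogen_acc_angle - cfg.halogen_angle_dev
    acc_hi = cfg.halogen_acc_angle + cfg.halogen_angle_dev
    for don in features.halogen_donors:
        for acc in features.halogen_acceptors:
            if don.side == acc.side:
                continue
            d = distance(don.halogen.coords, acc.acceptor.coords)
            if d > cfg.halogen_dist_max:
                continue
            don_angle = angle(don.carbon.coords, don.halogen.coords, acc.acceptor.coords)
            if not (don_lo <= don_angle <= don_hi):
                continue
            acc_angles = [
                angle(y.coords, acc.acceptor.coords, don.halogen.coords)
                for y in acc.neighbors
            ]
            acc_angle = min(acc_angles, key=lambda a: abs(a - cfg.halogen_acc_angle))
            if not (acc_lo <= acc_angle <= acc_hi):
                continue
            if don.side == "ligand":
                p_atoms, l_atoms = [acc.acceptor], [don.carbon, don.halogen]
            else:
                p_atoms, l_atoms = [don.carbon, don.halogen], [acc.acceptor]
            out.append(Interaction(
                type="halogen",
                protein_atoms=p_atoms,
                ligand_atoms=l_atoms,
                residue_label=_label(site, p_atoms[0]),
                measurements={
                    "dist": (d, "A"),
                    "don_angle": (don_angle, "deg"),
                    "acc_angle": (acc_angle, "deg"),
                },
                donor_side=don.side,
                subtype=don.halogen.element,
            ))
    return out


_DETECTORS = {
    "hydrophobic": detect_hydrophobic,
    "hbond": detect_hbonds,
    "waterbridge": detect_waterbridges,
    "saltbridge": detect_saltbridges,
    "pistack": detect_pistacking,
    "pication": detect_pication,
    "halogen": detect_halogenbonds,
}


def run_all_detectors(
    site: BindingSite, features: SiteFeatures, cfg: ThresholdConfig | None = None
) -> dict[str, list[Interaction]]:
    """Run all seven detectors; the result always has exactly seven keys."""
    if cfg is None:
        cfg = ThresholdConfig()
    return {name: _DETECTORS[name](site, features, cfg) for name in INTERACTION_TYPES}
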