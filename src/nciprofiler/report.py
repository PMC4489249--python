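"""Report model and serializers: XML, flat text, visualization script.

The report is a serialization-friendly snapshot of the pipeline result:
atom references are reduced to serial numbers, all measurements are fixed
to two decimals (PDB coordinate precision bounds meaningful digits), and
the creation timestamp is injectable so output is byte-identical across
runs on the same input. The XML writer and parser round-trip exactly.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field

from lxml import etree

from .detectors import INTERACTION_TYPES, Interaction, ThresholdConfig

__all__ = [
    "InteractionRecord",
    "SiteReport",
    "InteractionReport",
    "build_report",
    "write_xml",
    "parse_xml",
    "write_text",
    "write_vis_script",
]


@dataclass(frozen=True)
class InteractionRecord:
    """Flattened interaction: serial numbers instead of Atom references."""

    type: str
    protein_serials: tuple[int, ...]
    ligand_serials: tuple[int, ...]
    residue_label: str
    measurements: tuple[tuple[str, float, str], ...]  # (name, value, unit)
    donor_side: str = "n/a"
    subtype: str = ""
    water_serial: int | None = None


@dataclass
class SiteReport:
    site_id: str
    interactions: dict[str, list[InteractionRecord]] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        return {t: len(self.interactions.get(t, [])) for t in INTERACTION_TYPES}

    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class InteractionReport:
    structure_id: str
    created: str
    config: dict[str, float]
    sites: list[SiteReport] = field(default_factory=list)


def _record_from_interaction(i: Interaction) -> InteractionRecord:
    return InteractionRecord(
        type=i.type,
        protein_serials=tuple(a.serial for a in i.protein_atoms),
        ligand_serials=tuple(a.serial for a in i.ligand_atoms),
        residue_label=i.residue_label,
        measurements=tuple(
            (name, round(value, 2), unit) for name, (value, unit) in i.measurements.items()
        ),
        donor_side=i.donor_side,
        subtype=i.subtype,
        water_serial=i.water.serial if i.water is not None else None,
    )


def build_report(
    structure_id: str,
    site_results: list[tuple[str, dict[str, list[Interaction]]]],
    config: ThresholdConfig | None = None,
    created: str | None = None,
) -> InteractionReport:
    """Assemble a report from per-site refined interaction mappings.

    ``created`` is injectable for reproducible output; defaults to now (UTC).
    """
    if config is None:
        config = ThresholdConfig()
    if created is None:
        created = datetime.datetime.now(datetime.timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")
    sites = []
    for site_id, interactions in site_results:
        rec = {
            t: [_record_from_interaction(i) for i in interactions.get(t, [])]
            for t in INTERACTION_TYPES
        }
        sites.append(SiteReport(site_id=site_id, interactions=rec))
    return InteractionReport(
        structure_id=structure_id, created=created, config=config.to_dict(), sites=sites
    )


# ---------------------------------------------------------------------------
# XML


def write_xml(report: InteractionReport) -> str:
    """Serialize to the package's XML schema (see docs/report-schema.md)."""
    root = etree.Element("report", structure_id=report.structure_id, created=report.created)
    cfg_el = etree.SubElement(root, "config")
    for key in sorted(report.config):
        etree.SubElement(cfg_el, "threshold", name=key, value=f"{report.config[key]:.2f}")
    for site in report.sites:
        site_el = etree.SubElement(root, "bindingsite", id=site.site_id)
        summary = etree.SubElement(site_el, "summary")
        for t in INTERACTION_TYPES:
            etree.SubElement(summary, "count", type=t).text = str(site.counts[t])
        inter_el = etree.SubElement(site_el, "interactions")
        for t in INTERACTION_TYPES:
            type_el = etree.SubElement(inter_el, t)
            for n, rec in enumerate(site.interactions.get(t, []), start=1):
                rec_el = etree.SubElement(
                    type_el, "record", id=str(n), residue=rec.residue_label,
                    donor_side=rec.donor_side, subtype=rec.subtype,
                )
                etree.SubElement(rec_el, "protein_atoms").text = ",".join(
                    str(s) for s in rec.protein_serials
                )
                etree.SubElement(rec_el, "ligand_atoms").text = ",".join(
                    str(s) for s in rec.ligand_serials
                )
                if rec.water_serial is not None:
                    etree.SubElement(rec_el, "water_atom").text = str(rec.water_serial)
                for name, value, unit in rec.measurements:
                    etree.SubElement(
                        rec_el, "measure", name=name, value=f"{value:.2f}", unit=unit
                    )
    return etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode()


def parse_xml(text: str) -> InteractionReport:
    """Parse a report document back into an :class:`InteractionReport`."""
    root = etree.fromstring(text.encode())
    config = {
        el.get("name"): float(el.get("value")) for el in root.findall("config/threshold")
    }
    report = InteractionReport(
        structure_id=root.get("structure_id"), created=root.get("created"), config=config
    )
    for site_el in root.findall("bindingsite"):
        site = SiteReport(site_id=site_el.get("id"))
        for t in INTERACTION_TYPES:
            records = []
            for rec_el in site_el.findall(f"interactions/{t}/record"):
                def _serials(tag: str) -> tuple[int, ...]:
                    el = rec_el.find(tag)
                    if el is None or not el.text:
                        return ()
                    return tuple(int(s) for s in el.text.split(","))

                water_el = rec_el.find("water_atom")
                records.append(InteractionRecord(
                    type=t,
                    protein_serials=_serials("protein_atoms"),
                    ligand_serials=_serials("ligand_atoms"),
                    residue_label=rec_el.get("residue"),
                    measurements=tuple(
                        (m.get("name"), float(m.get("value")), m.get("unit"))
                        for m in rec_el.findall("measure")
                    ),
                    donor_side=rec_el.get("donor_side"),
                    subtype=rec_el.get("subtype"),
                    water_serial=int(water_el.text) if water_el is not None else None,
                ))
            site.interactions[t] = records
        report.sites.append(site)
    return report


# ---------------------------------------------------------------------------
# flat text


def write_text(report: InteractionReport) -> str:
    """Flat text report: one fixed-width, '|'-delimited table per
    interaction type and site."""
    lines = [
        f"Interaction report for {report.structure_id}",
        f"created: {report.created}",
        "=" * 60,
    ]
    for site in report.sites:
        lines.append("")
        lines.append(f"Binding site {site.site_id}")
        lines.append("-" * 60)
        if site.total() == 0:
            lines.append("no interactions detected")
            continue
        for t in INTERACTION_TYPES:
            records = site.interactions.get(t, [])
            if not records:
                continue
            lines.append(f"** {t} ({len(records)}) **")
            meas_names = [name for name, _, _ in records[0].measurements]
            header = ["RESIDUE", "PROT_ATOMS", "LIG_ATOMS", "WATER", "DONOR", "SUBTYPE"] + [
                n.upper() for n in meas_names
            ]
            rows = [header]
            for rec in records:
                meas = {name: f"{value:.2f}" for name, value, _ in rec.measurements}
                rows.append([
                    rec.residue_label,
                    "+".join(str(s) for s in rec.protein_serials),
                    "+".join(str(s) for s in rec.ligand_serials),
                    str(rec.water_serial) if rec.water_serial is not None else "-",
                    rec.donor_side,
                    rec.subtype or "-",
                ] + [meas[n] for n in meas_names])
            widths = [max(len(r[i]) for r in rows) for i in range(len(header))]
            for row in rows:
                lines.append(
                    "| " + " | ".join(c.ljust(w) for c, w in zip(row, widths)) + " |"
                )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# visualization script


_TYPE_COLORS = {
    "hydrophobic": "grey50",
    "hbond": "blue",
    "waterbridge": "lightblue",
    "saltbridge": "yellow",
    "pistack": "green",
    "pication": "orange",
    "halogen": "cyan",
}


def write_vis_script(report: InteractionReport, site_id: str, pdb_path: str = "structure.pdb") -> str:
    """Plain-text visualization command script (PyMOL dialect) for one site:
    one dashed distance object per interaction, colored by type."""
    site = next((s for s in report.sites if s.site_id == site_id), None)
    if site is None:
        available = ", ".join(s.site_id for s in report.sites) or "(none)"
        raise KeyError(f"unknown site_id {site_id!r}; available sites: {available}")
    lines = [
        f"# interaction visualization for {report.structure_id} site {site_id}",
        f"load {pdb_path}",
        "hide everything",
        "show sticks",
        "set dash_gap, 0.5",
    ]
    participating: set[int] = set()
    for t in INTERACTION_TYPES:
        for n, rec in enumerate(site.interactions.get(t, []), start=1):
            name = f"{t}_{rec.residue_label}_{n}"
            p = rec.protein_serials[-1]
            l = rec.ligand_serials[-1]
            participating.update(rec.protein_serials)
            participating.update(rec.ligand_serials)
            if rec.water_serial is not None:
                participating.add(rec.water_serial)
                lines.append(f"distance {name}_a, id {l}, id {rec.water_serial}")
                lines.append(f"distance {name}_b, id {rec.water_serial}, id {p}")
                lines.append(f"color {_TYPE_COLORS[t]}, {name}_a {name}_b")
            else:
                lines.append(f"distance {name}, id {p}, id {l}")
                lines.append(f"color {_TYPE_COLORS[t]}, {name}")
    if participating:
        sel = "+".join(str(s) for s in sorted(participating))
        lines.append(f"select participants, id {sel}")
        lines.append("show spheres, participants")
        lines.append("set sphere_scale, 0.3, participants")
    lines.append("zoom")
    return "\n".join(lines) + "\n"
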