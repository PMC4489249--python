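"""End-to-end profiling: parse -> hydrogenate -> filter ligands ->
binding sites -> characterize -> detect -> refine -> report."""

from __future__ import annotations

from dataclasses import dataclass, field

from .characterization import SiteFeatures, characterize
from .core import BindingSite, Structure
from .detectors import Interaction, ThresholdConfig, run_all_detectors
from .refinement import refine
from .report import InteractionReport, build_report
from .structure_io import (
    SITE_CUTOFF_DEFAULT,
    extract_binding_sites,
    filter_ligands,
    hydrogenate,
    parse_pdb,
)

__all__ = ["ProfileResult", "profile"]


@dataclass
class ProfileResult:
    """Everything the pipeline produced for one input."""

    structure: Structure
    sites: list[BindingSite]
    features: dict[str, SiteFeatures] = field(default_factory=dict)
    interactions: dict[str, dict[str, list[Interaction]]] = field(default_factory=dict)
    report: InteractionReport | None = None

    def inventory(self, site_id: str) -> dict[str, int]:
        """Non-zero interaction counts for one site."""
        return {
            t: len(v) for t, v in self.interactions[site_id].items() if v
        }


def profile(
    source,
    model: int = 1,
    config: ThresholdConfig | None = None,
    blacklist: set[str] | None = None,
    site_cutoff: float = SITE_CUTOFF_DEFAULT,
    identifier: str | None = None,
    created: str | None = None,
) -> ProfileResult:
    """Run the full four-stage pipeline on one PDB input.

    ``source`` is a path, file object or PDB text; ``blacklist`` defaults
    to the shipped list; ``created`` injects the report timestamp for
    reproducible output.
    """
    if config is None:
        config = ThresholdConfig()
    structure = parse_pdb(source, model=model, identifier=identifier)
    hydrogenate(structure)
    ligands = filter_ligands(structure, blacklist)
    sites = extract_binding_sites(structure, ligands, cutoff=site_cutoff)
    result = ProfileResult(structure=structure, sites=sites)
    site_results = []
    for site in sites:
        feats = characterize(site)
        refined = refine(run_all_detectors(site, feats, config))
        result.features[site.site_id] = feats
        result.interactions[site.site_id] = refined
        site_results.append((site.site_id, refined))
    result.report = build_report(
        structure.identifier, site_results, config=config, created=created
    )
    return result
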