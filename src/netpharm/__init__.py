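"""netpharm: integrative network-pharmacology target screening.

Stages: iTRAQ 4-plex reporter quantification and DEP calling (`itraq`),
Tanimoto fingerprint screening (`similarity`), scored-network centrality
and hub screening (`topology`), hypergeometric pathway overrepresentation
(`enrichment`), hub/DEP integration and key-target nomination
(`integration`), synthetic data with planted truth (`synthetic`) and file
formats plus the CLI (`io`, `cli`).
"""

from importlib import metadata, resources
from pathlib import Path

try:
    __version__ = metadata.version("netpharm")
except metadata.PackageNotFoundError:  # pragma: no cover
    __version__ = "0+unknown"

from . import enrichment, integration, io, itraq, similarity, synthetic, topology

__all__ = [
    "enrichment",
    "integration",
    "io",
    "itraq",
    "similarity",
    "synthetic",
    "topology",
    "serum_dep_summary_path",
]


def serum_dep_summary_path() -> Path:
    """Bundled 13-protein serum DEP summary from an NPC case-control
    4-plex iTRAQ experiment (30 patients vs pooled healthy control);
    ratios are NPC/control means over patients."""
    return Path(resources.files("netpharm").joinpath("data/serum_dep_summary.tsv"))
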