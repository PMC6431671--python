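"""Merging predicted hubs with experimental DEPs and nominating key targets.

The integration stage takes the major predicted hubs from the network
screen and the differentially expressed proteins from the quantification
stage, merges them into one candidate set (a node may carry both
provenances), builds the interaction subgraph induced on the merged
candidates, median-filters its edges and re-applies the triple-median
centrality screen.  Survivors — candidates whose degree, betweenness and
closeness all strictly exceed the induced-network medians — are the
nominated key targets, ranked by degree, then betweenness, closeness and
node id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from . import topology
from .enrichment import PathwayDB, enrich

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CandidateSet:
    """Merged hub/DEP candidates with provenance flags per node."""

    table: pd.DataFrame = field(repr=False)  # node_id, is_hub, is_dep

    @property
    def nodes(self) -> list[str]:
        return list(self.table["node_id"])

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class KeyTargetReport:
    """Nomination outcome: ranked key targets with full audit trail."""

    key_targets: list[str]
    topology: pd.DataFrame = field(repr=False)
    cuts: dict[str, float] = field(default_factory=dict)
    audit: pd.DataFrame | None = field(default=None, repr=False)
    provenance: pd.DataFrame | None = field(default=None, repr=False)
    enrichment: pd.DataFrame | None = field(default=None, repr=False)
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "key_targets": self.key_targets,
            "cuts": self.cuts,
            "note": self.note,
            "topology": self.topology.to_dict(orient="records"),
            "audit": (
                self.audit.to_dict(orient="records")
                if self.audit is not None else None
            ),
            "provenance": (
                self.provenance.to_dict(orient="records")
                if self.provenance is not None else None
            ),
            "enrichment": (
                self.enrichment.to_dict(orient="records")
                if self.enrichment is not None else None
            ),
        }


def merge_candidates(
    hubs: list[str],
    deps: list[str],
    mapping: dict[str, str] | None = None,
) -> CandidateSet:
    """Deduplicated union of predicted hubs and experimental DEPs.

    ``mapping`` optionally translates protein accessions to the gene-symbol
    namespace of the hub list; accessions without a mapping are kept under
    their own id with a warning.  Dual membership is preserved.
    """
    mapping = mapping or {}
    mapped_deps = []
    for d in deps:
        if d in mapping:
            mapped_deps.append(mapping[d])
        else:
            if mapping:
                logger.warning("no symbol mapping for %r; keeping raw id", d)
            mapped_deps.append(d)
    hub_set, dep_set = set(hubs), set(mapped_deps)
    merged = sorted(hub_set | dep_set)
    table = pd.DataFrame(
        {
            "node_id": merged,
            "is_hub": [n in hub_set for n in merged],
            "is_dep": [n in dep_set for n in merged],
        }
    )
    return CandidateSet(table=table)


def induced_interaction_network(
    candidates: CandidateSet,
    edges: pd.DataFrame,
    median_filter: bool = True,
) -> nx.Graph:
    """Interaction subgraph induced on the merged candidates.

    Keeps only edges with both endpoints in the candidate set, then applies
    the strict median-score edge filter.  Candidates absent from the edge
    table remain as isolated nodes (logged).
    """
    nodes = set(candidates.nodes)
    sub = edges[
        edges["node_a"].isin(nodes) & edges["node_b"].isin(nodes)
    ].reset_index(drop=True)
    if median_filter and not sub.empty:
        sub, retained = topology.filter_edges_by_median_score(sub)
        logger.info("median filter retained %.0f%% of induced edges",
                    100 * retained)
    g = topology.build_network(sub)
    isolated = nodes - set(g.nodes())
    if isolated:
        logger.info("%d candidates have no retained interactions", len(isolated))
    g.add_nodes_from(sorted(isolated))
    return g


def nominate_key_targets(
    g: nx.Graph,
    candidates: CandidateSet | None = None,
    pathway_db: PathwayDB | None = None,
    stat: str = "median",
) -> KeyTargetReport:
    """Triple-median screen on the induced network; survivors are key targets.

    Ranking: degree descending, ties by betweenness, closeness, node id.
    With fewer than three nodes the screen is meaningless and an error is
    raised.  When every node is topologically equivalent no node strictly
    exceeds the medians and the nomination is empty, with an explanatory
    note.  If a pathway database is given, overrepresentation of the full
    candidate set is appended to the report.
    """
    if g.number_of_nodes() < 3:
        raise ValueError("need at least 3 nodes to nominate key targets")
    records = topology.topology_table(g)
    selection = topology.select_hubs(records, stat=stat)
    ranked = (
        records[records["node_id"].isin(selection.hubs)]
        .sort_values(
            ["degree", "betweenness", "closeness", "node_id"],
            ascending=[False, False, False, True],
        )["node_id"]
        .tolist()
    )
    note = ""
    if not ranked:
        note = (
            "no node strictly exceeds all three "
            f"{stat}s; the network is topologically too uniform to "
            "distinguish key targets"
        )
        logger.warning(note)
    enrichment_table = None
    if pathway_db is not None and candidates is not None:
        try:
            enrichment_table = enrich(candidates.nodes, pathway_db)
        except ValueError as exc:
            logger.warning("enrichment skipped: %s", exc)
    return KeyTargetReport(
        key_targets=ranked,
        topology=records,
        cuts=selection.cuts,
        audit=selection.audit,
        provenance=candidates.table if candidates is not None else None,
        enrichment=enrichment_table,
        note=note,
    )


def run_integration(
    hubs: list[str],
    deps: list[str],
    edges: pd.DataFrame,
    mapping: dict[str, str] | None = None,
    pathway_db: PathwayDB | None = None,
    stat: str = "median",
) -> KeyTargetReport:
    """Convenience wrapper: merge -> induce -> nominate."""
    candidates = merge_candidates(hubs, deps, mapping)
    g = induced_interaction_network(candidates, edges)
    return nominate_key_targets(g, candidates, pathway_db, stat=stat)
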