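"""Pathway overrepresentation: hypergeometric upper tail and fold enrichment.

Given a query gene list, a collection of pathway gene sets and a gene
universe of size N, the overlap k between a query of size n and a pathway
of size K is scored by P[X >= k] for X ~ Hypergeometric(N, K, n), and the
effect size by fold enrichment (k/n)/(K/N).  Raw p-values are reported by
default; Benjamini-Hochberg adjustment is available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PathwayDB:
    """Pathway gene sets plus the background universe.

    The universe defaults to the union of all pathway genes when built from
    a GMT file; every pathway must be a subset of the universe.
    """

    pathways: dict[str, frozenset]
    universe: frozenset
    descriptions: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("universe must be nonempty")
        for pid, genes in self.pathways.items():
            extra = genes - self.universe
            if extra:
                raise ValueError(
                    f"pathway {pid!r} has genes outside the universe: "
                    f"{sorted(extra)[:5]}"
                )


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n).

    N is the universe size, K the pathway size, n the query size and k the
    observed overlap.  k = 0 gives exactly 1.0.
    """
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValueError(
            f"invalid hypergeometric bounds: k={k}, n={n}, K={K}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def fold_enrichment(k: int, n: int, K: int, N: int) -> float:
    """Observed over expected overlap rate: (k/n) / (K/N)."""
    return (k / n) / (K / N)


def enrich(
    query: list[str] | set[str],
    db: PathwayDB,
    adjust: bool = False,
) -> pd.DataFrame:
    """Overrepresentation test of a query gene list against every pathway.

    Query genes outside the universe are dropped with a warning.  One row
    per pathway with overlap k >= 1, sorted by p-value ascending, ties by
    pathway_id.  With ``adjust=True`` a Benjamini-Hochberg q-value column
    is added (raw p-values stay untouched).
    """
    query_set = set(query)
    dropped = query_set - db.universe
    if dropped:
        logger.warning(
            "dropped %d query genes outside the universe", len(dropped)
        )
    query_set &= db.universe
    if not query_set:
        raise ValueError("query is empty after intersecting with the universe")
    n, N = len(query_set), len(db.universe)
    rows = []
    for pid in sorted(db.pathways):
        genes = db.pathways[pid]
        overlap = sorted(query_set & genes)
        k, K = len(overlap), len(genes)
        if k == 0:
            continue
        rows.append(
            {
                "pathway_id": pid,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p_value": hypergeom_upper_tail(k, n, K, N),
                "fold_enrichment": fold_enrichment(k, n, K, N),
                "overlap_genes": ",".join(overlap),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["pathway_id", "k", "n", "K", "N", "p_value",
                 "fold_enrichment", "overlap_genes"],
    )
    out = out.sort_values(["p_value", "pathway_id"], ignore_index=True)
    if adjust and not out.empty:
        from statsmodels.stats.multitest import multipletests

        out["q_value"] = multipletests(
            out["p_value"].to_numpy(float), method="fdr_bh"
        )[1]
    return out
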