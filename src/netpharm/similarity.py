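"""Tanimoto fingerprint screening and compound-target edge assembly.

Compounds are represented by fixed-length binary fingerprints; the Tanimoto
coefficient |A∩B|/|A∪B| of their on-bit sets scores structural similarity
in [0, 1].  A compound is kept when its best Tanimoto score against any
reference-drug fingerprint strictly exceeds the threshold (default 0.8);
scores at or below the threshold mark the compound as redundant.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_TANIMOTO_THRESHOLD = 0.8


def parse_fingerprint(bits: str) -> np.ndarray:
    """Decode a '0101...' bitstring into a boolean vector."""
    if not bits or set(bits) - {"0", "1"}:
        raise ValueError(f"fingerprint must be a nonempty 0/1 string, got {bits!r}")
    return np.frombuffer(bits.encode(), dtype=np.uint8) == ord("1")


def format_fingerprint(fp: np.ndarray) -> str:
    return "".join("1" if b else "0" for b in np.asarray(fp, bool))


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient of two equal-length binary fingerprints.

    Symmetric; 1.0 for identical nonzero fingerprints, 0.0 for disjoint
    on-bit sets.  Two all-zero fingerprints have an empty union; their
    similarity is defined as 0 with a warning.
    """
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint lengths differ: {a.size} vs {b.size}")
    union = int(np.sum(a | b))
    if union == 0:
        logger.warning("both fingerprints all-zero; Tanimoto defined as 0")
        return 0.0
    return int(np.sum(a & b)) / union


def screen_compounds(
    library: pd.DataFrame,
    references: pd.DataFrame,
    threshold: float = DEFAULT_TANIMOTO_THRESHOLD,
) -> pd.DataFrame:
    """Score every library compound against reference fingerprints.

    Both tables need columns compound_id and fingerprint (bitstring).
    Returns one row per compound with best_tanimoto = max over references
    and kept = best_tanimoto strictly greater than the threshold.
    """
    if references.empty:
        raise ValueError("reference fingerprint set must be nonempty")
    if library.empty:
        logger.warning("empty compound library; nothing to screen")
        return pd.DataFrame(columns=["compound_id", "best_tanimoto", "kept"])
    refs = [parse_fingerprint(s) for s in references["fingerprint"]]
    records = []
    for _, row in library.iterrows():
        fp = parse_fingerprint(row["fingerprint"])
        best = max(tanimoto(fp, r) for r in refs)
        records.append(
            {"compound_id": row["compound_id"], "best_tanimoto": best,
             "kept": best > threshold}
        )
    out = pd.DataFrame(records)
    logger.info("kept %d / %d compounds at Tanimoto > %g",
                int(out["kept"].sum()), len(out), threshold)
    return out


def build_compound_target_edges(
    kept_compounds: pd.DataFrame | list[str],
    compound_targets: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Assemble the deduplicated compound→target edge list for kept compounds.

    Returns (edges, per-compound target counts, mean targets per compound).
    The mean divides distinct (compound, target) pairs by the number of kept
    compounds, so a kept compound with no annotated targets contributes 0 to
    the numerator but still counts in the denominator.  Target rows that
    reference compounds absent from the library are an error.
    """
    if isinstance(kept_compounds, pd.DataFrame):
        kept_ids = list(kept_compounds.loc[kept_compounds["kept"], "compound_id"])
        known_ids = set(kept_compounds["compound_id"])
    else:
        kept_ids = list(kept_compounds)
        known_ids = set(kept_ids)
    dangling = sorted(set(compound_targets["compound_id"]) - known_ids)
    if dangling:
        raise ValueError(
            f"compound-target table references unknown compounds: {dangling}"
        )
    edges = (
        compound_targets[compound_targets["compound_id"].isin(kept_ids)]
        .drop_duplicates(["compound_id", "target_id"])
        .sort_values(["compound_id", "target_id"], ignore_index=True)
    )
    counts = (
        edges.groupby("compound_id").size().reindex(kept_ids, fill_value=0)
        .rename("n_targets").rename_axis("compound_id").reset_index()
    )
    mean = len(edges) / len(kept_ids) if kept_ids else 0.0
    return edges, counts, mean
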