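"""Tabular and GMT readers/writers, config loading and the run manifest.

The universal tabular dialect is TSV with '#'-prefixed comment lines; no
spreadsheet formats.  Every documented schema is validated on read with
errors that name the offending column or line.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from .enrichment import PathwayDB

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A table or file does not match its documented schema."""


def read_table(path, schema: dict[str, type]) -> pd.DataFrame:
    """Read a TSV, skipping '#' comments, and validate against ``schema``.

    ``schema`` maps column name -> python type (str, int, float).  Missing
    columns raise a SchemaError naming the column; unparseable values raise
    one naming the column and the first offending row number (1-based data
    rows).  An empty file is an error, not an empty table.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty") from None
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    for col, typ in schema.items():
        if typ is str:
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise SchemaError(
                f"{path}: column {col!r} has non-{typ.__name__} value "
                f"{df[col][bad.idxmax()]!r} at data row {row}"
            )
        df[col] = converted.astype(typ if typ is not int else "int64")
    return df


def write_table(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Write a TSV with an optional '#' header comment (schema version line)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_gmt(path) -> PathwayDB:
    """Parse a GMT file (pathway_id TAB description TAB gene ...).

    Duplicate genes within one line are collapsed; CRLF endings are
    accepted; a line with fewer than three fields is an error naming the
    line number.  The universe is the union of all pathway genes.
    """
    pathways: dict[str, frozenset] = {}
    descriptions: dict[str, str] = {}
    with open(path, newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SchemaError(
                    f"{path}: GMT line {lineno} has {len(fields)} fields; "
                    "need pathway_id, description and at least one gene"
                )
            pid, desc, *genes = fields
            if pid in pathways:
                raise SchemaError(f"{path}: duplicate pathway id {pid!r}")
            pathways[pid] = frozenset(g for g in genes if g)
            descriptions[pid] = desc
    if not pathways:
        raise SchemaError(f"{path}: GMT file contains no pathways")
    universe = frozenset().union(*pathways.values())
    return PathwayDB(pathways=pathways, universe=universe,
                     descriptions=descriptions)


def write_gmt(pathways: dict[str, frozenset], path,
              descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for pid in sorted(pathways):
            genes = "\t".join(sorted(pathways[pid]))
            fh.write(f"{pid}\t{descriptions.get(pid, 'na')}\t{genes}\n")


def read_gene_list(path) -> list[str]:
    """One gene id per line; blank lines and '#' comments skipped."""
    out = []
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if g and not g.startswith("#"):
                out.append(g)
    return out


def read_mapping(path) -> dict[str, str]:
    """Two-column TSV: source id TAB target symbol."""
    df = read_table(path, {"source_id": str, "symbol": str})
    return dict(zip(df["source_id"], df["symbol"]))


def load_config(path) -> dict:
    """Load a YAML config of flat key: value sections."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a mapping of sections")
    return cfg


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record emitted for every CLI run."""

    tool_version: str
    config_hash: str
    seeds: dict = field(default_factory=dict)
    input_checksums: dict = field(default_factory=dict)
    row_counts: dict = field(default_factory=dict)
    warnings: dict = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    @classmethod
    def start(cls, version: str, config: dict, seeds: dict | None = None):
        blob = json.dumps(config, sort_keys=True, default=str).encode()
        return cls(
            tool_version=version,
            config_hash=hashlib.sha256(blob).hexdigest(),
            seeds=seeds or {},
            started=datetime.now(timezone.utc).isoformat(),
        )

    def add_input(self, path) -> None:
        self.input_checksums[str(path)] = sha256_file(path)

    def finish(self, path) -> None:
        self.finished = datetime.now(timezone.utc).isoformat()
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")
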