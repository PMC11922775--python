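"""Readers and writers for the external formats.

GMT (tab-separated gene sets), DEG tables (TSV with feature_id / log2fc /
p_adj), protein FASTA, and the pipeline's output tables.  All tables are TSV
with 6-significant-digit floats so repeated runs with the same config and
seed are byte-identical.  Sequence coordinates are 1-based inclusive
throughout; feature identifiers are case-sensitive and never harmonized here.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .centrality import CentralityScore, EnrichmentResult, OrderedGeneList
from .motif import MotifHit
from .network import DiffExpressionTable, PathwayCollection
from .prioritize import ChainResult, PathwayPriorityRecord
from .zones import ScanProfile, Zone

logger = logging.getLogger("ciliagraph")


class ParseError(ValueError):
    """Malformed input file."""


def _fmt(x: float) -> str:
    return f"{x:.6g}"


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(
    path: str | Path,
    anchor_name: str | None = None,
    query_set: Sequence[str] | None = None,
) -> PathwayCollection:
    """Read a GMT file: name, description, then member genes, tab-separated.

    Member lists are de-duplicated (order preserved); file order of pathways
    is kept; duplicate pathway names are an error.
    """
    path = Path(path)
    pathways: dict[str, list[str]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected ≥3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name = fields[0]
            if name in pathways:
                raise ParseError(f"{path}:{lineno}: duplicate pathway name {name!r}")
            pathways[name] = list(dict.fromkeys(f for f in fields[2:] if f))
    if not pathways:
        logger.warning("GMT file %s is empty", path)
    return PathwayCollection(
        pathways=pathways,
        anchor_name=anchor_name,
        query_set=list(query_set or []),
    )


def write_gmt(collection: PathwayCollection, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for name, members in collection.pathways.items():
            fh.write("\t".join([name, "synthetic"] + list(members)) + "\n")
    return path


# ---------------------------------------------------------------------------
# DEG tables
# ---------------------------------------------------------------------------

def read_deg_table(path: str | Path) -> DiffExpressionTable:
    """Read a TSV with columns feature_id, log2fc, p_adj (extras ignored).

    Significance flags are not set here; apply ``filter_significant``.
    Duplicate feature ids, out-of-range p_adj and non-numeric log2fc are
    errors naming the offending row.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str})
    required = {"feature_id", "log2fc", "p_adj"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    extras = [c for c in df.columns if c not in required]
    if extras:
        logger.info("ignoring extra DEG columns: %s", extras)
    for col in ("log2fc", "p_adj"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ParseError(f"{path}: non-numeric {col} at row {row + 2}")
        df[col] = coerced
    if df[["log2fc", "p_adj"]].isna().any().any():
        raise ParseError(f"{path}: missing log2fc/p_adj values")
    bad_p = ~df["p_adj"].between(0.0, 1.0)
    if bad_p.any():
        row = int(bad_p.idxmax())
        raise ParseError(
            f"{path}: p_adj outside [0,1] at row {row + 2} "
            f"(feature {df['feature_id'].iloc[row]!r})"
        )
    dup = df["feature_id"].duplicated()
    if dup.any():
        row = int(dup.idxmax())
        raise ParseError(
            f"{path}: duplicate feature id {df['feature_id'].iloc[row]!r} "
            f"at row {row + 2}"
        )
    return DiffExpressionTable(df[["feature_id", "log2fc", "p_adj"]].copy())


def write_deg_table(table: DiffExpressionTable, path: str | Path) -> Path:
    path = Path(path)
    out = table.data[["feature_id", "log2fc", "p_adj"]].copy()
    # str() gives the shortest round-trip repr, keeping write/read lossless
    out["log2fc"] = out["log2fc"].map(lambda v: str(float(v)))
    out["p_adj"] = out["p_adj"].map(lambda v: str(float(v)))
    out.to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Ordered (id, sequence) records, upper-cased; 1-based downstream.

    Empty sequences and duplicate ids are errors.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append((rec.id, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> Path:
    path = Path(path)
    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in records],
        str(path),
        "fasta",
    )
    return path


# ---------------------------------------------------------------------------
# Output tables
# ---------------------------------------------------------------------------

def write_ranked_pathways(
    records: Sequence[PathwayPriorityRecord], path: str | Path
) -> Path:
    """Ranked pathway table; ``passes_threshold`` is the strict > rule."""
    path = Path(path)
    rows = [
        {
            "pathway": r.pathway,
            "similarity": _fmt(r.similarity),
            "connection_strength": _fmt(r.connection_strength),
            "key_regulator": _fmt(r.key_regulator),
            "combined": _fmt(r.combined),
            "rank": r.rank,
            "passes_threshold": r.passes_threshold,
        }
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=[
            "pathway", "similarity", "connection_strength",
            "key_regulator", "combined", "rank", "passes_threshold",
        ],
    ).to_csv(path, sep="\t", index=False)
    return path


def write_gene_scores(
    scores: Sequence[CentralityScore], order: OrderedGeneList, path: str | Path
) -> Path:
    path = Path(path)
    rank = {g: i + 1 for i, g in enumerate(order.genes)}
    rows = sorted(scores, key=lambda s: rank[s.gene])
    pd.DataFrame(
        {
            "gene": [s.gene for s in rows],
            "score": [_fmt(s.score) for s in rows],
            "is_central": [s.is_central for s in rows],
            "rank": [rank[s.gene] for s in rows],
        }
    ).to_csv(path, sep="\t", index=False)
    return path


def write_enrichment(results: Sequence[EnrichmentResult], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "pathway": [r.pathway for r in results],
            "k_star": [r.k_star for r in results],
            "p": [_fmt(r.p) for r in results],
            "q": [_fmt(r.q) for r in results],
        }
    ).to_csv(path, sep="\t", index=False)
    return path


def write_profile(profile: ScanProfile, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "rank": range(1, len(profile.genes) + 1),
            "gene": profile.genes,
            "increment": profile.increments,
            "cumulative": profile.cumulative[1:],
        }
    ).to_csv(path, sep="\t", index=False)
    return path


def write_zones(zones: Sequence[Zone], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "start": [z.start for z in zones],
            "end": [z.end for z in zones],
            "sign": [z.sign for z in zones],
            "strength": [_fmt(z.strength) for z in zones],
        }
    ).to_csv(path, sep="\t", index=False)
    return path


def write_chain(result: ChainResult, path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {"position": i, "node": name, "kind": kind}
        for i, (kind, name) in enumerate(result.chain)
    ]
    df = pd.DataFrame(rows, columns=["position", "node", "kind"])
    with path.open("w") as fh:
        fh.write(f"# target={result.target}\treachable={result.reachable}"
                 f"\tdistance={result.distance}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def write_motif_hits(hits: Sequence[MotifHit], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "seq_id": [h.seq_id for h in hits],
            "start": [h.start for h in hits],
            "end": [h.end for h in hits],
            "tetramer": [h.tetramer for h in hits],
        }
    ).to_csv(path, sep="\t", index=False)
    return path
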