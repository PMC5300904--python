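"""Readers and writers for the pipeline's plain-text formats.

Expression and count matrices travel as TSV (first column gene id, header
row of sample ids, optional ``#``-prefixed provenance lines); gene sets as
GMT; annotations as BED6 plus a biotype column; designs and reports as
JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .enrichment import GeneSetCollection
from .knockdown import KnockdownDesign

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_counts_tsv",
    "read_gmt",
    "write_gmt",
    "read_bed_annotation",
    "write_bed_annotation",
    "read_design_json",
    "write_design_json",
    "provenance_line",
]

VALID_STRANDS = {"+", "-", "."}
VALID_BIOTYPES = {"lncRNA", "coding", "TF"}


def provenance_line(config: dict | None = None) -> str:
    digest = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12] if config else "none"
    return f"# isletlnc v{__version__} config_hash={digest}"


def read_expression_tsv(path) -> pd.DataFrame:
    """Genes x samples numeric matrix from TSV; rejects duplicates and
    non-numeric cells with the offending identifier in the message."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene id {dup!r} in {path}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"duplicate sample id {dup!r} in {path}")
    if df.isna().any().any():
        raise ValueError(f"ragged or missing cells in {path}")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    values.index.name = "gene"
    return values


def write_expression_tsv(expr: pd.DataFrame, path, config: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(provenance_line(config) + "\n")
        expr.to_csv(fh, sep="\t", index_label="gene")


def read_counts_tsv(path) -> pd.DataFrame:
    """Like read_expression_tsv but enforces non-negative integer counts."""
    df = read_expression_tsv(path)
    if (df.to_numpy() < 0).any() or (df.to_numpy() % 1 != 0).any():
        raise ValueError(f"counts in {path} must be non-negative integers")
    return df.astype(int)


def read_gmt(path) -> GeneSetCollection:
    """GMT gene sets: name <tab> description <tab> member..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description "
                                 "and at least one member")
            name, _desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"{path}:{lineno}: empty member list for {name!r}")
            sets[name] = set(members)
    return GeneSetCollection(sets=sets)


def write_gmt(sets: GeneSetCollection, path, descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name in sorted(sets.sets):
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc] + sorted(sets[name])) + "\n")


BED_COLUMNS = ["chrom", "start", "end", "gene_id", "score", "strand", "biotype"]


def read_bed_annotation(path) -> pd.DataFrame:
    """BED6 + biotype column (0-based half-open), sorted per chromosome."""
    df = pd.read_csv(path, sep="\t", names=BED_COLUMNS, comment="#", dtype=str)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    bad = df[df["start"] >= df["end"]]
    if not bad.empty:
        raise ValueError(f"start >= end for {bad.iloc[0]['gene_id']!r} in {path}")
    bad_strand = set(df["strand"]) - VALID_STRANDS
    if bad_strand:
        raise ValueError(f"unknown strand symbol(s) {sorted(bad_strand)} in {path}")
    bad_type = set(df["biotype"]) - VALID_BIOTYPES
    if bad_type:
        raise ValueError(f"unknown biotype(s) {sorted(bad_type)} in {path}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id {dup!r} in {path}")
    df = df.sort_values(["chrom", "start", "end", "gene_id"], kind="mergesort")
    return df[["chrom", "start", "end", "strand", "gene_id", "biotype"]].reset_index(drop=True)


def write_bed_annotation(annot: pd.DataFrame, path) -> None:
    out = annot.copy()
    out["score"] = 0
    out[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_design_json(path) -> KnockdownDesign:
    with open(path) as fh:
        return KnockdownDesign.from_dict(json.load(fh))


def write_design_json(design: KnockdownDesign, path) -> None:
    with open(path, "w") as fh:
        json.dump(design.to_dict(), fh, indent=2)
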