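"""Conserved exon-pair discovery from reciprocal BLAST evidence.

Exon pairs are retained when forward and reverse BLAST searches each report a
hit with E-value strictly below the cutoff (1e-5), when both exons are
internal (have a left and a right neighbor) in at least one transcript, and
are partitioned into set (a) — pairs whose parent genes are orthologous — and
set (b) — similar-sequence pairs in non-orthologous genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .annotation import Annotation
from .errors import AnnotationLookupError, ParseError

__all__ = [
    "BLAST6_COLUMNS",
    "ConservedPairTable",
    "load_blast_table",
    "load_ortholog_table",
    "reciprocal_filter",
    "require_internal",
    "partition_by_orthology",
    "restrict_to_exons",
]

BLAST6_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


@dataclass
class ConservedPairTable:
    """A set of aligned exon pairs between the two species.

    ``pairs`` columns: fly_exon_id, worm_exon_id, evalue_fw, evalue_rv and,
    after the orthology partition, is_orthologous.  One-to-many pairings are
    permitted; duplicate (fly, worm) rows are not.
    """

    pairs: pd.DataFrame
    species_a: str = "fly"
    species_b: str = "worm"

    def __post_init__(self):
        if self.pairs.duplicated(subset=["fly_exon_id", "worm_exon_id"]).any():
            raise ParseError("duplicate (fly_exon_id, worm_exon_id) rows in pair table")

    @property
    def m(self) -> int:
        return len(self.pairs)


def load_blast_table(path: str | Path) -> pd.DataFrame:
    """Parse a 12-column BLAST tabular (outfmt 6) file.

    E-values (column 11) are parsed as floats including scientific notation.
    A row with the wrong column count raises :class:`ParseError` naming the
    1-based line number.  An empty file yields an empty table.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    for i, ln in enumerate(lines, start=1):
        if len(ln.split("\t")) != 12:
            raise ParseError(f"{path}: line {i}: expected 12 tab-separated columns")
    if not lines:
        return pd.DataFrame(columns=BLAST6_COLUMNS)
    df = pd.read_csv(
        path,
        sep="\t",
        names=BLAST6_COLUMNS,
        dtype={"qseqid": str, "sseqid": str},
    )
    if (df["evalue"] < 0).any():
        raise ParseError(f"{path}: negative E-value")
    return df


def load_ortholog_table(path: str | Path) -> pd.DataFrame:
    """Read the 2-column orthologous-gene TSV (fly_gene_id, worm_gene_id)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["fly_gene_id", "worm_gene_id"], dtype=str)
    # tolerate a header row
    if df.iloc[0, 0] in ("fly_gene_id", "gene_a"):
        df = df.iloc[1:].reset_index(drop=True)
    return df


def reciprocal_filter(
    fw_hits: pd.DataFrame, rv_hits: pd.DataFrame, evalue_max: float = 1e-5
) -> pd.DataFrame:
    """Exon pairs hit in both directions, each with E-value strictly < cutoff.

    ``fw_hits``: fly exons as query, worm exons as subject; ``rv_hits`` the
    reverse.  When multiple HSPs connect the same pair, the minimum E-value
    per direction decides.  Returns columns (fly_exon_id, worm_exon_id,
    evalue_fw, evalue_rv), sorted for determinism.
    """
    if evalue_max <= 0:
        raise ParseError("evalue_max must be positive")
    empty = pd.DataFrame(columns=["fly_exon_id", "worm_exon_id", "evalue_fw", "evalue_rv"])
    if len(fw_hits) == 0 or len(rv_hits) == 0:
        return empty
    fw = (
        fw_hits.groupby(["qseqid", "sseqid"], as_index=False)["evalue"]
        .min()
        .rename(columns={"qseqid": "fly_exon_id", "sseqid": "worm_exon_id", "evalue": "evalue_fw"})
    )
    rv = (
        rv_hits.groupby(["qseqid", "sseqid"], as_index=False)["evalue"]
        .min()
        .rename(columns={"qseqid": "worm_exon_id", "sseqid": "fly_exon_id", "evalue": "evalue_rv"})
    )
    merged = fw.merge(rv, on=["fly_exon_id", "worm_exon_id"], how="inner")
    merged = merged[(merged["evalue_fw"] < evalue_max) & (merged["evalue_rv"] < evalue_max)]
    return (
        merged.sort_values(["fly_exon_id", "worm_exon_id"])
        .reset_index(drop=True)[["fly_exon_id", "worm_exon_id", "evalue_fw", "evalue_rv"]]
    )


def require_internal(
    pairs: pd.DataFrame, fly_annotation: Annotation, worm_annotation: Annotation
) -> pd.DataFrame:
    """Keep pairs whose exons are both internal in at least one transcript."""
    fly_known = set(fly_annotation.exons["exon_id"])
    worm_known = set(worm_annotation.exons["exon_id"])
    for eid in pairs["fly_exon_id"]:
        if eid not in fly_known:
            raise AnnotationLookupError(f"exon '{eid}' not in fly annotation")
    for eid in pairs["worm_exon_id"]:
        if eid not in worm_known:
            raise AnnotationLookupError(f"exon '{eid}' not in worm annotation")
    fly_internal = fly_annotation.internal_exon_ids()
    worm_internal = worm_annotation.internal_exon_ids()
    mask = pairs["fly_exon_id"].isin(fly_internal) & pairs["worm_exon_id"].isin(worm_internal)
    return pairs[mask].reset_index(drop=True)


def partition_by_orthology(
    pairs: pd.DataFrame,
    ortholog_table: pd.DataFrame,
    fly_annotation: Annotation,
    worm_annotation: Annotation,
) -> tuple[ConservedPairTable, ConservedPairTable]:
    """Split pairs into (set_a, set_b): orthologous-gene pairs vs the rest."""
    orth = set(zip(ortholog_table["fly_gene_id"], ortholog_table["worm_gene_id"]))
    flags = [
        (fly_annotation.gene_of(f), worm_annotation.gene_of(w)) in orth
        for f, w in zip(pairs["fly_exon_id"], pairs["worm_exon_id"])
    ]
    annotated = pairs.assign(is_orthologous=flags)
    set_a = annotated[annotated["is_orthologous"]].reset_index(drop=True)
    set_b = annotated[~annotated["is_orthologous"]].reset_index(drop=True)
    return ConservedPairTable(set_a), ConservedPairTable(set_b)


def restrict_to_exons(
    pairs: pd.DataFrame, fly_keep: set[str], worm_keep: set[str]
) -> pd.DataFrame:
    """Keep pairs whose exons both survive a per-species filter (e.g. cassette)."""
    mask = pairs["fly_exon_id"].isin(fly_keep) & pairs["worm_exon_id"].isin(worm_keep)
    return pairs[mask].reset_index(drop=True)
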