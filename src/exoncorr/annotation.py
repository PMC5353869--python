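"""Exon-level annotation: GTF loading, transcript structure, internal-exon queries.

The pipeline only needs exon features with ``gene_id``, ``transcript_id`` and
``exon_number`` attributes (plus an optional explicit ``exon_id``).  An exon is
*internal* — and therefore eligible to be a cassette exon — when it has both a
left and a right neighbor within at least one transcript.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import pandas as pd

from .errors import AnnotationLookupError, ParseError

__all__ = ["Annotation", "load_gtf", "write_gtf"]


@dataclass
class Annotation:
    """Per-species exon annotation.

    Parameters
    ----------
    exons
        One row per distinct exon: ``exon_id, gene_id, chrom, start, end, strand``.
        Coordinates are 1-based inclusive (GTF convention); ``start <= end``.
    transcript_exons
        Mapping ``transcript_id -> [exon_id, ...]`` in transcript (5'->3') order.
    """

    exons: pd.DataFrame
    transcript_exons: dict[str, list[str]]
    _gene_of: dict[str, str] = field(init=False, repr=False)
    _coords: dict[str, tuple] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        bad = self.exons[self.exons["start"] > self.exons["end"]]
        if len(bad):
            raise ParseError(f"exon with start > end: {bad.iloc[0]['exon_id']}")
        self._gene_of = dict(zip(self.exons["exon_id"], self.exons["gene_id"]))
        self._coords = {
            r.exon_id: (r.chrom, int(r.start), int(r.end), r.strand)
            for r in self.exons.itertuples()
        }

    def gene_of(self, exon_id: str) -> str:
        try:
            return self._gene_of[exon_id]
        except KeyError:
            raise AnnotationLookupError(f"exon '{exon_id}' not in annotation") from None

    def coords(self, exon_id: str) -> tuple:
        """(chrom, start, end, strand) of an exon."""
        try:
            return self._coords[exon_id]
        except KeyError:
            raise AnnotationLookupError(f"exon '{exon_id}' not in annotation") from None

    def positions(self, exon_id: str) -> list[tuple[str, int]]:
        """All (transcript_id, 1-based position) memberships of an exon."""
        if exon_id not in self._gene_of:
            raise AnnotationLookupError(f"exon '{exon_id}' not in annotation")
        out = []
        for tx, ex_list in self.transcript_exons.items():
            for pos, eid in enumerate(ex_list, start=1):
                if eid == exon_id:
                    out.append((tx, pos))
        return out

    def internal_exon_ids(self) -> set[str]:
        """Exons flanked on both sides in at least one transcript."""
        internal: set[str] = set()
        for ex_list in self.transcript_exons.values():
            internal.update(ex_list[1:-1])
        return internal

    def gene_ids(self) -> set[str]:
        return set(self.exons["gene_id"])


def load_gtf(path: str | Path) -> Annotation:
    """Load exon features from a GTF file into an :class:`Annotation`.

    Uses an in-memory gffutils database.  ``exon_id`` is taken from the
    attribute of that name when present, otherwise synthesized as
    ``<gene_id>:<chrom>:<start>-<end>``.  Transcript order follows the
    ``exon_number`` attribute.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    rows = []
    per_tx: dict[str, list[tuple[int, str]]] = {}
    for f in db.features_of_type("exon"):
        gene_id = f.attributes["gene_id"][0]
        tx_id = f.attributes["transcript_id"][0]
        if "exon_id" in f.attributes:
            exon_id = f.attributes["exon_id"][0]
        else:
            exon_id = f"{gene_id}:{f.seqid}:{f.start}-{f.end}"
        number = int(f.attributes["exon_number"][0]) if "exon_number" in f.attributes else f.start
        rows.append((exon_id, gene_id, f.seqid, f.start, f.end, f.strand))
        per_tx.setdefault(tx_id, []).append((number, exon_id))

    exons = (
        pd.DataFrame(rows, columns=["exon_id", "gene_id", "chrom", "start", "end", "strand"])
        .drop_duplicates(subset="exon_id")
        .reset_index(drop=True)
    )
    transcript_exons = {tx: [e for _, e in sorted(lst)] for tx, lst in per_tx.items()}
    return Annotation(exons=exons, transcript_exons=transcript_exons)


def write_gtf(annotation: Annotation, path: str | Path, source: str = "exoncorr") -> None:
    """Write exon features of an annotation as GTF (one line per transcript membership)."""
    with open(path, "w") as fh:
        for tx_id in sorted(annotation.transcript_exons):
            ex_list = annotation.transcript_exons[tx_id]
            for number, exon_id in enumerate(ex_list, start=1):
                chrom, start, end, strand = annotation.coords(exon_id)
                gene_id = annotation.gene_of(exon_id)
                attrs = (
                    f'gene_id "{gene_id}"; transcript_id "{tx_id}"; '
                    f'exon_number "{number}"; exon_id "{exon_id}";'
                )
                fh.write(
                    f"{chrom}\t{source}\texon\t{start}\t{end}\t.\t{strand}\t.\t{attrs}\n"
                )
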