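"""Pseudo-transcript construction for inclusion/skipping quantification.

For every internal exon two minimal transcripts are built from its flanking
neighbors in one source transcript: "transcript S" (skipped) joins the left
and right neighbors; "transcript I" (included) joins left neighbor, the exon
itself, and the right neighbor.  Quantifying these two against RNA-seq yields
the exon's inclusion and skipping expression levels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .annotation import Annotation

__all__ = ["PseudoTranscriptPair", "build_pseudo_transcripts", "write_pseudo_gtf"]


@dataclass(frozen=True)
class PseudoTranscriptPair:
    exon_id: str
    transcript_s: tuple[str, str]  # (left flank, right flank), transcript order
    transcript_i: tuple[str, str, str]  # (left flank, exon, right flank)
    source_transcript_id: str


def build_pseudo_transcripts(annotation: Annotation) -> list[PseudoTranscriptPair]:
    """One (S, I) pseudo-transcript pair per internal exon.

    When an exon is internal in several transcripts, the flanks come from one
    canonical source: the transcript with the most exons, ties broken by
    lexicographically smallest transcript ID.  Left/right neighbors are taken
    in transcript (5'->3') order.  Transcripts with fewer than 3 exons
    contribute nothing.
    """
    best: dict[str, tuple[int, str, tuple[str, str, str]]] = {}
    for tx_id, ex_list in annotation.transcript_exons.items():
        n = len(ex_list)
        if n < 3:
            continue
        for pos in range(1, n - 1):
            exon = ex_list[pos]
            cand = (-n, tx_id, (ex_list[pos - 1], exon, ex_list[pos + 1]))
            if exon not in best or cand < best[exon]:
                best[exon] = cand
    out = []
    for exon_id in sorted(best):
        _, tx_id, (left, _, right) = best[exon_id]
        out.append(
            PseudoTranscriptPair(
                exon_id=exon_id,
                transcript_s=(left, right),
                transcript_i=(left, exon_id, right),
                source_transcript_id=tx_id,
            )
        )
    return out


def write_pseudo_gtf(
    pairs: list[PseudoTranscriptPair], annotation: Annotation, path: str | Path
) -> None:
    """Emit the pseudo-transcript annotation as GTF.

    Transcript IDs encode the target exon and role: ``<exon_id>__S`` and
    ``<exon_id>__I``.  Exon features are written in genomic order within each
    transcript (GTF convention), five lines per pair (2 for S, 3 for I).
    """
    with open(path, "w") as fh:
        fh.write("## exoncorr pseudo-transcript annotation\n")
        for pair in pairs:
            gene_id = annotation.gene_of(pair.exon_id)
            for role, exons in (("S", pair.transcript_s), ("I", pair.transcript_i)):
                tx_id = f"{pair.exon_id}__{role}"
                feats = sorted(
                    (annotation.coords(e), e) for e in exons
                )  # genomic order by (chrom, start)
                for number, ((chrom, start, end, strand), exon_id) in enumerate(feats, 1):
                    attrs = (
                        f'gene_id "{gene_id}"; transcript_id "{tx_id}"; '
                        f'exon_number "{number}"; exon_id "{exon_id}";'
                    )
                    fh.write(
                        f"{chrom}\texoncorr\texon\t{start}\t{end}\t.\t{strand}\t.\t{attrs}\n"
                    )
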