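"""Classify predicted ORFs relative to the reference annotation.

Each ORF receives exactly one of twelve labels.  Precedence when several
rules could match, most specific first:

1. host-transcript biotype: ``TE_ORF`` (transposable element),
   ``pseudogene_ORF``, ``ncRNA_ORF`` (non-coding host, or a host without an
   annotated CDS);
2. exact genomic-block identity with the annotated CDS: ``annotated``;
3. same genomic stop, in frame: ``truncated`` (start strictly inside the
   CDS) or ``extended`` (start strictly upstream);
4. UTR-relative: ``uORF`` (entirely in the 5'UTR), ``overlapped_uORF``
   (starts in the 5'UTR, ends inside the CDS), ``dORF`` (entirely in the
   3'UTR), ``overlapped_dORF`` (starts inside the CDS out of frame, ends in
   the 3'UTR);
5. ``internal_ORF`` (fully inside the CDS, different frame);
6. ``novel`` (no annotation, or nothing overlaps).

"Same stop" is compared in genomic coordinates on the same strand, so the
rules are isoform-robust.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable

import numpy as np

from .io_formats import (
    NONCODING_BIOTYPES,
    PSEUDOGENE_BIOTYPES,
    TE_BIOTYPES,
    AnnotationSet,
    OrfTableRow,
    TranscriptAnnotation,
)

__all__ = ["CATEGORIES", "classify", "classify_all", "write_category_summary"]

CATEGORIES = [
    "annotated",
    "truncated",
    "extended",
    "uORF",
    "overlapped_uORF",
    "dORF",
    "overlapped_dORF",
    "ncRNA_ORF",
    "internal_ORF",
    "TE_ORF",
    "pseudogene_ORF",
    "novel",
]


def _tx_geometry(tx: TranscriptAnnotation):
    """(genomic position per transcript index, CDS interval in tx coords)."""
    pos = np.concatenate([np.arange(e.start, e.end) for e in tx.exons])
    if tx.strand == "-":
        pos = pos[::-1].copy()
    cds_tx = None
    if tx.cds:
        index_of = {int(g): i for i, g in enumerate(pos)}
        idx = sorted(
            index_of[g]
            for c in tx.cds
            for g in range(c.start, c.end)
            if g in index_of
        )
        if idx:
            cds_tx = (idx[0], idx[-1] + 1)
    return pos, cds_tx


def _stop_coord(blocks, strand: str) -> int:
    """Genomic coordinate identifying the 3' end of an ORF/CDS."""
    if strand == "+":
        return max(e for _, e in blocks)
    return min(s for s, _ in blocks)


def _host_transcript(orf: OrfTableRow, annotation: AnnotationSet):
    if orf.transcript_id in annotation:
        return annotation[orf.transcript_id]
    # fall back to the same-strand transcript with the largest span overlap
    o_start = min(s for s, _ in orf.blocks)
    o_end = max(e for _, e in orf.blocks)
    best, best_ov = None, 0
    for tx in annotation.transcripts.values():
        if tx.seq_id != orf.seq_id or tx.strand != orf.strand:
            continue
        span = tx.span
        ov = min(o_end, span.end) - max(o_start, span.start)
        if ov > best_ov:
            best, best_ov = tx, ov
    return best


def classify(orf: OrfTableRow, annotation: AnnotationSet | None) -> str:
    """Assign one category label to a predicted ORF."""
    if annotation is None or len(annotation) == 0:
        return "novel"
    tx = _host_transcript(orf, annotation)
    if tx is None:
        return "novel"

    biotype = (tx.biotype or "").lower()
    if biotype in TE_BIOTYPES:
        return "TE_ORF"
    if biotype in PSEUDOGENE_BIOTYPES:
        return "pseudogene_ORF"
    if biotype in NONCODING_BIOTYPES or not tx.cds:
        return "ncRNA_ORF"

    cds_blocks = tuple((c.start, c.end) for c in sorted(tx.cds, key=lambda c: c.start))
    if orf.blocks == cds_blocks:
        return "annotated"

    pos, cds_tx = _tx_geometry(tx)
    if cds_tx is None:
        return "ncRNA_ORF"
    cds_start, cds_end = cds_tx

    # project the ORF 5'/3' ends into this transcript's coordinates
    if orf.transcript_id == tx.transcript_id:
        o_start, o_end = orf.tx_start, orf.tx_end
    else:
        index_of = {int(g): i for i, g in enumerate(pos)}
        five = orf.blocks[0][0] if orf.strand == "+" else orf.blocks[-1][1] - 1
        three = orf.blocks[-1][1] - 1 if orf.strand == "+" else orf.blocks[0][0]
        if five not in index_of or three not in index_of:
            return "novel"
        o_start, o_end = index_of[five], index_of[three] + 1

    in_frame = (o_start - cds_start) % 3 == 0
    same_stop = _stop_coord(orf.blocks, orf.strand) == _stop_coord(
        cds_blocks, tx.strand
    )
    if same_stop and in_frame:
        if o_start > cds_start:
            return "truncated"
        if o_start < cds_start:
            return "extended"
        return "annotated"

    if o_end <= cds_start:
        return "uORF"
    if o_start < cds_start < o_end:
        return "overlapped_uORF"
    if o_start >= cds_end:
        return "dORF"
    if o_start < cds_end < o_end:
        return "overlapped_dORF"
    if cds_start <= o_start and o_end <= cds_end:
        return "internal_ORF"
    return "novel"


def classify_all(
    rows: Iterable[OrfTableRow], annotation: AnnotationSet | None
) -> tuple[list[OrfTableRow], Counter]:
    """Label every row in place; return (rows, per-category counts)."""
    rows = list(rows)
    summary: Counter = Counter({c: 0 for c in CATEGORIES})
    for row in rows:
        row.category = classify(row, annotation)
        summary[row.category] += 1
    return rows, summary


def write_category_summary(summary: Counter, path) -> None:
    with open(path, "w") as fh:
        fh.write("category\tcount\n")
        for cat in CATEGORIES:
            fh.write(f"{cat}\t{summary.get(cat, 0)}\n")
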