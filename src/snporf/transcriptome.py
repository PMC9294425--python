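"""Spliced transcript construction and projection of genomic diversity.

A :class:`TranscriptModel` carries the spliced sequence, the exon block
map and, through :attr:`genomic_positions`, an explicit bijection between
transcript coordinates and the underlying genomic sites.  Per-site
diversity is strand-symmetric: projecting a track onto a minus-strand
transcript reverses the coordinate map but never the values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .io_formats import (
    AnnotationSet,
    DiversityTrack,
    FormatError,
    GenomeSequence,
    GenomicInterval,
    TranscriptAnnotation,
)

__all__ = [
    "TranscriptModel",
    "build_transcripts",
    "project_diversity",
    "extract_metagene_regions",
    "sample_intergenic_windows",
]


@dataclass
class TranscriptModel:
    """A spliced transcript with its coordinate map onto the genome."""

    transcript_id: str
    gene_id: str
    seq_id: str
    strand: str
    exons: list[GenomicInterval]
    sequence: str
    genomic_positions: np.ndarray  # transcript index -> genomic site
    cds: tuple[int, int] | None = None  # transcript coordinates, stop included
    biotype: str | None = None
    cds_frame_ok: bool = True

    def __len__(self) -> int:
        return len(self.sequence)

    def to_genomic_blocks(self, tx_start: int, tx_end: int) -> tuple[tuple[int, int], ...]:
        """Genomic blocks (sorted, 0-based half-open) underlying [tx_start, tx_end)."""
        pos = np.sort(self.genomic_positions[tx_start:tx_end])
        if len(pos) == 0:
            return ()
        breaks = np.where(np.diff(pos) != 1)[0]
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [len(pos) - 1]))
        return tuple((int(pos[s]), int(pos[e]) + 1) for s, e in zip(starts, ends))


def build_transcripts(
    genome: GenomeSequence, annotation: AnnotationSet
) -> list[TranscriptModel]:
    """One spliced model per usable annotated transcript.

    Minus-strand transcripts are reverse-complemented; the genomic position
    map is reversed accordingly so index 0 is always the transcript 5' end.
    """
    models = []
    for tid in sorted(annotation.transcripts):
        tx = annotation.transcripts[tid]
        if not tx.usable:
            continue
        models.append(_build_one(genome, tx))
    return models


def _build_one(genome: GenomeSequence, tx: TranscriptAnnotation) -> TranscriptModel:
    if tx.seq_id not in genome:
        raise FormatError(
            f"transcript {tx.transcript_id}: seq_id {tx.seq_id!r} not in genome"
        )
    chrom = genome[tx.seq_id]
    parts = []
    pos_parts = []
    for exon in tx.exons:
        if exon.end > len(chrom):
            raise FormatError(
                f"transcript {tx.transcript_id}: exon [{exon.start},{exon.end}) "
                f"beyond end of {tx.seq_id} (length {len(chrom)})"
            )
        parts.append(chrom[exon.start:exon.end])
        pos_parts.append(np.arange(exon.start, exon.end))
    seq = "".join(parts)
    positions = np.concatenate(pos_parts)
    if tx.strand == "-":
        seq = str(Seq(seq).reverse_complement())
        positions = positions[::-1].copy()
    cds_tx = None
    frame_ok = True
    if tx.cds:
        # map every CDS genomic site into transcript coordinates
        index_of = {int(g): i for i, g in enumerate(positions)}
        tx_idx = sorted(
            index_of[g]
            for c in tx.cds
            for g in range(c.start, c.end)
            if g in index_of
        )
        if tx_idx:
            cds_tx = (tx_idx[0], tx_idx[-1] + 1)
            if (cds_tx[1] - cds_tx[0]) != len(tx_idx):
                frame_ok = False  # CDS not contiguous in transcript coords
            if (cds_tx[1] - cds_tx[0]) % 3 != 0:
                frame_ok = False
    return TranscriptModel(
        transcript_id=tx.transcript_id,
        gene_id=tx.gene_id,
        seq_id=tx.seq_id,
        strand=tx.strand,
        exons=list(tx.exons),
        sequence=seq,
        genomic_positions=positions,
        cds=cds_tx,
        biotype=tx.biotype,
        cds_frame_ok=frame_ok,
    )


def project_diversity(transcript: TranscriptModel, track: DiversityTrack) -> np.ndarray:
    """Per-transcript-position diversity vector (absent sites read 0)."""
    return track.values_at(transcript.seq_id, transcript.genomic_positions)


def extract_metagene_regions(
    transcripts: list[TranscriptModel],
    track: DiversityTrack,
    window: int = 50,
) -> dict[str, list[np.ndarray]]:
    """Fixed-length diversity windows for metagene profiling.

    CDS: the first `window` nt of each annotated CDS.  UTR5: the `window` nt
    immediately upstream of the start codon.  UTR3: the `window` nt
    immediately downstream of the stop codon.  Transcripts whose region is
    shorter than `window` are excluded from that region's set.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    out: dict[str, list[np.ndarray]] = {"CDS": [], "UTR5": [], "UTR3": []}
    for tx in transcripts:
        if tx.cds is None:
            continue
        div = project_diversity(tx, track)
        cds_start, cds_end = tx.cds
        if cds_end - cds_start >= window:
            out["CDS"].append(div[cds_start:cds_start + window])
        if cds_start >= window:
            out["UTR5"].append(div[cds_start - window:cds_start])
        if len(tx) - cds_end >= window:
            out["UTR3"].append(div[cds_end:cds_end + window])
    return out


def sample_intergenic_windows(
    genome: GenomeSequence,
    annotation: AnnotationSet,
    track: DiversityTrack,
    n: int = 10000,
    width: int = 50,
    seed: int | None = None,
) -> list[np.ndarray]:
    """`n` diversity windows sampled uniformly (with replacement) from
    intergenic space — the complement of all annotated gene spans on both
    strands."""
    rng = np.random.default_rng(seed)
    free: list[tuple[str, int, int]] = []
    spans_by_seq: dict[str, list[GenomicInterval]] = {}
    for span in annotation.gene_spans():
        spans_by_seq.setdefault(span.seq_id, []).append(span)
    for seq_id, chrom in genome.items():
        cursor = 0
        for span in sorted(spans_by_seq.get(seq_id, []), key=lambda s: s.start):
            if span.start - cursor >= width:
                free.append((seq_id, cursor, span.start))
            cursor = max(cursor, span.end)
        if len(chrom) - cursor >= width:
            free.append((seq_id, cursor, len(chrom)))
    if not free:
        raise ValueError(f"no intergenic region of length >= {width}")
    weights = np.array([e - s - width + 1 for _, s, e in free], dtype=float)
    probs = weights / weights.sum()
    choices = rng.choice(len(free), size=n, p=probs)
    offsets = rng.integers(0, weights[choices].astype(int), size=n)
    windows = []
    for idx, off in zip(choices, offsets):
        seq_id, s, _ = free[idx]
        start = s + int(off)
        positions = np.arange(start, start + width)
        windows.append(track.values_at(seq_id, positions))
    return windows
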