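"""Readers and writers for every on-disk format the predictor touches.

All internal coordinates are 0-based half-open; GTF/GFF3 1-based closed
coordinates and the 1-based POS column of per-site diversity tables are
converted at the file boundary.  Gzip input is handled transparently by
every reader.
"""

from __future__ import annotations

import gzip
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FormatError",
    "GenomeSequence",
    "GenomicInterval",
    "TranscriptAnnotation",
    "AnnotationSet",
    "DiversityTrack",
    "OrfTableRow",
    "read_fasta",
    "write_fasta",
    "read_gtf",
    "write_gtf",
    "read_site_pi",
    "write_site_pi",
    "compute_site_pi",
    "read_vcf_site_pi",
    "read_orf_table",
    "write_orf_table",
    "ORF_TABLE_COLUMNS",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

NONCODING_BIOTYPES = frozenset(
    {"non-coding", "noncoding", "ncrna", "lncrna", "lincrna", "mirna",
     "snorna", "snrna", "rrna", "trna", "antisense"}
)
TE_BIOTYPES = frozenset({"transposable_element", "transposon", "te"})
PSEUDOGENE_BIOTYPES = frozenset(
    {"pseudogene", "processed_pseudogene", "unprocessed_pseudogene"}
)


class FormatError(ValueError):
    """A file does not conform to its declared format."""


def _open_text(path) -> io.TextIOBase:
    path = Path(path)
    fh = open(path, "rb")
    magic = fh.read(2)
    fh.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=fh))
    return io.TextIOWrapper(fh)


# ---------------------------------------------------------------------------
# genome sequences
# ---------------------------------------------------------------------------

@dataclass
class GenomeSequence:
    """Uppercased chromosome/contig sequences keyed by unique seq_id."""

    records: dict[str, str] = field(default_factory=dict)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.records

    def __getitem__(self, seq_id: str) -> str:
        return self.records[seq_id]

    def __len__(self) -> int:
        return len(self.records)

    def length(self, seq_id: str) -> int:
        return len(self.records[seq_id])

    def items(self):
        return self.records.items()


def read_fasta(path) -> GenomeSequence:
    """Load a (optionally gzipped) FASTA file, uppercasing residues."""
    with _open_text(path) as fh:
        first = None
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                first = (lineno, line)
                break
        if first is None:
            raise FormatError(f"{path}: empty FASTA file")
        if not first[1].startswith(">"):
            raise FormatError(
                f"{path}: line {first[0]}: expected FASTA header starting with '>'"
            )
    genome = GenomeSequence()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in genome.records:
                raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
            seq = str(rec.seq).upper()
            if not seq:
                raise FormatError(f"{path}: record {rec.id!r} has empty sequence")
            genome.records[rec.id] = seq
    return genome


def write_fasta(genome: GenomeSequence, path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=seq_id, description="")
        for seq_id, seq in genome.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# genomic intervals and annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a strand of a reference sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class TranscriptAnnotation:
    """One transcript: its exons, CDS sub-intervals and biotype."""

    transcript_id: str
    gene_id: str
    seq_id: str
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)
    cds: list[GenomicInterval] = field(default_factory=list)
    biotype: str | None = None
    usable: bool = True

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.seq_id,
            min(e.start for e in self.exons),
            max(e.end for e in self.exons),
            self.strand,
        )

    def validate(self) -> None:
        if not self.exons:
            raise FormatError(f"transcript {self.transcript_id}: no exons")
        if len({(e.seq_id, e.strand) for e in self.exons}) != 1:
            raise FormatError(
                f"transcript {self.transcript_id}: exons on multiple seq_ids/strands"
            )
        self.exons.sort(key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise FormatError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )
        self.cds.sort(key=lambda c: c.start)
        for c in self.cds:
            if not any(e.start <= c.start and c.end <= e.end for e in self.exons):
                warnings.warn(
                    f"transcript {self.transcript_id}: CDS outside exon union; "
                    "flagged unusable"
                )
                self.usable = False


@dataclass
class AnnotationSet:
    """gene -> transcript -> feature hierarchy read from a GTF."""

    transcripts: dict[str, TranscriptAnnotation] = field(default_factory=dict)
    genes: dict[str, list[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.transcripts)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.transcripts

    def __getitem__(self, transcript_id: str) -> TranscriptAnnotation:
        return self.transcripts[transcript_id]

    def add(self, tx: TranscriptAnnotation) -> None:
        self.transcripts[tx.transcript_id] = tx
        self.genes.setdefault(tx.gene_id, []).append(tx.transcript_id)

    def gene_spans(self) -> list[GenomicInterval]:
        """One interval per gene covering all its transcripts (both strands)."""
        spans = []
        for gene_id, tids in self.genes.items():
            seqs = {self.transcripts[t].seq_id for t in tids}
            for seq_id in seqs:
                txs = [self.transcripts[t] for t in tids
                       if self.transcripts[t].seq_id == seq_id]
                start = min(tx.span.start for tx in txs)
                end = max(tx.span.end for tx in txs)
                spans.append(GenomicInterval(seq_id, start, end))
        return spans


_BIOTYPE_KEYS = ("transcript_biotype", "transcript_type", "gene_biotype",
                 "gene_type", "biotype")


def read_gtf(path) -> AnnotationSet:
    """Assemble the transcript hierarchy from a GTF 2.2 file.

    `stop_codon` features, when present, are merged into the CDS so that the
    stored CDS intervals always include the stop codon (the convention the
    predictor and the bundled GTF writer use).
    """
    import gffutils

    with _open_text(path) as fh:
        text = fh.read()
    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    ann = AnnotationSet()
    pending: dict[str, TranscriptAnnotation] = {}
    for feat in db.all_features():
        kind = feat.featuretype.lower()
        if kind not in ("exon", "cds", "stop_codon"):
            continue
        attrs = feat.attributes
        if "transcript_id" not in attrs:
            raise FormatError(
                f"{path}: {feat.featuretype} feature at {feat.seqid}:{feat.start} "
                "lacks transcript_id"
            )
        tid = attrs["transcript_id"][0]
        gid = attrs["gene_id"][0] if "gene_id" in attrs else tid
        tx = pending.get(tid)
        if tx is None:
            biotype = None
            for key in _BIOTYPE_KEYS:
                if key in attrs:
                    biotype = attrs[key][0]
                    break
            tx = TranscriptAnnotation(tid, gid, feat.seqid, feat.strand,
                                      biotype=biotype)
            pending[tid] = tx
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        if kind == "exon":
            tx.exons.append(iv)
        else:  # cds or stop_codon
            tx.cds.append(iv)
    for tx in pending.values():
        tx.cds = _merge_adjacent(tx.cds)
        tx.validate()
        ann.add(tx)
    return ann


def _merge_adjacent(ivs: list[GenomicInterval]) -> list[GenomicInterval]:
    if not ivs:
        return []
    ivs = sorted(ivs, key=lambda i: i.start)
    out = [ivs[0]]
    for iv in ivs[1:]:
        last = out[-1]
        if iv.start <= last.end:
            out[-1] = GenomicInterval(last.seq_id, last.start,
                                      max(last.end, iv.end), last.strand)
        else:
            out.append(iv)
    return out


def write_gtf(annotation: AnnotationSet, path, source: str = "snporf") -> None:
    """Write exon and CDS features (CDS includes the stop codon)."""
    with open(path, "w") as fh:
        for gene_id, tids in annotation.genes.items():
            for tid in tids:
                tx = annotation.transcripts[tid]
                attrs = f'gene_id "{gene_id}"; transcript_id "{tid}";'
                if tx.biotype:
                    attrs += f' transcript_biotype "{tx.biotype}";'
                for kind, ivs in (("exon", tx.exons), ("CDS", tx.cds)):
                    for iv in ivs:
                        fh.write(
                            f"{tx.seq_id}\t{source}\t{kind}\t{iv.start + 1}\t"
                            f"{iv.end}\t.\t{tx.strand}\t.\t{attrs}\n"
                        )


# ---------------------------------------------------------------------------
# per-site nucleotide diversity
# ---------------------------------------------------------------------------

class DiversityTrack:
    """Sparse map (seq_id, 0-based site) -> per-site nucleotide diversity.

    Sites absent from the track read as 0 (the ``--site-pi`` output of
    vcftools only lists sites present in the VCF; everything else is
    invariant in the sample).
    """

    def __init__(self):
        self._data: dict[str, dict[int, float]] = {}

    def set(self, seq_id: str, pos: int, pi: float) -> None:
        if pi < 0:
            raise ValueError(f"negative diversity at {seq_id}:{pos}")
        self._data.setdefault(seq_id, {})[pos] = float(pi)

    def get(self, seq_id: str, pos: int) -> float:
        chrom = self._data.get(seq_id)
        if chrom is None:
            return 0.0
        return chrom.get(pos, 0.0)

    def values_at(self, seq_id: str, positions: np.ndarray) -> np.ndarray:
        """Vector of diversity values at `positions` (absent sites -> 0)."""
        chrom = self._data.get(seq_id)
        if not chrom:
            return np.zeros(len(positions))
        return np.array([chrom.get(int(p), 0.0) for p in positions])

    def __len__(self) -> int:
        return sum(len(v) for v in self._data.values())

    def items(self):
        for seq_id in self._data:
            for pos, pi in self._data[seq_id].items():
                yield seq_id, pos, pi

    def __eq__(self, other) -> bool:
        if not isinstance(other, DiversityTrack):
            return NotImplemented
        return self._data == other._data


def read_site_pi(path) -> DiversityTrack:
    """Read a tab-delimited CHROM/POS/PI table (POS 1-based on disk)."""
    track = DiversityTrack()
    with _open_text(path) as fh:
        header = fh.readline()
        cols = header.rstrip("\n").split("\t")
        if cols[:3] != ["CHROM", "POS", "PI"]:
            raise FormatError(
                f"{path}: line 1: expected header CHROM\\tPOS\\tPI, got {cols[:3]}"
            )
        seen: set[tuple[str, int]] = set()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: fewer than 3 columns")
            chrom, pos_s, pi_s = parts[0], parts[1], parts[2]
            try:
                pos = int(pos_s)
                pi = float(pi_s)
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-numeric POS or PI"
                ) from None
            if pi < 0:
                raise FormatError(f"{path}: line {lineno}: negative PI {pi}")
            key = (chrom, pos)
            if key in seen:
                raise FormatError(
                    f"{path}: line {lineno}: duplicate site {chrom}:{pos}"
                )
            seen.add(key)
            track.set(chrom, pos - 1, pi)
    return track


def write_site_pi(track: DiversityTrack, path) -> None:
    rows = sorted(track.items())
    with open(path, "w") as fh:
        fh.write("CHROM\tPOS\tPI\n")
        for seq_id, pos, pi in rows:
            fh.write(f"{seq_id}\t{pos + 1}\t{pi!r}\n")


def compute_site_pi(
    allele_counts: Mapping[tuple[str, int], Sequence[int]],
) -> DiversityTrack:
    """Per-site pi from allele counts: mean pairwise difference proportion.

    pi = 1 - sum_a (n_a/n) * ((n_a-1)/(n-1)), the unbiased per-site
    nucleotide diversity over the n sampled alleles.  Sites with n < 2 are
    skipped with a warning.
    """
    track = DiversityTrack()
    for (seq_id, pos), counts in allele_counts.items():
        counts = [c for c in counts if c > 0]
        n = sum(counts)
        if n < 2:
            warnings.warn(f"site {seq_id}:{pos}: fewer than 2 alleles; skipped")
            continue
        same = sum(c * (c - 1) for c in counts) / (n * (n - 1))
        track.set(seq_id, pos, 1.0 - same)
    return track


def read_vcf_site_pi(path) -> DiversityTrack:
    """Per-site pi from the GT fields of a simple multi-sample VCF."""
    from cyvcf2 import VCF

    counts: dict[tuple[str, int], list[int]] = {}
    for var in VCF(str(path)):
        n_alleles = len(var.ALT) + 1
        tally = [0] * n_alleles
        for gt in var.genotypes:
            for allele in gt[:-1]:  # last element is phasing flag
                if allele is not None and allele >= 0:
                    tally[allele] += 1
        counts[(var.CHROM, var.start)] = tally
    # positions are already 0-based (cyvcf2 .start)
    track = DiversityTrack()
    for (seq_id, pos), tally in counts.items():
        tally = [c for c in tally if c > 0]
        n = sum(tally)
        if n < 2:
            warnings.warn(f"site {seq_id}:{pos + 1}: fewer than 2 called alleles")
            continue
        same = sum(c * (c - 1) for c in tally) / (n * (n - 1))
        track.set(seq_id, pos, 1.0 - same)
    return track


# ---------------------------------------------------------------------------
# ORF output tables
# ---------------------------------------------------------------------------

ORF_TABLE_COLUMNS = [
    "orf_id", "gene_id", "transcript_id", "seq_id", "strand", "blocks",
    "tx_start", "tx_end", "start_codon", "length_nt",
    "p_div_f0", "p_div_f1", "p_use_f1", "p_use_f2", "p_combined",
    "category", "orf_seq", "protein_seq",
]


@dataclass
class OrfTableRow:
    """One predicted ORF: coordinates, test p-values, category, sequence."""

    orf_id: str
    gene_id: str
    transcript_id: str
    seq_id: str
    strand: str
    blocks: tuple[tuple[int, int], ...]
    tx_start: int
    tx_end: int
    start_codon: str
    length_nt: int
    p_div_f0: float
    p_div_f1: float
    p_use_f1: float
    p_use_f2: float
    p_combined: float
    category: str = "novel"
    orf_seq: str = ""
    protein_seq: str = ""

    def __post_init__(self):
        if self.length_nt % 3 != 0:
            raise ValueError(f"{self.orf_id}: length {self.length_nt} not a "
                             "multiple of 3")
        if self.length_nt != sum(e - s for s, e in self.blocks):
            raise ValueError(f"{self.orf_id}: block lengths do not sum to "
                             f"{self.length_nt}")

    @property
    def identity(self) -> tuple:
        """Genomic identity used for deduplication and set comparison."""
        return (self.seq_id, self.strand, self.blocks)

    def to_dict(self) -> dict:
        d = {c: getattr(self, c) for c in ORF_TABLE_COLUMNS}
        d["blocks"] = ";".join(f"{s}-{e}" for s, e in self.blocks)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "OrfTableRow":
        blocks = tuple(
            tuple(int(x) for x in part.split("-"))
            for part in str(d["blocks"]).split(";")
        )
        kwargs = {c: d[c] for c in ORF_TABLE_COLUMNS}
        kwargs["blocks"] = blocks
        for c in ("tx_start", "tx_end", "length_nt"):
            kwargs[c] = int(kwargs[c])
        for c in ("p_div_f0", "p_div_f1", "p_use_f1", "p_use_f2", "p_combined"):
            kwargs[c] = float(kwargs[c])
        for c in ("orf_seq", "protein_seq"):
            if pd.isna(kwargs[c]):
                kwargs[c] = ""
        return cls(**kwargs)


def write_orf_table(rows: Iterable[OrfTableRow], path, format: str = "tsv") -> None:
    rows = list(rows)
    if format == "tsv":
        df = pd.DataFrame([r.to_dict() for r in rows], columns=ORF_TABLE_COLUMNS)
        df.to_csv(path, sep="\t", index=False)
    elif format == "bed12":
        with open(path, "w") as fh:
            for r in rows:
                blocks = sorted(r.blocks)
                chrom_start = blocks[0][0]
                chrom_end = blocks[-1][1]
                sizes = ",".join(str(e - s) for s, e in blocks)
                starts = ",".join(str(s - chrom_start) for s, e in blocks)
                fh.write(
                    f"{r.seq_id}\t{chrom_start}\t{chrom_end}\t{r.orf_id}\t0\t"
                    f"{r.strand}\t{chrom_start}\t{chrom_end}\t0\t"
                    f"{len(blocks)}\t{sizes}\t{starts}\n"
                )
    elif format == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for r in rows:
                blocks = sorted(r.blocks)
                span = (blocks[0][0] + 1, blocks[-1][1])
                attrs = (f"ID={r.orf_id};transcript_id={r.transcript_id};"
                         f"gene_id={r.gene_id};category={r.category}")
                fh.write(
                    f"{r.seq_id}\tsnporf\tORF\t{span[0]}\t{span[1]}\t.\t"
                    f"{r.strand}\t.\t{attrs}\n"
                )
                for s, e in blocks:
                    fh.write(
                        f"{r.seq_id}\tsnporf\tCDS\t{s + 1}\t{e}\t.\t"
                        f"{r.strand}\t.\tParent={r.orf_id}\n"
                    )
    else:
        raise ValueError(f"unknown ORF table format {format!r}")


def read_orf_table(path) -> list[OrfTableRow]:
    df = pd.read_csv(path, sep="\t", dtype={"seq_id": str})
    return [OrfTableRow.from_dict(rec) for rec in df.to_dict("records")]
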