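"""Synthetic genomes, annotations and diversity tracks with planted truth.

The generator emulates the statistical structure the predictor relies on:
a small eukaryote-like genome of multi-exon protein-coding genes with UTRs
and intergenic spacers, CDS codons drawn from a (skewed) codon-usage
table, and per-site nucleotide diversity that is segregating more often —
and with larger values — at wobble (third codon) positions than anywhere
else.  Every planted ORF is recorded in a truth manifest so prediction can
be scored exactly.

UTR and spacer sequence is random; 5' and 3' UTRs are generated ATG-free
(outside any deliberately planted sORF) so that the 5'-most-start scanning
policy recovers planted CDS boundaries exactly — real 5'UTRs do contain
upstream AUGs, a simplification documented in the methods note.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

from .io_formats import (
    STOP_CODONS,
    AnnotationSet,
    DiversityTrack,
    GenomeSequence,
    GenomicInterval,
    TranscriptAnnotation,
    write_fasta,
    write_gtf,
    write_site_pi,
)
from .orf_caller import SENSE_CODONS

__all__ = [
    "SimulationParams",
    "PlantedOrf",
    "TruthManifest",
    "simulate_genome",
    "simulate_diversity",
    "subsample_population_effect",
    "orf_tx_order_positions",
    "write_fixture",
]

_STOPS = sorted(STOP_CODONS)

# site classes for the diversity model
CLASS_INTERGENIC, CLASS_UTR, CLASS_CDS, CLASS_WOBBLE = 0, 1, 2, 3


@dataclass
class SimulationParams:
    """Layout, codon-usage and diversity parameters of the synthetic genome.

    Defaults are sized so the full simulate -> train -> predict -> evaluate
    loop runs in well under two minutes while leaving a strong but not
    trivial wobble signal (segregating-site probability 0.10 at wobble
    positions versus 0.03 elsewhere; pi | segregating is exponential with
    mean 0.15 at wobble positions and 0.05 elsewhere).
    """

    n_genes: int = 200
    exons_per_gene: tuple[int, int] = (1, 3)
    intron_length: tuple[int, int] = (60, 200)
    utr5_length: tuple[int, int] = (60, 200)
    utr3_length: tuple[int, int] = (60, 200)
    cds_length: tuple[int, int] = (300, 1500)
    spacer_length: tuple[int, int] = (200, 800)
    codon_table: dict[str, float] | None = None
    codon_concentration: float = 0.5
    n_uorfs_per_gene: int = 0
    n_dorfs_per_gene: int = 0
    sorf_length: tuple[int, int] = (60, 99)
    wobble_seg_prob: float = 0.10
    nonwobble_seg_prob: float = 0.03
    utr_seg_prob: float = 0.03
    intergenic_seg_prob: float = 0.03
    wobble_pi_mean: float = 0.15
    nonwobble_pi_mean: float = 0.05
    utr_pi_mean: float = 0.05
    intergenic_pi_mean: float = 0.05
    seq_id: str = "chr1"
    seed: int = 0

    def __post_init__(self):
        for name in ("wobble_seg_prob", "nonwobble_seg_prob", "utr_seg_prob",
                     "intergenic_seg_prob"):
            p = getattr(self, name)
            if not (0 <= p <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.wobble_seg_prob < self.nonwobble_seg_prob:
            raise ValueError("wobble segregating probability must be >= "
                             "non-wobble probability")
        for name in ("intron_length", "utr5_length", "utr3_length",
                     "cds_length", "spacer_length", "sorf_length"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"infeasible {name} range ({lo}, {hi})")
        if self.cds_length[0] < 9:
            raise ValueError("CDS length must be at least 9 nt")
        if self.sorf_length[0] < 9:
            raise ValueError("sORF length must be at least 9 nt")
        if self.n_genes < 0:
            raise ValueError("n_genes must be non-negative")


@dataclass
class PlantedOrf:
    orf_id: str
    gene_id: str
    transcript_id: str
    seq_id: str
    strand: str
    blocks: tuple[tuple[int, int], ...]
    tx_start: int
    tx_end: int
    length_nt: int
    kind: str  # CDS | uORF | dORF

    @property
    def identity(self) -> tuple:
        return (self.seq_id, self.strand, self.blocks)


@dataclass
class TruthManifest:
    orfs: list[PlantedOrf] = field(default_factory=list)
    codon_table: dict[str, float] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "orfs": [asdict(o) for o in self.orfs],
            "codon_table": self.codon_table,
            "params": self.params,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            payload = json.load(fh)
        orfs = []
        for d in payload["orfs"]:
            d["blocks"] = tuple(tuple(b) for b in d["blocks"])
            orfs.append(PlantedOrf(**d))
        return cls(orfs=orfs, codon_table=payload["codon_table"],
                   params=payload["params"])


def orf_tx_order_positions(
    blocks: tuple[tuple[int, int], ...], strand: str
) -> np.ndarray:
    """Genomic sites of an ORF ordered 5'->3' along the transcript."""
    pos = np.concatenate([np.arange(s, e) for s, e in sorted(blocks)])
    return pos if strand == "+" else pos[::-1]


# ---------------------------------------------------------------------------
# sequence generation helpers
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))
_NON_T = np.array(list("ACG"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length)) if length else ""


def _strip_atg(seq: str, rng: np.random.Generator) -> str:
    """Replace the middle base of every ATG so none remains (one pass safe:
    removing the T cannot create a new ATG)."""
    chars = list(seq)
    i = seq.find("ATG")
    while i != -1:
        chars[i + 1] = str(rng.choice(_NON_T))
        seq = "".join(chars)
        i = seq.find("ATG", i + 1)
    return seq


def _draw_codon_table(params: SimulationParams, rng: np.random.Generator) -> dict:
    if params.codon_table is not None:
        table = {c: float(params.codon_table.get(c, 0.0)) for c in SENSE_CODONS}
    else:
        probs = rng.dirichlet(np.full(len(SENSE_CODONS), params.codon_concentration))
        table = dict(zip(SENSE_CODONS, probs.tolist()))
    total = sum(table.values())
    return {c: v / total for c, v in table.items()}


def _orf_seq(rng, length: int, codon_probs, interior_codons) -> str:
    n_codons = length // 3
    interior = rng.choice(interior_codons, size=n_codons - 2, p=codon_probs)
    return "ATG" + "".join(interior) + str(rng.choice(_STOPS))


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------

def simulate_genome(
    params: SimulationParams,
) -> tuple[GenomeSequence, AnnotationSet, TruthManifest]:
    """Lay out genes with spacers and return genome, annotation and truth."""
    rng = np.random.default_rng(params.seed)
    table = _draw_codon_table(params, rng)
    codon_probs = np.array([table[c] for c in SENSE_CODONS])
    codon_arr = np.array(SENSE_CODONS)

    chrom_parts: list[str] = []
    cursor = 0
    ann = AnnotationSet()
    manifest = TruthManifest(codon_table=table, params=asdict(params))
    seq_id = params.seq_id

    def rint(lohi):
        return int(rng.integers(lohi[0], lohi[1] + 1))

    spacer = _random_seq(rng, rint(params.spacer_length))
    chrom_parts.append(spacer)
    cursor += len(spacer)

    for g in range(params.n_genes):
        gene_id = f"gene{g + 1:04d}"
        tid = f"{gene_id}.t1"
        strand = "+" if rng.random() < 0.5 else "-"

        len5 = rint(params.utr5_length)
        len3 = rint(params.utr3_length)
        cds_len = 3 * (rint(params.cds_length) // 3)
        utr5 = _strip_atg(_random_seq(rng, len5), rng)
        utr3 = _strip_atg(_random_seq(rng, len3), rng)
        cds = _orf_seq(rng, cds_len, codon_probs, codon_arr)

        # optionally plant sORFs inside the UTRs (sense frame of the mature
        # transcript); interior codons avoid ATG to keep UTRs otherwise
        # start-free
        non_atg = [c for c in SENSE_CODONS if c != "ATG"]
        non_atg_probs = np.array([table[c] for c in non_atg])
        non_atg_probs = non_atg_probs / non_atg_probs.sum()
        non_atg_arr = np.array(non_atg)
        planted_utr: list[tuple[int, int, str]] = []  # (mature_start, mature_end, kind)

        def plant(utr_seq: str, n: int, base_offset: int, kind: str) -> str:
            for _ in range(n):
                length = 3 * (rint(params.sorf_length) // 3)
                if length > len(utr_seq):
                    raise ValueError(
                        f"infeasible: sORF length {length} exceeds UTR length "
                        f"{len(utr_seq)}"
                    )
                off = int(rng.integers(0, len(utr_seq) - length + 1))
                orf = _orf_seq(rng, length, non_atg_probs, non_atg_arr)
                utr_seq = utr_seq[:off] + orf + utr_seq[off + length:]
                planted_utr.append((base_offset + off, base_offset + off + length,
                                    kind))
            return utr_seq

        if params.n_uorfs_per_gene:
            utr5 = plant(utr5, params.n_uorfs_per_gene, 0, "uORF")
        if params.n_dorfs_per_gene:
            utr3 = plant(utr3, params.n_dorfs_per_gene, len5 + cds_len, "dORF")

        mature = utr5 + cds + utr3
        m_len = len(mature)

        # split the mature transcript into exons; introns in between
        n_ex = rint(params.exons_per_gene)
        n_ex = min(n_ex, m_len - 1) if n_ex > 1 else n_ex
        if n_ex > 1:
            cuts = np.sort(rng.choice(np.arange(1, m_len), size=n_ex - 1,
                                      replace=False))
            bounds = [0, *cuts.tolist(), m_len]
        else:
            bounds = [0, m_len]
        exon_mblocks = list(zip(bounds[:-1], bounds[1:]))
        introns = [_random_seq(rng, rint(params.intron_length))
                   for _ in range(n_ex - 1)]

        sense_parts = []
        sense_offsets = np.empty(m_len, dtype=np.int64)
        off = 0
        for i, (a, b) in enumerate(exon_mblocks):
            sense_parts.append(mature[a:b])
            sense_offsets[a:b] = off + np.arange(b - a)
            off += b - a
            if i < len(introns):
                sense_parts.append(introns[i])
                off += len(introns[i])
        sense_gene = "".join(sense_parts)
        g_len = len(sense_gene)

        gene_start = cursor
        if strand == "+":
            gene_seq = sense_gene
            m2g = gene_start + sense_offsets
        else:
            gene_seq = str(Seq(sense_gene).reverse_complement())
            m2g = gene_start + (g_len - 1 - sense_offsets)
        chrom_parts.append(gene_seq)
        cursor += g_len

        def blocks_of(m_start: int, m_end: int) -> tuple[tuple[int, int], ...]:
            pos = np.sort(m2g[m_start:m_end])
            breaks = np.where(np.diff(pos) != 1)[0]
            starts = np.concatenate(([0], breaks + 1))
            ends = np.concatenate((breaks, [len(pos) - 1]))
            return tuple((int(pos[s]), int(pos[e]) + 1)
                         for s, e in zip(starts, ends))

        tx = TranscriptAnnotation(
            transcript_id=tid, gene_id=gene_id, seq_id=seq_id, strand=strand,
            biotype="protein_coding",
        )
        for a, b in exon_mblocks:
            for s, e in blocks_of(a, b):
                tx.exons.append(GenomicInterval(seq_id, s, e, strand))
        for s, e in blocks_of(len5, len5 + cds_len):
            tx.cds.append(GenomicInterval(seq_id, s, e, strand))
        tx.validate()
        ann.add(tx)

        manifest.orfs.append(
            PlantedOrf(
                orf_id=f"{gene_id}.orf", gene_id=gene_id, transcript_id=tid,
                seq_id=seq_id, strand=strand,
                blocks=blocks_of(len5, len5 + cds_len),
                tx_start=len5, tx_end=len5 + cds_len, length_nt=cds_len,
                kind="CDS",
            )
        )
        for k, (ms, me, kind) in enumerate(planted_utr):
            manifest.orfs.append(
                PlantedOrf(
                    orf_id=f"{gene_id}.{kind}{k + 1}", gene_id=gene_id,
                    transcript_id=tid, seq_id=seq_id, strand=strand,
                    blocks=blocks_of(ms, me), tx_start=ms, tx_end=me,
                    length_nt=me - ms, kind=kind,
                )
            )

        spacer = _random_seq(rng, rint(params.spacer_length))
        chrom_parts.append(spacer)
        cursor += len(spacer)

    genome = GenomeSequence({seq_id: "".join(chrom_parts)})
    return genome, ann, manifest


# ---------------------------------------------------------------------------
# diversity simulation
# ---------------------------------------------------------------------------

def _site_classes(
    genome: GenomeSequence, annotation: AnnotationSet, manifest: TruthManifest
) -> dict[str, np.ndarray]:
    classes = {
        seq_id: np.full(len(seq), CLASS_INTERGENIC, dtype=np.int8)
        for seq_id, seq in genome.items()
    }
    for tx in annotation.transcripts.values():
        arr = classes[tx.seq_id]
        for e in tx.exons:
            arr[e.start:e.end] = np.maximum(arr[e.start:e.end], CLASS_UTR)
        for c in tx.cds:
            arr[c.start:c.end] = np.maximum(arr[c.start:c.end], CLASS_CDS)
    for orf in manifest.orfs:
        arr = classes[orf.seq_id]
        pos = orf_tx_order_positions(orf.blocks, orf.strand)
        arr[pos] = np.maximum(arr[pos], CLASS_CDS)
        arr[pos[2::3]] = CLASS_WOBBLE
    return classes


def simulate_diversity(
    genome: GenomeSequence,
    annotation: AnnotationSet,
    manifest: TruthManifest,
    params: SimulationParams,
    seed: int | None = None,
) -> DiversityTrack:
    """Draw per-site pi: each site segregates independently with its class
    probability; segregating sites draw pi from an exponential with the
    class mean.  Non-segregating sites are omitted from the track."""
    rng = np.random.default_rng(
        params.seed + 1 if seed is None else seed
    )
    seg_prob = np.array([params.intergenic_seg_prob, params.utr_seg_prob,
                         params.nonwobble_seg_prob, params.wobble_seg_prob])
    pi_mean = np.array([params.intergenic_pi_mean, params.utr_pi_mean,
                        params.nonwobble_pi_mean, params.wobble_pi_mean])
    track = DiversityTrack()
    for seq_id, cls in _site_classes(genome, annotation, manifest).items():
        n = len(cls)
        seg = rng.random(n) < seg_prob[cls]
        mags = rng.exponential(1.0, n) * pi_mean[cls]
        for pos in np.nonzero(seg)[0]:
            track.set(seq_id, int(pos), float(mags[pos]))
    return track


def subsample_population_effect(
    track: DiversityTrack,
    fractions: list[float],
    seed: int = 0,
) -> dict[float, DiversityTrack]:
    """Emulate smaller population samples by thinning segregating sites.

    Each site is independently retained with probability equal to the
    fraction (rarer variants are lost first in a smaller sample; the
    uniform thinning is the simplest monotone stand-in).  Fraction 1
    reproduces the input track exactly.
    """
    out: dict[float, DiversityTrack] = {}
    for i, frac in enumerate(fractions):
        if not (0 <= frac <= 1):
            raise ValueError(f"fraction {frac} outside [0, 1]")
        rng = np.random.default_rng([seed, i])
        thin = DiversityTrack()
        for seq_id, pos, pi in track.items():
            if frac >= 1.0 or rng.random() < frac:
                thin.set(seq_id, pos, pi)
        out[frac] = thin
    return out


def write_fixture(
    outdir,
    genome: GenomeSequence,
    annotation: AnnotationSet,
    track: DiversityTrack,
    manifest: TruthManifest,
) -> dict[str, Path]:
    """Write genome.fa, annotation.gtf, pi.tsv and manifest.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "gtf": outdir / "annotation.gtf",
        "pi": outdir / "pi.tsv",
        "manifest": outdir / "manifest.json",
    }
    write_fasta(genome, paths["genome"])
    write_gtf(annotation, paths["gtf"])
    write_site_pi(track, paths["pi"])
    manifest.to_json(paths["manifest"])
    return paths
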