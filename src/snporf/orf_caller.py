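"""The core predictor: frame-wise diversity and codon-usage tests on
candidate ORFs.

For each candidate (start codon .. in-frame stop) the predictor asks two
questions, each as a pair of one-sided pooled-variance t-tests:

* diversity — are per-site pi values at frame-2 (wobble) positions greater
  than at frame-0 and frame-1 positions?
* codon usage — are the trained usage frequencies of the triplets read in
  the candidate's own frame greater than those read in the two shifted
  frames?

The four p-values are combined into one; because the two tests of each pair
share a sample (frame 2, respectively frame 0), the default combination is
Brown's correlation-adjusted Fisher method with the known structural
correlation, which keeps the null false-positive rate at the nominal alpha.
The codon-usage table is trained beforehand from a stringent diversity-only
pass restricted to ATG-initiated candidates of at least 300 nt.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
from Bio.Seq import Seq
from scipy import stats

from .io_formats import STOP_CODONS, DiversityTrack, OrfTableRow
from .transcriptome import TranscriptModel, project_diversity

__all__ = [
    "CallerConfig",
    "CandidateOrf",
    "CodonUsageTable",
    "FrameTestResult",
    "TrainingError",
    "UntestableCandidate",
    "SENSE_CODONS",
    "scan_candidates",
    "split_frames",
    "one_sided_t",
    "combine_pvalues",
    "diversity_frame_test",
    "usage_values",
    "usage_frame_test",
    "train_codon_usage",
    "predict_orfs",
]

ALL_CODONS = ["".join(t) for t in product("ACGT", repeat=3)]
SENSE_CODONS = [c for c in ALL_CODONS if c not in STOP_CODONS]

# Structural correlation between the two t-tests of a pair that share one
# sample: corr(t_1, t_2) = 1/2 when the three frames contribute equal
# variance.  Used by the default Brown combination.
_PAIR_CORR = 0.5


class TrainingError(RuntimeError):
    """The stringent preliminary pass produced no ORFs to train on."""


class UntestableCandidate(ValueError):
    """Too little information in a candidate to run the frame tests."""


@dataclass(frozen=True)
class CandidateOrf:
    """A start-to-stop interval in transcript coordinates (stop included)."""

    transcript_id: str
    start: int
    end: int
    start_codon: str

    def __post_init__(self):
        if (self.end - self.start) % 3 != 0:
            raise ValueError("candidate length not a multiple of 3")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class FrameTestResult:
    p_div_f0: float
    p_div_f1: float
    p_use_f1: float
    p_use_f2: float
    p_combined: float


@dataclass
class CodonUsageTable:
    """Relative usage of each sense codon, trained genome-wide.

    Stop codons have frequency 0; sense-codon frequencies sum to 1.
    """

    frequencies: dict[str, float]
    n_orfs: int = 0
    n_codons: int = 0

    def __post_init__(self):
        freqs = {c: 0.0 for c in ALL_CODONS}
        freqs.update({k: float(v) for k, v in self.frequencies.items()})
        for c in STOP_CODONS:
            freqs[c] = 0.0
        total = sum(freqs.values())
        if total <= 0:
            raise ValueError("codon usage table has no mass on sense codons")
        self.frequencies = {c: v / total for c, v in freqs.items()}

    @classmethod
    def uniform(cls) -> "CodonUsageTable":
        return cls({c: 1.0 / len(SENSE_CODONS) for c in SENSE_CODONS})

    def value(self, triplet: str) -> float:
        return self.frequencies.get(triplet, 0.0)


@dataclass
class CallerConfig:
    """Tunable parameters of the two-stage predictor."""

    start_codons: tuple[str, ...] = ("ATG",)
    min_length_nt: int = 60
    training_min_length_nt: int = 300
    alpha: float = 0.05
    combine_method: str = "brown"  # brown | fisher | stouffer
    start_policy: str = "5prime"  # 5prime | all
    min_informative_sites: int = 2
    max_n_fraction: float = 0.10
    per_nucleotide_usage: bool = False
    fdr: bool = False  # Benjamini-Hochberg across candidates

    def __post_init__(self):
        if self.min_length_nt % 3 or self.training_min_length_nt % 3:
            raise ValueError("minimum ORF lengths must be multiples of 3")
        if not (0 < self.alpha < 1) and self.alpha != 0:
            raise ValueError("alpha must be in [0, 1)")
        if self.start_policy not in ("5prime", "all"):
            raise ValueError(f"unknown start policy {self.start_policy!r}")
        if self.combine_method not in ("brown", "fisher", "stouffer"):
            raise ValueError(f"unknown combine method {self.combine_method!r}")
        self.start_codons = tuple(c.upper() for c in self.start_codons)


# ---------------------------------------------------------------------------
# candidate enumeration
# ---------------------------------------------------------------------------

def scan_candidates(
    sequence: str,
    config: CallerConfig,
    transcript_id: str = "",
    min_length: int | None = None,
    start_codons: tuple[str, ...] | None = None,
) -> list[CandidateOrf]:
    """Enumerate start..stop candidates frame by frame.

    Under the default 5'-most policy each (stop, frame) pair yields at most
    one candidate — the longest ORF ending at that stop; the `all` policy
    also reports nested, downstream starts.
    """
    min_len = config.min_length_nt if min_length is None else min_length
    starts = config.start_codons if start_codons is None else start_codons
    n = len(sequence)
    out: list[CandidateOrf] = []
    for frame in range(3):
        pending: list[int] = []
        for pos in range(frame, n - 2, 3):
            codon = sequence[pos:pos + 3]
            if codon in STOP_CODONS:
                for s in pending:
                    length = pos + 3 - s
                    if length >= min_len:
                        out.append(
                            CandidateOrf(transcript_id, s, pos + 3,
                                         sequence[s:s + 3])
                        )
                    if config.start_policy == "5prime":
                        break
                pending = []
            elif codon in starts:
                if config.start_policy == "all" or not pending:
                    pending.append(pos)
    out.sort(key=lambda c: (c.start, c.end))
    return out


def split_frames(values, start: int, end: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split values[start:end] into the three codon-position frames."""
    if (end - start) % 3 != 0:
        raise ValueError("split_frames: interval length not a multiple of 3")
    v = np.asarray(values, dtype=float)[start:end]
    return v[0::3], v[1::3], v[2::3]


# ---------------------------------------------------------------------------
# the statistical tests
# ---------------------------------------------------------------------------

def one_sided_t(a, b) -> float:
    """Pooled-variance two-sample t-test of H1: mean(b) > mean(a).

    Both samples need at least two values.  When both samples are constant
    the test degenerates and the p-value is decided by the means alone
    (0 / 0.5 / 1 for greater / equal / smaller).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise UntestableCandidate(
            f"one_sided_t needs >= 2 values per sample (got {len(a)}, {len(b)})"
        )
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        mb, ma = float(np.mean(b)), float(np.mean(a))
        if mb > ma:
            return 0.0
        if mb < ma:
            return 1.0
        return 0.5
    import warnings as _warnings

    with _warnings.catch_warnings():
        # one constant sample is routine with sparse diversity vectors; the
        # pooled variance is still carried by the other sample
        _warnings.filterwarnings("ignore", message="Precision loss occurred")
        return float(
            stats.ttest_ind(b, a, equal_var=True, alternative="greater").pvalue
        )


def _brown_params(corr: np.ndarray) -> tuple[float, float]:
    """Scale c and df f of the chi^2 approximating Brown's statistic."""
    k = corr.shape[0]
    cov = 0.0
    for i in range(k):
        for j in range(i + 1, k):
            r = corr[i, j]
            # Kost & McDermott polynomial approximation of
            # cov(-2 ln p_i, -2 ln p_j) for correlated test statistics
            cov += 3.263 * r + 0.710 * r**2 + 0.027 * r**3
    mean = 2.0 * k
    var = 4.0 * k + 2.0 * cov
    return var / (2.0 * mean), 2.0 * mean**2 / var


def combine_pvalues(ps, method: str = "fisher", corr: np.ndarray | None = None) -> float:
    """Combine p-values into one.

    `fisher` and `stouffer` assume independence; `brown` is Fisher's
    statistic referred to a scaled chi^2 whose moments account for the
    pairwise correlation of the tests (identity correlation reduces brown
    to fisher).
    """
    ps = np.asarray(ps, dtype=float)
    if ps.size == 0:
        raise ValueError("combine_pvalues: empty p-value list")
    tiny = np.finfo(float).tiny
    ps = np.clip(ps, tiny, 1.0)
    if method == "fisher":
        return float(stats.combine_pvalues(ps, method="fisher").pvalue)
    if method == "stouffer":
        return float(stats.combine_pvalues(ps, method="stouffer").pvalue)
    if method == "brown":
        if corr is None:
            corr = np.eye(len(ps))
        X = -2.0 * float(np.sum(np.log(ps)))
        c, f = _brown_params(np.asarray(corr, dtype=float))
        return float(stats.chi2.sf(X / c, f))
    raise ValueError(f"unknown combination method {method!r}")


def _pair_corr_matrix(n_pairs: int) -> np.ndarray:
    """Block correlation: tests 2i and 2i+1 share a sample (corr 1/2)."""
    k = 2 * n_pairs
    corr = np.eye(k)
    for i in range(n_pairs):
        corr[2 * i, 2 * i + 1] = corr[2 * i + 1, 2 * i] = _PAIR_CORR
    return corr


def diversity_frame_test(values, config: CallerConfig) -> tuple[float, float]:
    """(p_div_f0, p_div_f1): is frame-2 diversity greater than frame 0 / 1?

    `values` is the diversity-vector slice of one candidate (length a
    multiple of 3, zeros included).  Candidates with fewer than
    `config.min_informative_sites` segregating positions are untestable.
    """
    v = np.asarray(values, dtype=float)
    if len(v) % 3 != 0:
        raise ValueError("candidate slice length not a multiple of 3")
    if len(v) < 6:
        raise UntestableCandidate("candidate shorter than 2 codons")
    if int(np.count_nonzero(v)) < config.min_informative_sites:
        raise UntestableCandidate(
            f"fewer than {config.min_informative_sites} segregating sites"
        )
    f0, f1, f2 = split_frames(v, 0, len(v))
    return one_sided_t(f0, f2), one_sided_t(f1, f2)


def usage_values(
    sequence: str,
    start: int,
    end: int,
    frame_shift: int,
    table: CodonUsageTable,
    per_nucleotide: bool = False,
) -> np.ndarray:
    """Trained usage frequency of each sense triplet read at `frame_shift`.

    The reading starts at `start + frame_shift` and steps by 3; the trailing
    incomplete triplet of shifted readings is dropped.  Stop triplets and
    triplets containing N carry no usage information and are excluded.
    With `per_nucleotide` every triplet contributes three identical values
    (the per-nucleotide assignment; triples the t-test sample size).
    """
    if (end - start) % 3 != 0:
        raise ValueError("usage_values: interval length not a multiple of 3")
    if frame_shift not in (0, 1, 2):
        raise ValueError("frame_shift must be 0, 1 or 2")
    vals = []
    for pos in range(start + frame_shift, end - 2, 3):
        tri = sequence[pos:pos + 3]
        if tri in STOP_CODONS or "N" in tri:
            continue
        vals.append(table.value(tri))
    out = np.asarray(vals, dtype=float)
    if per_nucleotide:
        out = np.repeat(out, 3)
    return out


def usage_frame_test(
    sequence: str,
    candidate: CandidateOrf,
    table: CodonUsageTable,
    config: CallerConfig | None = None,
) -> tuple[float, float]:
    """(p_use_f1, p_use_f2): is frame-0 codon usage greater than frame 1 / 2?"""
    config = config or CallerConfig()
    per_nt = config.per_nucleotide_usage
    u0 = usage_values(sequence, candidate.start, candidate.end, 0, table, per_nt)
    u1 = usage_values(sequence, candidate.start, candidate.end, 1, table, per_nt)
    u2 = usage_values(sequence, candidate.start, candidate.end, 2, table, per_nt)
    return one_sided_t(u1, u0), one_sided_t(u2, u0)


# ---------------------------------------------------------------------------
# training and prediction
# ---------------------------------------------------------------------------

def _n_fraction(sequence: str, start: int, end: int) -> float:
    return sequence.count("N", start, end) / (end - start)


def _diversity_p_combined(div_slice, config: CallerConfig) -> tuple[float, float, float]:
    p0, p1 = diversity_frame_test(div_slice, config)
    pc = combine_pvalues([p0, p1], config.combine_method, _pair_corr_matrix(1))
    return p0, p1, pc


def _train_one(
    tx: TranscriptModel, div: np.ndarray, config: CallerConfig
) -> tuple[Counter, int]:
    counts: Counter = Counter()
    n_orfs = 0
    cands = scan_candidates(
        tx.sequence, config, tx.transcript_id,
        min_length=config.training_min_length_nt, start_codons=("ATG",),
    )
    for cand in cands:
        if _n_fraction(tx.sequence, cand.start, cand.end) > config.max_n_fraction:
            continue
        try:
            _, _, pc = _diversity_p_combined(div[cand.start:cand.end], config)
        except UntestableCandidate:
            continue
        if pc < config.alpha:
            n_orfs += 1
            for pos in range(cand.start, cand.end - 3, 3):  # stop excluded
                codon = tx.sequence[pos:pos + 3]
                if "N" not in codon and codon not in STOP_CODONS:
                    counts[codon] += 1
    return counts, n_orfs


def train_codon_usage(
    transcripts: list[TranscriptModel],
    track: DiversityTrack,
    config: CallerConfig,
    n_jobs: int = 1,
) -> CodonUsageTable:
    """Train the genome-wide codon usage table.

    The preliminary pass uses only the two diversity t-tests, canonical ATG
    starts and candidates of at least `config.training_min_length_nt`
    (default 300 nt); the codons of all preliminary ORFs are pooled with
    stop codons excluded and normalized to frequencies.
    """
    if not transcripts:
        raise TrainingError("no transcripts supplied")
    results = _map_transcripts(_train_one, transcripts, track, config, n_jobs)
    counts: Counter = Counter()
    n_orfs = 0
    for c, n in results:
        counts.update(c)
        n_orfs += n
    total = sum(counts.values())
    if total == 0:
        raise TrainingError(
            "preliminary diversity-only pass predicted no ORFs; supply more "
            "transcripts/diversity data or relax alpha"
        )
    freqs = {codon: cnt / total for codon, cnt in counts.items()}
    return CodonUsageTable(freqs, n_orfs=n_orfs, n_codons=total)


def _predict_one(
    tx: TranscriptModel, div: np.ndarray, config: CallerConfig,
    table: CodonUsageTable,
) -> list[tuple]:
    results = []
    for cand in scan_candidates(tx.sequence, config, tx.transcript_id):
        if _n_fraction(tx.sequence, cand.start, cand.end) > config.max_n_fraction:
            continue
        try:
            p_div_f0, p_div_f1 = diversity_frame_test(
                div[cand.start:cand.end], config
            )
            p_use_f1, p_use_f2 = usage_frame_test(tx.sequence, cand, table, config)
        except UntestableCandidate:
            continue
        p_combined = combine_pvalues(
            [p_div_f0, p_div_f1, p_use_f1, p_use_f2],
            config.combine_method,
            _pair_corr_matrix(2),
        )
        results.append(
            (cand, FrameTestResult(p_div_f0, p_div_f1, p_use_f1, p_use_f2,
                                   p_combined))
        )
    return results


def _map_transcripts(fn, transcripts, track, config, n_jobs, *extra):
    vectors = (project_diversity(tx, track) for tx in transcripts)
    if n_jobs == 1:
        return [fn(tx, div, config, *extra) for tx, div in zip(transcripts, vectors)]
    from joblib import Parallel, delayed

    return Parallel(n_jobs=n_jobs)(
        delayed(fn)(tx, div, config, *extra)
        for tx, div in zip(transcripts, vectors)
    )


def predict_orfs(
    transcripts: list[TranscriptModel],
    track: DiversityTrack,
    table: CodonUsageTable,
    config: CallerConfig | None = None,
    n_jobs: int = 1,
) -> list[OrfTableRow]:
    """Run the four frame tests on every candidate and report significant ORFs.

    Candidates reached through different transcript isoforms but with
    identical genomic blocks and strand are collapsed to a single row.
    Output order (and hence orf_id assignment) is deterministic: sorted by
    genomic coordinate.
    """
    config = config or CallerConfig()
    per_tx = _map_transcripts(_predict_one, transcripts, track, config,
                              n_jobs, table)
    tx_by_id = {tx.transcript_id: tx for tx in transcripts}
    tested = [item for sub in per_tx for item in sub]
    if config.fdr and tested:
        from statsmodels.stats.multitest import multipletests

        reject, *_ = multipletests(
            [ft.p_combined for _, ft in tested], alpha=config.alpha, method="fdr_bh"
        )
        accepted = [t for t, rej in zip(tested, reject) if rej]
    else:
        accepted = [t for t in tested if t[1].p_combined < config.alpha]

    seen: dict[tuple, None] = {}
    rows = []
    for cand, ft in accepted:
        tx = tx_by_id[cand.transcript_id]
        blocks = tx.to_genomic_blocks(cand.start, cand.end)
        identity = (tx.seq_id, tx.strand, blocks)
        if identity in seen:
            continue
        seen[identity] = None
        orf_seq = tx.sequence[cand.start:cand.end]
        protein = str(Seq(orf_seq).translate()).rstrip("*")
        rows.append(
            OrfTableRow(
                orf_id="",
                gene_id=tx.gene_id,
                transcript_id=tx.transcript_id,
                seq_id=tx.seq_id,
                strand=tx.strand,
                blocks=blocks,
                tx_start=cand.start,
                tx_end=cand.end,
                start_codon=cand.start_codon,
                length_nt=cand.length,
                p_div_f0=ft.p_div_f0,
                p_div_f1=ft.p_div_f1,
                p_use_f1=ft.p_use_f1,
                p_use_f2=ft.p_use_f2,
                p_combined=ft.p_combined,
                orf_seq=orf_seq,
                protein_seq=protein,
            )
        )
    rows.sort(key=lambda r: (r.seq_id, r.blocks[0][0], r.blocks[-1][1],
                             r.strand, r.blocks))
    for i, row in enumerate(rows, start=1):
        row.orf_id = f"ORF_{i:06d}"
    return rows
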