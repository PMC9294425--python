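# Methods

## The signal

Synonymous substitutions concentrate at third codon positions, so per-site
nucleotide diversity π sampled from a population is, on average, elevated
at every third base of coding sequence.  `snporf` treats this as a line
component at f = 1/3 cycles/nt in the spectrum of π along a transcript and
as a mean shift between codon-position classes within a candidate ORF.
π is defined on genomic sites and treated as strand-symmetric; one track
is projected onto transcripts of both strands through each transcript's
exon coordinate map.  Sites absent from the table read as 0 (the
`--site-pi` convention lists only variant sites); values are not capped at
1, so alternative diversity measures pass through unchanged.

## Periodicity assessment

Metagene profiles are positionwise means of equal-length windows: the
first 50 nt of each CDS, the 50 nt upstream of start codons, the 50 nt
downstream of stop codons, and 10,000 random 50-bp windows from the
complement of annotated gene spans.  Windows shorter than the target
length are excluded; isoforms contribute independently.

Each profile is mean-centered and tested with Thomson's harmonic F-test:
with DPSS tapers v₀…v_{K−1} (time-bandwidth NW = 4, K = 7 tapers — the
common default of the multitaper family; both exposed as parameters), the
eigencoefficients y_k(f) are regressed on the taper DC values U_k(0) to
estimate a complex line amplitude μ(f), and

    F(f) = (K−1) |μ(f)|² Σ_k U_k(0)² / Σ_k |y_k(f) − μ(f) U_k(0)|²

is referred to F(2, 2K−2).  Significance at 1/3 cycles/nt uses p < 0.001.
A constant profile is reported as degenerate with p = 1 everywhere.

*Frequency grid.*  F is evaluated on the Fourier grid of the series
zero-padded 4× and then rounded up to the next multiple of 3, so that 1/3
is itself a grid frequency for any window length.  This matters: the grid
spacing (≈ 0.005 cycles/nt at n = 50) is far finer than the multitaper
resolution bandwidth (2W = 2·NW/n = 0.16), so when the line frequency
falls between two bins, noise decides which of the two adjacent bins
carries the maximal F.  Placing 1/3 on the grid makes the reported peak
location stable and the p-value at 1/3 exact rather than interpolated.

## The predictor

Candidates are start-to-stop intervals in transcript coordinates: a
configurable start codon set (default {ATG}; CTG/GTG/TTG can be added),
an in-frame stop, length ≡ 0 (mod 3) and ≥ 60 nt, no internal in-frame
stop.  Under the default 5′-most policy each (stop, frame) pair yields the
longest ORF; an `all` policy enumerates nested starts.  Candidates with
more than 10% N are skipped, as are candidates with fewer than 2
segregating sites (a t-test on all-zero vectors would be vacuous;
zero-π positions are otherwise included so the per-position sample size is
preserved).

Four one-sided pooled-variance ("Student") two-sample t-tests are run per
candidate: diversity frame 2 > frame 0, frame 2 > frame 1; trained codon
usage of frame-0 readings > frame-1 readings and > frame-2 readings.
When both samples are constant the p-value is decided by the means
(0 / 0.5 / 1).  Usage vectors carry one value per sense triplet of the
reading; stop triplets and triplets containing N carry no usage
information and are excluded.  This keeps the usage test a pure
codon-preference test: scoring stops as 0 would turn it into a
stop-depletion test that fires on every syntactic ORF (candidates have no
internal in-frame stops by construction) and destroys null calibration.
A per-nucleotide mode (each triplet contributing three identical values)
is available as a config switch; it only inflates the t-test degrees of
freedom.

*Combining the four tests.*  The two diversity tests share the frame-2
sample and the two usage tests share the frame-0 sample, giving a
structural correlation of ≈ 1/2 within each pair.  Plain Fisher
combination under this dependence is anti-conservative (measured null
false-positive rate ≈ 0.078 at α = 0.05), so the default is Brown's
method: Fisher's statistic referred to a scaled χ² whose moments use the
Kost–McDermott covariance polynomial with the known pair correlation
(measured null rate ≈ 0.05).  Plain `fisher` and `stouffer` remain
available as config options.  No multiple-testing correction is applied
by default; a Benjamini–Hochberg switch exists.

*Training.*  The codon-usage table is trained by a diversity-only pass
restricted to ATG starts and candidates ≥ 300 nt at the same α; codons of
accepted ORFs are pooled (stop codons excluded, start codons included)
and normalized over the 61 sense codons.  The training and final passes
share α; the thresholds, lengths and start sets are all in
`CallerConfig`.

Predicted ORFs reached through different isoforms are collapsed by
(seq_id, strand, genomic blocks); output order and ORF ids are assigned by
genomic coordinate, so runs are byte-deterministic and worker count
(`--nCores`, via joblib over transcripts) affects speed only.

## Classification

Twelve mutually exclusive labels, assigned with a fixed precedence:
biotype of the host transcript first (transposable element, pseudogene,
non-coding), then exact block identity with the annotated CDS
("annotated"), then stop-sharing in genomic coordinates ("truncated" /
"extended" for in-frame starts inside / upstream of the CDS), then
UTR-relative placement (uORF, overlapped uORF, dORF, overlapped dORF —
the overlapped dORF requires an out-of-frame start inside the CDS), then
"internal ORF" for out-of-frame containment, else "novel".  With no
annotation supplied every ORF is "novel".  Stop comparisons are genomic
and strand-aware, so the labels are isoform-robust.

## Synthetic data: what it emulates, and what it does not

`SimulationParams` defaults define the study conditions used throughout
the test suite: 200 genes, 1–3 exons, CDS 300–1500 nt, UTRs 60–200 nt,
introns 60–200 nt, spacers 200–800 nt; CDS codons drawn from a
Dirichlet(0.5)-skewed sense-codon table; sites segregate independently
with probability 0.10 at wobble positions versus 0.03 elsewhere, and
π | segregating is exponential with mean 0.15 (wobble) versus 0.05
(elsewhere).  These values give a strong but not saturating signal and a
full simulate→train→predict→evaluate loop in seconds.  Optional uORFs and
dORFs can be planted inside the UTRs and are recorded in the truth
manifest alongside every CDS.

Deliberate simplifications, and hence the limits of what passing tests
demonstrate: UTR and intergenic sequence is i.i.d. random, and UTRs are
generated ATG-free (outside planted sORFs) so that the 5′-most-start
policy can recover planted boundaries exactly — real 5′UTRs contain
upstream AUGs, which in real data convert some exact matches into
"extended" calls.  Sites are independent (no linkage), with no indels, no
paralogy or polyploidy, and no coalescent structure; the method only
consumes marginal per-site π, so linkage is irrelevant to its statistics,
but genome-scale results on real polyploid data are outside what the
simulator can certify.  Population-size effects are emulated by uniform
thinning of segregating sites (retention probability = sampled fraction),
which reproduces the qualitative monotonicity of recall in population
size, not the allele-frequency detail of real subsampling.

## Numerical and calibration notes

* p = 0 is clamped to the smallest positive double before logs.
* The null calibration contracts (false-positive rate ≈ α; uniform
  diversity p-values) are asserted under a dense exchangeable null —
  every site segregating, equal exponential π across frames, 300-nt
  candidates, a skewed usage table — where the pooled-t sampling
  assumptions hold.  At realistic sparsity (a few percent of sites
  segregating) the frame tests become *conservative* (measured
  candidate-level false-positive rate ≈ 0.03 at α = 0.05): zero-inflated
  π violates the t assumptions in the safe direction.
* Type-I error of the harmonic F-test at 1/3 on white noise is within 2×
  the nominal 0.001 (10,000-replicate Monte Carlo in the test suite).
* "Longer than 300 bp" and "longer than 60 bp" are implemented
  inclusively (≥).  Overlapping significant candidates in different
  frames are all reported; deduplication is by exact genomic identity
  only.

## Known limitations

Prediction is restricted to annotated transcripts (no de novo or
splice-aware discovery), GTF is the only annotation input, and
mass-spectrometry support is a pure formula on externally supplied counts
— no peptide-spectrum matching is performed.  Genomes with very low
diversity (young populations, small samples) starve the frame tests of
segregating sites; candidates then become untestable rather than being
reported at inflated confidence.
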