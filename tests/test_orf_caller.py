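import itertools

import numpy as np
import pytest
from scipy import stats

from snporf import io_formats as io
from snporf import orf_caller as oc
from snporf import transcriptome as tr

CFG = oc.CallerConfig()


def brute_force_orfs(seq, starts=("ATG",), min_len=9, policy="5prime"):
    """Independent enumeration of all (start, stop) in-frame pairs."""
    found = []
    for s in range(len(seq) - 2):
        if seq[s:s + 3] not in starts:
            continue
        for e in range(s + 3, len(seq) - 2 + 1, 3):
            codon = seq[e:e + 3]
            if codon in io.STOP_CODONS:
                if e + 3 - s >= min_len:
                    found.append((s, e + 3))
                break
    if policy == "5prime":
        best = {}
        for s, e in found:
            key = (e, s % 3)
            if key not in best or s < best[key][0]:
                best[key] = (s, e)
        found = sorted(best.values())
    return sorted(found)


class TestScanCandidates:
    def test_minimal_orf(self):
        cands = oc.scan_candidates("ATGAAATAA", CFG, min_length=9)
        assert [(c.start, c.end, c.start_codon) for c in cands] == \
               [(0, 9, "ATG")]

    def test_length_filter(self):
        assert oc.scan_candidates("ATGAAATAA", CFG, min_length=60) == []

    def test_five_prime_most_vs_all(self):
        seq = "ATGATGGGGTAA"
        five = oc.scan_candidates(seq, CFG, min_length=9)
        assert [(c.start, c.end) for c in five] == [(0, 12)]
        cfg_all = oc.CallerConfig(start_policy="all")
        both = oc.scan_candidates(seq, cfg_all, min_length=9)
        assert [(c.start, c.end) for c in both] == [(0, 12), (3, 12)]

    def test_near_cognate_starts(self):
        cfg = oc.CallerConfig(start_codons=("ATG", "CTG", "GTG", "TTG"))
        cands = oc.scan_candidates("CTGAAATGA", cfg, min_length=9)
        assert [(c.start, c.end, c.start_codon) for c in cands] == \
               [(0, 9, "CTG")]

    @pytest.mark.parametrize("policy", ["5prime", "all"])
    def test_matches_brute_force_on_random_sequences(self, policy, rng):
        cfg = oc.CallerConfig(start_policy=policy)
        for _ in range(40):
            seq = "".join(rng.choice(list("ACGT"), size=rng.integers(30, 200)))
            got = sorted(
                (c.start, c.end)
                for c in oc.scan_candidates(seq, cfg, min_length=9)
            )
            assert got == brute_force_orfs(seq, min_len=9, policy=policy), seq

    def test_candidate_invariants(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=500))
        for c in oc.scan_candidates(seq, CFG, min_length=9):
            assert c.length % 3 == 0
            assert seq[c.start:c.start + 3] == "ATG"
            assert seq[c.end - 3:c.end] in io.STOP_CODONS
            inner = [seq[p:p + 3] for p in range(c.start + 3, c.end - 3, 3)]
            assert not any(t in io.STOP_CODONS for t in inner)


class TestSplitFrames:
    def test_example(self):
        f0, f1, f2 = oc.split_frames([1, 2, 3, 4, 5, 6], 0, 6)
        assert (f0.tolist(), f1.tolist(), f2.tolist()) == \
               ([1, 4], [2, 5], [3, 6])

    def test_not_multiple_of_three(self):
        with pytest.raises(ValueError):
            oc.split_frames([1, 2, 3, 4], 0, 4)

    def test_frames_partition_the_slice(self, rng):
        values = rng.random(60)
        f0, f1, f2 = oc.split_frames(values, 6, 36)
        merged = sorted(np.concatenate([f0, f1, f2]).tolist())
        assert merged == sorted(values[6:36].tolist())


def textbook_pooled_t(a, b):
    """Independent pooled-variance one-sided p for mean(b) > mean(a)."""
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) \
        / (na + nb - 2)
    t = (np.mean(b) - np.mean(a)) / np.sqrt(sp2 * (1 / na + 1 / nb))
    return stats.t.sf(t, na + nb - 2)


class TestOneSidedT:
    def test_identical_samples_give_half(self):
        a = [0.1, 0.4, 0.2]
        assert oc.one_sided_t(a, a) == pytest.approx(0.5)

    def test_spec_example_detects_difference(self):
        p = oc.one_sided_t([0, 0, 0.01, 0], [0.02, 0.03, 0.02, 0.03])
        assert p < 0.01
        assert p == pytest.approx(
            textbook_pooled_t([0, 0, 0.01, 0], [0.02, 0.03, 0.02, 0.03]),
            abs=1e-12,
        )

    def test_single_value_rejected(self):
        with pytest.raises(oc.UntestableCandidate):
            oc.one_sided_t([1.0], [1.0, 2.0])

    @pytest.mark.parametrize(
        "a,b,expected",
        [([0, 0], [1, 1], 0.0), ([1, 1], [0, 0], 1.0), ([1, 1], [1, 1], 0.5)],
    )
    def test_zero_variance_rules(self, a, b, expected):
        assert oc.one_sided_t(a, b) == expected

    def test_matches_textbook_formula(self, rng):
        for _ in range(200):
            a = rng.normal(size=rng.integers(2, 30))
            b = rng.normal(size=rng.integers(2, 30))
            assert oc.one_sided_t(a, b) == pytest.approx(
                textbook_pooled_t(a, b), abs=1e-10
            )


class TestCombinePvalues:
    def test_all_ones(self):
        assert oc.combine_pvalues([1, 1], "fisher") == pytest.approx(1.0)

    def test_fisher_half_half(self):
        # X = -2(ln .5 + ln .5) = 2.7726; survival of chi2_4
        assert oc.combine_pvalues([0.5, 0.5], "fisher") == pytest.approx(
            stats.chi2.sf(2.772588722, 4), abs=1e-6
        )

    def test_monotone_in_input(self):
        grid = np.linspace(0.01, 0.99, 20)
        combined = [oc.combine_pvalues([p], "fisher") for p in grid]
        assert np.all(np.diff(combined) > 0)

    def test_brown_reduces_to_fisher_for_identity_correlation(self, rng):
        ps = rng.random(4)
        assert oc.combine_pvalues(ps, "brown", np.eye(4)) == pytest.approx(
            oc.combine_pvalues(ps, "fisher"), rel=1e-9
        )

    def test_brown_is_more_conservative_under_positive_correlation(self):
        corr = oc._pair_corr_matrix(2)
        ps = [0.01, 0.02, 0.03, 0.04]
        assert oc.combine_pvalues(ps, "brown", corr) > \
            oc.combine_pvalues(ps, "fisher")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            oc.combine_pvalues([], "fisher")


class TestDiversityFrameTest:
    def test_uniform_wobble_elevation_zero_variance_rule(self):
        v = np.zeros(60)
        v[2::3] = 0.01
        p0, p1 = oc.diversity_frame_test(v, CFG)
        assert (p0, p1) == (0.0, 0.0)

    def test_too_few_segregating_sites_untestable(self):
        v = np.zeros(60)
        v[2] = 0.5
        with pytest.raises(oc.UntestableCandidate, match="segregating"):
            oc.diversity_frame_test(v, CFG)

    def test_one_codon_untestable(self):
        with pytest.raises(oc.UntestableCandidate):
            oc.diversity_frame_test([0.1, 0.2, 0.3], CFG)

    def test_null_pvalues_roughly_uniform(self, rng):
        """Sparse exchangeable diversity: p_div_f0 has mean ~ 0.5 and fills
        the unit interval (full KS calibration lives in the acceptance
        suite)."""
        ps = []
        for _ in range(400):
            v = np.where(rng.random(150) < 0.1,
                         rng.exponential(0.1, 150), 0.0)
            if np.count_nonzero(v) < 2:
                continue
            ps.append(oc.diversity_frame_test(v, CFG)[0])
        assert 0.4 < np.mean(ps) < 0.6
        assert min(ps) < 0.1 and max(ps) > 0.9


class TestUsageValues:
    def test_uniform_table_constant(self):
        table = oc.CodonUsageTable.uniform()
        vals = oc.usage_values("ATGAAACCCGGG", 0, 12, 0, table)
        assert np.allclose(vals, 1 / 61)

    def test_skewed_table_frame0(self):
        table = oc.CodonUsageTable({"ATG": 0.5, "AAA": 0.5})
        vals = oc.usage_values("ATGAAATAA", 0, 9, 0, table)
        # stop triplet carries no usage information and is dropped
        assert vals.tolist() == [0.5, 0.5]

    @pytest.mark.parametrize("shift", [0, 1, 2])
    def test_shifted_reading_counts(self, shift, rng):
        # stop-free sequence so no triplet is dropped
        seq = "".join(rng.choice(["GCA", "GCC", "GCG", "GCT"], size=40))
        table = oc.CodonUsageTable.uniform()
        vals = oc.usage_values(seq, 0, len(seq), shift, table)
        assert len(vals) == (len(seq) - shift) // 3

    def test_n_triplets_dropped(self):
        table = oc.CodonUsageTable.uniform()
        vals = oc.usage_values("ATGANACCC", 0, 9, 0, table)
        assert len(vals) == 2  # ANA dropped

    def test_per_nucleotide_mode_triples_values(self):
        table = oc.CodonUsageTable.uniform()
        v1 = oc.usage_values("ATGAAACCC", 0, 9, 0, table)
        v3 = oc.usage_values("ATGAAACCC", 0, 9, 0, table, per_nucleotide=True)
        assert len(v3) == 3 * len(v1)


class TestUsageFrameTest:
    def test_uniform_table_is_neutral(self):
        table = oc.CodonUsageTable.uniform()
        cand = oc.CandidateOrf("t", 0, 30, "ATG")
        seq = "ATG" + "GCA" * 8 + "TAA"
        p1, p2 = oc.usage_frame_test(seq, cand, table)
        assert (p1, p2) == (0.5, 0.5)

    def test_preferred_codons_detected(self):
        freqs = {c: 0.001 for c in oc.SENSE_CODONS}
        for c in ("GCA", "GAA", "AAA", "ATG"):
            freqs[c] = 0.2
        table = oc.CodonUsageTable(freqs)
        seq = "ATG" + "GCAGAAAAA" * 10 + "TAA"
        cand = oc.CandidateOrf("t", 0, len(seq), "ATG")
        p1, p2 = oc.usage_frame_test(seq, cand, table)
        assert p1 < 0.01 and p2 < 0.01

    def test_invariant_to_codon_order(self, rng):
        freqs = {c: 1.0 + i for i, c in enumerate(oc.SENSE_CODONS)}
        table = oc.CodonUsageTable(freqs)
        codons = ["GCA", "GAA", "AAA", "CCT", "GGG"] * 6
        seq1 = "ATG" + "".join(codons) + "TAA"
        rng.shuffle(codons)
        seq2 = "ATG" + "".join(codons) + "TAA"
        c1 = oc.CandidateOrf("t", 0, len(seq1), "ATG")
        p_a = oc.usage_frame_test(seq1, c1, table)[0]
        # frame-0 values are permuted -> identical mean/variance -> same p
        v1 = oc.usage_values(seq1, 0, len(seq1), 0, table)
        v2 = oc.usage_values(seq2, 0, len(seq2), 0, table)
        assert sorted(v1.tolist()) == sorted(v2.tolist())


def _mini_transcript(seq, pi_by_pos):
    genome = io.GenomeSequence({"chr1": seq})
    tx = io.TranscriptAnnotation("t1", "g1", "chr1", "+")
    tx.exons = [io.GenomicInterval("chr1", 0, len(seq), "+")]
    tx.validate()
    ann = io.AnnotationSet()
    ann.add(tx)
    track = io.DiversityTrack()
    for pos, pi in pi_by_pos.items():
        track.set("chr1", pos, pi)
    return tr.build_transcripts(genome, ann), track


class TestTraining:
    def test_single_orf_codon_frequencies(self):
        seq = "ATGAAAAAGTAA"
        pis = {2: 0.3, 5: 0.2, 8: 0.25, 11: 0.28}
        models, track = _mini_transcript(seq, pis)
        cfg = oc.CallerConfig(training_min_length_nt=12, min_length_nt=12)
        table = oc.train_codon_usage(models, track, cfg)
        assert table.frequencies["ATG"] == pytest.approx(1 / 3)
        assert table.frequencies["AAA"] == pytest.approx(1 / 3)
        assert table.frequencies["AAG"] == pytest.approx(1 / 3)
        assert table.frequencies["TAA"] == 0.0
        assert table.n_orfs == 1 and table.n_codons == 3

    def test_no_preliminary_orfs_is_an_error(self):
        models, track = _mini_transcript("ATGAAAAAGTAA", {})
        with pytest.raises(oc.TrainingError):
            oc.train_codon_usage(models, track,
                                 oc.CallerConfig(training_min_length_nt=12))

    def test_pooling_across_orfs(self, small_sim, small_transcripts):
        """Trained frequencies equal pooled codon counts of planted CDSs to
        within sampling noise of the generator table."""
        params, _, _, manifest, track = small_sim
        table = oc.train_codon_usage(small_transcripts, track, CFG)
        gen = np.array([manifest.codon_table[c] for c in oc.SENSE_CODONS])
        got = np.array([table.frequencies[c] for c in oc.SENSE_CODONS])
        assert np.abs(gen - got).max() < 0.02


@pytest.fixture(scope="module")
def predictions(small_sim, small_transcripts):
    _, _, _, _, track = small_sim
    table = oc.train_codon_usage(small_transcripts, track, CFG)
    return oc.predict_orfs(small_transcripts, track, table, CFG)


class TestPredictOrfs:
    def test_planted_orfs_recovered_exactly(self, small_sim, predictions):
        _, _, _, manifest, _ = small_sim
        planted = {o.identity for o in manifest.orfs if o.kind == "CDS"}
        predicted = {r.identity for r in predictions}
        assert len(planted & predicted) / len(planted) >= 0.9

    def test_alpha_zero_predicts_nothing(self, small_sim, small_transcripts):
        _, _, _, _, track = small_sim
        table = oc.CodonUsageTable.uniform()
        cfg = oc.CallerConfig(alpha=0.0)
        assert oc.predict_orfs(small_transcripts, track, table, cfg) == []

    def test_prediction_sets_nest_in_alpha(self, small_sim, small_transcripts):
        _, _, _, _, track = small_sim
        table = oc.train_codon_usage(small_transcripts, track, CFG)
        sets = []
        for alpha in (0.001, 0.01, 0.05):
            cfg = oc.CallerConfig(alpha=alpha)
            rows = oc.predict_orfs(small_transcripts, track, table, cfg)
            sets.append({r.identity for r in rows})
        assert sets[0] <= sets[1] <= sets[2]

    def test_reported_pvalues_below_alpha(self, predictions):
        assert all(r.p_combined < CFG.alpha for r in predictions)

    def test_frame_identity_of_reported_orfs(self, small_sim, predictions):
        """Reported frame-2 positions are exactly the third bases of codons."""
        for r in predictions[:10]:
            assert (r.tx_end - r.tx_start) % 3 == 0
            assert r.orf_seq[:3] == r.start_codon
            assert r.orf_seq[-3:] in io.STOP_CODONS

    def test_deterministic(self, small_sim, small_transcripts):
        _, _, _, _, track = small_sim
        table = oc.train_codon_usage(small_transcripts, track, CFG)
        r1 = oc.predict_orfs(small_transcripts, track, table, CFG)
        r2 = oc.predict_orfs(small_transcripts, track, table, CFG)
        assert r1 == r2

    def test_duplicate_isoforms_collapse(self, small_sim):
        """Two identical isoforms of one gene yield a single ORF row."""
        _, genome, annotation, _, track = small_sim
        first_tid = sorted(annotation.transcripts)[0]
        base = annotation.transcripts[first_tid]
        dup = io.TranscriptAnnotation(
            base.transcript_id + "_copy", base.gene_id, base.seq_id,
            base.strand, exons=list(base.exons), cds=list(base.cds),
            biotype=base.biotype,
        )
        ann2 = io.AnnotationSet()
        ann2.add(base)
        ann2.add(dup)
        models = tr.build_transcripts(genome, ann2)
        cfg = oc.CallerConfig(training_min_length_nt=300)
        table = oc.CodonUsageTable.uniform()
        rows = oc.predict_orfs(models, track, table, cfg)
        idents = [r.identity for r in rows]
        assert len(idents) == len(set(idents))
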