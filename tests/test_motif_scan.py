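"""PWM log-odds, exact DP p-values against exhaustive enumeration, scanning."""

import itertools

import numpy as np
import pytest

from fusionomics.core_io import GenomicInterval
from fusionomics.motif_scan import (
    PWM,
    UNIFORM_BG,
    motif_score_pvalue,
    motif_set_association,
    peak_motif_proportion,
    pwm_log_odds,
    read_meme,
    read_pfm,
    reverse_complement,
    scan_sequence,
    score_distribution,
)

BASES = "ACGT"


def random_pwm(rng, width):
    counts = tuple(tuple(float(c) for c in rng.integers(1, 50, 4)) for _ in range(width))
    return PWM(f"rand_w{width}", counts, pseudocount=0.1)


def brute_force_sf(pwm, background, score):
    """Oracle: enumerate all 4^w words and sum background probabilities of
    those scoring >= score (continuous log-odds, no integerization)."""
    lods = pwm_log_odds(pwm, background)
    bg = np.asarray(background) / np.sum(background)
    total = 0.0
    for word in itertools.product(range(4), repeat=pwm.width):
        s = sum(lods[i, b] for i, b in enumerate(word))
        if s >= score:
            total += float(np.prod([bg[b] for b in word]))
    return total


class TestLogOdds:
    def test_uniform_pwm_uniform_background_is_zero(self):
        pwm = PWM("u", ((1.0, 1.0, 1.0, 1.0),) * 3, pseudocount=0.0)
        assert np.allclose(pwm_log_odds(pwm), 0.0)

    def test_certain_base_scores_two_bits(self):
        pwm = PWM("a", ((1.0, 0.0, 0.0, 0.0),), pseudocount=0.0)
        assert pwm_log_odds(pwm)[0, 0] == pytest.approx(2.0)

    def test_pseudocount_arithmetic(self):
        # counts (4,0,0,0), pseudocount 1, uniform bg: P(A) = 4.25/5 = 0.85
        pwm = PWM("p", ((4.0, 0.0, 0.0, 0.0),), pseudocount=1.0)
        assert pwm.probabilities()[0, 0] == pytest.approx(0.85)
        assert pwm_log_odds(pwm)[0, 0] == pytest.approx(np.log2(3.4), abs=1e-6)

    def test_zero_background_rejected(self):
        pwm = PWM("z", ((1.0, 1.0, 1.0, 1.0),))
        with pytest.raises(ValueError):
            pwm_log_odds(pwm, (0.5, 0.5, 0.0, 0.0))

    def test_invalid_pwm_rejected(self):
        with pytest.raises(ValueError):
            PWM("bad", ())
        with pytest.raises(ValueError):
            PWM("bad", ((1.0, -1.0, 0.0, 0.0),))


class TestScorePvalue:
    def test_max_score_pvalue_is_best_word_probability(self):
        pwm = PWM("w2", ((10.0, 1.0, 1.0, 1.0), (1.0, 10.0, 1.0, 1.0)), pseudocount=0.0)
        lods = pwm_log_odds(pwm)
        # query just below the max: integerization error is bounded by w * epsilon
        max_score = lods.max(axis=1).sum() - 2 * 1e-3
        assert motif_score_pvalue(pwm, max_score) == pytest.approx(0.25 * 0.25, abs=1e-9)

    def test_min_score_pvalue_is_one(self):
        pwm = PWM("w2", ((10.0, 1.0, 1.0, 1.0),) * 2)
        lods = pwm_log_odds(pwm)
        assert motif_score_pvalue(pwm, lods.min(axis=1).sum() - 1) == 1.0

    def test_distribution_sums_to_one(self):
        rng = np.random.default_rng(2)
        for width in (1, 3, 5):
            dist, _ = score_distribution(random_pwm(rng, width))
            assert sum(dist.values()) == pytest.approx(1.0, abs=1e-9)

    def test_dp_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(12)
        for _ in range(8):
            width = int(rng.integers(2, 5))
            pwm = random_pwm(rng, width)
            bg = rng.dirichlet([5.0] * 4)
            lods = pwm_log_odds(pwm, bg)
            for q in (0.2, 0.5, 0.9):
                s = float(lods.max(axis=1).sum()) * q
                got = motif_score_pvalue(pwm, s, bg)
                want = brute_force_sf(pwm, bg, s)
                # integerization can move words at the threshold boundary
                want_lo = brute_force_sf(pwm, bg, s + width * 1e-3)
                want_hi = brute_force_sf(pwm, bg, s - width * 1e-3)
                assert want_lo - 1e-9 <= got <= want_hi + 1e-9
                assert got == pytest.approx(want, abs=0.02)

    def test_pvalue_non_increasing_in_score(self):
        pwm = PWM("m", ((8.0, 2.0, 1.0, 1.0), (1.0, 9.0, 1.0, 1.0), (2.0, 2.0, 6.0, 2.0)))
        scores = np.linspace(-10, 6, 40)
        ps = [motif_score_pvalue(pwm, s) for s in scores]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))


class TestScanSequence:
    CONSENSUS_PWM = PWM(
        "cons", tuple(tuple(50.0 if b == c else 1.0 for b in BASES) for c in "ACGTAC")
    )

    def test_planted_consensus_found_at_offset(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("GT"), 30))
        seq = seq[:5] + "ACGTAC" + seq[11:]
        hits = scan_sequence(seq, self.CONSENSUS_PWM, p_threshold=1e-3)
        plus_hits = [h for h in hits if h.strand == "+"]
        assert [h.offset for h in plus_hits] == [5]

    def test_all_n_sequence_has_no_hits(self):
        assert scan_sequence("N" * 50, self.CONSENSUS_PWM, 0.5) == []

    def test_sequence_shorter_than_motif(self):
        assert scan_sequence("ACG", self.CONSENSUS_PWM) == []

    def test_palindrome_hits_both_strands_same_locus(self):
        pal = PWM("pal", tuple(tuple(50.0 if b == c else 1.0 for b in BASES)
                               for c in "ACGT"))  # ACGT is its own revcomp
        seq = "TTTTTACGTTTTTT"
        hits = scan_sequence(seq, pal, p_threshold=5e-3)
        offsets = {(h.offset, h.strand) for h in hits}
        assert (5, "+") in offsets and (5, "-") in offsets

    def test_strand_consistency_under_reverse_complement(self):
        rng = np.random.default_rng(33)
        pwm = random_pwm(rng, 5)
        seq = "".join(rng.choice(list(BASES), 200))
        fwd = scan_sequence(seq, pwm, p_threshold=0.05)
        rev = scan_sequence(reverse_complement(seq), pwm, p_threshold=0.05)
        # a +-strand hit at offset o maps to a --strand hit at L - w - o
        L, w = len(seq), pwm.width
        mapped = {(L - w - h.offset, {"+": "-", "-": "+"}[h.strand]) for h in rev}
        assert {(h.offset, h.strand) for h in fwd} == mapped


class TestPeakMotifProportion:
    def test_planted_proportion_exact_at_stringent_threshold(self):
        rng = np.random.default_rng(8)
        genome = {"chr1": "".join(rng.choice(list(BASES), 60_000))}
        pwm = PWM("strong", tuple(tuple(97.0 if b == c else 1.0 for b in BASES)
                                  for c in "ACATTCCA"))
        peaks = []
        seq = list(genome["chr1"])
        for i in range(100):
            start = i * 500
            peaks.append(GenomicInterval("chr1", start, start + 200))
            if i < 58:
                seq[start + 96 : start + 104] = list("ACATTCCA")
        genome["chr1"] = "".join(seq)
        pct, flags = peak_motif_proportion(peaks, genome, pwm, p_threshold=2e-5)
        assert sum(flags[:58]) == 58
        assert pct == pytest.approx(58.0, abs=3.0)

    def test_peak_beyond_contig_rejected(self):
        genome = {"chr1": "ACGT" * 10}
        pwm = PWM("m", ((1.0, 1.0, 1.0, 1.0),))
        with pytest.raises(ValueError, match="beyond contig"):
            peak_motif_proportion([GenomicInterval("chr1", 0, 100)], genome, pwm)

    def test_association_test_flags_enrichment(self):
        odds, p = motif_set_association([True] * 40 + [False] * 10,
                                        [True] * 5 + [False] * 45)
        assert odds > 1 and p < 1e-6


class TestReaders:
    def test_meme_round_trip_shape(self, tmp_path):
        path = tmp_path / "m.meme"
        path.write_text(
            "MEME version 4\n\nALPHABET= ACGT\n\n"
            "MOTIF TEST\nletter-probability matrix: alength= 4 w= 2\n"
            "0.7 0.1 0.1 0.1\n0.1 0.7 0.1 0.1\n"
        )
        (pwm,) = read_meme(path)
        assert pwm.name == "TEST" and pwm.width == 2
        assert pwm.consensus() == "AC"

    def test_pfm_rows_are_bases(self, tmp_path):
        path = tmp_path / "m.pfm"
        path.write_text("10\t1\n1\t10\n1\t1\n1\t1\n")
        pwm = read_pfm(path)
        assert pwm.width == 2 and pwm.consensus() == "AC"

    def test_pfm_wrong_row_count_rejected(self, tmp_path):
        path = tmp_path / "m.pfm"
        path.write_text("1\t1\n2\t2\n")
        with pytest.raises(ValueError):
            read_pfm(path)
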