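"""PWM construction, exact score distribution, and scanning.

The independent oracles here are (a) exhaustive enumeration of all 4**L
words for the score distribution, (b) a naive pure-Python sliding-window
scorer for hit lists, and (c) biopython's PSSM for log-odds construction.
"""

import itertools

import numpy as np
import pytest
from Bio import motifs as bio_motifs

import promotif.motifs as pm
from promotif import (PFM, ConfigurationError, InputError, calibrate_threshold,
                      consensus_pfm, count_hits, pfm_to_pwm, scan_promoter,
                      score_distribution)
from promotif.promoters import reverse_complement

from conftest import make_promoter, random_pfm

BASES = "ACGT"


def enumerate_distribution(pwm, granularity):
    """Oracle: discretized score distribution by brute force over 4**L words."""
    k = np.rint(pwm.log_odds / granularity).astype(np.int64)
    L = pwm.length
    dist = {}
    for word in itertools.product(range(4), repeat=L):
        score = sum(int(k[b, j]) for j, b in enumerate(word))
        prob = float(np.prod([pwm.background[b] for b in word]))
        dist[score] = dist.get(score, 0.0) + prob
    grid = np.array(sorted(dist)) * granularity
    probs = np.array([dist[s] for s in sorted(dist)])
    return grid, probs


def naive_scan(seq, pwm):
    """Oracle: per-window scoring with explicit loops, both strands."""
    L = pwm.length
    hits = []
    for offset in range(len(seq) - L + 1):
        window = seq[offset:offset + L]
        if any(b not in BASES for b in window):
            continue
        for strand, w in (("+", window), ("-", reverse_complement(window))):
            score = sum(pwm.log_odds[BASES.index(b), j] for j, b in enumerate(w))
            if score >= pwm.score_threshold:
                hits.append((offset, strand, score))
    return hits


class TestPfmToPwm:
    def test_uniform_column_gives_zero_log_odds(self):
        pfm = PFM("u", np.full((4, 3), 25.0))
        pwm = pfm_to_pwm(pfm, pseudocount=1.0)
        assert np.allclose(pwm.log_odds, 0.0)

    def test_hand_computed_column(self):
        # column (100,0,0,0), uniform background, pseudocount 1:
        # p_A = (100 + 0.25) / 101, log-odds = log2(p_A / 0.25)
        pfm = PFM("h", np.array([[100.0], [0.0], [0.0], [0.0]]))
        pwm = pfm_to_pwm(pfm, pseudocount=1.0)
        p_a = 100.25 / 101
        assert pwm.log_odds[0, 0] == pytest.approx(np.log2(p_a / 0.25))
        assert pwm.log_odds[1, 0] == pytest.approx(np.log2((0.25 / 101) / 0.25))

    def test_scale_invariance_without_pseudocount(self, rng):
        counts = rng.integers(1, 50, size=(4, 5)).astype(float)
        a = pfm_to_pwm(PFM("a", counts), pseudocount=0.0)
        b = pfm_to_pwm(PFM("b", counts * 2), pseudocount=0.0)
        assert np.allclose(a.log_odds, b.log_odds)

    def test_zero_column_with_zero_pseudocount_rejected(self):
        pfm = PFM("z", np.array([[1.0, 1.0], [0.0, 1.0], [0.0, 1.0], [0.0, 1.0]]))
        with pytest.raises(ConfigurationError):
            pfm_to_pwm(pfm, pseudocount=0.0)

    def test_matches_biopython_pssm(self, rng):
        """Cross-check against Bio.motifs with background-proportional
        pseudocounts — an independent implementation of the same formula."""
        counts = rng.integers(0, 30, size=(4, 6)).astype(float) + 1
        bg = np.array([0.3, 0.2, 0.2, 0.3])
        pc = 0.8
        pwm = pfm_to_pwm(PFM("x", counts), background=bg, pseudocount=pc)
        m = bio_motifs.Motif(counts={b: counts[i].tolist()
                                     for i, b in enumerate(BASES)})
        m.pseudocounts = {b: pc * bg[i] for i, b in enumerate(BASES)}
        m.background = {b: bg[i] for i, b in enumerate(BASES)}
        ref = np.array([list(m.pssm[b]) for b in BASES])
        assert np.allclose(pwm.log_odds, ref)


class TestScoreDistribution:
    @pytest.mark.parametrize("length", [1, 2, 3, 4, 5, 6])
    def test_dp_equals_enumeration(self, rng, length):
        pfm = random_pfm(rng, length)
        bg = np.array([0.2, 0.3, 0.3, 0.2])
        pwm = pfm_to_pwm(pfm, background=bg)
        grid, probs = score_distribution(pwm, granularity=1e-4)
        egrid, eprobs = enumerate_distribution(pwm, 1e-4)
        # compare as distributions over the discrete grid (DP grid may hold
        # zero-probability cells between achievable scores)
        dp = {round(g / 1e-4): p for g, p in zip(grid, probs) if p > 0}
        en = {round(g / 1e-4): p for g, p in zip(egrid, eprobs)}
        assert set(dp) == set(en)
        for key in en:
            assert dp[key] == pytest.approx(en[key], abs=1e-12)

    def test_probabilities_sum_to_one(self, rng):
        pwm = pfm_to_pwm(random_pfm(rng, 7))
        _, probs = score_distribution(pwm)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_invalid_granularity(self, rng):
        pwm = pfm_to_pwm(random_pfm(rng, 3))
        with pytest.raises(ConfigurationError):
            score_distribution(pwm, granularity=0)


class TestCalibrateThreshold:
    def test_alpha_one_gives_min_score(self, rng):
        pwm = pfm_to_pwm(random_pfm(rng, 4))
        thr = calibrate_threshold(pwm, alpha=1.0, granularity=1e-4)
        assert thr == pytest.approx(pwm.min_score, abs=pwm.length * 1e-4)

    def test_threshold_monotone_in_alpha(self, rng):
        pwm = pfm_to_pwm(random_pfm(rng, 5))
        alphas = [1.0, 0.5, 0.1, 1e-2, 1e-3]
        thresholds = [calibrate_threshold(pwm, a) for a in alphas]
        assert thresholds == sorted(thresholds)

    def test_tail_at_threshold_respects_alpha(self, rng):
        pwm = pfm_to_pwm(random_pfm(rng, 4))
        alpha = 0.05
        g = 1e-4
        thr = calibrate_threshold(pwm, alpha=alpha, granularity=g)
        grid, probs = score_distribution(pwm, granularity=g)
        # undo the rounding-slack adjustment to recover the DP grid point
        tail = probs[grid >= thr + g * pwm.length / 2 - 1e-12].sum()
        assert tail <= alpha + 1e-12

    def test_unreachable_alpha_clamps_to_max(self):
        pwm = pfm_to_pwm(consensus_pfm("AC", concentration=0.9))
        thr = calibrate_threshold(pwm, alpha=1e-12, granularity=1e-4)
        assert thr == pytest.approx(pwm.max_score, abs=2e-4)


class TestScan:
    def test_short_promoter_yields_no_hits(self, sharp_pfm):
        pwm = pfm_to_pwm(sharp_pfm).calibrated(0.01)
        assert scan_promoter(make_promoter("ACG"), pwm) == []

    def test_palindromic_consensus_hits_both_strands(self):
        # ACGT is its own reverse complement: one window, two hits
        pwm = pfm_to_pwm(consensus_pfm("ACGT", concentration=0.99)).calibrated(1e-3)
        hits = scan_promoter(make_promoter("TTACGTTT"), pwm)
        assert [(h.offset, h.strand) for h in hits] == [(2, "+"), (2, "-")]

    def test_strand_symmetry(self, rng, sharp_pfm):
        pwm = pfm_to_pwm(sharp_pfm).calibrated(0.02)
        seq = "".join(rng.choice(list(BASES), size=80)) + "ACGTTGCA" + \
              "".join(rng.choice(list(BASES), size=40))
        fwd = scan_promoter(make_promoter(seq), pwm)
        rev = scan_promoter(make_promoter(reverse_complement(seq)), pwm)
        flipped = sorted((len(seq) - h.offset - pwm.length,
                          "+" if h.strand == "-" else "-") for h in rev)
        assert sorted((h.offset, h.strand) for h in fwd) == flipped

    def test_n_windows_skipped(self, sharp_pfm):
        pwm = pfm_to_pwm(sharp_pfm).calibrated(1e-3)
        hits = scan_promoter(make_promoter("AANGTTGCAACGTTGCA"), pwm)
        # windows at offsets 0-2 cover the N and must be skipped on both
        # strands; the N-free consensus occurrence at offset 9 is called
        assert all(h.offset > 2 for h in hits)
        assert any(h.offset == 9 and h.strand == "+" for h in hits)

    def test_matches_naive_scanner(self, rng):
        for _ in range(10):
            pwm = pfm_to_pwm(random_pfm(rng, int(rng.integers(3, 9)))).calibrated(0.05)
            seq = "".join(rng.choice(list("ACGTN"), size=60,
                                     p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            got = [(h.offset, h.strand, h.score)
                   for h in scan_promoter(make_promoter(seq), pwm)]
            expected = naive_scan(seq, pwm)
            assert [(o, s) for o, s, _ in got] == [(o, s) for o, s, _ in expected]
            assert np.allclose([s for *_, s in got], [s for *_, s in expected])

    def test_uncalibrated_pwm_rejected(self, sharp_pfm):
        with pytest.raises(ConfigurationError):
            scan_promoter(make_promoter("ACGTACGT"), pfm_to_pwm(sharp_pfm))


class TestCountHits:
    def test_counts_include_zero_hit_genes(self, sharp_pfm):
        pwm = pfm_to_pwm(sharp_pfm).calibrated(1e-3)
        proms = [make_promoter("ACGTTGCA" + "A" * 20, gene_id="g1"),
                 make_promoter("T" * 28, gene_id="g2")]
        counts = count_hits(proms, pwm)
        assert counts["g1"] >= 1 and counts["g2"] == 0

    def test_order_invariance(self, rng, sharp_pfm):
        pwm = pfm_to_pwm(sharp_pfm).calibrated(0.02)
        proms = [make_promoter("".join(rng.choice(list(BASES), size=50)),
                               gene_id=f"g{i}") for i in range(10)]
        a = count_hits(proms, pwm).sort_index()
        b = count_hits(proms[::-1], pwm).sort_index()
        assert a.equals(b)

    def test_duplicate_gene_ids_rejected(self, sharp_pfm):
        pwm = pfm_to_pwm(sharp_pfm).calibrated(0.02)
        proms = [make_promoter("ACGT" * 10, gene_id="g1")] * 2
        with pytest.raises(InputError):
            count_hits(proms, pwm)

    def test_background_false_hit_rate(self, rng):
        """Total hit count on background-only promoters matches the analytic
        expectation 2 * (scannable windows) * alpha within 4 Poisson sd."""
        alpha = 1e-3
        pwm = pfm_to_pwm(random_pfm(rng, 8)).calibrated(alpha)
        grid, probs = score_distribution(pwm, granularity=pwm.granularity)
        realized = probs[grid >= pwm.score_threshold - 1e-12].sum()
        plen, n = 200, 400
        proms = [make_promoter("".join(rng.choice(list(BASES), size=plen)),
                               gene_id=f"g{i}") for i in range(n)]
        total = count_hits(proms, pwm).sum()
        expected = 2 * n * (plen - pwm.length + 1) * realized
        assert abs(total - expected) <= 4 * np.sqrt(expected)


class TestMotifIO:
    def test_jaspar_round_trip(self, tmp_path, rng):
        pfms = [random_pfm(rng, 5), consensus_pfm("ACGTAC", motif_id="cons6")]
        path = tmp_path / "motifs.jaspar"
        pm.write_jaspar(pfms, path)
        back = pm.read_jaspar(path)
        assert [p.motif_id for p in back] == [p.motif_id for p in pfms]
        for a, b in zip(pfms, back):
            assert np.allclose(a.counts, b.counts)

    def test_plain_matrix_dialect(self, tmp_path):
        path = tmp_path / "m.txt"
        path.write_text("1 2 3\n4 5 6\n7 8 9\n1 1 1\n")
        pfm = pm.read_plain_matrix(path, "plain")
        assert pfm.counts.shape == (4, 3)
        assert pfm.counts[2, 1] == 8

    def test_invalid_pfm_rejected(self):
        with pytest.raises(InputError):
            PFM("bad", np.zeros((4, 2)))
        with pytest.raises(InputError):
            PFM("neg", -np.ones((4, 2)))
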