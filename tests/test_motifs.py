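import numpy as np
import pytest
from scipy import stats

from cistrokit.intervals import GenomicInterval, PeakSet, overlap
from cistrokit.motifs import (
    PWM,
    MotifError,
    binomial_enrichment,
    denovo_kmer_enrichment,
    pwm_from_kmer_hits,
    pwm_scores,
    reverse_complement,
    sample_background_regions,
    scan_pwm,
)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestPWM:
    def test_rows_must_sum_to_one(self):
        with pytest.raises(MotifError):
            PWM(np.full((4, 4), 0.3))

    def test_from_consensus_peaks_at_consensus(self):
        pwm = PWM.from_consensus("ACGT", 0.85)
        assert pwm.probs[0, 0] == pytest.approx(0.85)
        assert pwm.probs.sum(axis=1) == pytest.approx(1.0)


class TestScanPWM:
    def test_degenerate_pwm_hits_literal_matches_only(self):
        pwm = PWM.from_consensus("ACGTAC", match_prob=1 - 3e-12)
        seqs = ["TTACGTACTT", "TTTTTTTTTT", "TT" + reverse_complement("ACGTAC") + "TT"]
        hits = scan_pwm(seqs, pwm, score_threshold=10.0)
        assert [h > 0 for h in hits] == [True, False, True]

    def test_minus_strand_instance_detected(self):
        pwm = PWM.from_consensus("AGGTCAGG", match_prob=0.97)
        inst = reverse_complement("AGGTCAGG")
        rng = np.random.default_rng(0)
        seq = random_seq(rng, 40) + inst + random_seq(rng, 40)
        assert scan_pwm([seq], pwm, score_threshold=12.0)[0] > 0

    def test_scores_match_direct_sum_oracle(self):
        rng = np.random.default_rng(1)
        probs = rng.dirichlet(np.ones(4), size=6)
        pwm = PWM(probs)
        seq = random_seq(rng, 50)
        fwd, rev = pwm_scores(seq, pwm)
        for i in range(len(seq) - 6 + 1):
            expected = sum(
                np.log2(probs[j, "ACGT".index(seq[i + j])] / 0.25) for j in range(6)
            )
            assert fwd[i] == pytest.approx(expected, abs=1e-9)
        rc = reverse_complement(seq)
        for i in range(len(rc) - 6 + 1):
            expected = sum(
                np.log2(probs[j, "ACGT".index(rc[i + j])] / 0.25) for j in range(6)
            )
            assert rev[i] == pytest.approx(expected, abs=1e-9)

    def test_n_bases_never_score(self):
        pwm = PWM.from_consensus("AAAA", 0.9)
        assert scan_pwm(["NNNNNN"], pwm, score_threshold=-100.0)[0] == 0

    def test_strand_symmetry(self):
        rng = np.random.default_rng(2)
        pwm = PWM.from_consensus("ACGTACGT", 0.9)
        seqs = [random_seq(rng, 100) for _ in range(20)]
        rc = [reverse_complement(s) for s in seqs]
        assert scan_pwm(seqs, pwm, 5.0) == scan_pwm(rc, pwm, 5.0)


class TestBackgroundSampling:
    def test_contract_on_toy_genome(self):
        genome = {"chr1": "ACGT" * 2500}
        regions = sample_background_regions(genome, n=10, width=200, seed=0)
        assert len(regions) == 10
        assert all(iv.width == 200 for iv in regions)

    def test_deterministic_given_seed(self):
        genome = {"chr1": "ACGT" * 2500}
        a = sample_background_regions(genome, n=20, width=100, seed=5)
        b = sample_background_regions(genome, n=20, width=100, seed=5)
        assert [iv.sort_key() for iv in a] == [iv.sort_key() for iv in b]

    def test_never_overlaps_exclusion_set(self):
        rng = np.random.default_rng(3)
        genome = {"chr1": "".join(rng.choice(list("ACGT"), size=40_000))}
        exclude = PeakSet(
            [GenomicInterval("chr1", s, s + 1000) for s in range(0, 40_000, 2000)]
        )
        regions = sample_background_regions(
            genome, n=50, width=150, exclude=exclude, seed=7
        )
        assert overlap(regions, exclude).n_a_hit == 0

    def test_infeasible_request_reports_achieved_count(self):
        genome = {"chr1": "ACGT" * 100}
        exclude = PeakSet([GenomicInterval("chr1", 0, 400)])
        with pytest.raises(MotifError, match="achieved"):
            sample_background_regions(
                genome, n=10, width=200, exclude=exclude, seed=0,
                max_tries_per_region=5,
            )


class TestBinomialEnrichment:
    def test_zero_hits_give_unity(self):
        assert binomial_enrichment(0, 100, 50, 1000) == 1.0

    def test_full_hits_closed_form(self):
        p0 = 500 / 50_000
        assert binomial_enrichment(10, 10, 500, 50_000) == pytest.approx(p0**10)

    def test_matches_exact_tail_sum(self):
        p0 = 500 / 50_000
        oracle = sum(
            stats.binom.pmf(k, 100, p0) for k in range(10, 101)
        )
        assert binomial_enrichment(10, 100, 500, 50_000) == pytest.approx(
            oracle, abs=1e-12
        )

    def test_zero_background_rate_floored(self):
        p = binomial_enrichment(3, 100, 0, 1000)
        assert 0 < p < 1

    def test_monotone_in_target_hits(self):
        ps = [binomial_enrichment(k, 100, 500, 50_000) for k in range(0, 50, 5)]
        assert ps == sorted(ps, reverse=True)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            binomial_enrichment(11, 10, 0, 100)


class TestDenovo:
    def test_planted_kmer_ranks_first(self):
        rng = np.random.default_rng(4)
        motif = "ACGTTAGC"
        targets = []
        for i in range(120):
            s = random_seq(rng, 100)
            if i < 80:
                off = int(rng.integers(0, 92))
                s = s[:off] + motif + s[off + 8 :]
            targets.append(s)
        background = [random_seq(rng, 100) for _ in range(600)]
        ranked = denovo_kmer_enrichment(targets, background, k=8, top=5)
        top = ranked[0].consensus
        d = min(
            sum(a != b for a, b in zip(top, motif)),
            sum(a != b for a, b in zip(top, reverse_complement(motif))),
        )
        assert d <= 1

    def test_one_mismatch_neighbors_collapsed(self):
        rng = np.random.default_rng(5)
        motif = "ACGTTAGC"
        targets = []
        for _ in range(60):
            s = random_seq(rng, 80)
            targets.append(s[:30] + motif + s[38:])
        background = [random_seq(rng, 80) for _ in range(300)]
        ranked = denovo_kmer_enrichment(targets, background, k=8, top=10)
        for i, a in enumerate(ranked):
            for b in ranked[i + 1 :]:
                d = min(
                    sum(x != y for x, y in zip(a.consensus, b.consensus)),
                    sum(
                        x != y
                        for x, y in zip(
                            a.consensus, reverse_complement(b.consensus)
                        )
                    ),
                )
                assert d > 1

    def test_k_beyond_enumeration_bound_rejected(self):
        with pytest.raises(MotifError, match="bound"):
            denovo_kmer_enrichment(["ACGTACGTACGTACGT"], ["ACGTACGTACGTACGT"], k=13)

    def test_short_target_rejected(self):
        with pytest.raises(MotifError):
            denovo_kmer_enrichment(["ACG"], ["ACGTACGT"], k=8)

    def test_null_runs_rarely_reach_significance(self):
        """Target and background drawn from the same distribution: the top
        Bonferroni-adjusted p should rarely cross 0.05."""
        rng = np.random.default_rng(6)
        sig = 0
        n_runs = 20
        for _ in range(n_runs):
            targets = [random_seq(rng, 100) for _ in range(40)]
            background = [random_seq(rng, 100) for _ in range(400)]
            ranked = denovo_kmer_enrichment(targets, background, k=8, top=1)
            if ranked and ranked[0].p * ranked[0].n_candidates < 0.05:
                sig += 1
        assert sig <= 2


class TestPWMFromHits:
    def test_identical_hits_recover_consensus(self):
        motif = "ACGTTAGC"
        rng = np.random.default_rng(7)
        targets = [
            random_seq(rng, 20) + motif + random_seq(rng, 20) for _ in range(30)
        ]
        ranked = denovo_kmer_enrichment(
            targets, [random_seq(rng, 48) for _ in range(100)], k=8, top=1
        )
        pwm = pwm_from_kmer_hits(ranked[0], targets)
        assert pwm.probs.sum(axis=1) == pytest.approx(1.0)
        called = "".join("ACGT"[i] for i in pwm.probs.argmax(axis=1))
        assert called in (motif, reverse_complement(motif))

    def test_degenerate_position_recovered(self):
        rng = np.random.default_rng(8)
        targets = []
        for _ in range(200):
            base = "A" if rng.random() < 0.5 else "G"
            inst = "ACGTT" + base + "GC"
            targets.append(random_seq(rng, 20) + inst + random_seq(rng, 20))
        ranked = denovo_kmer_enrichment(
            targets, [random_seq(rng, 48) for _ in range(200)], k=8, top=3
        )
        pwm = pwm_from_kmer_hits(ranked[0], targets)
        # position 5 (0-based) splits ~50/50 between A and G
        pos = 5
        if ranked[0].consensus not in [m[:8] for m in [t[20:28] for t in targets]]:
            # consensus may be the reverse complement; flip the position
            pos = 8 - 1 - 5
        a, g = pwm.probs[pos, 0], pwm.probs[pos, 2]
        c, t = pwm.probs[pos, 1], pwm.probs[pos, 3]
        pair = sorted([a + g, c + t])
        assert max(a + g, c + t) > 0.7  # the A/G split dominates either strand
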