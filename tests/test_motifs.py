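"""Motif models: background estimation, log-odds, exact p-values, scanning."""

from itertools import product

import numpy as np
import pytest

from temotif.motifs import (
    BackgroundModel,
    PWM,
    ScoreMatrix,
    background_from_fasta,
    encode,
    log_odds,
    revcomp,
    sample_high_scoring_word,
    scan_genome,
    score_pvalue_table,
)

UNIFORM = BackgroundModel.uniform()


def random_pwm(rng, width, motif_id="m"):
    return PWM(motif_id, motif_id, rng.dirichlet(np.ones(4), size=width))


def enumerate_words(width):
    return np.array(list(product(range(4), repeat=width)), dtype=np.int64)


class TestPWMValidation:
    def test_rows_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            PWM("m", "t", [[0.5, 0.5, 0.1, 0.1]])

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            PWM("m", "t", [[1.2, -0.2, 0.0, 0.0]])


class TestBackground:
    def test_symmetric_composition(self):
        bg = background_from_fasta({"c": "ACGT" * 1000}, smoothing=0.0)
        assert np.allclose(bg.freqs, 0.25)

    def test_strand_pooling_forces_at_symmetry(self):
        bg = background_from_fasta({"c": "A" * 4000})
        assert bg.freqs[0] == pytest.approx(bg.freqs[3])
        assert bg.freqs[0] == pytest.approx(0.5, abs=1e-3)

    def test_counting_oracle_60pct_at(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), p=[0.3, 0.2, 0.2, 0.3], size=50_000))
        bg = background_from_fasta({"c": seq}, smoothing=0.0)
        counts = np.array([seq.count(b) for b in "ACGT"], dtype=float)
        pooled = counts + counts[::-1]
        assert np.allclose(bg.freqs, pooled / pooled.sum())

    def test_all_n_rejected(self):
        with pytest.raises(ValueError, match="unambiguous"):
            background_from_fasta({"c": "NNNN"})


class TestLogOdds:
    def test_uniform_pwm_uniform_bg_scores_zero(self):
        pwm = PWM("m", "t", np.full((3, 4), 0.25))
        sm = log_odds(pwm, UNIFORM)
        assert np.allclose(sm.scores, 0.0)

    def test_certain_base_two_bits(self):
        mat = np.zeros((3, 4))
        mat[:, 0] = 1.0
        sm = log_odds(PWM("m", "t", mat), UNIFORM, pseudocount=0.0)
        assert np.allclose(sm.scores[:, 0], 2.0)
        assert sm.real_score_words(np.zeros((1, 3), dtype=np.int64))[0] == pytest.approx(6.0)

    def test_formula_recomputation(self):
        rng = np.random.default_rng(1)
        pwm = random_pwm(rng, 4)
        bg = BackgroundModel([0.4, 0.1, 0.1, 0.4])
        sm = log_odds(pwm, bg, pseudocount=0.1)
        expect = np.log2(
            (pwm.matrix + 0.1 * bg.freqs) / 1.1 / bg.freqs
        )
        assert np.allclose(sm.scores, expect)


class TestPvalueTable:
    def test_unique_best_word_tail(self):
        mat = np.zeros((2, 4))
        mat[:, 1] = 1.0
        sm = log_odds(PWM("m", "t", mat), UNIFORM)
        assert float(sm.pvalue_of_int(sm.max_int_score)) == pytest.approx(1 / 16)

    def test_full_mass_at_minus_infinity(self):
        sm = log_odds(random_pwm(np.random.default_rng(2), 5), UNIFORM)
        assert float(sm.pvalue_of_int(0)) == pytest.approx(1.0)
        assert float(sm.pvalue_of_int(-5)) == 1.0

    @pytest.mark.parametrize("bg", [UNIFORM, BackgroundModel([0.35, 0.15, 0.15, 0.35])])
    def test_dp_equals_enumeration_width5(self, bg):
        rng = np.random.default_rng(3)
        pwm = random_pwm(rng, 5)
        sm = log_odds(pwm, bg)
        score_pvalue_table(sm)
        words = enumerate_words(5)
        ints = sm.score_words(words)
        probs = np.prod(bg.freqs[words], axis=1)
        assert probs.sum() == pytest.approx(1.0)
        for t in np.unique(ints):
            assert float(sm.pvalue_of_int(int(t))) == pytest.approx(
                probs[ints >= t].sum(), rel=1e-10
            )

    def test_tail_monotone_non_increasing(self):
        sm = log_odds(random_pwm(np.random.default_rng(4), 7), UNIFORM)
        tail = sm.build_pvalue_table()
        assert (np.diff(tail) <= 1e-15).all()


class TestScan:
    def _planted(self, rng, width=8, n_plant=10, length=20_000):
        seq = rng.choice(list("ACGT"), size=length)
        mat = np.full((width, 4), 0.02)
        mat[np.arange(width), rng.integers(0, 4, width)] = 0.94
        pwm = PWM("m", "t", mat)
        genome0 = {"chr1": "".join(seq)}
        sm = log_odds(pwm, background_from_fasta(genome0))
        word = sample_high_scoring_word(pwm, sm, rng, 1e-6)
        starts = sorted(rng.choice(length // 20 - 2, size=n_plant, replace=False) * 20)
        for s in starts:
            seq[s : s + width] = list(word)
        return {"chr1": "".join(seq)}, sm, starts, width

    def test_planted_sites_recovered(self):
        rng = np.random.default_rng(5)
        genome, sm, starts, w = self._planted(rng)
        hits = scan_genome(genome, sm, 1e-4)
        got = {h.interval.start for h in hits}
        assert set(starts) <= got

    def test_strand_symmetry(self):
        rng = np.random.default_rng(6)
        genome, sm, _, w = self._planted(rng, n_plant=4, length=5000)
        hits = scan_genome(genome, sm, 1e-3)
        rc = {"chr1": revcomp(genome["chr1"])}
        hits_rc = scan_genome(rc, sm, 1e-3)
        L = len(genome["chr1"])
        fwd = sorted((h.interval.start, round(h.pvalue, 12)) for h in hits)
        mir = sorted((L - h.interval.end, round(h.pvalue, 12)) for h in hits_rc)
        assert fwd == mir

    def test_threshold_monotone_subset(self):
        rng = np.random.default_rng(7)
        genome, sm, _, w = self._planted(rng, n_plant=5, length=10_000)
        loose = {(h.interval.start, h.strand) for h in scan_genome(genome, sm, 1e-3)}
        tight = {(h.interval.start, h.strand) for h in scan_genome(genome, sm, 1e-5)}
        assert tight <= loose

    def test_n_windows_skipped(self):
        rng = np.random.default_rng(12)
        seq = "".join(rng.choice(list("ACGT"), 60)) + "N" + "".join(rng.choice(list("ACGT"), 60))
        sm = log_odds(random_pwm(rng, 4), UNIFORM)
        hits = scan_genome({"c": seq}, sm, 0.5)
        assert len(hits) > 0
        assert all("N" not in seq[h.interval.start : h.interval.end] for h in hits)

    def test_short_chromosome_skipped(self):
        sm = log_odds(random_pwm(np.random.default_rng(8), 6), UNIFORM)
        assert scan_genome({"c": "ACG"}, sm, 1e-2) == []

    def test_false_positive_rate_matches_attained_tail(self):
        """Chance-hit count is binomially compatible with the attained tail
        probability at the threshold cutoff."""
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGT"), p=[0.3, 0.2, 0.2, 0.3], size=200_000))
        genome = {"c": seq}
        pwm = random_pwm(rng, 9, "fp")
        sm = log_odds(pwm, background_from_fasta(genome))
        _, attained = sm.cutoff_for_pvalue(1e-3)
        hits = scan_genome(genome, sm, 1e-3, max_strand=False)
        trials = 2 * (len(seq) - 8)
        expect = attained * trials
        assert abs(len(hits) - expect) < 5 * np.sqrt(max(expect, 1.0))

    def test_max_strand_keeps_better_scoring_strand(self):
        rng = np.random.default_rng(10)
        genome, sm, _, w = self._planted(rng, n_plant=3, length=6000)
        both = scan_genome(genome, sm, 1e-3, max_strand=False)
        collapsed = scan_genome(genome, sm, 1e-3, max_strand=True)
        by_start = {}
        for h in both:
            by_start.setdefault(h.interval.start, []).append(h)
        for h in collapsed:
            group = by_start[h.interval.start]
            assert h.score == pytest.approx(max(g.score for g in group), abs=1e-9)
        starts = [h.interval.start for h in collapsed]
        assert len(starts) == len(set(starts))


def test_sampled_words_pass_scan_threshold():
    rng = np.random.default_rng(11)
    mat = np.full((10, 4), 0.02)
    mat[np.arange(10), rng.integers(0, 4, 10)] = 0.94
    pwm = PWM("m", "t", mat)
    sm = log_odds(pwm, BackgroundModel([0.3, 0.2, 0.2, 0.3]))
    for _ in range(20):
        word = sample_high_scoring_word(pwm, sm, rng, 1e-6)
        ints = sm.score_words(encode(word)[None, :])
        assert float(sm.pvalue_of_int(int(ints[0]))) <= 1e-6
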