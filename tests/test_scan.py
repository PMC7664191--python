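import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from enhmotif.scan import (
    PWM,
    SCORE_EPS,
    apply_conservation,
    information_content,
    reverse_complement,
    scan_sequence,
    site_pvalue,
)
from conftest import indicator_pwm, random_dirichlet_pwm, soft_pwm


def enum_pvalue(pwm: PWM, score: float) -> float:
    """Brute-force oracle: enumerate all 4^L words on the same score grid."""
    probs = np.maximum(pwm.probs, 1e-4)
    q = np.rint(np.log2(probs / pwm.background) / SCORE_EPS).astype(np.int64)
    qscore = int(np.rint(score / SCORE_EPS))
    total = 0.0
    L = pwm.length
    for word in itertools.product(range(4), repeat=L):
        if q[np.arange(L), word].sum() >= qscore:
            total += float(np.prod(pwm.background[list(word)]))
    return total


class TestInformationContent:
    def test_uniform_columns_carry_zero_bits(self):
        pwm = PWM("u", np.full((7, 4), 0.25))
        assert information_content(pwm) == pytest.approx(0.0)

    def test_deterministic_columns_carry_two_bits_each(self):
        pwm = indicator_pwm("ACGTA")
        assert information_content(pwm) == pytest.approx(10.0)  # boundary of IC>=10

    def test_half_half_column_carries_one_bit(self):
        pwm = PWM("h", np.array([[0.5, 0.5, 0.0, 0.0]]))
        assert information_content(pwm) == pytest.approx(1.0)


class TestSitePvalue:
    def test_minimum_score_has_pvalue_one(self, rng):
        pwm = random_dirichlet_pwm(rng, 5)
        assert site_pvalue(pwm, pwm.score_min) == pytest.approx(1.0)

    def test_indicator_maximum_is_quarter_to_the_length(self):
        pwm = indicator_pwm("ACGTAC")
        assert site_pvalue(pwm, pwm.score_max) == pytest.approx(0.25 ** 6)

    @pytest.mark.parametrize("length", [3, 5, 8])
    def test_dp_matches_enumeration(self, length, rng):
        pwm = random_dirichlet_pwm(rng, length)
        lodq = pwm._scanner.q
        for _ in range(12):
            word = rng.integers(0, 4, size=length)
            score = float(lodq[np.arange(length), word].sum()) * SCORE_EPS
            assert site_pvalue(pwm, score) == pytest.approx(
                enum_pvalue(pwm, score), abs=1e-6
            )

    def test_dp_matches_enumeration_nonuniform_background(self, rng):
        bg = np.array([0.4, 0.1, 0.1, 0.4])
        pwm = PWM("nb", rng.dirichlet(np.full(4, 0.5), size=4), background=bg)
        lodq = pwm._scanner.q
        for _ in range(8):
            word = rng.integers(0, 4, size=4)
            score = float(lodq[np.arange(4), word].sum()) * SCORE_EPS
            assert site_pvalue(pwm, score) == pytest.approx(
                enum_pvalue(pwm, score), abs=1e-6
            )

    def test_length3_best_score_counts_qualifying_words(self, rng):
        """P(best score) equals the fraction of 3-mers attaining it."""
        pwm = random_dirichlet_pwm(rng, 3)
        p = site_pvalue(pwm, pwm.score_max)
        lodq = pwm._scanner.q
        n_best = sum(
            lodq[np.arange(3), w].sum() >= pwm._scanner.qmax
            for w in itertools.product(range(4), repeat=3)
        )
        assert p == pytest.approx(n_best / 64)

    def test_monotone_nonincreasing_in_score(self, rng):
        pwm = random_dirichlet_pwm(rng, 6)
        scores = np.linspace(pwm.score_min, pwm.score_max, 40)
        ps = [site_pvalue(pwm, s) for s in scores]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_out_of_range_score_clamped_with_warning(self, caplog):
        pwm = indicator_pwm("ACG")
        with caplog.at_level("WARNING"):
            assert site_pvalue(pwm, pwm.score_max + 5.0) == pytest.approx(0.25 ** 3)
        assert "clamping" in caplog.text


class TestScanSequence:
    def test_consensus_word_scores_relative_one(self):
        pwm = indicator_pwm("ACGTA")
        sites = [s for s in scan_sequence(pwm, "TTACGTATT", p_max=1.0) if s.strand == "+"]
        assert len(sites) == 1
        assert sites[0].offset == 2
        assert sites[0].rel_score == pytest.approx(1.0)

    def test_reverse_complement_word_found_on_minus_strand(self):
        pwm = indicator_pwm("AACGT")
        seq = "GG" + reverse_complement("AACGT") + "GG"
        sites = scan_sequence(pwm, seq, match_min=0.9, p_max=1.0)
        assert [(s.offset, s.strand) for s in sites] == [(2, "-")]
        assert sites[0].rel_score == pytest.approx(1.0)

    def test_strand_reflection_symmetry(self, rng):
        """Scanning S and revcomp(S) gives mirror-image site sets."""
        pwm = soft_pwm("ACGTACGT", dominant=0.7)
        seq = "".join(rng.choice(list("ACGT"), size=60))
        fwd = scan_sequence(pwm, seq, match_min=0.5, p_max=1.0)
        rev = scan_sequence(pwm, reverse_complement(seq), match_min=0.5, p_max=1.0)
        L = pwm.length
        reflected = {
            (len(seq) - L - s.offset, "+-"["+-".index(s.strand) ^ 1], round(s.score, 4))
            for s in rev
        }
        assert {(s.offset, s.strand, round(s.score, 4)) for s in fwd} == reflected

    def test_windows_containing_n_are_skipped(self):
        pwm = indicator_pwm("ACGTA")
        assert scan_sequence(pwm, "ACNTA" * 4, p_max=1.0, match_min=0.01) == []
        assert scan_sequence(pwm, "N" * 50, p_max=1.0, match_min=0.01) == []

    def test_rel_score_affine_invariant_under_column_shift(self, rng):
        """Adding a constant to every log-odds entry of a column leaves the
        min/max-normalized relative score of every word unchanged."""
        pwm = random_dirichlet_pwm(rng, 5)
        sc = pwm._scanner
        shifts = rng.integers(-5000, 5001, size=(5, 1))
        q2 = sc.q + shifts
        span1 = sc.qmax - sc.qmin
        span2 = q2.max(axis=1).sum() - q2.min(axis=1).sum()
        for _ in range(10):
            w = rng.integers(0, 4, size=5)
            rel1 = (sc.q[np.arange(5), w].sum() - sc.qmin) / span1
            rel2 = (q2[np.arange(5), w].sum() - q2.min(axis=1).sum()) / span2
            assert rel1 == pytest.approx(rel2)

    def test_planted_consensus_sites_fully_recalled(self, rng):
        pwm = soft_pwm("ACGGTTACCAGTTGGA", dominant=0.9, motif_id="p")
        hits = 0
        for i in range(20):
            flank = "".join(rng.choice(list("ACGT"), size=50))
            seq = flank + pwm.consensus + flank
            sites = scan_sequence(pwm, seq, match_min=0.8, p_max=0.05)
            assert any(s.offset == 50 for s in sites)
            hits += 1
        assert hits == 20


class TestConservation:
    def make_sites(self, pwm, seq, name):
        return scan_sequence(pwm, seq, enhancer_name=name, p_max=1.0)

    def test_ortholog_with_consensus_is_conserved(self):
        pwm = indicator_pwm("ACGTACGT")
        sites = self.make_sites(pwm, "TT" + pwm.consensus + "TT", "e1")
        out = apply_conservation(
            sites, [pwm], {"e1": "o1"}, {"o1": "GGACGTACGTGG"}, match_min=0.8
        )
        assert all(s.conserved for s in out)

    def test_all_n_ortholog_is_not_conserved(self):
        pwm = indicator_pwm("ACGTACGT")
        sites = self.make_sites(pwm, "TT" + pwm.consensus + "TT", "e1")
        out = apply_conservation(sites, [pwm], {"e1": "o1"}, {"o1": "N" * 30}, 0.8)
        assert not any(s.conserved for s in out)

    def test_unmapped_enhancer_is_not_conserved(self):
        pwm = indicator_pwm("ACGTACGT")
        sites = self.make_sites(pwm, "TT" + pwm.consensus + "TT", "e1")
        out = apply_conservation(sites, [pwm], {}, {}, 0.8)
        assert not any(s.conserved for s in out)

    def test_missing_ortholog_record_is_error_naming_id(self):
        pwm = indicator_pwm("ACGTACGT")
        sites = self.make_sites(pwm, "TT" + pwm.consensus + "TT", "e1")
        with pytest.raises(KeyError, match="o_missing"):
            apply_conservation(sites, [pwm], {"e1": "o_missing"}, {}, 0.8)

    def test_conservation_found_on_either_strand(self):
        pwm = indicator_pwm("AAACGTGC")
        sites = self.make_sites(pwm, "TT" + pwm.consensus + "TT", "e1")
        orth = "GG" + reverse_complement(pwm.consensus) + "GG"
        out = apply_conservation(sites, [pwm], {"e1": "o1"}, {"o1": orth}, 0.8)
        assert all(s.conserved for s in out)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2**32 - 1))
def test_pvalue_monotonicity_property(seed):
    """Survival function of the score distribution never increases."""
    rng = np.random.default_rng(seed)
    pwm = random_dirichlet_pwm(rng, int(rng.integers(4, 9)))
    sf = pwm._scanner.survival
    assert np.all(np.diff(sf) <= 1e-15)
    assert sf[0] == pytest.approx(1.0)
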