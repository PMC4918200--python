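"""Weighted base-pair maximization: oracle agreement and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from retrozyme.fold import fold, fraction_paired_report, hhr_blocked
from retrozyme.seqio import GenomeRecord

PAIRS = {("G", "C"): 3, ("C", "G"): 3, ("A", "U"): 2, ("U", "A"): 2,
         ("G", "U"): 1, ("U", "G"): 1}


def brute_force_optimum(seq, weights=None, min_loop=3):
    """Exhaustive enumeration over all nested structures (test oracle)."""
    table = weights or PAIRS

    def best(i, j):
        if j - i <= min_loop:
            return 0
        b = best(i, j - 1)
        for k in range(i, j - min_loop):
            w = table.get((seq[k], seq[j]), 0)
            if w:
                left = best(i, k - 1) if k > i else 0
                b = max(b, w + left + best(k + 1, j - 1))
        return b

    return best(0, len(seq) - 1)


class TestFold:
    def test_unpairable(self):
        r = fold("AAAA")
        assert r.pairs == () and r.fraction_paired == 0.0

    def test_simple_hairpin(self):
        # all four GC pairs close over the AAAA loop: 8/12 paired
        r = fold("GGGGAAAACCCC")
        assert r.pairs == ((0, 11), (1, 10), (2, 9), (3, 8))
        assert r.fraction_paired == pytest.approx(8 / 12)
        assert r.dotbracket == "((((....))))"

    def test_t_read_as_u(self):
        assert fold("GGGGAAAACCCC").score == fold("GGGGAAAACCCC".replace(
            "U", "T")).score

    def test_invalid_characters(self):
        with pytest.raises(ValueError):
            fold("ACGX")
        with pytest.raises(ValueError):
            fold("")

    def test_structure_invariants_random(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 80))
            s = "".join(rng.choice(list("ACGU"), size=n))
            r = fold(s)
            partner = {}
            for i, j in r.pairs:
                assert j - i > 3
                assert (s[i], s[j]) in PAIRS
                assert i not in partner and j not in partner
                partner[i] = j
                partner[j] = i
            # nestedness: no crossing pairs
            for (i1, j1) in r.pairs:
                for (i2, j2) in r.pairs:
                    assert not (i1 < i2 < j1 < j2)
            assert r.dotbracket.count("(") == len(r.pairs)
            assert 0.0 <= r.fraction_paired <= 1.0

    def test_dp_matches_brute_force(self, rng):
        for _ in range(40):
            n = int(rng.integers(8, 22))
            s = "".join(rng.choice(list("ACGU"), size=n))
            assert fold(s).score == brute_force_optimum(s)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGU", min_size=5, max_size=40))
    def test_revcomp_invariance_without_wobble(self, s):
        """With Watson-Crick pairs only, the pairing statistic is invariant
        under reverse complement (pairs map onto pairs)."""
        wc = {"GC": 3, "AU": 2}
        comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
        rc = "".join(comp[c] for c in reversed(s))
        assert fold(s, weights=wc).fraction_paired == \
            fold(rc, weights=wc).fraction_paired

    def test_appending_revcomp_does_not_decrease_fraction(self, rng):
        comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
        for _ in range(20):
            n = int(rng.integers(10, 50))
            s = "".join(rng.choice(list("ACGU"), size=n))
            rc = "".join(comp[c] for c in reversed(s))
            assert fold(s + rc).fraction_paired >= fold(s).fraction_paired


class TestReport:
    def test_perfect_hairpin(self, rng):
        stem = "".join(rng.choice(list("ACGU"), size=20))
        comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
        hairpin = stem + "AAAA" + "".join(comp[c] for c in reversed(stem))
        df = fraction_paired_report([GenomeRecord("h", hairpin)])
        assert df.loc[0, "fraction_paired"] == pytest.approx(40 / 44)

    def test_empty_record_set(self):
        df = fraction_paired_report([])
        assert len(df) == 0
        assert list(df.columns) == ["id", "length", "fraction_paired", "score"]

    def test_planted_monomer_beats_shuffles_on_average(self, benchmark, rng):
        """A real (planted) monomer carries designed self-complementarity
        (LTR hairpin, helices); mononucleotide shuffles lose part of it."""
        from retrozyme.simulate import mononucleotide_shuffle

        el = next(e for e in benchmark["elements"]
                  if e.classification == "full_retrozyme")
        mono = el.monomer[0]
        f0 = fold(mono).fraction_paired
        shuffled = np.mean([
            fold(mononucleotide_shuffle(mono, rng)).fraction_paired
            for _ in range(20)])
        assert f0 > shuffled


class TestHhrBlocked:
    def test_no_pairs_in_span(self):
        r = fold("AAAAAAAAAAGGGGAAAACCCC")
        assert hhr_blocked(r, (0, 8)) == 0.0

    def test_whole_sequence_span_is_zero(self):
        r = fold("GGGGAAAACCCC")
        assert hhr_blocked(r, (0, r.length)) == 0.0

    def test_enclosing_hairpin_blocks_motif(self, rng):
        # motif region designed to pair entirely with a downstream
        # complement (the blocked conformation of the hammerhead)
        comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
        motif = "".join(rng.choice(list("ACGU"), size=30))
        seq = motif + "AAAA" + "".join(comp[c] for c in reversed(motif))
        r = fold(seq)
        assert hhr_blocked(r, (0, 30)) > 0.5

    def test_out_of_bounds_span(self):
        r = fold("GGGGAAAACCCC")
        with pytest.raises(ValueError):
            hhr_blocked(r, (5, 50))
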