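"""Hammerhead scanner: detection, bona fide filter, degenerate copies."""

import numpy as np
import pytest

from retrozyme.descriptor import HHRDescriptor, PAIR_WEIGHT, matches_iupac
from retrozyme.scan import (check_tertiary, find_degenerate_copies,
                            scan_sequence)
from retrozyme.seqio import GenomeRecord, Interval, revcomp
from retrozyme.simulate import _rand_seq, make_hhr


def _planted_genome(topology, seed, bg_len=2000, offset=100):
    rng = np.random.default_rng(seed)
    motif, cut, rec = make_hhr(HHRDescriptor(), topology, rng)
    bg = _rand_seq(np.random.default_rng(seed + 1000), bg_len, 0.4)
    g = GenomeRecord("c", bg[:offset] + motif + bg[offset:])
    return g, motif, offset + cut, rec


class TestScan:
    def test_poly_a_yields_nothing(self, desc):
        assert scan_sequence(GenomeRecord("a", "A" * 1000), desc) == []

    def test_short_sequence_is_empty_not_error(self, desc):
        assert scan_sequence(GenomeRecord("a", "ACGT" * 5), desc) == []

    def test_empty_topology_set_is_error(self, desc):
        with pytest.raises(ValueError):
            HHRDescriptor(topologies=())

    @pytest.mark.parametrize("topology", ["I", "III"])
    def test_planted_motif_recovered(self, desc, topology):
        g, motif, cut, rec = _planted_genome(topology, seed=1)
        hits = [h for h in scan_sequence(g, desc) if h.bona_fide]
        assert len(hits) == 1
        h = hits[0]
        assert h.topology == topology
        assert h.strand == "+"
        assert h.cleavage_pos == cut
        assert h.layout == rec["layout"]

    def test_reverse_complement_mirrors_hit(self, desc):
        g, motif, cut, rec = _planted_genome("III", seed=1)
        fwd = scan_sequence(g, desc)
        rev = scan_sequence(GenomeRecord("c", revcomp(g.seq)), desc)
        L = len(g.seq)
        assert len(fwd) == len(rev)
        mirrored = sorted(
            (L - h.location.end, L - h.location.start,
             "-" if h.strand == "+" else "+", L - h.cleavage_pos,
             h.topology, h.score, h.bona_fide) for h in rev)
        original = sorted(
            (h.location.start, h.location.end, h.strand, h.cleavage_pos,
             h.topology, h.score, h.bona_fide) for h in fwd)
        assert mirrored == original

    def test_determinism(self, desc):
        g, *_ = _planted_genome("III", seed=5)
        a = scan_sequence(g, desc)
        b = scan_sequence(g, desc)
        assert a == b

    def test_hits_revalidate(self, desc):
        """Soundness: every reported hit satisfies its own invariants when
        re-checked against the raw sequence."""
        for seed in range(3):
            g, *_ = _planted_genome("III", seed=20 + seed)
            for h in scan_sequence(g, desc):
                seq = h.seq
                # core segments match the degenerate patterns
                a0 = h.core_positions["core_seg_A"]
                assert all(matches_iupac(seq[a0 + i], c)
                           for i, c in enumerate(desc.core_seg_A))
                b0 = h.core_positions["core_seg_B"]
                assert all(matches_iupac(seq[b0 + i], c)
                           for i, c in enumerate(desc.core_seg_B))
                # each helix's arms pair under the allowed pair set
                for arm5, arm3 in h.helices.values():
                    s5, s3 = [g.seq[a.start:a.end] for a in (arm5, arm3)]
                    if h.strand == "-":
                        s5, s3 = revcomp(s3), revcomp(s5)
                    wob = 0
                    for i in range(len(s5)):
                        w = PAIR_WEIGHT.get((s5[i], s3[len(s3) - 1 - i]))
                        assert w is not None
                        wob += w == 1
                    assert wob <= desc.max_wobbles_per_helix
                assert h.location.start <= h.cleavage_pos <= h.location.end
                assert len(h.seq) <= desc.max_span

    def test_core_mutation_makes_motif_invisible(self, desc):
        """Single substitutions at non-N core positions kill detection."""
        rng = np.random.default_rng(7)
        motif, cut, rec = make_hhr(desc, "III", rng)
        pad = _rand_seq(rng, 600, 0.4)
        for off, code in rec["core_offsets"]:
            if code == "N":
                continue
            for bad in "ACGT":
                if matches_iupac(bad, code):
                    continue
                broken = motif[:off] + bad + motif[off + 1:]
                g = GenomeRecord("d", pad[:300] + broken + pad[300:])
                hits = scan_sequence(g, desc)
                assert not any(h.cleavage_pos == 300 + cut for h in hits), \
                    f"core position {off} ({code}->{bad}) still detected"


class TestTertiary:
    def _hit(self, loop1, loop2, topology="III"):
        from retrozyme.scan import HHRHit

        return HHRHit(location=Interval("c", 0, 60), topology=topology,
                      helices={}, loops={"1": loop1, "2": loop2, "3": None},
                      core_positions={}, cleavage_pos=5, score=10,
                      seq="A" * 60, layout=(3, 4, 3, 4, 3, -1))

    @staticmethod
    def _brute_best_run(a, b, pairs=frozenset({("A", "T"), ("T", "A"),
                                               ("G", "C"), ("C", "G")})):
        best = 0
        for i in range(len(a)):
            for j in range(len(b)):
                k = 0
                while i + k < len(a) and j - k >= 0 \
                        and (a[i + k], b[j - k]) in pairs:
                    k += 1
                best = max(best, k)
        return best

    def test_four_pair_run(self, desc):
        h = check_tertiary(self._hit("GCTAAAA", "AAATAGC"), desc)
        assert h.tertiary_pairs == 4
        assert h.bona_fide

    def test_no_complementarity(self, desc):
        h = check_tertiary(self._hit("AAAA", "AAAA"), desc)
        assert h.tertiary_pairs == 0
        assert not h.bona_fide

    def test_matches_brute_force_on_random_loops(self, desc, rng):
        for _ in range(200):
            l1 = _rand_seq(rng, int(rng.integers(3, 12)), 0.5)
            l2 = _rand_seq(rng, int(rng.integers(3, 12)), 0.5)
            h = check_tertiary(self._hit(l1, l2), desc)
            assert h.tertiary_pairs == self._brute_best_run(l1, l2)

    def test_planted_motif_loses_bona_fide_with_poly_a_loop2(self, desc):
        rng = np.random.default_rng(3)
        motif, cut, rec = make_hhr(desc, "III", rng)
        hits = scan_sequence(GenomeRecord("m", motif), desc)
        assert hits and hits[0].bona_fide
        h = hits[0]
        # neutralize the kissing interaction: loop2 -> poly-A against a
        # loop1 chosen free of T (so no chance A:T run)
        loop1 = "GCGCG"
        h2 = check_tertiary(self._hit(loop1, "A" * 6), desc)
        assert not h2.bona_fide


class TestDegenerateCopies:
    @staticmethod
    def _mutate(s, n, rng):
        out = list(s)
        for i in rng.choice(len(s), size=n, replace=False):
            out[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[out[i]]
        return "".join(out)

    def _setup(self, n_sub, seed=9):
        rng = np.random.default_rng(seed)
        seedseq = _rand_seq(rng, 90, 0.4)
        copy = self._mutate(seedseq, n_sub, rng)
        bg = _rand_seq(rng, 12000, 0.4)
        g = GenomeRecord("g", bg[:4000] + seedseq + bg[4000:8000]
                         + copy + bg[8000:])
        return seedseq, g

    def test_copy_at_91pct_identity_found(self):
        seedseq, g = self._setup(8)   # 82/90 = 91.1% >= 90%
        res = find_degenerate_copies(seedseq, g)
        assert any(iv.start == 8090 and iv.end == 8180 for iv in res)

    def test_copy_at_87pct_identity_not_found(self):
        seedseq, g = self._setup(12)  # 78/90 = 86.7% < 90%
        assert find_degenerate_copies(seedseq, g) == []

    def test_self_excluded(self):
        rng = np.random.default_rng(11)
        seedseq = _rand_seq(rng, 90, 0.4)
        g = GenomeRecord("g", seedseq)
        assert find_degenerate_copies(seedseq, g) == []

    def test_minus_strand_copy(self):
        rng = np.random.default_rng(13)
        seedseq = _rand_seq(rng, 90, 0.4)
        bg = _rand_seq(rng, 6000, 0.4)
        g = GenomeRecord("g", bg[:2000] + seedseq + bg[2000:4000]
                         + revcomp(seedseq) + bg[4000:])
        res = find_degenerate_copies(
            seedseq, g, exclude=Interval("g", 2000, 2090, "+"))
        assert res == [Interval("g", 4090, 4180, "-")]

    def test_window_longer_than_seed_is_error(self):
        with pytest.raises(ValueError, match="window"):
            find_degenerate_copies("ACGT" * 10, GenomeRecord("g", "A" * 200),
                                   window=90)
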