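"""Element assembly: pairing, LTR delimitation, TSD, boxes, classes."""

import numpy as np
import pytest

from retrozyme.annotate import (BoxConsensus, RetrozymeElement,
                                annotate_genome, delimit_ltrs,
                                extract_monomer, find_boxes, find_tsd,
                                pair_hhrs)
from retrozyme.scan import HHRHit, scan_sequence
from retrozyme.seqio import GenomeRecord, Interval, revcomp
from retrozyme.simulate import SyntheticSpec, _rand_seq, build_genome, make_hhr


def _stub(contig="c", start=0, end=60, strand="+", cut=10, topology="III",
          bona_fide=True, score=30):
    return HHRHit(location=Interval(contig, start, end, strand),
                  topology=topology, helices={}, loops={},
                  core_positions={}, cleavage_pos=cut, score=score,
                  seq="A" * (end - start), layout=(), tertiary_pairs=3,
                  bona_fide=bona_fide)


class TestPairing:
    def test_two_hits_750_apart_pair(self):
        hits = [_stub(start=100, end=160, cut=110),
                _stub(start=850, end=910, cut=860)]
        runs = pair_hhrs(hits)
        assert len(runs) == 1 and len(runs[0]) == 2

    def test_opposite_strands_do_not_pair(self):
        hits = [_stub(start=100, end=160, cut=110),
                _stub(start=850, end=910, cut=860, strand="-")]
        assert pair_hhrs(hits) == []

    def test_three_hits_at_800_800_form_one_run(self):
        hits = [_stub(start=i * 800, end=i * 800 + 60, cut=i * 800 + 10)
                for i in range(3)]
        runs = pair_hhrs(hits)
        assert len(runs) == 1 and len(runs[0]) == 3

    def test_spacing_bounds(self):
        # 300 nt apart: below min_spacing; 1200: above max
        hits = [_stub(start=0, end=60, cut=10),
                _stub(start=300, end=360, cut=310),
                _stub(start=1500, end=1560, cut=1510)]
        assert pair_hhrs(hits) == []

    def test_non_bona_fide_excluded(self):
        hits = [_stub(start=100, end=160, cut=110, bona_fide=False),
                _stub(start=850, end=910, cut=860)]
        assert pair_hhrs(hits) == []


def _single_element_genome(seed=21, divergence=0.0, strand="+", monomer=None):
    kwargs = dict(genome_length=20_000, n_full=1, n_solo=0, n_multimer=0,
                  n_decoys=0, ltr_divergence=divergence, strand=strand,
                  seed=seed)
    if monomer is not None:
        kwargs["monomer_length"] = (monomer, monomer)
    spec = SyntheticSpec(**kwargs)
    records, truths = build_genome(spec)
    return records, truths[0]


class TestDelimitation:
    def test_identical_ltrs(self, desc):
        records, truth = _single_element_genome(divergence=0.0)
        hits = [h for h in scan_sequence(records, desc) if h.bona_fide]
        assert len(hits) == 2
        res = delimit_ltrs(hits, records)
        assert res is not None
        ltr1, ltr2, identity, length = res
        assert identity == 1.0
        for ltr, t_ltr in zip((ltr1, ltr2), truth.ltrs):
            assert abs(len(ltr) - len(t_ltr)) <= 5

    def test_two_percent_divergence(self, desc):
        # seed chosen so the realized substitution count (6 over ~270
        # eligible positions) actually represents the 2% condition
        records, truth = _single_element_genome(seed=1, divergence=0.02)
        hits = [h for h in scan_sequence(records, desc) if h.bona_fide]
        res = delimit_ltrs(hits, records)
        assert res is not None
        ltr1, ltr2, identity, length = res
        assert identity >= 0.95
        for ltr, t_ltr in zip((ltr1, ltr2), truth.ltrs):
            assert abs(ltr.start - t_ltr.start) <= 15
            assert abs(ltr.end - t_ltr.end) <= 15

    def test_unrelated_flanks_give_absent(self, desc):
        """Two stray hammerheads at element-like spacing but with random
        flanks must not yield an LTR pair."""
        rng = np.random.default_rng(31)
        m1, c1, _ = make_hhr(desc, "III", rng)
        m2, c2, _ = make_hhr(desc, "III", rng)
        filler = 750 - (len(m1) - c1) - c2
        seq = (_rand_seq(rng, 2000, 0.4) + m1 + _rand_seq(rng, filler, 0.4)
               + m2 + _rand_seq(rng, 2000, 0.4))
        g = GenomeRecord("c", seq)
        hits = [h for h in scan_sequence(g, desc) if h.bona_fide]
        assert len(hits) == 2
        assert delimit_ltrs(hits, g) is None

    def test_mixed_strand_pair_is_error(self, desc):
        with pytest.raises(ValueError):
            delimit_ltrs([_stub(), _stub(strand="-", start=800, end=860,
                                         cut=810)],
                         GenomeRecord("c", "A" * 2000))


class TestTsd:
    # aperiodic 40-mer element body and unrelated flanks, so the only
    # boundary duplication is the one planted in each test
    CORE = "TGCAAACTGAGCTTTGAGCTACTGATCGGGCCAGCCAGTC"
    LEFT = "TGCGATGATCAGAGTA"
    RIGHT = "CCATTGACATTCCTAT"

    def test_planted_wwrr_tsd(self):
        seq = self.LEFT + "TAGG" + self.CORE + "TAGG" + self.RIGHT
        start = len(self.LEFT) + 4
        end = start + len(self.CORE)
        res = find_tsd(start, end, seq)
        assert res is not None
        left, right, k, s, e, wwrr = res
        assert (left, right, k) == ("TAGG", "TAGG", 4)
        assert (s, e) == (start, end)
        assert wwrr is True

    def test_no_duplication(self):
        seq = self.LEFT + self.CORE + self.RIGHT
        assert find_tsd(len(self.LEFT), len(self.LEFT) + len(self.CORE),
                        seq) is None

    def test_non_wwrr_tsd(self):
        seq = self.LEFT + "CCGG" + self.CORE + "CCGG" + self.RIGHT
        start = len(self.LEFT) + 4
        res = find_tsd(start, start + len(self.CORE), seq)
        assert res is not None
        assert res[2] == 4 and res[0] == "CCGG" and res[5] is False

    def test_longer_duplication_preferred(self):
        seq = self.LEFT + "GATAGG" + self.CORE + "GATAGG" + self.RIGHT
        start = len(self.LEFT) + 6
        res = find_tsd(start, start + len(self.CORE), seq)
        assert res is not None and res[2] == 6 and res[0] == "GATAGG"

    def test_boundary_sliding_recovers_shifted_tsd(self):
        seq = self.LEFT + "TTAA" + self.CORE + "TTAA" + self.RIGHT
        start = len(self.LEFT) + 4
        end = start + len(self.CORE)
        res = find_tsd(start + 3, end - 2, seq)  # boundaries off by 3 and 2
        assert res is not None
        assert res[0] == "TTAA" and (res[3], res[4]) == (start, end)


class TestBoxes:
    def test_planted_boxes_found_exactly(self, desc, benchmark):
        boxes = BoxConsensus()
        full = [e for e in benchmark["elements"]
                if e.classification == "full_retrozyme"]
        assert full
        n_pbs = sum(e.pbs_match is not None for e in full)
        n_ppt = sum(e.ppt_match is not None for e in full)
        assert n_pbs == len(full)
        assert n_ppt == len(full)
        # mismatch counts stay within the configured tolerance
        assert all(e.pbs_match[1] <= boxes.max_mismatches for e in full)
        assert all(e.ppt_match[1] <= boxes.max_mismatches for e in full)
        # and the standalone purine-run detector fires too
        assert sum(e.ppt_run is not None for e in full) == len(full)

    def test_mutated_box3_still_found_with_mismatch_count(self, desc):
        records, truth = _single_element_genome(seed=25)
        g = records[0]
        boxes = BoxConsensus()
        # mutate 4 positions of the planted box3 occurrence (5'LTR end +
        # PBS junction): ltr1 is the first truth LTR on the plus strand
        ltr1 = truth.ltrs[0] if truth.element.strand == "+" else truth.ltrs[1]
        if truth.element.strand == "+":
            box_start = ltr1.end - boxes.box3_ltr_len
            idxs = [box_start + i for i in (2, 7, 14, 20)]
        else:
            box_start = ltr1.start + boxes.box3_ltr_len - 1
            idxs = [box_start - i for i in (2, 7, 14, 20)]
        seq = list(g.seq)
        for i in idxs:
            seq[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[i]]
        g2 = GenomeRecord(g.id, "".join(seq))
        hits = [h for h in scan_sequence(g2, desc) if h.bona_fide]
        els = annotate_genome(g2, hits)
        full = [e for e in els if e.classification == "full_retrozyme"]
        assert len(full) == 1
        assert full[0].pbs_match is not None
        assert full[0].pbs_match[1] == 4

    def test_standalone_ppt_detector(self):
        # purine run of >=8 with <=1 pyrimidine directly upstream of ltr2
        seq = "T" * 60 + "GAGAGAGGGGAA" + "C" * 400
        el = RetrozymeElement(
            location=Interval("c", 10, 400, "+"),
            classification="full_retrozyme",
            ltr1=Interval("c", 10, 60, "+"),
            ltr2=Interval("c", 72, 400, "+"))
        _, _, ppt_run = find_boxes(el, GenomeRecord("c", seq), BoxConsensus())
        assert ppt_run is not None
        assert len(ppt_run) >= 8


class TestClassification:
    def test_benchmark_partition(self, benchmark):
        """Every bona fide hit lands in exactly one element class."""
        hits = [h for h in benchmark["hits"] if h.bona_fide]
        counted = sum(len(e.hhrs) for e in benchmark["elements"])
        assert counted == len(hits)
        ids = [id(h) for e in benchmark["elements"] for h in e.hhrs]
        assert len(ids) == len(set(ids))

    def test_solo_ltr(self, desc):
        spec = SyntheticSpec(genome_length=20_000, n_full=0, n_solo=1,
                             n_multimer=0, n_decoys=0, seed=33)
        records, truths = build_genome(spec)
        hits = scan_sequence(records, desc)
        els = annotate_genome(records, hits)
        assert [e.classification for e in els] == ["solo_LTR"]
        assert els[0].location.reciprocal_overlap(truths[0].element) > 0.5

    def test_bare_hhr_is_orphan(self, desc):
        rng = np.random.default_rng(35)
        motif, cut, _ = make_hhr(desc, "III", rng)
        g = GenomeRecord("c", _rand_seq(rng, 1000, 0.4) + motif
                         + _rand_seq(rng, 1000, 0.4))
        els = annotate_genome(g, scan_sequence(g, desc))
        assert [e.classification for e in els] == ["orphan_HHR"]

    def test_annotator_is_pure(self, desc):
        records, _ = _single_element_genome(seed=40)
        hits = scan_sequence(records, desc)
        a = annotate_genome(records, hits)
        b = annotate_genome(records, hits)
        assert len(a) == len(b)
        assert all(x.location == y.location
                   and x.classification == y.classification
                   and x.monomer == y.monomer for x, y in zip(a, b))


class TestMonomer:
    @pytest.mark.parametrize("length", [753, 679, 689, 979])
    def test_pinned_monomer_lengths(self, desc, length):
        """Elements built at the monomer sizes reported for cloned
        retrozymes (Jc_066-like 753 nt; strawberry 679; clementine 689;
        eucalyptus 979) are recovered at exactly those sizes."""
        spec = SyntheticSpec(genome_length=20_000, n_full=1, n_solo=0,
                             n_multimer=0, n_decoys=0, seed=50 + length,
                             monomer_length=(length, length),
                             internal_length=(1, 2000))
        records, truths = build_genome(spec)
        assert truths[0].monomer_length == length
        els = annotate_genome(records, scan_sequence(records, desc))
        full = [e for e in els if e.classification == "full_retrozyme"]
        assert len(full) == 1
        assert full[0].monomer[1] == length
        c1, c2 = full[0].cleavage_positions
        assert full[0].monomer[1] == c2 - c1

    def test_minus_strand_monomer_is_revcomp_of_plus_slice(self, desc):
        records, truth = _single_element_genome(seed=60, strand="-")
        els = annotate_genome(records, scan_sequence(records, desc))
        full = [e for e in els if e.classification == "full_retrozyme"]
        assert len(full) == 1
        el = full[0]
        c1, c2 = el.cleavage_positions
        plus_slice = records[0].seq[c1:c2]
        assert el.monomer[0] == revcomp(plus_slice).replace("T", "U")

    def test_inverted_cuts_is_error(self):
        el = RetrozymeElement(location=Interval("c", 0, 100),
                              classification="full_retrozyme",
                              cleavage_positions=(50, 50))
        with pytest.raises(ValueError):
            extract_monomer(el, GenomeRecord("c", "A" * 200))
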