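"""Assembly of hammerhead hits into annotated retrozyme elements.

A full retrozyme is a non-autonomous LTR retroelement: two direct
repeats (LTRs) of roughly 300-400 bp, each carrying one hammerhead
ribozyme, delimiting an internal region of roughly 300-600 bp, the whole
element flanked by a 4-bp target site duplication (TSD).  The two
self-cleavage sites delimit the monomer RNA (roughly 600-1000 nt) that
accumulates in vivo as circular RNA.  Two ~25-nt boxes are conserved
across species: the 3' box spans the 5'LTR / primer-binding-site (PBS,
tRNA-Met) junction and the 5' box spans the polypurine-tract (PPT) /
3'LTR junction — the same junction sequences used by autonomous
Ty3-gypsy retrotransposons, whose machinery retrozymes are thought to
borrow.

The annotator anchors on tandem bona fide hammerhead hits, delimits the
LTR pair by cleavage-anchored alignment extension, locates TSD and
boxes, classifies every bona fide hit into exactly one of
{full_retrozyme, multimeric_retrozyme(n), solo_LTR, orphan_HHR}, and
extracts the cleavage-to-cleavage monomer RNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .descriptor import matches_iupac
from .scan import HHRHit
from .seqio import GenomeRecord, GffFeature, Interval, as_genome_dict, fetch, revcomp

__all__ = [
    "BoxConsensus", "RetrozymeElement", "AnnotationConfig",
    "pair_hhrs", "delimit_ltrs", "find_tsd", "find_boxes", "classify",
    "extract_monomer", "annotate_genome", "elements_to_gff", "census_table",
]

_IUPAC_COMP = str.maketrans("ACGTURYSWKMBDHVN", "TGCAAYRSWMKVHDBN")


def _revcomp_iupac(consensus: str) -> str:
    return consensus.translate(_IUPAC_COMP)[::-1]


@dataclass(frozen=True)
class BoxConsensus:
    """The two ~25-nt junction boxes shared with Ty3-gypsy LTR ends.

    ``box3`` spans LTR 3' end + PBS; ``box5`` spans PPT + LTR 5' end.
    ``box3_ltr_len`` / ``ppt_len`` mark where the LTR boundary falls
    inside each box.  The default strings are placeholders with the
    canonical plant Ty3-gypsy PBS (complement of tRNA-Met 3' end) and a
    purine-rich PPT; they are configuration, not literature transcripts,
    and the synthetic generator embeds whatever is configured.
    """

    box3: str = "TTGGTTGGTGCCATGGTATCAGAGC"
    box5: str = "AAGGGGAGGGGATGTTAGGGCCAAT"
    box3_ltr_len: int = 13
    ppt_len: int = 12
    max_mismatches: int = 6
    search_window: int = 40

    def __post_init__(self) -> None:
        for b in (self.box3, self.box5):
            if not 15 <= len(b) <= 40:
                raise ValueError(f"box length {len(b)} outside 15-40 nt")
        if self.max_mismatches >= min(len(self.box3), len(self.box5)):
            raise ValueError("mismatch threshold must be below box length")
        if not 0 < self.box3_ltr_len < len(self.box3):
            raise ValueError("box3_ltr_len must fall inside box3")
        if not 0 < self.ppt_len < len(self.box5):
            raise ValueError("ppt_len must fall inside box5")

    @property
    def ltr5_head(self) -> str:
        """LTR 5'-end part of box5 (starts every LTR)."""
        return self.box5[self.ppt_len:]

    @property
    def ltr3_tail(self) -> str:
        """LTR 3'-end part of box3 (ends every LTR)."""
        return self.box3[:self.box3_ltr_len]

    @property
    def pbs(self) -> str:
        return self.box3[self.box3_ltr_len:]

    @property
    def ppt(self) -> str:
        return self.box5[:self.ppt_len]


@dataclass
class AnnotationConfig:
    min_spacing: int = 400          # cleavage-to-cleavage, nt
    max_spacing: int = 1100
    min_ltr_len: int = 200
    min_ltr_identity: float = 0.70
    monomer_bounds: tuple[int, int] = (500, 1200)
    tsd_lens: tuple[int, ...] = (6, 5, 4)
    tsd_flank_window: int = 12
    solo_context: tuple[int, int] = (250, 450)
    ltr_extension_cap: int = 700
    rolling_window: int = 20
    rolling_min_identity: float = 0.6


@dataclass
class RetrozymeElement:
    """An annotated element; ``location`` is the TSD-exclusive span."""

    location: Interval
    classification: str                 # full_retrozyme | multimeric_retrozyme
                                        # | solo_LTR | orphan_HHR
    hhrs: list = field(default_factory=list)
    n_units: int = 1
    ltr1: Interval | None = None
    ltr2: Interval | None = None
    ltr_identity: float | None = None
    ltr_alignment_length: int | None = None
    tsd: tuple[str, str, int] | None = None
    tsd_wwrr: bool | None = None
    pbs_match: tuple[Interval, int] | None = None
    ppt_match: tuple[Interval, int] | None = None
    ppt_run: Interval | None = None
    internal: Interval | None = None
    monomer: tuple[str, int] | None = None
    cleavage_positions: tuple[int, ...] = ()

    @property
    def strand(self) -> str:
        return self.location.strand


# --- pairing --------------------------------------------------------------


def pair_hhrs(hits: Sequence[HHRHit], min_spacing: int = 400,
              max_spacing: int = 1100) -> list[list[HHRHit]]:
    """Maximal same-contig/strand/topology runs of >=2 bona fide hits with
    consecutive cleavage-to-cleavage distances inside bounds.

    Spacing is measured between cleavage positions (the monomer size),
    not between motif starts.  Overlapping runs are resolved
    leftmost-longest by the maximality of the chaining.
    """
    groups: dict[tuple, list[HHRHit]] = {}
    for h in hits:
        if not h.bona_fide:
            continue
        groups.setdefault((h.location.contig, h.strand, h.topology), []).append(h)
    runs: list[list[HHRHit]] = []
    for key in sorted(groups):
        hs = sorted(groups[key], key=lambda h: h.cleavage_pos)
        run = [hs[0]]
        for h in hs[1:]:
            d = h.cleavage_pos - run[-1].cleavage_pos
            if min_spacing <= d <= max_spacing:
                run.append(h)
            else:
                if len(run) >= 2:
                    runs.append(run)
                run = [h]
        if len(run) >= 2:
            runs.append(run)
    return runs


# --- LTR delimitation -----------------------------------------------------


def _banded_columns(a: str, b: str, band: int = 10, match: int = 1,
                    mismatch: int = -1, gap: int = -2):
    """Global banded alignment (scores +1/-1/-2, band around the main
    diagonal); returns (is_match, advance_a, advance_b) per column.

    The scored model (rather than edit distance) matters here: gaps are
    costlier than mismatches, so unrelated sequence aligns at ~25%
    identity instead of being gap-shuffled upward, and the rolling
    identity trim stops where homology really ends."""
    n, m = len(a), len(b)
    if abs(n - m) > band:
        raise ValueError("length difference exceeds the band")
    NEG = -10 ** 9
    width = 2 * band + 1
    # dp[i][j - i + band]; cells outside the band stay NEG
    dp = [[NEG] * width for _ in range(n + 1)]
    dp[0][band] = 0
    for j in range(1, min(m, band) + 1):
        dp[0][j + band] = j * gap
    for i in range(1, n + 1):
        row = dp[i]
        prev = dp[i - 1]
        for d in range(max(0, band - i), min(width, m - i + band + 1)):
            j = i + d - band
            if j == 0:
                row[d] = i * gap
                continue
            s = prev[d] + (match if a[i - 1] == b[j - 1] else mismatch)
            if d + 1 < width and prev[d + 1] + gap > s:   # gap in b
                s = prev[d + 1] + gap
            if d - 1 >= 0 and row[d - 1] + gap > s:       # gap in a
                s = row[d - 1] + gap
            row[d] = s
    cols = []
    i, j = n, m
    while i > 0 or j > 0:
        d = j - i + band
        if i > 0 and j > 0 and dp[i][d] == dp[i - 1][d] + (
                match if a[i - 1] == b[j - 1] else mismatch):
            cols.append((a[i - 1] == b[j - 1], True, True))
            i -= 1
            j -= 1
        elif i > 0 and d + 1 < width and dp[i][d] == dp[i - 1][d + 1] + gap:
            cols.append((False, True, False))
            i -= 1
        else:
            cols.append((False, False, True))
            j -= 1
    cols.reverse()
    return cols


def _anchored_extension(wa: str, wb: str, window: int, min_ident: float):
    """Extend a homology block from the aligned start of two windows.

    Returns (consumed_a, consumed_b, matches, columns) for the block up to
    the outermost position where rolling ``window``-column identity stays
    >= ``min_ident``; the end is then trimmed back to a clean terminal
    match run (5 consecutive matching columns) so that chance matches in
    unrelated flanking sequence cannot drag the boundary outward.
    """
    if not wa or not wb:
        return 0, 0, 0, 0
    cols = _banded_columns(wa, wb)
    match = [c[0] for c in cols]
    n = len(cols)
    if n < window:
        extent = n if sum(match) / n >= min_ident else 0
    else:
        extent = 0
        run = sum(match[:window])
        pos = 0
        while True:
            if run / window >= min_ident:
                extent = pos + window
            else:
                break
            if pos + window >= n:
                break
            run += match[pos + window] - match[pos]
            pos += 1
    anchor = min(5, max(1, extent))
    while extent >= anchor and not all(match[extent - anchor:extent]):
        extent -= 1
    while extent > 0 and not match[extent - 1]:
        extent -= 1
    ca = sum(1 for c in cols[:extent] if c[1])
    cb = sum(1 for c in cols[:extent] if c[2])
    return ca, cb, sum(match[:extent]), extent


def delimit_ltrs(pair: Sequence[HHRHit], genome, min_ltr_len: int = 200,
                 min_identity: float = 0.70, cap: int = 700,
                 rolling_window: int = 20, rolling_min_identity: float = 0.6):
    """Delimit the direct-repeat (LTR) pair around two tandem hammerheads.

    The two repeat copies are anchored offset-aligned at their cleavage
    positions and the match is extended outward in both directions; each
    end is trimmed to the outermost position where rolling identity stays
    above threshold.  Returns (ltr1, ltr2, identity, alignment_length) or
    None when the homologous block is shorter than ``min_ltr_len`` or
    below ``min_identity`` — absence is a value, not an error.
    """
    a, b = sorted(pair[:2], key=lambda h: h.cleavage_pos)
    if a.strand != b.strand or a.location.contig != b.location.contig:
        raise ValueError("LTR delimitation needs a same-strand, same-contig pair")
    gd = as_genome_dict(genome)
    rec = gd[a.location.contig]
    L = len(rec.seq)
    c1, c2 = a.cleavage_pos, b.cleavage_pos
    w_right = min(c2 - c1, L - c2, cap)
    w_left = min(c2 - c1, c1, cap)

    ra, rb, rm, rcols = _anchored_extension(
        rec.seq[c1:c1 + w_right], rec.seq[c2:c2 + w_right],
        rolling_window, rolling_min_identity)
    la, lb, lm, lcols = _anchored_extension(
        rec.seq[c1 - w_left:c1][::-1], rec.seq[c2 - w_left:c2][::-1],
        rolling_window, rolling_min_identity)

    cols = rcols + lcols
    if cols == 0:
        return None
    identity = (rm + lm) / cols
    if cols < min_ltr_len or identity < min_identity:
        return None
    strand = a.strand
    ltr1 = Interval(rec.id, c1 - la, c1 + ra, strand)
    ltr2 = Interval(rec.id, c2 - lb, c2 + rb, strand)
    return ltr1, ltr2, identity, cols


# --- TSD ------------------------------------------------------------------


def _is_wwrr(tsd: str) -> bool:
    return (len(tsd) == 4
            and tsd[0] in "AT" and tsd[1] in "AT"
            and tsd[2] in "AG" and tsd[3] in "AG")


def find_tsd(start: int, end: int, seq: str, lens: Sequence[int] = (6, 5, 4),
             flank_window: int = 12):
    """Longest exact target-site duplication at the element boundaries.

    The left copy must end exactly at the element start and the right
    copy begin exactly at the element end, after sliding both boundaries
    independently by at most ``flank_window`` nt.  Longer duplications
    are preferred (insertion boundaries from repeat trimming can be off
    by a few nt); among equal lengths the smallest boundary shift wins.
    Returns (left, right, k, slid_start, slid_end, wwrr) or None.
    """
    for k in sorted(lens, reverse=True):
        best = None
        for dl in range(-flank_window, flank_window + 1):
            s = start + dl
            if s - k < 0:
                continue
            left = seq[s - k:s]
            if "N" in left:
                continue
            for dr in range(-flank_window, flank_window + 1):
                e = end + dr
                if e + k > len(seq) or e <= s:
                    continue
                if seq[e:e + k] == left:
                    key = (abs(dl) + abs(dr), dl, dr)
                    if best is None or key < best[0]:
                        best = (key, left, s, e)
        if best is not None:
            _, tsd, s, e = best
            return tsd, tsd, k, s, e, (_is_wwrr(tsd) if k == 4 else None)
    return None


# --- boxes ----------------------------------------------------------------


def _sense_slice(junction: int, o1: int, o2: int, strand: str, contig: str,
                 L: int) -> Interval | None:
    """Element-sense offsets [o1,o2) relative to a junction -> plus Interval."""
    if strand == "+":
        s, e = junction + o1, junction + o2
    else:
        s, e = junction - o2, junction - o1
    if s < 0 or e > L or s >= e:
        return None
    return Interval(contig, s, e, strand)


def _match_consensus(seq: str, consensus: str) -> int:
    return sum(1 for b, c in zip(seq, consensus) if not matches_iupac(b, c))


def _scan_box(rec: GenomeRecord, consensus: str, junction: int, expected: int,
              strand: str, window: int, max_mm: int):
    """Best consensus placement near an element-sense junction.

    ``expected`` is the element-sense offset of the consensus start
    relative to the junction.  Returns (Interval, mismatches) or None.
    """
    best = None
    for o in range(expected - window, expected + window + 1):
        iv = _sense_slice(junction, o, o + len(consensus), strand, rec.id,
                          len(rec.seq))
        if iv is None:
            continue
        mm = _match_consensus(fetch(iv, rec), consensus)
        if mm <= max_mm:
            key = (mm, abs(o - expected))
            if best is None or key < best[0]:
                best = (key, iv, mm)
    return None if best is None else (best[1], best[2])


def find_boxes(element: RetrozymeElement, genome, boxes: BoxConsensus):
    """Locate the conserved 3' box (LTR 3' end + PBS) and 5' box (PPT +
    LTR 5' end) at the inner LTR junctions, plus a standalone polypurine
    tract upstream of the element-sense 3' LTR."""
    if element.ltr1 is None or element.ltr2 is None:
        return None, None, None
    gd = as_genome_dict(genome)
    rec = gd[element.location.contig]
    strand = element.strand
    ltr5p = element.ltr1 if strand == "+" else element.ltr2
    ltr3p = element.ltr2 if strand == "+" else element.ltr1
    junc3 = ltr5p.end if strand == "+" else ltr5p.start      # 5'LTR / PBS
    junc5 = ltr3p.start if strand == "+" else ltr3p.end      # PPT / 3'LTR

    pbs_match = _scan_box(rec, boxes.box3, junc3, -boxes.box3_ltr_len, strand,
                          boxes.search_window, boxes.max_mismatches)
    ppt_match = _scan_box(rec, boxes.box5, junc5, -boxes.ppt_len, strand,
                          boxes.search_window, boxes.max_mismatches)

    # standalone PPT: longest purine run (>=8 nt, <=1 pyrimidine) within
    # 40 nt upstream (element sense) of the 3' LTR
    ppt_run = None
    iv = _sense_slice(junc5, -40, 0, strand, rec.id, len(rec.seq))
    if iv is not None:
        s = fetch(iv, rec)
        best = None
        for i in range(len(s)):
            pyr = 0
            for j in range(i, len(s)):
                if s[j] not in "AG":
                    pyr += 1
                    if pyr > 1:
                        break
                if j - i + 1 >= 8 and (best is None or j - i + 1 > best[1]):
                    best = (i, j - i + 1)
        if best is not None:
            o1 = -40 + best[0]
            ppt_run = _sense_slice(junc5, o1, o1 + best[1], strand, rec.id,
                                   len(rec.seq))
    return pbs_match, ppt_match, ppt_run


# --- monomer --------------------------------------------------------------


def extract_monomer(element: RetrozymeElement, genome) -> tuple[str, int]:
    """Cleavage-to-cleavage monomer RNA of an element (element sense,
    RNA alphabet).  Length equals the coordinate difference exactly."""
    cuts = element.cleavage_positions
    if len(cuts) < 2:
        raise ValueError("element has fewer than two cleavage positions")
    # for multimeric runs the monomer is one repeat unit: the first
    # consecutive cleavage-to-cleavage interval (element sense)
    if element.strand == "-":
        c1, c2 = cuts[-2], cuts[-1]
    else:
        c1, c2 = cuts[0], cuts[1]
    if c2 <= c1:
        raise ValueError(f"inverted cleavage positions {c1}, {c2}")
    gd = as_genome_dict(genome)
    s = gd[element.location.contig].seq[c1:c2]
    if element.strand == "-":
        s = revcomp(s)
    return s.replace("T", "U"), c2 - c1


# --- classification / driver ---------------------------------------------


def _solo_context(hit: HHRHit, rec: GenomeRecord, boxes: BoxConsensus,
                  cfg: AnnotationConfig):
    """Solo-LTR test: an isolated LTR carries the LTR halves of the two
    boxes at its ends; look for them around a lone bona fide hammerhead
    within a 250-450 nt context."""
    strand = hit.strand
    head, tail = boxes.ltr5_head, boxes.ltr3_tail
    mm_head = max(1, round(boxes.max_mismatches * len(head) / len(boxes.box5)))
    mm_tail = max(1, round(boxes.max_mismatches * len(tail) / len(boxes.box3)))
    lo, hi = cfg.solo_context
    anchor = hit.location.start if strand == "+" else hit.location.end
    # element-sense offset of the motif start relative to the anchor is 0
    best = None
    for o_head in range(-hi, 1):
        iv_h = _sense_slice(anchor, o_head, o_head + len(head), strand, rec.id,
                            len(rec.seq))
        if iv_h is None or _match_consensus(fetch(iv_h, rec), head) > mm_head:
            continue
        for o_tail in range(0, hi + 1):
            span = (o_tail + len(tail)) - o_head
            if not lo <= span <= hi:
                continue
            iv_t = _sense_slice(anchor, o_tail, o_tail + len(tail), strand,
                                rec.id, len(rec.seq))
            if iv_t is None or _match_consensus(fetch(iv_t, rec), tail) > mm_tail:
                continue
            if best is None or span < best[0]:
                best = (span, o_head, o_tail + len(tail))
    if best is None:
        return None
    _, o1, o2 = best
    return _sense_slice(anchor, o1, o2, strand, rec.id, len(rec.seq))


def classify(hits: Sequence[HHRHit], genome, boxes: BoxConsensus | None = None,
             cfg: AnnotationConfig | None = None) -> list[RetrozymeElement]:
    """Full annotation: pair, delimit, locate TSD/boxes, extract monomers
    and classify.  Every bona fide hit ends up in exactly one element
    (full/multimeric runs consume their constituent hits; the rest become
    solo_LTR or orphan_HHR singletons)."""
    boxes = boxes or BoxConsensus()
    cfg = cfg or AnnotationConfig()
    gd = as_genome_dict(genome)
    elements: list[RetrozymeElement] = []
    consumed: set[int] = set()

    runs = pair_hhrs([h for h in hits if h.bona_fide],
                     cfg.min_spacing, cfg.max_spacing)
    for run in runs:
        # validate each link by repeat homology; split the run at failures
        segments: list[list[HHRHit]] = [[run[0]]]
        links: list[tuple] = []
        for h in run[1:]:
            res = delimit_ltrs([segments[-1][-1], h], gd, cfg.min_ltr_len,
                               cfg.min_ltr_identity, cfg.ltr_extension_cap,
                               cfg.rolling_window, cfg.rolling_min_identity)
            if res is None:
                segments.append([h])
            else:
                segments[-1].append(h)
                links.append(res)
        for seg in segments:
            if len(seg) < 2:
                continue
            el = _build_element(seg, gd, boxes, cfg)
            if el is not None:
                elements.append(el)
                consumed.update(id(h) for h in seg)

    for h in hits:
        if not h.bona_fide or id(h) in consumed:
            continue
        rec = gd[h.location.contig]
        ctx = _solo_context(h, rec, boxes, cfg)
        if ctx is not None:
            elements.append(RetrozymeElement(
                location=ctx, classification="solo_LTR", hhrs=[h],
                cleavage_positions=(h.cleavage_pos,)))
        else:
            elements.append(RetrozymeElement(
                location=h.location, classification="orphan_HHR", hhrs=[h],
                cleavage_positions=(h.cleavage_pos,)))
    elements.sort(key=lambda e: (e.location.contig, e.location.start))
    return elements


def _build_element(seg: Sequence[HHRHit], gd, boxes: BoxConsensus,
                   cfg: AnnotationConfig) -> RetrozymeElement | None:
    rec = gd[seg[0].location.contig]
    outer = (seg[0], seg[-1])
    res = delimit_ltrs(outer, gd, cfg.min_ltr_len, cfg.min_ltr_identity,
                       min(cfg.ltr_extension_cap,
                           min(b.cleavage_pos - a.cleavage_pos
                               for a, b in zip(seg, seg[1:]))),
                       cfg.rolling_window, cfg.rolling_min_identity)
    if res is None:
        return None
    ltr1, ltr2, identity, aln_len = res
    strand = seg[0].strand
    cuts = tuple(sorted(h.cleavage_pos for h in seg))
    monomer_len = cuts[1] - cuts[0]
    n_units = len(seg) - 1
    if len(seg) == 2:
        in_bounds = cfg.monomer_bounds[0] <= monomer_len <= cfg.monomer_bounds[1]
        cls = "full_retrozyme" if in_bounds else "orphan_pair"
    else:
        cls = "multimeric_retrozyme"
    if cls == "orphan_pair":
        return None

    loc = Interval(rec.id, ltr1.start, ltr2.end, strand)
    el = RetrozymeElement(
        location=loc, classification=cls, hhrs=list(seg), n_units=n_units,
        ltr1=ltr1, ltr2=ltr2, ltr_identity=identity,
        ltr_alignment_length=aln_len, cleavage_positions=cuts)
    tsd = find_tsd(loc.start, loc.end, rec.seq, cfg.tsd_lens,
                   cfg.tsd_flank_window)
    if tsd is not None:
        left, right, k, s, e, wwrr = tsd
        el.tsd = (left, right, k)
        el.tsd_wwrr = wwrr
        if s < ltr1.end and e > ltr2.start and s < e:
            el.location = Interval(rec.id, s, e, strand)
    if ltr1.end < ltr2.start:
        el.internal = Interval(rec.id, ltr1.end, ltr2.start, strand)
    el.pbs_match, el.ppt_match, el.ppt_run = find_boxes(el, gd, boxes)
    el.monomer = extract_monomer(el, gd)
    return el


def annotate_genome(genome, hits: Sequence[HHRHit],
                    boxes: BoxConsensus | None = None,
                    cfg: AnnotationConfig | None = None) -> list[RetrozymeElement]:
    """Convenience driver: classify all hits of a genome."""
    return classify(hits, genome, boxes, cfg)


# --- output ---------------------------------------------------------------


def elements_to_gff(elements: Iterable[RetrozymeElement]) -> list[GffFeature]:
    feats: list[GffFeature] = []
    for i, el in enumerate(elements):
        eid = f"rz{i:04d}"
        attrs = {"ID": eid, "classification": el.classification,
                 "n_units": el.n_units}
        if el.ltr_identity is not None:
            attrs["ltr_identity"] = f"{el.ltr_identity:.3f}"
        if el.tsd is not None:
            attrs["tsd"] = el.tsd[0]
            attrs["tsd_wwrr"] = str(el.tsd_wwrr).lower()
        if el.monomer is not None:
            attrs["monomer_length"] = el.monomer[1]
        ftype = "retrozyme" if el.classification in (
            "full_retrozyme", "multimeric_retrozyme") else (
            "LTR" if el.classification == "solo_LTR" else "hammerhead_ribozyme")
        feats.append(GffFeature(ftype, el.location, attrs))
        for j, ltr in enumerate(filter(None, (el.ltr1, el.ltr2))):
            feats.append(GffFeature("LTR", ltr,
                                    {"ID": f"{eid}.ltr{j + 1}", "Parent": eid}))
        if el.pbs_match is not None:
            feats.append(GffFeature("PBS", el.pbs_match[0],
                                    {"ID": f"{eid}.pbs", "Parent": eid,
                                     "mismatches": el.pbs_match[1]}))
        if el.ppt_match is not None:
            feats.append(GffFeature("PPT", el.ppt_match[0],
                                    {"ID": f"{eid}.ppt", "Parent": eid,
                                     "mismatches": el.ppt_match[1]}))
        for h in el.hhrs:
            feats.append(GffFeature("hammerhead_ribozyme", h.location,
                                    {"ID": f"{eid}.hhr{h.cleavage_pos}",
                                     "Parent": eid, "topology": h.topology},
                                    score=h.score))
    return feats


def census_table(hits: Sequence[HHRHit],
                 elements: Sequence[RetrozymeElement]):
    """Per-contig census: hit and class counts plus monomer length stats."""
    import pandas as pd

    rows = {}
    for h in hits:
        r = rows.setdefault(h.location.contig, {
            "contig": h.location.contig, "n_hhrs": 0, "n_bona_fide": 0,
            "n_full": 0, "n_solo": 0, "n_multimer": 0, "n_orphan": 0,
            "monomer_lengths": []})
        r["n_hhrs"] += 1
        r["n_bona_fide"] += h.bona_fide
    for el in elements:
        r = rows.setdefault(el.location.contig, {
            "contig": el.location.contig, "n_hhrs": 0, "n_bona_fide": 0,
            "n_full": 0, "n_solo": 0, "n_multimer": 0, "n_orphan": 0,
            "monomer_lengths": []})
        key = {"full_retrozyme": "n_full", "solo_LTR": "n_solo",
               "multimeric_retrozyme": "n_multimer",
               "orphan_HHR": "n_orphan"}[el.classification]
        r[key] += 1
        if el.monomer is not None:
            r["monomer_lengths"].append(el.monomer[1])
    out = []
    for r in rows.values():
        ml = r.pop("monomer_lengths")
        r["monomer_len_min"] = min(ml) if ml else None
        r["monomer_len_median"] = sorted(ml)[len(ml) // 2] if ml else None
        r["monomer_len_max"] = max(ml) if ml else None
        out.append(r)
    return pd.DataFrame(out)
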