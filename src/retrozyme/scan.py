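"""Hammerhead ribozyme detection in genomic DNA.

The scanner seeds on exact occurrences of the least-degenerate word of
the catalytic core (``CTGA`` under defaults), then attempts to assemble
the full three-helix junction around each seed within the descriptor's
length ranges, in every enabled circularly permuted topology and on both
strands.  Hits are screened for the helix I / helix II loop-loop
("kissing") interaction that distinguishes bona fide hammerheads, and
overlapping candidates are resolved greedily by descending helix
stability score.

Motifs whose catalytic core deviates from the descriptor are invisible
to the scanner by design; near-identical relatives of a confirmed hit
are recovered separately by :func:`find_degenerate_copies`, mirroring
the field's usual structure-search-then-homology-search two-step.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import edlib

from .descriptor import HHRDescriptor, PAIR_WEIGHT, helix_pairing, matches_iupac
from .seqio import GenomeRecord, GffFeature, Interval, as_genome_dict, revcomp

__all__ = ["HHRHit", "scan_sequence", "check_tertiary", "find_degenerate_copies",
           "hits_to_gff"]


@dataclass(frozen=True)
class HHRHit:
    """One located hammerhead motif (all coordinates plus-strand)."""

    location: Interval
    topology: str
    helices: dict                 # {"I": (Interval, Interval), ...}
    loops: dict                   # {"1": str|None, "2": str|None, "3": str|None}
    core_positions: dict          # local offsets of core segments in the motif
    cleavage_pos: int             # plus-strand between-base index of the cut
    score: int                    # helix-stability score (GC=3, AT=2, GT=1)
    seq: str                      # motif sequence, strand-oriented
    layout: tuple                 # (h1, l1, h2, l2, h3, l3); absent loops = -1
    tertiary_pairs: int = 0
    bona_fide: bool = False

    @property
    def strand(self) -> str:
        return self.location.strand


# --- motif assembly -------------------------------------------------------


def _local_to_plus(a: int, b: int, origin: int, L: int, strand: str, contig: str) -> Interval:
    """Map a motif-local [a,b) slice of the oriented scan string to a
    plus-strand Interval.  ``origin`` is the slice start in scan-string
    coordinates; L is the contig length."""
    s, e = origin + a, origin + b
    if strand == "+":
        return Interval(contig, s, e, "+")
    return Interval(contig, L - e, L - s, "-")


def _candidates_for_seed(S: str, p: int, desc: HHRDescriptor):
    """Yield candidate layouts around a core_seg_A match at position p of
    the oriented string S.  Each candidate is a dict of local coordinates
    (relative to S) plus topology/score/loop info."""
    lenA = len(desc.core_seg_A)
    lenB = len(desc.core_seg_B)
    lenC = len(desc.cleavage_context)
    lenJ = len(desc.cut_adjacent)
    n = len(S)
    mw = desc.max_wobbles_per_helix

    def seg_ok(start: int, pattern: str) -> bool:
        if start < 0 or start + len(pattern) > n:
            return False
        for i, code in enumerate(pattern):
            if not matches_iupac(S[start + i], code):
                return False
        return True

    # closed helix II + core_seg_B block shared by types I and III
    # (type II opens helix II and is assembled separately)
    q = p + lenA
    h2_blocks = []
    if "I" in desc.topologies or "III" in desc.topologies:
        for h2 in range(desc.helix2_len[0], desc.helix2_len[1] + 1):
            for l2 in range(desc.loop_len[0], desc.loop_len[1] + 1):
                r = q + 2 * h2 + l2
                if not seg_ok(r, desc.core_seg_B):
                    continue
                sc2 = helix_pairing(S[q:q + h2],
                                    S[q + h2 + l2:q + h2 + l2 + h2], mw)
                if sc2 is None:
                    continue
                h2_blocks.append((h2, l2, r, sc2))

    # helix I + cleavage context block upstream of core_seg_A (types II/III)
    def h1_blocks():
        out = []
        for h1 in range(desc.helix1_len[0], desc.helix1_len[1] + 1):
            for l1 in range(desc.loop_len[0], desc.loop_len[1] + 1):
                cpos = p - 2 * h1 - l1 - lenJ  # local index of cut_adjacent
                if cpos - lenC < 0:
                    continue
                if not seg_ok(cpos, desc.cut_adjacent):
                    continue
                if not seg_ok(cpos - lenC, desc.cleavage_context):
                    continue
                sc1 = helix_pairing(S[p - h1:p], S[cpos + lenJ:cpos + lenJ + h1], mw)
                if sc1 is None:
                    continue
                out.append((h1, l1, cpos, sc1))
        return out

    blocks1 = h1_blocks() if ("II" in desc.topologies or "III" in desc.topologies) else []

    if "III" in desc.topologies:
        # [armIII5] NUH ^ C [armIb] loop1 [armIa] coreA [helixII/loop2] coreB [armIII3]
        for (h2, l2, r, sc2) in h2_blocks:
            for (h1, l1, cpos, sc1) in blocks1:
                for h3 in range(desc.helix3_len[0], desc.helix3_len[1] + 1):
                    a5 = cpos - lenC - h3
                    if a5 < 0 or r + lenB + h3 > n:
                        continue
                    sc3 = helix_pairing(S[a5:a5 + h3], S[r + lenB:r + lenB + h3], mw)
                    if sc3 is None:
                        continue
                    yield {
                        "topology": "III",
                        "start": a5, "end": r + lenB + h3, "cut": cpos,
                        "h1": (p - h1, p), "h1b": (cpos + lenJ, cpos + lenJ + h1),
                        "h2": (q, q + h2), "h2b": (q + h2 + l2, q + 2 * h2 + l2),
                        "h3": (a5, a5 + h3), "h3b": (r + lenB, r + lenB + h3),
                        "loop1": S[p - h1 - l1:p - h1],
                        "loop2": S[q + h2:q + h2 + l2],
                        "loop3": None,
                        "layout": (h1, l1, h2, l2, h3, -1),
                        "score": sc1 + sc2 + sc3,
                        "coreA": p, "coreB": r, "ctx": cpos - lenC,
                    }

    if "I" in desc.topologies:
        # [armIa] coreA [helixII/loop2] coreB [helixIII/loop3] NUH ^ C [armIb]
        for (h2, l2, r, sc2) in h2_blocks:
            for h3 in range(desc.helix3_len[0], desc.helix3_len[1] + 1):
                for l3 in range(desc.loop_len[0], desc.loop_len[1] + 1):
                    u = r + lenB + 2 * h3 + l3  # NUH start
                    if not seg_ok(u, desc.cleavage_context):
                        continue
                    if not seg_ok(u + lenC, desc.cut_adjacent):
                        continue
                    sc3 = helix_pairing(S[r + lenB:r + lenB + h3], S[u - h3:u], mw)
                    if sc3 is None:
                        continue
                    for h1 in range(desc.helix1_len[0], desc.helix1_len[1] + 1):
                        if p - h1 < 0 or u + lenC + lenJ + h1 > n:
                            continue
                        bstart = u + lenC + lenJ
                        sc1 = helix_pairing(S[p - h1:p], S[bstart:bstart + h1], mw)
                        if sc1 is None:
                            continue
                        yield {
                            "topology": "I",
                            "start": p - h1, "end": bstart + h1, "cut": u + lenC,
                            "h1": (p - h1, p), "h1b": (bstart, bstart + h1),
                            "h2": (q, q + h2), "h2b": (q + h2 + l2, q + 2 * h2 + l2),
                            "h3": (r + lenB, r + lenB + h3), "h3b": (u - h3, u),
                            "loop1": None,
                            "loop2": S[q + h2:q + h2 + l2],
                            "loop3": S[r + lenB + h3:u - h3],
                            "layout": (h1, -1, h2, l2, h3, l3),
                            "score": sc1 + sc2 + sc3,
                            "coreA": p, "coreB": r, "ctx": u,
                        }

    if "II" in desc.topologies:
        # [armII3] coreB [helixIII/loop3] NUH ^ C [armIb] loop1 [armIa] coreA [armII5]
        for (h1, l1, cpos, sc1) in blocks1:
            for h3 in range(desc.helix3_len[0], desc.helix3_len[1] + 1):
                for l3 in range(desc.loop_len[0], desc.loop_len[1] + 1):
                    b = cpos - lenC - 2 * h3 - l3 - len(desc.core_seg_B)
                    if b < 0:
                        continue
                    if not seg_ok(b, desc.core_seg_B):
                        continue
                    a5 = b + len(desc.core_seg_B)
                    sc3 = helix_pairing(S[a5:a5 + h3],
                                        S[cpos - lenC - h3:cpos - lenC], mw)
                    if sc3 is None:
                        continue
                    for h2 in range(desc.helix2_len[0], desc.helix2_len[1] + 1):
                        if b - h2 < 0 or q + h2 > n:
                            continue
                        sc2 = helix_pairing(S[q:q + h2], S[b - h2:b], mw)
                        if sc2 is None:
                            continue
                        yield {
                            "topology": "II",
                            "start": b - h2, "end": q + h2, "cut": cpos,
                            "h1": (p - h1, p), "h1b": (cpos + lenJ, cpos + lenJ + h1),
                            "h2": (q, q + h2), "h2b": (b - h2, b),
                            "h3": (a5, a5 + h3),
                            "h3b": (cpos - lenC - h3, cpos - lenC),
                            "loop1": S[p - h1 - l1:p - h1],
                            "loop2": None,
                            "loop3": S[a5 + h3:cpos - lenC - h3],
                            "layout": (h1, l1, h2, -1, h3, l3),
                            "score": sc1 + sc2 + sc3,
                            "coreA": p, "coreB": b, "ctx": cpos - lenC,
                        }


def _tertiary_run(loop_a: str, loop_b: str, allow_wobble: bool) -> int:
    """Longest contiguous antiparallel complementary run between two loops."""
    best = 0
    na, nb = len(loop_a), len(loop_b)
    for i0 in range(na):
        for j0 in range(nb - 1, -1, -1):
            k = 0
            while i0 + k < na and j0 - k >= 0:
                a, b = loop_a[i0 + k], loop_b[j0 - k]
                w = PAIR_WEIGHT.get((a, b))
                if w is None or (w == 1 and not allow_wobble):
                    break
                k += 1
            best = max(best, k)
    return best


def check_tertiary(hit: HHRHit, desc: HHRDescriptor) -> HHRHit:
    """Score the helix I / helix II loop-loop interaction and set bona_fide.

    For type I motifs (open helix I, no loop 1) the terminal nucleotides
    of the distal helix-I arm stand in for loop 1.  For type II motifs
    (open helix II, no loop 2) the loops of the closed helices I and III
    are compared instead; this is reported for completeness but is not
    the canonical loop1-loop2 contact.
    """
    loop2 = hit.loops.get("2")
    loop1 = hit.loops.get("1")
    if hit.topology == "I":
        arm_b = hit.seq[-desc.type1_distal_window:]
        loop1 = arm_b
    if hit.topology == "II":
        loop2 = hit.loops.get("3")
    if not loop1 or not loop2:
        t = 0
    else:
        t = _tertiary_run(loop1, loop2, desc.tertiary_allow_wobble)
    return replace(hit, tertiary_pairs=t, bona_fide=t >= desc.min_tertiary_pairs)


def _scan_oriented(S: str, strand: str, rec: GenomeRecord, desc: HHRDescriptor):
    """All candidate layouts of one oriented string, as HHRHit objects."""
    L = len(rec.seq)
    word = desc.seed_word
    off = desc.seed_offset
    lenA = len(desc.core_seg_A)
    hits = []
    pos = S.find(word)
    while pos != -1:
        p = pos - off
        if p >= 0 and p + lenA <= len(S):
            ok = all(matches_iupac(S[p + i], c) for i, c in enumerate(desc.core_seg_A))
            if ok:
                for cand in _candidates_for_seed(S, p, desc):
                    origin = 0
                    loc = _local_to_plus(cand["start"], cand["end"], origin, L,
                                         strand, rec.id)
                    cut_local = cand["cut"]
                    cut = cut_local if strand == "+" else L - cut_local
                    helices = {}
                    for name, key in (("I", "h1"), ("II", "h2"), ("III", "h3")):
                        a = _local_to_plus(*cand[key], origin, L, strand, rec.id)
                        b = _local_to_plus(*cand[key + "b"], origin, L, strand, rec.id)
                        helices[name] = (a, b)
                    st = cand["start"]
                    hit = HHRHit(
                        location=loc,
                        topology=cand["topology"],
                        helices=helices,
                        loops={"1": cand["loop1"], "2": cand["loop2"],
                               "3": cand["loop3"]},
                        core_positions={"core_seg_A": cand["coreA"] - st,
                                        "core_seg_B": cand["coreB"] - st,
                                        "cleavage_context": cand["ctx"] - st},
                        cleavage_pos=cut,
                        score=cand["score"],
                        seq=S[cand["start"]:cand["end"]],
                        layout=cand["layout"],
                    )
                    hits.append(check_tertiary(hit, desc))
        pos = S.find(word, pos + 1)
    return hits


def scan_sequence(genome, desc: HHRDescriptor | None = None) -> list[HHRHit]:
    """Detect hammerhead motifs on both strands of every record.

    Returns non-overlapping best-scoring hits sorted by (contig, start,
    strand).  Overlap between candidates is resolved greedily by
    descending helix-stability score with orientation-independent
    tie-breaks, so the output is mirror-symmetric under reverse
    complementation of the input.
    """
    desc = desc or HHRDescriptor()
    if not desc.topologies:
        raise ValueError("descriptor has an empty topology set")
    out: list[HHRHit] = []
    for rec in as_genome_dict(genome).values():
        if len(rec.seq) < desc.min_span:
            continue
        cands = _scan_oriented(rec.seq, "+", rec, desc)
        cands += _scan_oriented(revcomp(rec.seq), "-", rec, desc)
        # bona fide candidates take precedence over raw helix score: an
        # open-helix arm extended by chance flank pairing can outscore the
        # genuine layout while shifting the loop-loop window off the motif
        cands.sort(key=lambda h: (-h.bona_fide, -h.score, -h.tertiary_pairs,
                                  h.topology, h.layout, h.seq,
                                  h.location.start))
        chosen: list[HHRHit] = []
        for h in cands:
            if all(not h.location.overlaps(c.location) for c in chosen):
                chosen.append(h)
        out.extend(chosen)
    out.sort(key=lambda h: (h.location.contig, h.location.start, h.strand))
    return out


# --- degenerate-copy expansion -------------------------------------------


def _gap_and_match_counts(cigar: str) -> tuple[int, int]:
    gaps = matches = 0
    num = ""
    for c in cigar:
        if c.isdigit():
            num += c
        else:
            n = int(num)
            num = ""
            if c in "ID":
                gaps += n
            elif c == "=":
                matches += n
    return gaps, matches


def find_degenerate_copies(seed_hit_seq: str, genome, min_identity: float = 0.90,
                           window: int = 90, max_gaps: int = 2,
                           exclude: Interval | None = None) -> list[Interval]:
    """Genomic windows (both strands) matching ``seed_hit_seq`` at or above
    ``min_identity`` under an ungapped-or-lightly-gapped alignment.

    Identity is the fraction of exactly matching query positions; at most
    ``max_gaps`` gap columns are tolerated.  The seed's own location is
    excluded (``exclude`` if given, else the first exact occurrence), and
    overlapping matches are merged per strand.
    """
    seed = seed_hit_seq.upper().replace("U", "T")
    if window > len(seed):
        raise ValueError(f"window {window} exceeds seed length {len(seed)}")
    k = int(len(seed) * (1.0 - min_identity)) + max_gaps
    gd = as_genome_dict(genome)

    if exclude is None:
        for rec in gd.values():
            i = rec.seq.find(seed)
            if i != -1:
                exclude = Interval(rec.id, i, i + len(seed), "+")
                break

    found: list[Interval] = []
    for rec in gd.values():
        L = len(rec.seq)
        for strand in "+-":
            target = bytearray(
                (rec.seq if strand == "+" else revcomp(rec.seq)).encode()
            )
            # repeatedly take the current best match(es) and mask them out,
            # until nothing within k edits remains
            while True:
                res = edlib.align(seed, bytes(target).decode(), mode="HW",
                                  task="locations", k=k)
                if res["editDistance"] < 0:
                    break
                spans = [(st, en + 1) for st, en in res["locations"]]
                for st, en in spans:  # evaluate all tied-best locations
                    sub = bytes(target[st:en]).decode()
                    aln = edlib.align(seed, sub, mode="NW", task="path")
                    gaps, matches = _gap_and_match_counts(aln["cigar"])
                    if gaps <= max_gaps and matches / len(seed) >= min_identity:
                        if strand == "+":
                            iv = Interval(rec.id, st, en, "+")
                        else:
                            iv = Interval(rec.id, L - en, L - st, "-")
                        if exclude is None or not iv.overlaps(exclude):
                            found.append(iv)
                for st, en in spans:  # then mask them out together
                    target[st:en] = b"N" * (en - st)
    return _merge_intervals(found)


def _merge_intervals(ivs: Sequence[Interval]) -> list[Interval]:
    out: list[Interval] = []
    for iv in sorted(ivs, key=lambda v: (v.contig, v.strand, v.start)):
        if out and out[-1].contig == iv.contig and out[-1].strand == iv.strand \
                and iv.start <= out[-1].end:
            prev = out.pop()
            iv = Interval(iv.contig, prev.start, max(prev.end, iv.end), iv.strand)
        out.append(iv)
    return out


def hits_to_gff(hits: Iterable[HHRHit]) -> list[GffFeature]:
    feats = []
    for i, h in enumerate(hits):
        feats.append(GffFeature(
            "hammerhead_ribozyme", h.location,
            {"ID": f"hhr{i:05d}", "topology": h.topology,
             "bona_fide": str(h.bona_fide).lower(),
             "tertiary_pairs": h.tertiary_pairs,
             "cleavage_pos": h.cleavage_pos},
            score=h.score))
    return feats
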