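"""Seeded synthetic genomes with planted retrozymes and ground truth.

The generator emulates the genomic anatomy the pipeline is built to
recover: random-background chromosomes carrying full retrozymes (two
~330-bp LTRs, each with one hammerhead ribozyme, around a 300-600 bp
internal region, flanked by a 4-bp WWRR target-site duplication and the
conserved junction boxes), solo LTRs, tandem multimers (3-4 hammerheads)
and a catalogue of decoys that probe each filter independently
(core-mutated hammerheads, shuffled monomers, stray hammerhead pairs
without LTR context, LTR pairs without hammerheads).

Background is i.i.d. nucleotide sequence at a configurable GC content;
no repeat landscape is simulated.  LTR divergence is applied outside the
hammerhead footprint (the ribozyme is under purifying selection in real
elements).  All randomness flows from the spec seed and the same seed
reproduces byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .annotate import BoxConsensus, find_tsd
from .descriptor import HHRDescriptor, iupac_choices
from .scan import scan_sequence
from .seqio import GenomeRecord, Interval, revcomp

__all__ = ["SyntheticSpec", "TruthRecord", "make_hhr", "make_retrozyme",
           "build_genome", "mononucleotide_shuffle", "DECOY_KINDS"]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

DECOY_KINDS = ("core_mutant", "shuffled_monomer", "stray_hhr_pair",
               "ltr_pair_no_hhr")


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic genome."""

    genome_length: int = 5_000_000
    gc_content: float = 0.4
    n_full: int = 20
    n_solo: int = 5
    n_multimer: int = 2
    n_decoys: int = 10
    ltr_length: int = 330
    internal_length: tuple[int, int] = (300, 600)
    monomer_length: tuple[int, int] = (600, 1000)
    ltr_divergence: float = 0.01
    tsd_length: int = 4
    hhr_topology: str = "III"
    strand: str = "both"          # "+", "-" or "both" (random per element)
    seed: int = 7
    contig_id: str = "synth1"
    min_gap: int = 1250           # between planted inserts, nt

    def __post_init__(self) -> None:
        if min(self.n_full, self.n_solo, self.n_multimer, self.n_decoys) < 0:
            raise ValueError("counts must be >= 0")
        if not 0 <= self.ltr_divergence < 1:
            raise ValueError("ltr_divergence must be a substitution rate")
        if self.strand not in ("+", "-", "both"):
            raise ValueError("strand must be '+', '-' or 'both'")


@dataclass(frozen=True)
class TruthRecord:
    """Machine-readable ground truth for one planted item."""

    cls: str
    element: Interval
    ltrs: tuple = ()
    hhr_spans: tuple = ()
    cleavage_positions: tuple = ()
    tsd: str | None = None
    monomer_length: int | None = None
    n_units: int = 1
    params: dict = field(default_factory=dict)


def _rand_seq(rng: np.random.Generator, n: int, gc: float = 0.4) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _instantiate(consensus: str, rng: np.random.Generator) -> str:
    return "".join(c if c in "ACGT" else rng.choice(list(iupac_choices(c)))
                   for c in consensus)


def mononucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    arr = np.array(list(seq))
    rng.shuffle(arr)
    return "".join(arr)


# --- hammerhead construction ---------------------------------------------


def _sample_arm_pair(rng, n: int, wobble_prob: float = 0.25):
    """An antiparallel helix (arm5, arm3) with at most one G.T wobble."""
    arm5 = list(_rand_seq(rng, n, 0.5))
    arm3 = [_COMP[b] for b in reversed(arm5)]
    if n >= 2 and rng.random() < wobble_prob:
        i = int(rng.integers(0, n))
        a = arm5[i]
        if a == "C":
            arm5[i] = "T"          # T.G wobble
        elif a == "A":
            arm5[i] = "G"          # G.T wobble
        elif a == "G":
            arm3[n - 1 - i] = "T"
        else:
            arm3[n - 1 - i] = "G"
    return "".join(arm5), "".join(arm3)


def _assemble(topology: str, parts: dict, desc: HHRDescriptor):
    """Linearize the hammerhead cycle for one topology; returns
    (sequence, local cut index)."""
    A, B = parts["coreA"], parts["coreB"]
    ctx, adj = parts["ctx"], parts["adj"]
    a5, a3 = parts["armI"]
    b5, b3 = parts["armII"]
    c5, c3 = parts["armIII"]
    l1, l2, l3 = parts.get("loop1"), parts.get("loop2"), parts.get("loop3")
    if topology == "III":
        seq = c5 + ctx + adj + a3 + l1 + a5 + A + b5 + l2 + b3 + B + c3
        cut = len(c5) + len(ctx)
    elif topology == "I":
        seq = a5 + A + b5 + l2 + b3 + B + c5 + l3 + c3 + ctx + adj + a3
        cut = len(seq) - len(a3) - len(adj)
    elif topology == "II":
        seq = b3 + B + c5 + l3 + c3 + ctx + adj + a3 + l1 + a5 + A + b5
        cut = len(b3) + len(B) + 2 * len(c5) + len(l3) + len(ctx)
    else:
        raise ValueError(f"unknown topology {topology!r}")
    return seq, cut


def make_hhr(desc: HHRDescriptor | None = None, topology: str = "III",
             rng: np.random.Generator | None = None, max_tries: int = 200):
    """A random hammerhead motif satisfying every hit invariant.

    Helices are sampled uniformly inside the descriptor ranges, loops are
    random except for a planted loop-loop complementary run of at least
    ``min_tertiary_pairs``.  Candidates are validated against the scanner
    so the recorded layout and cleavage offset are the unique best parse
    (ambiguous draws are rejected and resampled).

    Returns (sequence, cleavage_offset, layout_record).
    """
    desc = desc or HHRDescriptor()
    rng = rng if rng is not None else np.random.default_rng(0)
    if topology not in ("I", "II", "III"):
        raise ValueError(f"unknown topology {topology!r}")
    scan_desc = desc if topology in desc.topologies else replace(
        desc, topologies=tuple(desc.topologies) + (topology,))

    for _ in range(max_tries):
        h1 = int(rng.integers(desc.helix1_len[0], desc.helix1_len[1] + 1))
        h2 = int(rng.integers(desc.helix2_len[0], desc.helix2_len[1] + 1))
        h3 = int(rng.integers(desc.helix3_len[0], desc.helix3_len[1] + 1))
        llo = desc.loop_len[0]
        lhi = min(desc.loop_len[1], 12)  # compact loops, as in plant HHRs
        l1n = int(rng.integers(llo, lhi + 1))
        l2n = int(rng.integers(llo, lhi + 1))
        l3n = int(rng.integers(llo, lhi + 1))
        parts = {
            "coreA": _instantiate(desc.core_seg_A, rng),
            "coreB": _instantiate(desc.core_seg_B, rng),
            "ctx": _instantiate(desc.cleavage_context, rng),
            "adj": _instantiate(desc.cut_adjacent, rng),
            "armI": _sample_arm_pair(rng, h1),
            "armII": _sample_arm_pair(rng, h2),
            "armIII": _sample_arm_pair(rng, h3),
            "loop1": _rand_seq(rng, l1n, 0.5),
            "loop2": _rand_seq(rng, l2n, 0.5),
            "loop3": _rand_seq(rng, l3n, 0.5),
        }

        # plant the tertiary (kissing) interaction used by the bona fide
        # filter: loop1-loop2 for type III, distal arm-loop2 for type I,
        # loop1-loop3 for type II
        if topology == "III":
            src, dst = "loop2", "loop1"
            src_seq = parts[src]
        elif topology == "I":
            tail = (parts["ctx"] + parts["adj"] + parts["armI"][1])
            src_seq = tail[-desc.type1_distal_window:]
            src, dst = None, "loop2"
        else:
            src, dst = "loop3", "loop1"
            src_seq = parts[src]
        dstseq = list(parts[dst])
        t_hi = max(desc.min_tertiary_pairs, min(4, len(src_seq), len(dstseq)))
        t = int(rng.integers(desc.min_tertiary_pairs, t_hi + 1))
        i0 = int(rng.integers(0, len(src_seq) - t + 1))
        j0 = int(rng.integers(t - 1, len(dstseq)))
        for k in range(t):
            dstseq[j0 - k] = _COMP[src_seq[i0 + k]]
        parts[dst] = "".join(dstseq)

        seq, cut = _assemble(topology, parts, desc)
        hits = scan_sequence(GenomeRecord("m", seq), scan_desc)
        if (len(hits) == 1 and hits[0].strand == "+"
                and hits[0].topology == topology
                and hits[0].cleavage_pos == cut and hits[0].bona_fide):
            record = {
                "topology": topology, "layout": hits[0].layout,
                "cut": cut, "length": len(seq),
                "core_offsets": _core_offsets(topology, parts),
            }
            return seq, cut, record
    raise RuntimeError(
        f"could not build an unambiguous type {topology} hammerhead in "
        f"{max_tries} attempts (descriptor ranges may be degenerate)")


def _core_offsets(topology: str, parts: dict) -> list[tuple[int, str]]:
    """(local offset, IUPAC code) of every core-constrained position."""
    desc_codes = {
        "coreA": "CTGANGA", "coreB": "GAAA", "ctx": "NTH", "adj": "C"}
    # rebuild the segment order to find offsets
    order = {
        "III": ["armIII.0", "ctx", "adj", "armI.1", "loop1", "armI.0",
                "coreA", "armII.0", "loop2", "armII.1", "coreB", "armIII.1"],
        "I": ["armI.0", "coreA", "armII.0", "loop2", "armII.1", "coreB",
              "armIII.0", "loop3", "armIII.1", "ctx", "adj", "armI.1"],
        "II": ["armII.1", "coreB", "armIII.0", "loop3", "armIII.1", "ctx",
               "adj", "armI.1", "loop1", "armI.0", "coreA", "armII.0"],
    }[topology]
    out = []
    off = 0
    for name in order:
        if "." in name:
            base, idx = name.split(".")
            seg = parts[base][int(idx)]
        else:
            seg = parts[name]
        if name in desc_codes:
            for i, code in enumerate(desc_codes[name]):
                out.append((off + i, code))
        off += len(seg)
    return out


# --- element construction -------------------------------------------------


def _mutate(seq: str, rate: float, protected: Sequence[tuple[int, int]],
            rng: np.random.Generator):
    if rate <= 0:
        return seq, []
    out = list(seq)
    positions = []
    prot = [(s, e) for s, e in protected]
    for i in range(len(out)):
        if any(s <= i < e for s, e in prot):
            continue
        if rng.random() < rate:
            out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
            positions.append(i)
    return "".join(out), positions


def _sample_tsd(spec: SyntheticSpec, rng) -> str:
    if spec.tsd_length == 4:
        return (rng.choice(list("AT")) + rng.choice(list("AT"))
                + rng.choice(list("AG")) + rng.choice(list("AG")))
    return _rand_seq(rng, spec.tsd_length, 0.5)


def _make_ltr(spec: SyntheticSpec, desc, boxes: BoxConsensus, rng,
              motif: str | None = None, cut: int | None = None):
    """One LTR: box5 LTR-head + filler + hammerhead + filler + box3 LTR-tail.

    With ``motif=None`` a fresh hammerhead is built; passing an explicit
    (possibly broken) motif supports decoy construction.
    """
    head = _instantiate(boxes.ltr5_head, rng)
    tail = _instantiate(boxes.ltr3_tail, rng)
    if motif is None:
        motif, cut, _rec = make_hhr(desc, spec.hhr_topology, rng)
    rem = spec.ltr_length - len(head) - len(tail) - len(motif)
    if rem < 40:
        raise ValueError(f"ltr_length {spec.ltr_length} too small for motif "
                         f"of {len(motif)} nt plus boxes")
    fa = int(rng.integers(20, rem - 20 + 1))
    fb = rem - fa
    ltr = head + _rand_seq(rng, fa, spec.gc_content) + motif \
        + _rand_seq(rng, fb, spec.gc_content) + tail
    hhr_span = (len(head) + fa, len(head) + fa + len(motif))
    return ltr, len(head) + fa + (cut if cut is not None else 0), hhr_span


def _internal_len(spec: SyntheticSpec, boxes: BoxConsensus, rng) -> int:
    lo, hi = spec.internal_length
    base = spec.ltr_length + len(boxes.pbs) + len(boxes.ppt)
    mlo, mhi = spec.monomer_length
    if mlo == mhi:                       # pinned monomer size
        n = mlo - base
    else:
        n = int(rng.integers(lo, hi + 1))
        n = min(max(n, mlo - base), mhi - base)
    if n < 1:
        raise ValueError("internal/monomer length ranges are inconsistent "
                         f"with ltr_length {spec.ltr_length}")
    return n


def make_retrozyme(spec: SyntheticSpec, rng: np.random.Generator,
                   desc: HHRDescriptor | None = None,
                   boxes: BoxConsensus | None = None,
                   n_hhrs: int = 2, cls: str = "full_retrozyme",
                   motif: str | None = None, cut: int | None = None):
    """One element as (insert_seq, relative TruthRecord fields).

    Layout: TSD + [LTR + PBS + internal + PPT] * (n_hhrs - 1) + LTR + TSD,
    the later LTR copies mutated at ``ltr_divergence`` outside the
    hammerhead footprint.  Coordinates in the returned dict are relative
    to the insert (element sense); ``build_genome`` maps them onto the
    chromosome and strand.
    """
    desc = desc or HHRDescriptor()
    boxes = boxes or BoxConsensus()
    ltr, cut_in_ltr, hhr_span = _make_ltr(spec, desc, boxes, rng, motif, cut)
    pbs = _instantiate(boxes.pbs, rng)
    ppt = _instantiate(boxes.ppt, rng)
    ilen = _internal_len(spec, boxes, rng)
    unit = ltr + pbs + _rand_seq(rng, ilen, spec.gc_content) + ppt
    ulen = len(unit)

    parts = []
    mutations = []
    for k in range(n_hhrs - 1):
        if k == 0:
            parts.append(unit)
        else:
            m, pos = _mutate(unit, spec.ltr_divergence, [hhr_span], rng)
            parts.append(m)
            mutations.extend(k * ulen + p for p in pos)
    ltr_last, pos = _mutate(ltr, spec.ltr_divergence, [hhr_span], rng)
    mutations.extend((n_hhrs - 1) * ulen + p for p in pos)
    parts.append(ltr_last)
    E = "".join(parts)

    cuts = [cut_in_ltr + k * ulen for k in range(n_hhrs)]
    ltrs = [(k * ulen, k * ulen + len(ltr)) for k in range(n_hhrs)]
    spans = [(k * ulen + hhr_span[0], k * ulen + hhr_span[1])
             for k in range(n_hhrs)]
    tsd = _sample_tsd(spec, rng)
    return {
        "cls": cls, "E": E, "tsd": tsd, "cuts": cuts, "ltrs": ltrs,
        "hhr_spans": spans, "monomer_length": ulen, "n_units": n_hhrs - 1,
        "params": {"ltr_length": spec.ltr_length, "internal_length": ilen,
                   "mutations": mutations},
    }


def _make_solo(spec, rng, desc, boxes):
    ltr, cut_in_ltr, hhr_span = _make_ltr(spec, desc, boxes, rng)
    return {"cls": "solo_LTR", "E": ltr, "tsd": _sample_tsd(spec, rng),
            "cuts": [cut_in_ltr], "ltrs": [(0, len(ltr))],
            "hhr_spans": [hhr_span], "monomer_length": None, "n_units": 1,
            "params": {"ltr_length": spec.ltr_length}}


def _break_core(motif: str, cut: int, record: dict, rng):
    """One substitution at a random non-N core position (a decoy that the
    structural scan must never report)."""
    candidates = [(off, code) for off, code in record["core_offsets"]
                  if code != "N"]
    off, code = candidates[int(rng.integers(0, len(candidates)))]
    bad = [b for b in "ACGT" if b not in iupac_choices(code)]
    out = list(motif)
    out[off] = rng.choice(bad)
    return "".join(out), off


def _make_decoy(kind: str, spec, rng, desc, boxes):
    if kind == "core_mutant":
        motif, cut, rec = make_hhr(desc, spec.hhr_topology, rng)
        broken, _ = _break_core(motif, cut, rec, rng)
        d = make_retrozyme(spec, rng, desc, boxes, cls="decoy_core_mutant",
                           motif=broken, cut=cut)
        d["cuts"] = []
        d["hhr_spans"] = []
        d["monomer_length"] = None
        return d
    if kind == "shuffled_monomer":
        full = make_retrozyme(spec, rng, desc, boxes)
        mono = full["E"][full["cuts"][0]:full["cuts"][1]]
        return {"cls": "decoy_shuffled_monomer",
                "E": mononucleotide_shuffle(mono, rng), "tsd": None,
                "cuts": [], "ltrs": [], "hhr_spans": [],
                "monomer_length": None, "n_units": 0, "params": {}}
    if kind == "stray_hhr_pair":
        m1, c1, _ = make_hhr(desc, spec.hhr_topology, rng)
        m2, c2, _ = make_hhr(desc, spec.hhr_topology, rng)
        d = int(rng.integers(500, 901))
        filler = d - (len(m1) - c1) - c2
        E = m1 + _rand_seq(rng, filler, spec.gc_content) + m2
        return {"cls": "decoy_stray_hhr_pair", "E": E, "tsd": None,
                "cuts": [c1, c1 + d], "ltrs": [],
                "hhr_spans": [(0, len(m1)), (len(E) - len(m2), len(E))],
                "monomer_length": None, "n_units": 0, "params": {}}
    if kind == "ltr_pair_no_hhr":
        # a full-element skeleton whose "hammerhead" is plain filler
        fake = _rand_seq(rng, 70, 0.5)
        d = make_retrozyme(spec, rng, desc, boxes,
                           cls="decoy_ltr_pair_no_hhr", motif=fake, cut=0)
        d["cuts"] = []
        d["hhr_spans"] = []
        d["monomer_length"] = None
        return d
    raise ValueError(f"unknown decoy kind {kind!r}")


# --- genome assembly ------------------------------------------------------


def _place(rng, n_items: int, bg_len: int, min_gap: int, margin: int = 1000,
           max_tries: int = 1000) -> list[int]:
    for _ in range(max_tries):
        pos = sorted(int(p) for p in
                     rng.integers(margin, bg_len - margin, size=n_items))
        if all(b - a >= min_gap for a, b in zip(pos, pos[1:])):
            return pos
    raise RuntimeError("could not place elements without overlap; "
                       "increase genome_length or reduce counts")


def _to_plus(span: tuple[int, int], e_len: int, insert_at: int,
             tsd_len: int, strand: str) -> tuple[int, int]:
    a, b = span
    if strand == "+":
        return insert_at + tsd_len + a, insert_at + tsd_len + b
    return insert_at + tsd_len + e_len - b, insert_at + tsd_len + e_len - a


def build_genome(spec: SyntheticSpec | None = None,
                 desc: HHRDescriptor | None = None,
                 boxes: BoxConsensus | None = None):
    """Assemble the synthetic chromosome and its ground truth.

    Returns ([GenomeRecord], [TruthRecord]).  Elements are placed
    uniformly at random with a minimum inter-insert gap; the same seed
    yields byte-identical output.
    """
    spec = spec or SyntheticSpec()
    desc = desc or HHRDescriptor()
    boxes = boxes or BoxConsensus()
    rng = np.random.default_rng(spec.seed)

    items = []
    for _ in range(spec.n_full):
        items.append(make_retrozyme(spec, rng, desc, boxes))
    for _ in range(spec.n_solo):
        items.append(_make_solo(spec, rng, desc, boxes))
    for _ in range(spec.n_multimer):
        n = int(rng.choice([3, 4]))
        items.append(make_retrozyme(spec, rng, desc, boxes, n_hhrs=n,
                                    cls="multimeric_retrozyme"))
    for i in range(spec.n_decoys):
        items.append(_make_decoy(DECOY_KINDS[i % len(DECOY_KINDS)],
                                 spec, rng, desc, boxes))

    total = sum(len(it["E"]) + 2 * len(it["tsd"] or "") for it in items)
    if total >= spec.genome_length:
        raise ValueError("total planted length exceeds genome_length")

    order = rng.permutation(len(items))
    background = _rand_seq(rng, spec.genome_length, spec.gc_content)
    positions = _place(rng, len(items), spec.genome_length, spec.min_gap)

    strands = []
    for idx in order:
        if spec.strand == "both":
            strands.append("+" if rng.random() < 0.5 else "-")
        else:
            strands.append(spec.strand)

    pieces = []
    truths: list[TruthRecord] = []
    prev = 0
    offset = 0
    for slot, idx in enumerate(order):
        it = items[idx]
        strand = strands[slot]
        p = positions[slot]
        pieces.append(background[prev:p])
        offset_here = p + offset
        tsd = it["tsd"] or ""
        E = it["E"]
        body = E if strand == "+" else revcomp(E)
        insert = tsd + body + tsd
        pieces.append(insert)
        e_len = len(E)
        elem = Interval(spec.contig_id, offset_here + len(tsd),
                        offset_here + len(tsd) + e_len, strand)
        # between-base cut index maps as: plus_cut = origin + (e_len - c)
        if strand == "-":
            cuts = sorted(offset_here + len(tsd) + e_len - c
                          for c in it["cuts"])
        else:
            cuts = sorted(offset_here + len(tsd) + c for c in it["cuts"])
        ltrs = tuple(Interval(spec.contig_id,
                              *_to_plus(s, e_len, offset_here, len(tsd),
                                        strand), strand)
                     for s in it["ltrs"])
        spans = tuple(Interval(spec.contig_id,
                               *_to_plus(s, e_len, offset_here, len(tsd),
                                         strand), strand)
                      for s in it["hhr_spans"])
        truths.append(TruthRecord(
            cls=it["cls"], element=elem, ltrs=ltrs, hhr_spans=spans,
            cleavage_positions=tuple(cuts), tsd=it["tsd"] or None,
            monomer_length=it["monomer_length"], n_units=it["n_units"],
            params=it["params"]))
        prev = p
        offset += len(insert)
    pieces.append(background[prev:])
    seq = "".join(pieces)

    seq, truths = _disambiguate_tsds(seq, truths, spec, rng)
    rec = GenomeRecord(spec.contig_id, seq)
    truths.sort(key=lambda t: t.element.start)
    return [rec], truths


def _disambiguate_tsds(seq: str, truths: Sequence[TruthRecord],
                       spec: SyntheticSpec, rng):
    """Ensure each planted TSD is the unique best boundary duplication.

    Random flank bases occasionally create a longer spurious duplication
    near the insertion point, which would make the annotated TSD (and the
    recorded boundaries) ambiguous; the offending flank background (and,
    if that is not enough, the TSD itself) is resampled.  Flanks are pure
    background by the min-gap placement guarantee, so this never touches
    another planted item.
    """
    s = list(seq)
    k = spec.tsd_length
    out: list[TruthRecord] = []
    for t in truths:
        if t.tsd is None:
            out.append(t)
            continue
        st, en = t.element.start, t.element.end
        tsd = t.tsd
        for attempt in range(50):
            found = find_tsd(st, en, "".join(s), (6, 5, 4), 12)
            if (found is not None and found[2] == k
                    and found[3] == st and found[4] == en):
                break
            for pos in list(range(st - k - 18, st - k)) + \
                    list(range(en + k, en + k + 18)):
                s[pos] = _rand_seq(rng, 1, spec.gc_content)
            if attempt >= 10:
                tsd = _sample_tsd(spec, rng)
                s[st - k:st] = list(tsd)
                s[en:en + k] = list(tsd)
        else:
            raise RuntimeError("could not disambiguate a planted TSD")
        out.append(replace(t, tsd=tsd) if tsd != t.tsd else t)
    return "".join(s), out
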