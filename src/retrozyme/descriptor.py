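"""Parametric model of the hammerhead ribozyme motif.

The hammerhead is modeled as a cycle

    [helix I] - core_seg_A - [helix II + loop2] - core_seg_B -
    [helix III + loop3] - cleavage_context ^cut - cut_adjacent - [helix I]

A genomic motif linearizes the cycle by opening exactly one helix; the
opened helix's two arms become the motif's outermost complementary arms
and define the topology type (I, II or III).  Only types I and III occur
in plants; type II scanning is implemented but off by default.

Sequences are handled DNA-side (U -> T), so the catalytic core defaults
are the DNA spellings of CUGANGA / GAAA / NUH with an invariant C
immediately 3' of the cut.  Counting every position of the two core
segments, the cleavage triplet and the invariant cut-adjacent residue
gives the 15 conserved catalytic-core positions of the motif.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = ["HHRDescriptor", "matches_iupac", "iupac_choices", "PAIR_WEIGHT", "is_pair"]

# IUPAC degenerate-code expansion (DNA side).  A genomic N never matches a
# descriptor position, including descriptor N.
_IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def iupac_choices(code: str) -> str:
    return _IUPAC_SETS[code]


def matches_iupac(base: str, code: str) -> bool:
    return base in _IUPAC_SETS[code]


# Helix-stability weights (DNA spelling; GT is the G.U wobble).
PAIR_WEIGHT = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "T"): 2, ("T", "A"): 2,
    ("G", "T"): 1, ("T", "G"): 1,
}

_WOBBLE = {("G", "T"), ("T", "G")}


def is_pair(a: str, b: str, allow_wobble: bool = True) -> bool:
    p = (a, b)
    if p in _WOBBLE:
        return allow_wobble
    return p in PAIR_WEIGHT


def helix_pairing(arm5: str, arm3: str, max_wobbles: int) -> int | None:
    """Score of an antiparallel helix ``arm5``/``arm3``; None if the arms do
    not pair under Watson-Crick + at most ``max_wobbles`` G.T wobbles."""
    n = len(arm5)
    if len(arm3) != n:
        return None
    score = 0
    wob = 0
    for i in range(n):
        p = (arm5[i], arm3[n - 1 - i])
        w = PAIR_WEIGHT.get(p)
        if w is None:
            return None
        if p in _WOBBLE:
            wob += 1
            if wob > max_wobbles:
                return None
        score += w
    return score


@dataclass(frozen=True)
class HHRDescriptor:
    """Tunable hammerhead descriptor; defaults span typical plant HHRs."""

    core_seg_A: str = "CTGANGA"      # between helix I and helix II
    core_seg_B: str = "GAAA"         # between helix II and helix III
    cleavage_context: str = "NTH"    # immediately 5' of the cut
    cut_adjacent: str = "C"          # invariant residue immediately 3' of the cut
    helix1_len: tuple[int, int] = (3, 7)
    helix2_len: tuple[int, int] = (3, 6)
    helix3_len: tuple[int, int] = (2, 5)
    loop_len: tuple[int, int] = (3, 20)
    max_wobbles_per_helix: int = 1
    tertiary_allow_wobble: bool = False
    min_tertiary_pairs: int = 2
    type1_distal_window: int = 6     # arm window standing in for loop 1 in type I
    topologies: tuple[str, ...] = ("I", "III")

    def __post_init__(self) -> None:
        for seg in (self.core_seg_A, self.core_seg_B, self.cleavage_context,
                    self.cut_adjacent):
            if not seg or any(c not in _IUPAC_SETS for c in seg):
                raise ValueError(f"core segment {seg!r} is not IUPAC")
        if not self.topologies:
            raise ValueError("descriptor needs a non-empty topology set")
        if any(t not in ("I", "II", "III") for t in self.topologies):
            raise ValueError(f"unknown topology in {self.topologies}")
        for lo, hi in (self.helix1_len, self.helix2_len, self.helix3_len):
            if not 1 <= lo <= hi:
                raise ValueError("helix length ranges must be non-empty with min >= 1")
        if not 3 <= self.loop_len[0] <= self.loop_len[1]:
            raise ValueError("loop length range must be non-empty with min >= 3")

    @property
    def n_core_positions(self) -> int:
        """Number of core-constrained positions (15 under defaults)."""
        return (len(self.core_seg_A) + len(self.core_seg_B)
                + len(self.cleavage_context) + len(self.cut_adjacent))

    @property
    def seed_word(self) -> str:
        """Least-degenerate exact word of core_seg_A used to seed the scan."""
        best = ""
        cur = ""
        for c in self.core_seg_A:
            if _IUPAC_SETS[c] == c:  # concrete base
                cur += c
                if len(cur) > len(best):
                    best = cur
            else:
                cur = ""
        if not best:
            raise ValueError("core_seg_A has no exact sub-word to seed on")
        return best

    @property
    def seed_offset(self) -> int:
        return self.core_seg_A.index(self.seed_word)

    def with_topologies(self, *tops: str) -> "HHRDescriptor":
        return replace(self, topologies=tuple(tops))

    def helix_range(self, helix: int) -> tuple[int, int]:
        return (self.helix1_len, self.helix2_len, self.helix3_len)[helix - 1]

    @property
    def max_span(self) -> int:
        """Upper bound on the linearized motif length (any topology)."""
        return (2 * (self.helix1_len[1] + self.helix2_len[1] + self.helix3_len[1])
                + 2 * self.loop_len[1]
                + len(self.core_seg_A) + len(self.core_seg_B)
                + len(self.cleavage_context) + len(self.cut_adjacent))

    @property
    def min_span(self) -> int:
        return (2 * (self.helix1_len[0] + self.helix2_len[0] + self.helix3_len[0])
                + 2 * self.loop_len[0]
                + len(self.core_seg_A) + len(self.core_seg_B)
                + len(self.cleavage_context) + len(self.cut_adjacent))
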