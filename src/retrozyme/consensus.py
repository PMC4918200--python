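"""Consensus strings and column statistics for aligned sequence sets.

The rendering follows the convention used for retrozyme box and
hammerhead alignments: totally conserved columns are uppercase (a base,
or R/Y when a purine/pyrimidine class is total), columns conserved in
70-100% of sequences are lowercase, and columns below 70% conservation
are dots.  Gaps are excluded from the per-column denominator.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = ["AlignedSet", "build_consensus", "column_frequencies",
           "center_star_align"]

_PURINES = set("AG")
_PYRIMIDINES = set("CTU")


@dataclass(frozen=True)
class AlignedSet:
    """Equal-length gapped rows over {A,C,G,T,U,-}."""

    ids: tuple
    rows: tuple

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("an alignment needs at least two rows")
        n = len(self.rows[0])
        if any(len(r) != n for r in self.rows):
            raise ValueError("alignment rows differ in length")

    @classmethod
    def from_pairs(cls, pairs) -> "AlignedSet":
        ids, rows = zip(*pairs)
        return cls(tuple(ids), tuple(r.upper() for r in rows))

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def column(self, i: int) -> str:
        return "".join(r[i] for r in self.rows)


def _column_symbol(col: str, full: float, partial: float) -> str:
    bases = [c for c in col if c != "-"]
    n = len(bases)
    if n == 0:
        return "."
    counts = Counter(bases)
    top_base, top = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
    pur = sum(v for b, v in counts.items() if b in _PURINES)
    pyr = sum(v for b, v in counts.items() if b in _PYRIMIDINES)
    eps = 1e-9
    if top >= full * n - eps:
        return top_base.upper()
    if pur >= full * n - eps:
        return "R"
    if pyr >= full * n - eps:
        return "Y"
    if top >= partial * n - eps:
        return top_base.lower()
    if pur >= partial * n - eps:
        return "r"
    if pyr >= partial * n - eps:
        return "y"
    return "."


def build_consensus(aln: AlignedSet, full: float = 1.0,
                    partial: float = 0.70) -> str:
    """Consensus string under the uppercase/lowercase/dot rendering rules."""
    if not 0 < partial < full <= 1:
        raise ValueError("need 0 < partial < full <= 1")
    return "".join(_column_symbol(aln.column(i), full, partial)
                   for i in range(aln.n_columns))


def column_frequencies(aln: AlignedSet) -> pd.DataFrame:
    """Per-column base frequencies (gap-excluded denominator)."""
    rows = []
    for i in range(aln.n_columns):
        col = [c for c in aln.column(i) if c != "-"]
        n = len(col)
        counts = Counter(col)
        row = {"column": i, "n_nongap": n}
        for b, v in sorted(counts.items()):
            row[b] = v / n
        rows.append(row)
    return pd.DataFrame(rows).fillna(0.0)


# --- a minimal aligner for synthetic fixtures ----------------------------


def _nw(a: str, b: str, match: int = 1, mismatch: int = -1, gap: int = -2):
    """Global alignment (Needleman-Wunsch) returning the two gapped rows.

    Deliberately simple: it only serves to build alignment fixtures for
    near-identical synthetic sequences, not to compete with a real MSA
    program."""
    n, m = len(a), len(b)
    score = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        score[i][0] = i * gap
    for j in range(1, m + 1):
        score[0][j] = j * gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            d = score[i - 1][j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            score[i][j] = max(d, score[i - 1][j] + gap, score[i][j - 1] + gap)
    ra, rb = [], []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i][j] == score[i - 1][j - 1] + (
                match if a[i - 1] == b[j - 1] else mismatch):
            ra.append(a[i - 1])
            rb.append(b[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and score[i][j] == score[i - 1][j] + gap:
            ra.append(a[i - 1])
            rb.append("-")
            i -= 1
        else:
            ra.append("-")
            rb.append(b[j - 1])
            j -= 1
    return "".join(reversed(ra)), "".join(reversed(rb))


def center_star_align(seqs: Sequence[str], ids: Sequence[str] | None = None
                      ) -> AlignedSet:
    """Center-star multiple alignment (+1/-1/-2) for test fixtures."""
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    ids = tuple(ids) if ids is not None else tuple(
        f"seq{i}" for i in range(len(seqs)))
    # center = sequence with the best summed pairwise score proxy (length tie
    # broken by order); for near-identical fixtures the first is fine, but
    # pick the medoid by total pairwise identity to be principled
    center = 0
    if len(seqs) > 2:
        best = None
        for i, s in enumerate(seqs):
            tot = sum(sum(x == y for x, y in zip(*_nw(s, t)))
                      for j, t in enumerate(seqs) if j != i)
            if best is None or tot > best[0]:
                best = (tot, i)
        center = best[1]

    master = seqs[center]
    aligned = {center: master}
    for i, s in enumerate(seqs):
        if i == center:
            continue
        ac, ai = _nw(master, s)
        # merge: propagate any new master gaps into previously aligned rows
        if ac != master:
            merged = {}
            for k, row in aligned.items():
                out, pos = [], 0
                for c in ac:
                    if c == "-":
                        out.append("-")
                    else:
                        out.append(row[pos])
                        pos += 1
                merged[k] = "".join(out)
            aligned = merged
            master = ac
        aligned[i] = ai
    rows = tuple(aligned[i] for i in range(len(seqs)))
    return AlignedSet(ids, rows)
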