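"""Sequence I/O, coordinate conventions and feature writers.

All internal coordinates are 0-based half-open on the plus strand; the
GFF3 writer converts to 1-based inclusive on output and the reader
converts back.  Minus-strand intervals store plus-strand coordinates and
sequence retrieval reverse-complements.  Cleavage positions are
between-base indices ``i`` (the cut falls between ``seq[i-1]`` and
``seq[i]``) on the plus strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomeRecord",
    "Interval",
    "read_fasta",
    "write_fasta",
    "fetch",
    "revcomp",
    "normalize_seq",
    "write_gff3",
    "read_gff3",
    "write_bed6",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# IUPAC one-letter nucleotide codes; everything outside {A,C,G,T,U} is
# conservatively collapsed to N and never matches a descriptor position.
_IUPAC = set("ACGTUNRYSWKMBDHV")


def revcomp(seq: str) -> str:
    """Reverse complement over the normalized {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_seq(seq: str, *, context: str = "") -> str:
    """Uppercase, U->T, non-ACGTN IUPAC codes -> N. Reject anything else."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - _IUPAC
    if bad:
        raise ValueError(
            f"non-IUPAC characters {sorted(bad)} in sequence {context or '<anonymous>'}"
        )
    return "".join(c if c in "ACGTN" else "N" for c in s)


@dataclass(frozen=True)
class GenomeRecord:
    """One FASTA record, normalized to the {A,C,G,T,N} alphabet."""

    id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open interval on the plus strand of ``contig``."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def reciprocal_overlap(self, other: "Interval") -> float:
        """min(overlap/len(self), overlap/len(other)); 0 if disjoint."""
        if not self.overlaps(other):
            return 0.0
        ov = min(self.end, other.end) - max(self.start, other.start)
        return min(ov / len(self), ov / len(other))


GenomeDict = dict[str, GenomeRecord]


def as_genome_dict(genome) -> GenomeDict:
    if isinstance(genome, dict):
        return genome
    if isinstance(genome, GenomeRecord):
        return {genome.id: genome}
    return {rec.id: rec for rec in genome}


def read_fasta(path) -> list[GenomeRecord]:
    """Read a (multi-)FASTA file into normalized :class:`GenomeRecord` s.

    Raises on empty files, duplicate ids and non-IUPAC characters, naming
    the offending record.
    """
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(GenomeRecord(rec.id, normalize_seq(str(rec.seq), context=rec.id)))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[GenomeRecord], path, width: int = 70) -> None:
    seqs = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def fetch(interval: Interval, genome) -> str:
    """Sequence of ``interval``: plus-strand slice, reverse-complemented
    for minus-strand intervals."""
    gd = as_genome_dict(genome)
    if interval.contig not in gd:
        raise KeyError(f"unknown contig {interval.contig!r}")
    rec = gd[interval.contig]
    if interval.end > len(rec):
        raise ValueError(
            f"interval [{interval.start},{interval.end}) out of bounds for "
            f"{interval.contig} (length {len(rec)})"
        )
    s = rec.seq[interval.start : interval.end]
    return revcomp(s) if interval.strand == "-" else s


# ---------------------------------------------------------------------------
# Feature writers.  A "feature" here is a small dict-like payload; the
# annotate/scan modules provide ``to_gff_features()`` adapters producing
# (type, Interval, attributes, parent_id) tuples.
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GffFeature:
    ftype: str
    interval: Interval
    attributes: dict
    score: float | None = None


def _fmt_attrs(attrs: dict) -> str:
    if not attrs:
        return "."
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def write_gff3(features: Sequence[GffFeature], path, source: str = "retrozyme") -> None:
    """Write GFF3 with 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            iv = f.interval
            score = "." if f.score is None else f"{f.score:g}"
            fh.write(
                "\t".join(
                    [
                        iv.contig,
                        source,
                        f.ftype,
                        str(iv.start + 1),
                        str(iv.end),
                        score,
                        iv.strand,
                        ".",
                        _fmt_attrs(f.attributes),
                    ]
                )
                + "\n"
            )


def read_gff3(path) -> list[GffFeature]:
    """Re-parse a GFF3 file written by :func:`write_gff3` (round-trip exact)."""
    feats: list[GffFeature] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        contig, _source, ftype, start, end, score, strand, _phase, attrs = line.split("\t")
        attributes = {}
        if attrs != ".":
            for kv in attrs.split(";"):
                k, _, v = kv.partition("=")
                attributes[k] = v
        feats.append(
            GffFeature(
                ftype,
                Interval(contig, int(start) - 1, int(end), strand),
                attributes,
                None if score == "." else float(score),
            )
        )
    return feats


def write_bed6(features: Sequence[GffFeature], path) -> None:
    """BED6 writer (0-based half-open, as stored internally)."""
    with open(path, "w") as fh:
        for f in features:
            iv = f.interval
            name = f.attributes.get("ID", f.ftype)
            score = 0 if f.score is None else int(round(f.score))
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )
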