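"""Reference model: genome, miRNA precursors, flank expansion and naming.

The unit from which candidate isomiRs are enumerated is the *expanded
precursor*: the database precursor padded with genomic flanks (default 6 nt
on each side) so that isoforms extending past a possibly-truncated database
annotation, or arising from an unannotated arm, can still be reported.

Two naming schemes live here:

* **offset labels** ``name|d5|d3`` — database-relative: how far the isomiR's
  5' start and 3' end sit from the database's mature ("reference") miRNA,
  measured in precursor orientation, negative meaning upstream (toward 5').
* **genome-anchored labels**
  ``<precursor>&WithFlank&<chrom>|<strand>|<gStart>|<gEnd>@<s>.<e>.<len>``
  — assembly-dependent: the flank-padded precursor's genomic span plus the
  isomiR's 1-based inclusive span within the expanded precursor.

All user-visible coordinates are 1-based inclusive.  The working alphabet
is DNA (T, not U); sequences containing other letters are rejected or, for
N in the genome, simply never enumerated.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "Genome",
    "MatureReference",
    "Precursor",
    "ExpandedPrecursor",
    "Placement",
    "ReferenceError",
    "revcomp",
    "expand_precursor",
    "offset_label",
    "genome_label",
    "alternative_labels",
    "load_precursors",
    "write_precursors",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DB_TAGS = ("miRBase", "miRCarta", "other")


class ReferenceError(ValueError):
    """Invalid genome/annotation input."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


class Genome:
    """An in-memory reference genome: chromosome name -> uppercase sequence.

    Whole chromosomes are held in memory because both the exhaustive
    genome-wide substring search of the table builder and the scanning
    oracle need fast random access to full sequences.
    """

    def __init__(self, chroms: Mapping[str, str]):
        if not chroms:
            raise ReferenceError("genome has no chromosomes")
        self._chroms: dict[str, str] = {}
        for name, seq in chroms.items():
            s = seq.upper()
            if not s:
                raise ReferenceError(f"chromosome {name!r} is empty")
            if set(s) - set("ACGTN"):
                bad = sorted(set(s) - set("ACGTN"))
                raise ReferenceError(f"chromosome {name!r} has non-ACGTN characters {bad}")
            if name in self._chroms:
                raise ReferenceError(f"duplicate chromosome name {name!r}")
            self._chroms[name] = s

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._chroms

    def __getitem__(self, chrom: str) -> str:
        try:
            return self._chroms[chrom]
        except KeyError:
            raise ReferenceError(f"chromosome {chrom!r} not in genome") from None

    def chroms(self) -> list[str]:
        return sorted(self._chroms)

    def length(self, chrom: str) -> int:
        return len(self[chrom])

    def slice(self, chrom: str, start: int, end: int) -> str:
        """1-based inclusive forward-strand slice."""
        seq = self[chrom]
        if not (1 <= start <= end <= len(seq)):
            raise ReferenceError(
                f"span {chrom}:{start}-{end} outside chromosome bounds (1-{len(seq)})"
            )
        return seq[start - 1 : end]


@dataclass(frozen=True)
class MatureReference:
    """A database's mature miRNA ("reference miRNA") within its precursor.

    ``offset_in_precursor`` is the 1-based start within the *un-expanded*
    precursor, in precursor orientation.
    """

    name: str
    offset_in_precursor: int
    length: int

    def __post_init__(self):
        if self.offset_in_precursor < 1 or self.length < 1:
            raise ReferenceError(f"invalid mature reference {self.name!r}")


@dataclass(frozen=True)
class Precursor:
    name: str
    db_tag: str
    chrom: str
    strand: str
    start: int  # 1-based inclusive, genomic
    end: int
    matures: tuple[MatureReference, ...] = ()

    def __post_init__(self):
        if self.db_tag not in DB_TAGS:
            raise ReferenceError(f"unknown db tag {self.db_tag!r} (expected one of {DB_TAGS})")
        if self.strand not in "+-":
            raise ReferenceError(f"invalid strand {self.strand!r} for {self.name}")
        if self.start > self.end:
            raise ReferenceError(f"precursor {self.name}: start > end")
        for m in self.matures:
            if m.offset_in_precursor + m.length - 1 > self.end - self.start + 1:
                raise ReferenceError(
                    f"mature {m.name} does not lie fully within precursor {self.name}"
                )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ExpandedPrecursor:
    """A precursor padded with genomic flanks and anchored to the genome.

    ``flank_lo``/``flank_hi`` are the padding actually applied below
    ``parent.start`` and above ``parent.end`` in genomic coordinates; they
    equal the requested flank unless clipped at a chromosome edge
    (``clipped`` is then set).  ``sequence`` is precursor-oriented: for a
    minus-strand precursor it is the reverse complement of the forward
    genomic slice of the padded span.
    """

    parent: Precursor
    flank_lo: int
    flank_hi: int
    sequence: str
    clipped: bool = False

    @property
    def genomic_start(self) -> int:
        return self.parent.start - self.flank_lo

    @property
    def genomic_end(self) -> int:
        return self.parent.end + self.flank_hi

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def flank5(self) -> int:
        """Flank length on the precursor's 5' side (orientation-aware)."""
        return self.flank_lo if self.parent.strand == "+" else self.flank_hi

    def genomic_coord(self, pos: int) -> int:
        """Map a 1-based position in the expanded sequence to its genomic coordinate."""
        if not 1 <= pos <= self.length:
            raise ReferenceError(f"position {pos} outside expanded precursor {self.parent.name}")
        if self.parent.strand == "+":
            return self.genomic_start + pos - 1
        return self.genomic_end - pos + 1

    def position_of(self, gcoord: int) -> int:
        """Inverse of :meth:`genomic_coord`."""
        if not self.genomic_start <= gcoord <= self.genomic_end:
            raise ReferenceError(
                f"genomic coordinate {gcoord} outside expanded span of {self.parent.name}"
            )
        if self.parent.strand == "+":
            return gcoord - self.genomic_start + 1
        return self.genomic_end - gcoord + 1

    def mature_span(self, mature: MatureReference) -> tuple[int, int]:
        """(start, end), 1-based inclusive, of a mature reference in expanded coordinates."""
        start = mature.offset_in_precursor + self.flank5
        return start, start + mature.length - 1


@dataclass(frozen=True)
class Placement:
    """An isomiR's location within one expanded precursor (1-based inclusive)."""

    precursor: ExpandedPrecursor
    start: int
    length: int

    def __post_init__(self):
        if self.start < 1 or self.start + self.length - 1 > self.precursor.length:
            raise ReferenceError(
                f"placement {self.start}+{self.length} outside expanded precursor "
                f"{self.precursor.parent.name} (length {self.precursor.length})"
            )

    @property
    def end(self) -> int:
        return self.start + self.length - 1

    def sort_key(self):
        p = self.precursor.parent
        return (p.db_tag, p.name, self.start, self.length)


def expand_precursor(p: Precursor, genome: Genome, flank: int = 6) -> ExpandedPrecursor:
    """Pad a precursor with genomic flanks and extract its oriented sequence.

    Flanks falling off a chromosome end are clipped (and the result flagged);
    a precursor whose own span exceeds the chromosome, or whose chromosome is
    absent, is a hard error.
    """
    if flank < 0:
        raise ReferenceError("flank must be >= 0")
    chrom_len = genome.length(p.chrom)
    if not (1 <= p.start and p.end <= chrom_len):
        raise ReferenceError(
            f"precursor {p.name} span {p.start}-{p.end} exceeds chromosome {p.chrom}"
        )
    flank_lo = min(flank, p.start - 1)
    flank_hi = min(flank, chrom_len - p.end)
    fwd = genome.slice(p.chrom, p.start - flank_lo, p.end + flank_hi)
    seq = fwd if p.strand == "+" else revcomp(fwd)
    return ExpandedPrecursor(
        parent=p,
        flank_lo=flank_lo,
        flank_hi=flank_hi,
        sequence=seq,
        clipped=(flank_lo != flank or flank_hi != flank),
    )


def offset_label(mature: MatureReference, placement: Placement) -> str:
    """Database-relative label ``name|d5|d3``.

    d5 = isomiR 5' start minus the mature reference's 5' start, d3 the same
    for the 3' ends, both in precursor orientation: negative values mean the
    isomiR's end lies upstream (toward the 5' side) of the reference's.
    """
    m_start, m_end = placement.precursor.mature_span(mature)
    d5 = placement.start - m_start
    d3 = placement.end - m_end
    return f"{mature.name}|{d5}|{d3}"


def genome_label(placement: Placement) -> str:
    """Genome-anchored ``&WithFlank&`` label for a placement."""
    xp = placement.precursor
    p = xp.parent
    return (
        f"{p.name}&WithFlank&{p.chrom}|{p.strand}|{xp.genomic_start}|{xp.genomic_end}"
        f"@{placement.start}.{placement.end}.{placement.length}"
    )


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start <= b_end and b_start <= a_end


def alternative_labels(placements: Iterable[Placement]) -> list[str]:
    """All offset labels of a sequence across every loaded reference set.

    One label per (reference set, mature reference) whose span overlaps a
    placement of the sequence.  Disagreements between databases are kept
    verbatim, never reconciled: the same molecule may legitimately be
    ``x|0|0`` in one collection and ``y|0|-2`` in another.
    """
    labels = set()
    for pl in placements:
        for m in pl.precursor.parent.matures:
            m_start, m_end = pl.precursor.mature_span(m)
            if _overlaps(pl.start, pl.end, m_start, m_end):
                labels.add(offset_label(m, pl))
    return sorted(labels)


def placements_of(seq: str, expanded: Iterable[ExpandedPrecursor]) -> list[Placement]:
    """Every occurrence of ``seq`` within the given expanded precursors."""
    out = []
    for xp in expanded:
        start = xp.sequence.find(seq)
        while start != -1:
            out.append(Placement(xp, start + 1, len(seq)))
            start = xp.sequence.find(seq, start + 1)
    return sorted(out, key=Placement.sort_key)


# ---------------------------------------------------------------------------
# Annotation I/O: a documented TSV dialect.
#
# Columns (tab-separated, one precursor per row, '#' comment lines allowed):
#   db      miRBase | miRCarta | other
#   name    precursor name, unique within its db
#   chrom   chromosome name matching the genome FASTA
#   strand  + | -
#   start   1-based inclusive genomic start
#   end     1-based inclusive genomic end
#   matures semicolon-joined "name:offset:length" entries (may be empty);
#           offset is the 1-based start within the un-expanded precursor,
#           in precursor orientation.

_PRECURSOR_HEADER = ["db", "name", "chrom", "strand", "start", "end", "matures"]


def load_precursors(path: str | Path) -> list[Precursor]:
    """Read precursor/mature annotations from the TSV dialect above."""
    opener = gzip.open if str(path).endswith(".gz") else open
    out = []
    seen = set()
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.split("\t") == _PRECURSOR_HEADER:
                continue
            fields = line.split("\t")
            if len(fields) != len(_PRECURSOR_HEADER):
                raise ReferenceError(f"{path}:{lineno}: expected {len(_PRECURSOR_HEADER)} columns")
            db, name, chrom, strand, start, end, matures = fields
            mats = []
            if matures:
                for entry in matures.split(";"):
                    mname, off, mlen = entry.split(":")
                    mats.append(MatureReference(mname, int(off), int(mlen)))
            if (db, name) in seen:
                raise ReferenceError(f"{path}:{lineno}: duplicate precursor {db}/{name}")
            seen.add((db, name))
            out.append(
                Precursor(name, db, chrom, strand, int(start), int(end), tuple(mats))
            )
    return sorted(out, key=lambda p: (p.db_tag, p.name))


def write_precursors(precursors: Iterable[Precursor], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_PRECURSOR_HEADER) + "\n")
        for p in sorted(precursors, key=lambda p: (p.db_tag, p.name)):
            mats = ";".join(
                f"{m.name}:{m.offset_in_precursor}:{m.length}" for m in p.matures
            )
            fh.write(
                "\t".join([p.db_tag, p.name, p.chrom, p.strand, str(p.start), str(p.end), mats])
                + "\n"
            )
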