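"""Offline construction of the k-mer lookup tables.

The profiler never aligns reads.  Instead, an offline build enumerates every
candidate isomiR — every substring of length 18-26 nt of every flank-expanded
precursor in the selected reference set — and resolves, once and for all:

* every placement of the candidate within every loaded reference set
  (for database-relative labels);
* every exact genomic instance of the candidate, on both strands of every
  chromosome (deterministic exhaustive search);
* whether the candidate is *exclusive* to miRNA-space (the union of
  flank-expanded precursor intervals of the selected set) or *ambiguous*
  (at least one instance elsewhere);
* which RepeatMasker classes fully contain any of its instances.

A second, disjoint table precomputes *variant-containing* candidates: each
qualifying population variant (MAF >= 1% in at least one reference
population) or somatic mutation is applied alone to the expanded precursor
sequence, and every edited k-mer covering the edit is recorded together with
its templated counterpart and generating variant(s).

Tables are serialized as versioned plain-text TSV so they are diffable and
can be amended by hand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .reference import (
    ExpandedPrecursor,
    Genome,
    MatureReference,
    Placement,
    Precursor,
    ReferenceError,
    expand_precursor,
    placements_of,
    revcomp,
)

__all__ = [
    "GenomicInstance",
    "KmerRecord",
    "Variant",
    "VariantKmerRecord",
    "LookupTableBundle",
    "MirnaSpace",
    "RepeatAnnotation",
    "TableError",
    "REPEAT_CLASSES",
    "KMIN",
    "KMAX",
    "enumerate_candidates",
    "find_genomic_instances",
    "classify_exclusivity",
    "annotate_repeats",
    "build_variant_table",
    "build_tables",
    "serialize_bundle",
    "load_bundle",
    "load_variants",
]

KMIN = 18
KMAX = 26

FORMAT_VERSION = "1"

#: The 20 RepeatMasker repeat classes recognized for overlap annotation.
REPEAT_CLASSES = frozenset(
    {
        "SINE", "SINE?", "LINE", "RC", "RC?", "RNA", "scRNA", "srpRNA", "rRNA",
        "tRNA", "DNA", "DNA?", "snRNA", "Retroposon", "Unknown", "LTR", "LTR?",
        "Satellite", "Low_complexity", "Simple_repeat",
    }
)

SNP_SOURCES = ("dbSNP", "gnomAD")
SOMATIC_SOURCES = ("COSMIC",)
MAF_THRESHOLD = 0.01


class TableError(ValueError):
    """Invalid table-build input or corrupt serialized table."""


@dataclass(frozen=True)
class GenomicInstance:
    """One exact genomic occurrence of a k-mer (1-based inclusive span).

    On the minus strand the occurrence means the k-mer equals the reverse
    complement of the forward-strand slice.
    """

    chrom: str
    strand: str
    start: int
    end: int
    inside_mirna_space: bool | None = None

    def sort_key(self):
        return (self.chrom, self.start, self.strand)


@dataclass
class KmerRecord:
    """A wild-type candidate isomiR with all its annotations."""

    seq: str
    placements: list[Placement]
    instances: list[GenomicInstance]
    exclusive: str  # "Y" | "N"
    repeat_classes: list[str]


@dataclass(frozen=True)
class Variant:
    """A single-nucleotide replacement, insertion or deletion (VCF-style).

    ``pos``/``ref``/``alt`` follow VCF conventions on the forward strand:
    an SNV has 1-nt ref and alt; a 1-nt insertion has ref=X alt=XY; a 1-nt
    deletion has ref=XY alt=X.  ``population_afs`` maps population name to
    allele frequency (only meaningful for SNP sources).
    """

    vid: str
    source: str
    chrom: str
    pos: int
    ref: str
    alt: str
    population_afs: tuple[tuple[str, float], ...] = ()

    def __post_init__(self):
        if self.source not in SNP_SOURCES + SOMATIC_SOURCES:
            raise TableError(f"variant {self.vid}: unknown source {self.source!r}")
        r, a = len(self.ref), len(self.alt)
        ok = (
            (r == 1 and a == 1)
            or (r == 1 and a == 2 and self.alt[0] == self.ref)
            or (r == 2 and a == 1 and self.ref[0] == self.alt)
        )
        if not ok:
            raise TableError(
                f"variant {self.vid}: only 1-nt substitutions, insertions and "
                f"deletions are supported (ref={self.ref}, alt={self.alt})"
            )

    @property
    def kind(self) -> str:
        if len(self.ref) == len(self.alt):
            return "snv"
        return "ins" if len(self.alt) > len(self.ref) else "del"

    def passes_frequency_filter(self) -> bool:
        """Somatic mutations always pass; SNPs need MAF >= 1% in >= 1 population."""
        if self.source in SOMATIC_SOURCES:
            return True
        return any(af >= MAF_THRESHOLD for _, af in self.population_afs)


@dataclass
class VariantKmerRecord:
    """A variant-modified candidate isomiR, absent from the wild-type table."""

    seq: str
    variant_ids: list[tuple[str, str]]  # (source, identifier)
    templated_seq: str
    placements: list[Placement]


class MirnaSpace:
    """The union of flank-expanded precursor intervals of one reference set.

    Containment queries ignore strand: a genomic instance on either strand
    of an expanded precursor interval counts as inside miRNA-space, because
    exclusivity is about where a sequence *occurs*, not its orientation.
    """

    def __init__(self, expanded: Iterable[ExpandedPrecursor]):
        self._trees: dict[str, IntervalTree] = {}
        for xp in expanded:
            tree = self._trees.setdefault(xp.parent.chrom, IntervalTree())
            # half-open internally; user-visible coordinates stay 1-based inclusive
            tree.addi(xp.genomic_start, xp.genomic_end + 1)

    def contains(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end] lies fully inside some expanded precursor interval."""
        tree = self._trees.get(chrom)
        if tree is None:
            return False
        return any(iv.begin <= start and end < iv.end for iv in tree.overlap(start, end + 1))


class RepeatAnnotation:
    """RepeatMasker-style repeat intervals with class names.

    Input rows: chrom, start, end (1-based inclusive), class.  Class names
    are validated at load time against the 20 recognized RepeatMasker
    classes.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int, str]]):
        self._trees: dict[str, IntervalTree] = {}
        for chrom, start, end, cls in intervals:
            if cls not in REPEAT_CLASSES:
                raise TableError(f"unknown RepeatMasker class {cls!r}")
            if start > end:
                raise TableError(f"repeat interval {chrom}:{start}-{end} has start > end")
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end + 1, cls)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RepeatAnnotation":
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#") or line.startswith("chrom\t"):
                    continue
                fields = line.split("\t")
                if len(fields) != 4:
                    raise TableError(f"{path}:{lineno}: expected 4 columns")
                chrom, start, end, rcls = fields
                rows.append((chrom, int(start), int(end), rcls))
        return cls(rows)

    def classes_containing(self, chrom: str, start: int, end: int) -> set[str]:
        """Classes of repeat intervals fully containing [start, end]."""
        tree = self._trees.get(chrom)
        if tree is None:
            return set()
        return {
            iv.data for iv in tree.overlap(start, end + 1) if iv.begin <= start and end < iv.end
        }


EMPTY_REPEATS = RepeatAnnotation([])


# ---------------------------------------------------------------------------
# Core build operations


def enumerate_candidates(
    expanded: Sequence[ExpandedPrecursor], kmin: int = KMIN, kmax: int = KMAX
) -> dict[str, list[Placement]]:
    """Every substring of length kmin..kmax of every expanded precursor.

    Returns seq -> all placements, each placement one (precursor, position)
    occurrence.  Substrings containing N are skipped: exact-match lookup is
    undefined for ambiguous bases.
    """
    out: dict[str, list[Placement]] = {}
    for xp in expanded:
        s = xp.sequence
        for k in range(kmin, kmax + 1):
            for i in range(len(s) - k + 1):
                sub = s[i : i + k]
                if "N" in sub:
                    continue
                out.setdefault(sub, []).append(Placement(xp, i + 1, k))
    for placements in out.values():
        placements.sort(key=Placement.sort_key)
    return out


def find_genomic_instances(seq: str, genome: Genome) -> list[GenomicInstance]:
    """Every exact occurrence of ``seq`` on both strands of every chromosome.

    Deterministic, exhaustive: overlapping occurrences are all reported, and
    results are ordered by (chrom, start, strand).  A palindromic sequence
    yields one instance per strand at the same locus.
    """
    if not seq or set(seq) - set("ACGT"):
        raise TableError(f"genome search requires an ACGT sequence, got {seq!r}")
    rc = revcomp(seq)
    out: list[GenomicInstance] = []
    for chrom in genome.chroms():
        text = genome[chrom]
        for query, strand in ((seq, "+"), (rc, "-")):
            i = text.find(query)
            while i != -1:
                out.append(GenomicInstance(chrom, strand, i + 1, i + len(seq)))
                i = text.find(query, i + 1)
    return sorted(out, key=GenomicInstance.sort_key)


def classify_exclusivity(
    instances: Sequence[GenomicInstance], space: MirnaSpace
) -> tuple[str, list[GenomicInstance]]:
    """Tag a k-mer exclusive ("Y") or ambiguous ("N") against miRNA-space.

    Returns the tag and the instances re-annotated with their
    ``inside_mirna_space`` flag.  An empty instance list is an error: a
    table k-mer must occur at least at its source locus.
    """
    if not instances:
        raise TableError("a table k-mer must have at least one genomic instance")
    annotated = [
        GenomicInstance(
            gi.chrom, gi.strand, gi.start, gi.end, space.contains(gi.chrom, gi.start, gi.end)
        )
        for gi in instances
    ]
    tag = "Y" if all(gi.inside_mirna_space for gi in annotated) else "N"
    return tag, annotated


def annotate_repeats(
    instances: Sequence[GenomicInstance], repeats: RepeatAnnotation
) -> list[str]:
    """Sorted, de-duplicated repeat classes whose intervals fully contain any instance."""
    classes: set[str] = set()
    for gi in instances:
        classes |= repeats.classes_containing(gi.chrom, gi.start, gi.end)
    return sorted(classes)


# ---------------------------------------------------------------------------
# Variant table


def _apply_variant_forward(fwd: str, offset: int, v: Variant) -> tuple[str, tuple[int, ...], dict]:
    """Apply a variant to the forward-strand expanded slice.

    Returns (mutated forward sequence, indices in the mutated sequence a
    k-mer must cover, index-mapping descriptor for templated-sequence
    recovery).  ``offset`` is the variant position as a 0-based index into
    ``fwd``.
    """
    if v.kind == "snv":
        mut = fwd[:offset] + v.alt + fwd[offset + 1 :]
        return mut, (offset,), {"kind": "snv"}
    if v.kind == "ins":
        mut = fwd[: offset + 1] + v.alt[1] + fwd[offset + 1 :]
        return mut, (offset + 1,), {"kind": "ins", "i": offset + 1}
    # deletion of the base at offset+1: a k-mer must span the junction
    mut = fwd[: offset + 1] + fwd[offset + 2 :]
    return mut, (offset, offset + 1), {"kind": "del", "i": offset + 1}


def _templated_forward_range(a: int, b: int, desc: dict) -> tuple[int, int]:
    """Map a mutated-sequence span [a, b] back to the original forward span."""
    kind = desc["kind"]
    if kind == "snv":
        return a, b
    i = desc["i"]
    if kind == "ins":
        # drop the inserted base; a span starting *at* it begins at the
        # original base just downstream of the insertion point
        lo = a if a <= i else a - 1
        hi = b - 1 if b >= i else b
        return lo, hi
    # deletion: indices at or beyond the junction shift up by one, and a span
    # crossing the junction reabsorbs the deleted base
    lo = a if a < i else a + 1
    hi = b if b < i else b + 1
    return lo, hi


def load_variants(path: str | Path) -> list[Variant]:
    """Read variants from a documented TSV: id, source, chrom, pos, ref, alt, afs.

    ``afs`` is a semicolon-joined list of ``population=frequency`` entries
    (may be empty, e.g. for somatic mutations).
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("id\t"):
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise TableError(f"{path}:{lineno}: expected 7 columns")
            vid, source, chrom, pos, ref, alt, afs = fields
            pafs = []
            if afs:
                for entry in afs.split(";"):
                    popname, freq = entry.split("=")
                    pafs.append((popname, float(freq)))
            out.append(Variant(vid, source, chrom, int(pos), ref, alt, tuple(pafs)))
    return out


def write_variants(variants: Iterable[Variant], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tsource\tchrom\tpos\tref\talt\tafs\n")
        for v in variants:
            afs = ";".join(f"{p}={f:g}" for p, f in v.population_afs)
            fh.write("\t".join([v.vid, v.source, v.chrom, str(v.pos), v.ref, v.alt, afs]) + "\n")


def build_variant_table(
    expanded: Sequence[ExpandedPrecursor],
    variants: Sequence[Variant],
    genome: Genome,
    wildtype_keys: frozenset[str] | set[str],
    kmin: int = KMIN,
    kmax: int = KMAX,
) -> dict[str, VariantKmerRecord]:
    """Precompute variant-containing candidate isomiRs.

    Each kept variant (frequency filter above) falling inside an expanded
    precursor is applied *alone* to that precursor's sequence; every edited
    k-mer of post-edit length kmin..kmax whose span covers the edit is
    emitted with its templated counterpart.  Sequences already present in
    the wild-type table are dropped (no double counting); identical
    sequences from multiple (variant, precursor) pairs are merged with all
    generators listed.
    """
    table: dict[str, VariantKmerRecord] = {}
    for v in variants:
        if not v.passes_frequency_filter():
            continue
        ref_slice = genome.slice(v.chrom, v.pos, v.pos + len(v.ref) - 1)
        if ref_slice != v.ref:
            raise TableError(
                f"variant {v.vid}: ref allele {v.ref!r} does not match genome "
                f"({v.chrom}:{v.pos} is {ref_slice!r})"
            )
        for xp in expanded:
            p = xp.parent
            if p.chrom != v.chrom:
                continue
            # the whole edited ref span must lie inside the expanded interval
            if not (xp.genomic_start <= v.pos and v.pos + len(v.ref) - 1 <= xp.genomic_end):
                continue
            fwd = xp.sequence if p.strand == "+" else revcomp(xp.sequence)
            offset = v.pos - xp.genomic_start
            mut_fwd, cover_fwd, desc = _apply_variant_forward(fwd, offset, v)
            if p.strand == "+":
                mut, cover = mut_fwd, cover_fwd
            else:
                mut = revcomp(mut_fwd)
                cover = tuple(len(mut_fwd) - 1 - c for c in cover_fwd)
            lo_cover, hi_cover = min(cover), max(cover)
            for k in range(kmin, kmax + 1):
                for s in range(max(0, hi_cover - k + 1), min(lo_cover, len(mut) - k) + 1):
                    kmer = mut[s : s + k]
                    if "N" in kmer or kmer in wildtype_keys:
                        continue
                    # recover the templated counterpart via forward coordinates
                    if p.strand == "+":
                        fa, fb = s, s + k - 1
                    else:
                        fa, fb = len(mut) - (s + k), len(mut) - 1 - s
                    ta, tb = _templated_forward_range(fa, fb, desc)
                    templated_fwd = fwd[ta : tb + 1]
                    templated = templated_fwd if p.strand == "+" else revcomp(templated_fwd)
                    t_start = ta + 1 if p.strand == "+" else xp.length - tb
                    placement = Placement(xp, t_start, len(templated))
                    rec = table.get(kmer)
                    if rec is None:
                        table[kmer] = VariantKmerRecord(
                            seq=kmer,
                            variant_ids=[(v.source, v.vid)],
                            templated_seq=templated,
                            placements=[placement],
                        )
                    else:
                        if (v.source, v.vid) not in rec.variant_ids:
                            rec.variant_ids.append((v.source, v.vid))
                        if placement not in rec.placements:
                            rec.placements.append(placement)
    for rec in table.values():
        rec.variant_ids.sort()
        rec.placements.sort(key=Placement.sort_key)
    return table


# ---------------------------------------------------------------------------
# Bundle


@dataclass
class LookupTableBundle:
    """Everything the profiler needs, fully precomputed.

    ``expanded``: all flank-expanded precursors of every loaded reference
    set, keyed (db_tag, name).  ``wildtype``/``variant`` key sets are
    disjoint by construction.
    """

    wildtype: dict[str, KmerRecord]
    variant: dict[str, VariantKmerRecord]
    expanded: dict[tuple[str, str], ExpandedPrecursor]
    metadata: dict

    @property
    def kmin(self) -> int:
        return self.metadata["kmin"]

    @property
    def kmax(self) -> int:
        return self.metadata["kmax"]


def build_tables(
    genome: Genome,
    precursors: Sequence[Precursor],
    reference_set: str,
    repeats: RepeatAnnotation | None = None,
    variants: Sequence[Variant] = (),
    flank: int = 6,
    kmin: int = KMIN,
    kmax: int = KMAX,
    genome_tag: str = "custom",
) -> LookupTableBundle:
    """Run the full offline build.

    Candidates and miRNA-space come from the ``reference_set`` precursors;
    placements are additionally computed against every other loaded set so
    that alternative labels can be reported.  The result is independent of
    the input ordering of ``precursors``.
    """
    if repeats is None:
        repeats = EMPTY_REPEATS
    if kmin < 1 or kmin > kmax:
        raise TableError("need 1 <= kmin <= kmax")
    ordered = sorted(precursors, key=lambda p: (p.db_tag, p.name))
    sets_present = {p.db_tag for p in ordered}
    if ordered and reference_set not in sets_present:
        raise TableError(f"reference set {reference_set!r} not among loaded sets {sorted(sets_present)}")
    expanded = {(p.db_tag, p.name): expand_precursor(p, genome, flank) for p in ordered}
    primary = [xp for (db, _), xp in expanded.items() if db == reference_set]
    others = [xp for (db, _), xp in expanded.items() if db != reference_set]
    space = MirnaSpace(primary)

    candidates = enumerate_candidates(primary, kmin, kmax)
    wildtype: dict[str, KmerRecord] = {}
    for seq in sorted(candidates):
        placements = candidates[seq] + placements_of(seq, others)
        placements.sort(key=Placement.sort_key)
        instances = find_genomic_instances(seq, genome)
        tag, instances = classify_exclusivity(instances, space)
        wildtype[seq] = KmerRecord(
            seq=seq,
            placements=placements,
            instances=instances,
            exclusive=tag,
            repeat_classes=annotate_repeats(instances, repeats),
        )

    variant_table = build_variant_table(
        primary, variants, genome, frozenset(wildtype), kmin, kmax
    )
    metadata = {
        "format_version": FORMAT_VERSION,
        "reference_set": reference_set,
        "loaded_sets": sorted(sets_present),
        "genome_tag": genome_tag,
        "flank": flank,
        "kmin": kmin,
        "kmax": kmax,
    }
    return LookupTableBundle(wildtype, variant_table, expanded, metadata)


# ---------------------------------------------------------------------------
# Serialization: versioned plain-text TSV, byte-deterministic.


def _placements_str(placements: Sequence[Placement]) -> str:
    return ";".join(
        f"{pl.precursor.parent.db_tag}:{pl.precursor.parent.name}:{pl.start}:{pl.length}"
        for pl in placements
    )


def _parse_placements(text: str, expanded: Mapping[tuple[str, str], ExpandedPrecursor]):
    out = []
    if text:
        for entry in text.split(";"):
            db, name, start, length = entry.rsplit(":", 3)
            try:
                xp = expanded[(db, name)]
            except KeyError:
                raise TableError(f"placement references unknown precursor {db}/{name}") from None
            out.append(Placement(xp, int(start), int(length)))
    return out


def serialize_bundle(bundle: LookupTableBundle, outdir: str | Path) -> None:
    """Write a bundle as metadata.json + precursors.tsv + wildtype.tsv + variants.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "metadata.json", "w") as fh:
        json.dump(bundle.metadata, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "precursors.tsv", "w") as fh:
        fh.write("db\tname\tchrom\tstrand\tstart\tend\tflank_lo\tflank_hi\tclipped\tsequence\tmatures\n")
        for (db, name) in sorted(bundle.expanded):
            xp = bundle.expanded[(db, name)]
            p = xp.parent
            mats = ";".join(f"{m.name}:{m.offset_in_precursor}:{m.length}" for m in p.matures)
            fh.write(
                "\t".join(
                    [
                        db, name, p.chrom, p.strand, str(p.start), str(p.end),
                        str(xp.flank_lo), str(xp.flank_hi), "1" if xp.clipped else "0",
                        xp.sequence, mats,
                    ]
                )
                + "\n"
            )
    with open(outdir / "wildtype.tsv", "w") as fh:
        fh.write("seq\texclusive\trepeat_classes\tplacements\tinstances\n")
        for seq in sorted(bundle.wildtype):
            rec = bundle.wildtype[seq]
            inst = ";".join(
                f"{gi.chrom}:{gi.strand}:{gi.start}:{gi.end}:{'1' if gi.inside_mirna_space else '0'}"
                for gi in rec.instances
            )
            fh.write(
                "\t".join(
                    [
                        seq, rec.exclusive, ",".join(rec.repeat_classes),
                        _placements_str(rec.placements), inst,
                    ]
                )
                + "\n"
            )
    with open(outdir / "variants.tsv", "w") as fh:
        fh.write("seq\ttemplated_seq\tvariant_ids\tplacements\n")
        for seq in sorted(bundle.variant):
            rec = bundle.variant[seq]
            vids = ";".join(f"{src}:{vid}" for src, vid in rec.variant_ids)
            fh.write(
                "\t".join([seq, rec.templated_seq, vids, _placements_str(rec.placements)]) + "\n"
            )


def load_bundle(indir: str | Path) -> LookupTableBundle:
    """Inverse of :func:`serialize_bundle`; errors on version mismatch or truncation."""
    indir = Path(indir)
    meta_path = indir / "metadata.json"
    if not meta_path.exists():
        raise TableError(f"no lookup-table bundle at {indir} (metadata.json missing)")
    with open(meta_path) as fh:
        metadata = json.load(fh)
    if metadata.get("format_version") != FORMAT_VERSION:
        raise TableError(
            f"bundle format version {metadata.get('format_version')!r} != {FORMAT_VERSION!r}"
        )

    expanded: dict[tuple[str, str], ExpandedPrecursor] = {}
    for fields in _read_tsv(indir / "precursors.tsv", 11):
        db, name, chrom, strand, start, end, flank_lo, flank_hi, clipped, seq, mats = fields
        matures = []
        if mats:
            for entry in mats.split(";"):
                mname, off, mlen = entry.rsplit(":", 2)
                matures.append(MatureReference(mname, int(off), int(mlen)))
        p = Precursor(name, db, chrom, strand, int(start), int(end), tuple(matures))
        expanded[(db, name)] = ExpandedPrecursor(
            p, int(flank_lo), int(flank_hi), seq, clipped == "1"
        )

    wildtype: dict[str, KmerRecord] = {}
    for seq, excl, rcls, pls, inst in _read_tsv(indir / "wildtype.tsv", 5):
        instances = []
        if inst:
            for entry in inst.split(";"):
                chrom, strand, start, end, inside = entry.rsplit(":", 4)
                instances.append(
                    GenomicInstance(chrom, strand, int(start), int(end), inside == "1")
                )
        wildtype[seq] = KmerRecord(
            seq=seq,
            placements=_parse_placements(pls, expanded),
            instances=instances,
            exclusive=excl,
            repeat_classes=rcls.split(",") if rcls else [],
        )

    variant: dict[str, VariantKmerRecord] = {}
    for seq, templated, vids, pls in _read_tsv(indir / "variants.tsv", 4):
        pairs = []
        if vids:
            for entry in vids.split(";"):
                src, vid = entry.split(":", 1)
                pairs.append((src, vid))
        variant[seq] = VariantKmerRecord(
            seq=seq,
            variant_ids=pairs,
            templated_seq=templated,
            placements=_parse_placements(pls, expanded),
        )
    return LookupTableBundle(wildtype, variant, expanded, metadata)


def _read_tsv(path: Path, ncols: int):
    if not path.exists():
        raise TableError(f"bundle file missing: {path}")
    with open(path) as fh:
        header = fh.readline()
        if not header.endswith("\n"):
            raise TableError(f"truncated bundle file: {path}")
        for lineno, line in enumerate(fh, 2):
            if not line.endswith("\n"):
                raise TableError(f"truncated bundle file: {path} (line {lineno})")
            fields = line.rstrip("\n").split("\t")
            if len(fields) != ncols:
                raise TableError(f"{path}:{lineno}: expected {ncols} columns, got {len(fields)}")
            yield fields
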