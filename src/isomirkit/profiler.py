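"""Online profiling phase: read ingestion, resolution and quantification.

Reads are first collapsed into a frequency table (distinct sequence ->
count), then each distinct sequence is resolved against the precomputed
lookup tables in a fixed order:

1. exact key of the wild-type table  -> one *wildtype* hit;
2. exact key of the variant table    -> one *variant* hit;
3. otherwise, 3' non-templated-addition (NTA) rescue: the terminal
   homopolymeric suffix is stripped one nucleotide at a time, re-querying
   the wild-type table after each strip; the first success with a core of
   at least kmin nt yields one *nta* hit (minimal trimming wins, i.e. the
   fewest nucleotides are attributed to post-transcriptional addition);
4. otherwise the sequence is unmapped.

Each distinct sequence therefore contributes its count to exactly one
category — there is no double counting — and abundances are per distinct
sequence, never split across the (possibly many) precursor placements.
Reads longer than the table's kmax can only enter via NTA rescue: the
length cap applies to the templated portion only.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from . import plates
from .reference import Placement, alternative_labels, genome_label
from .tables import LookupTableBundle

__all__ = [
    "ReadFrequencyTable",
    "IsomirHit",
    "RunSummary",
    "FastqError",
    "load_reads",
    "resolve_read",
    "resolve_all",
    "quantify",
    "summarize",
    "profile_reads",
]


class FastqError(ValueError):
    """Malformed FASTQ input; carries the offending record index."""


@dataclass
class ReadFrequencyTable:
    """Collapsed reads: distinct usable sequence -> count.

    ``total_input_reads`` counts usable reads only (the sum of ``counts``);
    reads containing N or shorter than kmin are excluded from lookup and
    tracked in ``filtered_with_n`` / ``filtered_too_short`` so the run
    summary can still account for every sequenced read.
    """

    counts: dict[str, int] = field(default_factory=dict)
    total_input_reads: int = 0
    filtered_with_n: int = 0
    filtered_too_short: int = 0

    @property
    def total_sequenced_reads(self) -> int:
        return self.total_input_reads + self.filtered_with_n + self.filtered_too_short

    def add(self, seq: str, n: int = 1) -> None:
        self.counts[seq] = self.counts.get(seq, 0) + n
        self.total_input_reads += n


def load_reads(path: str | Path, kmin: int = 18) -> ReadFrequencyTable:
    """Collapse a (possibly gzipped) FASTQ file into a frequency table.

    Reads are expected to be quality-trimmed and adapter-free already.
    Sequences are uppercased; U is accepted and normalized to T.
    """
    from Bio import SeqIO

    opener = gzip.open if str(path).endswith(".gz") else open
    table = ReadFrequencyTable()
    with opener(path, "rt") as fh:
        records = SeqIO.parse(fh, "fastq")
        index = 0
        while True:
            try:
                rec = next(records)
            except StopIteration:
                break
            except ValueError as exc:
                raise FastqError(f"malformed FASTQ record #{index + 1}: {exc}") from exc
            index += 1
            seq = str(rec.seq).upper().replace("U", "T")
            if "N" in seq or set(seq) - set("ACGT"):
                table.filtered_with_n += 1
            elif len(seq) < kmin:
                table.filtered_too_short += 1
            else:
                table.add(seq)
    return table


@dataclass
class IsomirHit:
    """One distinct read sequence resolved to its annotations.

    ``templated_core`` is the genome-templated part: the read itself for
    wildtype hits, the read minus its 3' tail for NTA hits, and the
    wild-type counterpart for variant hits.  Exclusivity and repeat classes
    are absent (None) for variant hits by design.  The license plate
    encodes the full read sequence; the core is reported separately.
    """

    read_seq: str
    category: str  # "wildtype" | "nta" | "variant"
    templated_core: str
    tail: str
    placements: list[Placement]
    exclusive: str | None
    repeat_classes: list[str] | None
    variant_ids: list[tuple[str, str]]
    raw_count: int = 0
    rpm_all: float = 0.0
    rpm_mapped: float = 0.0

    @property
    def plate(self) -> str:
        return str(plates.encode(self.read_seq))

    @property
    def offset_labels(self) -> list[str]:
        return alternative_labels(self.placements)

    @property
    def genome_labels(self) -> list[str]:
        return [genome_label(pl) for pl in self.placements]


@dataclass
class RunSummary:
    """Per-run accounting; exclusive/ambiguous/variant partition mapped reads."""

    total_reads: int
    mapped_exclusive: int
    mapped_ambiguous: int
    mapped_variant: int
    nta_rescued: int
    unmapped: int
    filtered_with_n: int
    filtered_too_short: int
    zero_mapped_note: bool = False

    @property
    def mapped(self) -> int:
        return self.mapped_exclusive + self.mapped_ambiguous + self.mapped_variant

    def percentages(self) -> dict[str, float]:
        t = self.total_reads
        if t == 0:
            return {k: 0.0 for k in ("exclusive", "ambiguous", "variant", "nta", "unmapped")}
        return {
            "exclusive": 100.0 * self.mapped_exclusive / t,
            "ambiguous": 100.0 * self.mapped_ambiguous / t,
            "variant": 100.0 * self.mapped_variant / t,
            "nta": 100.0 * self.nta_rescued / t,
            "unmapped": 100.0 * self.unmapped / t,
        }


def _homopolymer_run(seq: str) -> int:
    """Length of the terminal homopolymer run (e.g. ...GAAA -> 3)."""
    last = seq[-1]
    n = 0
    for c in reversed(seq):
        if c != last:
            break
        n += 1
    return n


def resolve_read(seq: str, bundle: LookupTableBundle) -> IsomirHit | None:
    """Resolve one distinct sequence to at most one hit (or None if unmapped)."""
    kmin = bundle.kmin
    if len(seq) < kmin:
        return None
    rec = bundle.wildtype.get(seq)
    if rec is not None:
        return IsomirHit(
            read_seq=seq,
            category="wildtype",
            templated_core=seq,
            tail="",
            placements=list(rec.placements),
            exclusive=rec.exclusive,
            repeat_classes=list(rec.repeat_classes),
            variant_ids=[],
        )
    vrec = bundle.variant.get(seq)
    if vrec is not None:
        return IsomirHit(
            read_seq=seq,
            category="variant",
            templated_core=vrec.templated_seq,
            tail="",
            placements=list(vrec.placements),
            exclusive=None,
            repeat_classes=None,
            variant_ids=list(vrec.variant_ids),
        )
    # NTA rescue: strip the terminal homopolymer one nucleotide at a time
    run = _homopolymer_run(seq)
    for t in range(1, run + 1):
        core = seq[:-t]
        if len(core) < kmin:
            break
        crec = bundle.wildtype.get(core)
        if crec is not None:
            return IsomirHit(
                read_seq=seq,
                category="nta",
                templated_core=core,
                tail=seq[-t:],
                placements=list(crec.placements),
                exclusive=crec.exclusive,
                repeat_classes=list(crec.repeat_classes),
                variant_ids=[],
            )
    return None


def resolve_all(table: ReadFrequencyTable, bundle: LookupTableBundle) -> list[IsomirHit]:
    """Resolve every distinct sequence; deterministic (sequence-sorted) order."""
    hits = []
    for seq in sorted(table.counts):
        hit = resolve_read(seq, bundle)
        if hit is not None:
            hits.append(hit)
    return hits


def quantify(hits: Sequence[IsomirHit], table: ReadFrequencyTable) -> list[IsomirHit]:
    """Attach raw counts and reads-per-million abundances to each hit.

    ``rpm_all`` normalizes by total usable input reads, ``rpm_mapped`` by
    total mapped reads; both are reported because no single normalization
    suits every analysis.  Counts are per distinct sequence and are never
    split across placements.
    """
    total_mapped = sum(table.counts[h.read_seq] for h in hits)
    for h in hits:
        h.raw_count = table.counts[h.read_seq]
        h.rpm_all = h.raw_count * 1e6 / table.total_input_reads if table.total_input_reads else 0.0
        h.rpm_mapped = h.raw_count * 1e6 / total_mapped if total_mapped else 0.0
    return list(hits)


def summarize(hits: Sequence[IsomirHit], table: ReadFrequencyTable) -> RunSummary:
    """Partition all sequenced reads into exclusive/ambiguous/variant/unmapped.

    NTA hits inherit the exclusivity of their templated core and are also
    tallied separately as rescued reads.
    """
    excl = ambig = varc = nta = 0
    for h in hits:
        n = table.counts[h.read_seq]
        if h.category == "variant":
            varc += n
        elif h.exclusive == "Y":
            excl += n
        else:
            ambig += n
        if h.category == "nta":
            nta += n
    total = table.total_sequenced_reads
    mapped = excl + ambig + varc
    return RunSummary(
        total_reads=total,
        mapped_exclusive=excl,
        mapped_ambiguous=ambig,
        mapped_variant=varc,
        nta_rescued=nta,
        unmapped=total - mapped,
        filtered_with_n=table.filtered_with_n,
        filtered_too_short=table.filtered_too_short,
        zero_mapped_note=(mapped == 0),
    )


def profile_reads(
    bundle: LookupTableBundle, fastq_path: str | Path
) -> tuple[list[IsomirHit], ReadFrequencyTable, RunSummary]:
    """Convenience end-to-end run: load, resolve, quantify, summarize."""
    table = load_reads(fastq_path, kmin=bundle.kmin)
    hits = quantify(resolve_all(table, bundle), table)
    summary = summarize(hits, table)
    return hits, table, summary
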