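"""Synthetic reference and read simulator with exact ground truth.

Everything the pipeline consumes — genome FASTA, precursor/mature
annotations for two reference sets, repeat intervals, a variant list and
simulated FASTQ reads — is generated here from a single seed, together with
a truth table recording what was planted where.  The layout deliberately
exercises every behaviour the profiler must get right:

* a precursor whose mature sequence also occurs at a planted *decoy* locus
  outside miRNA-space (forcing an *ambiguous* tag), once inside a LINE
  repeat copy and once inside a Simple_repeat interval;
* a pair of overlapping precursors sharing a k-mer (multiple placements,
  one genomic instance);
* a precursor whose mature reference differs in length between the two
  loaded databases (the same molecule is ``|0|0`` in one collection and
  ``|0|-2`` in the other);
* SNV, 1-nt insertion and 1-nt deletion variants, both common (kept),
  rare (filtered out) and somatic (kept unconditionally);
* reads with 3' non-templated homopolymer tails, variant-carrying reads,
  unmappable junk, N-containing reads and too-short reads.

The mini-genome totals ~90 kb over three chromosomes: large enough to host
decoys and repeats, small enough that the quadratic scanning oracle used in
tests runs in seconds.  The background is uniform random sequence; after
planting, the generator verifies that no planted k-mer acquired an
accidental extra genomic copy (re-drawing the background deterministically
if one did), so the exclusive/ambiguous partition of the truth table is
guaranteed, not merely probable.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from .reference import (
    Genome,
    MatureReference,
    Precursor,
    expand_precursor,
    revcomp,
    write_precursors,
)
from .tables import (
    Variant,
    build_variant_table,
    enumerate_candidates,
    find_genomic_instances,
    write_variants,
)

__all__ = ["FixtureSpec", "FixtureReference", "FixtureError", "make_reference", "simulate_reads"]


class FixtureError(ValueError):
    """Inconsistent fixture specification."""


# (name, db, chrom, strand, start, end, [(mature_name, offset, length)])
_PRECURSOR_PLAN = [
    ("mc-mir-1", "miRCarta", "chr1", "+", 5001, 5060, [("mc-miR-1-5p", 7, 22)]),
    ("mb-mir-1", "miRBase", "chr1", "+", 5001, 5060, [("mb-miR-1-5p", 7, 22)]),
    ("mc-mir-2", "miRCarta", "chr1", "-", 12001, 12064, [("mc-miR-2-3p", 9, 21)]),
    ("mb-mir-2", "miRBase", "chr1", "-", 12001, 12064, [("mb-miR-2-3p", 9, 21)]),
    # overlapping pair: both contain chr2:8028-8048
    ("mc-mir-3a", "miRCarta", "chr2", "+", 8001, 8060, [("mc-miR-3a-5p", 28, 21)]),
    ("mc-mir-3b", "miRCarta", "chr2", "+", 8021, 8080, [("mc-miR-3b-5p", 8, 21)]),
    ("mb-mir-3a", "miRBase", "chr2", "+", 8001, 8060, [("mb-miR-3a-5p", 28, 21)]),
    ("mb-mir-3b", "miRBase", "chr2", "+", 8021, 8080, [("mb-miR-3b-5p", 8, 21)]),
    # database disagreement: miRBase's mature is 2 nt longer at the 3' end
    ("mc-mir-5", "miRCarta", "chr2", "+", 15001, 15062, [("mc-miR-5-5p", 10, 20)]),
    ("mb-mir-5", "miRBase", "chr2", "+", 15001, 15062, [("mb-miR-5-5p", 10, 22)]),
    ("mc-mir-6", "miRCarta", "chr3", "+", 4001, 4058, [("mc-miR-6-5p", 8, 22)]),
    ("mb-mir-6", "miRBase", "chr3", "+", 4001, 4058, [("mb-miR-6-5p", 8, 22)]),
]

# decoys: exact forward copies of (src_chrom, src_start, src_end) planted at
# (dst_chrom, dst_start), outside miRNA-space
_DEFAULT_DECOYS = (
    ("chr1", 5007, 5028, "chr3", 12000),   # copy of the mc-mir-1 mature, inside a LINE copy
    ("chr1", 12036, 12056, "chr2", 25000),  # copy of the mc-mir-2 mature locus, inside Simple_repeat
)

_REPEAT_PLAN = (
    ("chr3", 11990, 12040, "LINE"),
    ("chr2", 24990, 25040, "Simple_repeat"),
    ("chr1", 30001, 30300, "SINE"),
)

_SNV_ALT = {"A": "G", "C": "T", "G": "A", "T": "C"}


@dataclass(frozen=True)
class FixtureSpec:
    """All knobs of the synthetic dataset; same seed, byte-identical outputs."""

    seed: int = 7
    chrom_sizes: tuple[tuple[str, int], ...] = (("chr1", 40000), ("chr2", 30000), ("chr3", 20000))
    flank: int = 6
    kmin: int = 18
    kmax: int = 26
    decoys: tuple[tuple[str, int, int, str, int], ...] = _DEFAULT_DECOYS
    # read recipe: planted copy numbers per category
    n_mc1: int = 30
    n_mc2: int = 25
    n_overlap: int = 15
    n_mc5: int = 20
    n_nta: int = 12
    nta_tail_len: int = 3
    n_variant_snp: int = 10
    n_variant_somatic: int = 8
    n_junk_seqs: int = 3
    n_junk_each: int = 6
    n_with_n: int = 3
    n_too_short: int = 2


@dataclass
class FixtureReference:
    """The generated reference plus ground truth and key sets."""

    spec: FixtureSpec
    genome: Genome
    precursors: list[Precursor]
    repeat_rows: list[tuple[str, int, int, str]]
    variants: list[Variant]
    truth: dict
    wildtype_keys: frozenset
    variant_keys: frozenset

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write genome FASTA, annotation TSVs, variant list and truth table."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "precursors": outdir / "precursors.tsv",
            "repeats": outdir / "repeats.tsv",
            "variants": outdir / "variants.tsv",
            "truth": outdir / "truth.json",
        }
        with open(paths["genome"], "w") as fh:
            for chrom in self.genome.chroms():
                fh.write(f">{chrom}\n")
                seq = self.genome[chrom]
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
        write_precursors(self.precursors, paths["precursors"])
        with open(paths["repeats"], "w") as fh:
            fh.write("chrom\tstart\tend\tclass\n")
            for chrom, start, end, cls in self.repeat_rows:
                fh.write(f"{chrom}\t{start}\t{end}\t{cls}\n")
        write_variants(self.variants, paths["variants"])
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths


def _random_genome(spec: FixtureSpec, attempt: int) -> dict[str, str]:
    rng = random.Random((spec.seed + 100003 * attempt) % 2**31)
    return {name: "".join(rng.choice("ACGT") for _ in range(n)) for name, n in spec.chrom_sizes}


def make_reference(spec: FixtureSpec = FixtureSpec()) -> FixtureReference:
    """Build the synthetic reference; raises on inconsistent specs."""
    precursors = [
        Precursor(name, db, chrom, strand, start, end,
                  tuple(MatureReference(*m) for m in mats))
        for name, db, chrom, strand, start, end, mats in _PRECURSOR_PLAN
    ]
    # decoy targets must sit outside every flank-expanded precursor interval
    for src_chrom, s, e, dst_chrom, dst in spec.decoys:
        d_end = dst + (e - s)
        for p in precursors:
            if p.chrom == dst_chrom and dst <= p.end + spec.flank and p.start - spec.flank <= d_end:
                raise FixtureError(
                    f"decoy at {dst_chrom}:{dst}-{d_end} lies inside precursor {p.name}"
                )

    for attempt in range(25):
        chroms = _random_genome(spec, attempt)
        for src_chrom, s, e, dst_chrom, dst in spec.decoys:
            src = chroms[src_chrom][s - 1 : e]
            tgt = chroms[dst_chrom]
            chroms[dst_chrom] = tgt[: dst - 1] + src + tgt[dst - 1 + len(src):]
        genome = Genome(chroms)
        watch = _watch_list(spec, genome)
        if all(
            len(find_genomic_instances(seq, genome)) == expected
            for seq, expected in watch.items()
        ):
            break
    else:
        raise FixtureError("could not generate a collision-free background genome")

    variants = _plant_variants(genome)
    expanded_mc = [
        expand_precursor(p, genome, spec.flank) for p in precursors if p.db_tag == "miRCarta"
    ]
    wildtype_keys = frozenset(enumerate_candidates(expanded_mc, spec.kmin, spec.kmax))
    variant_keys = frozenset(
        build_variant_table(expanded_mc, variants, genome, wildtype_keys, spec.kmin, spec.kmax)
    )

    seqs = _planted_sequences(spec, genome)
    truth = {
        "seed": spec.seed,
        "planted_sequences": seqs,
        "watch_instances": {seq: n for seq, n in watch.items()},
        "expected_exclusive": {
            seqs["mc1_mature"]: "N",
            seqs["mc2_mature"]: "N",
            seqs["overlap20"]: "Y",
            seqs["mc5_mature"]: "Y",
            seqs["mc6_mature"]: "Y",
        },
        "expected_repeat_classes": {
            seqs["mc1_mature"]: ["LINE"],
            seqs["mc2_mature"]: ["Simple_repeat"],
            seqs["overlap20"]: [],
            seqs["mc5_mature"]: [],
        },
        "expected_offset_labels": {
            seqs["mc5_mature"]: ["mb-miR-5-5p|0|-2", "mc-miR-5-5p|0|0"],
        },
        "expected_placements": {seqs["overlap20"]: 4},  # 2 precursors x 2 databases
    }
    return FixtureReference(
        spec=spec,
        genome=genome,
        precursors=precursors,
        repeat_rows=list(_REPEAT_PLAN),
        variants=variants,
        truth=truth,
        wildtype_keys=wildtype_keys,
        variant_keys=variant_keys,
    )


def _planted_sequences(spec: FixtureSpec, genome: Genome) -> dict[str, str]:
    return {
        "mc1_mature": genome.slice("chr1", 5007, 5028),
        "mc2_mature": revcomp(genome.slice("chr1", 12036, 12056)),
        "overlap20": genome.slice("chr2", 8031, 8050),
        "mc5_mature": genome.slice("chr2", 15010, 15029),
        "mb5_mature": genome.slice("chr2", 15010, 15031),
        "mc6_mature": genome.slice("chr3", 4008, 4029),
    }


def _watch_list(spec: FixtureSpec, genome: Genome) -> dict[str, int]:
    """Planted k-mers and the exact number of genomic instances each must have."""
    seqs = _planted_sequences(spec, genome)
    return {
        seqs["mc1_mature"]: 2,  # source + decoy copy
        seqs["mc2_mature"]: 2,
        seqs["overlap20"]: 1,
        seqs["mc5_mature"]: 1,
        seqs["mb5_mature"]: 1,
        seqs["mc6_mature"]: 1,
    }


def _plant_variants(genome: Genome) -> list[Variant]:
    """Variants whose ref alleles are read off the final genome."""
    def ref(chrom, pos, n=1):
        return genome.slice(chrom, pos, pos + n - 1)

    v1_ref = ref("chr3", 4015)
    v2_ref = ref("chr1", 5015)
    v3_ref = ref("chr1", 12045)
    v4_ref = ref("chr3", 4020)
    v5_ref = ref("chr1", 12040, 2)
    return [
        # common SNP inside the mc-mir-6 mature: kept (MAF >= 1% in one population)
        Variant("rs_fix_1", "dbSNP", "chr3", 4015, v1_ref, _SNV_ALT[v1_ref],
                (("AFR", 0.05), ("EUR", 0.001))),
        # rare SNP: filtered out by the 1% MAF gate
        Variant("rs_fix_2", "dbSNP", "chr1", 5015, v2_ref, _SNV_ALT[v2_ref], (("ALL", 0.002),)),
        # somatic mutation inside the minus-strand mc-mir-2 mature: kept unconditionally
        Variant("COSM_fix_1", "COSMIC", "chr1", 12045, v3_ref, _SNV_ALT[v3_ref]),
        # 1-nt insertion and deletion, both common
        Variant("rs_fix_3", "dbSNP", "chr3", 4020, v4_ref, v4_ref + "G", (("AMR", 0.02),)),
        Variant("rs_fix_4", "dbSNP", "chr1", 12040, v5_ref, v5_ref[0], (("EAS", 0.03),)),
    ]


def _nta_read(ref: FixtureReference) -> str:
    """Core + homopolymer tail, guaranteed to resolve only via trim-and-rescan."""
    spec = ref.spec
    core = _planted_sequences(spec, ref.genome)["mc2_mature"]
    for nt in "TGCA":
        if nt == core[-1]:
            continue  # tail must not extend the core's own terminal run
        if core + nt in ref.wildtype_keys:
            continue  # a templated extension would be a wild-type hit instead
        read = core + nt * spec.nta_tail_len
        if read not in ref.wildtype_keys and read not in ref.variant_keys:
            return read
    raise FixtureError("no usable non-templated tail nucleotide for the NTA read")


def _variant_read_snv(genome: Genome, chrom: str, lo: int, hi: int, pos: int, alt: str,
                      strand: str) -> str:
    fwd = genome.slice(chrom, lo, hi)
    off = pos - lo
    mut = fwd[:off] + alt + fwd[off + 1 :]
    return mut if strand == "+" else revcomp(mut)


def _junk_reads(ref: FixtureReference, rng: random.Random) -> list[str]:
    """Random 22-mers rejected unless they fail every resolution route."""
    out: list[str] = []
    while len(out) < ref.spec.n_junk_seqs:
        cand = "".join(rng.choice("ACGT") for _ in range(22))
        if cand in ref.wildtype_keys or cand in ref.variant_keys or cand in out:
            continue
        run = 1
        while run < len(cand) and cand[-1 - run] == cand[-1]:
            run += 1
        cores = [cand[:-t] for t in range(1, run + 1)]
        if any(len(c) >= ref.spec.kmin and c in ref.wildtype_keys for c in cores):
            continue
        out.append(cand)
    return out


def simulate_reads(
    ref: FixtureReference, fastq_path: str | Path, order_seed: int | None = None
) -> dict:
    """Write simulated reads and return the per-read truth.

    ``order_seed`` only permutes the order of records in the FASTQ file;
    the read content and counts are fully determined by the fixture spec.
    """
    spec = ref.spec
    seqs = _planted_sequences(spec, ref.genome)
    rng = random.Random(spec.seed + 1)

    v1_read = _variant_read_snv(ref.genome, "chr3", 4008, 4029, 4015, _SNV_ALT[ref.genome.slice("chr3", 4015, 4015)], "+")
    v3_read = _variant_read_snv(ref.genome, "chr1", 12036, 12056, 12045, _SNV_ALT[ref.genome.slice("chr1", 12045, 12045)], "-")
    for vread, vid in ((v1_read, "rs_fix_1"), (v3_read, "COSM_fix_1")):
        if vread not in ref.variant_keys:
            raise FixtureError(f"planted variant read for {vid} missing from the variant table")

    nta_read = _nta_read(ref)
    junk = _junk_reads(ref, rng)
    n_read = seqs["mc1_mature"][:10] + "N" + seqs["mc1_mature"][11:]
    short_read = seqs["mc1_mature"][:16]

    recipe: list[tuple[str, int, str]] = [
        (seqs["mc1_mature"], spec.n_mc1, "wildtype"),
        (seqs["mc2_mature"], spec.n_mc2, "wildtype"),
        (seqs["overlap20"], spec.n_overlap, "wildtype"),
        (seqs["mc5_mature"], spec.n_mc5, "wildtype"),
        (nta_read, spec.n_nta, "nta"),
        (v1_read, spec.n_variant_snp, "variant"),
        (v3_read, spec.n_variant_somatic, "variant"),
    ]
    recipe += [(j, spec.n_junk_each, "unmapped") for j in junk]
    recipe += [(n_read, spec.n_with_n, "filtered_n"), (short_read, spec.n_too_short, "filtered_short")]

    records = []
    for seq, count, _ in recipe:
        records += [seq] * count
    random.Random(spec.seed + 2 if order_seed is None else order_seed).shuffle(records)

    fastq_path = Path(fastq_path)
    fastq_path.parent.mkdir(parents=True, exist_ok=True)
    with open(fastq_path, "w") as fh:
        for i, seq in enumerate(records, 1):
            fh.write(f"@sim_read_{i}\n{seq}\n+\n{'I' * len(seq)}\n")

    reads_truth = {seq: {"count": count, "category": cat} for seq, count, cat in recipe}
    mapped_cats = ("wildtype", "nta", "variant")
    total = sum(r["count"] for r in reads_truth.values())
    return {
        "reads": reads_truth,
        "nta": {"read": nta_read, "core": nta_read[: -spec.nta_tail_len], "tail": nta_read[-spec.nta_tail_len:]},
        "variant_reads": {v1_read: [["dbSNP", "rs_fix_1"]], v3_read: [["COSMIC", "COSM_fix_1"]]},
        "summary": {
            "total_reads": total,
            "mapped": sum(r["count"] for r in reads_truth.values() if r["category"] in mapped_cats),
            "variant": sum(r["count"] for r in reads_truth.values() if r["category"] == "variant"),
            "nta": sum(r["count"] for r in reads_truth.values() if r["category"] == "nta"),
            "unmapped": sum(
                r["count"] for r in reads_truth.values() if r["category"] not in mapped_cats
            ),
            "filtered_n": spec.n_with_n,
            "filtered_short": spec.n_too_short,
        },
    }
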