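# Methods

## Model and assumptions

isomirkit treats isomiR profiling as an exact set-membership problem rather
than an alignment problem. The central assumption is that every reportable
templated isomiR is a contiguous substring, 18–26 nt long, of some
flank-expanded miRNA precursor; everything else reachable from a read is
either a 3′ non-templated extension of such a substring or a precomputed
1-nt variant of one. Under that assumption the complete candidate space is
finite and enumerable offline, which buys three properties alignment-based
pipelines struggle with:

* **determinism** — results are a pure function of (tables, reads); the
  profiler holds no tunable scoring parameters;
* **exhaustiveness** — a read whose templated core is in the candidate
  space cannot be missed, and *every* precursor placement and genomic
  instance of a sequence is reported, not a best hit;
* **no double counting** — each distinct read sequence contributes its
  count to exactly one category (wild-type, NTA or variant); placements are
  annotation, not allocation.

The cost is equally explicit: reads whose templated region differs from the
reference genome in any way not precomputed (unlisted variants, internal
editing, 5′ additions) are reported as unmapped, and novel miRNA loci are
invisible by construction.

## Coordinates, orientation, alphabet

All user-visible coordinates are 1-based inclusive; half-open arithmetic is
internal only. Precursor-oriented sequences of minus-strand precursors are
reverse complements of the forward genomic slice, and position *p* of an
expanded precursor maps bijectively to one genomic coordinate (asserted as
a round-trip property in the tests). The working alphabet is DNA: FASTQ
input is DNA-space, U on input is normalized to T, and U appears only in
prose. Reads or candidate substrings containing N are excluded from
enumeration and lookup — exact-match semantics are undefined for ambiguous
bases — but N-containing reads are still counted in the run summary.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `flank` | 6 | nt | padding per precursor side; lets isoforms extend past truncated database annotations and unannotated arms. Flanks are part of miRNA-space: a 3′-extended isomiR lying partly in flank must still be classifiable as exclusive. Clipped (with a flag) at chromosome edges. |
| `kmin` | 18 | nt | shortest candidate/templated core; shorter sequences are too promiscuous genomically to annotate meaningfully. |
| `kmax` | 26 | nt | longest *templated* candidate. Reads longer than `kmax` are still reportable via NTA rescue, because the cap applies to the templated portion only. |
| MAF threshold | 0.01 | frequency | SNP-source variants (dbSNP and gnomAD alike) enter the variant table only with MAF ≥ 1 % in at least one reference population; somatic (COSMIC) variants enter unconditionally. |

## Exclusivity and repeats

miRNA-space is the union of flank-expanded precursor intervals of the
*selected* reference set. A k-mer is exclusive (`Y`) iff every genomic
instance lies fully inside some such interval, on either strand — ambiguity
concerns where a sequence *occurs*, not its orientation, so an antisense
instance inside a precursor interval counts as in-space (the annotation
databases are silent here; this is a package decision). Repeat annotation
requires full containment of an instance within a repeat interval, not mere
overlap, and reports the sorted, de-duplicated class names drawn from the
20 RepeatMasker classes. Exclusive k-mers may legitimately carry repeat
classes; the two attributes are independent.

## Variant table construction

Each kept variant is applied *alone* (combinations of co-occurring variants
are not enumerated); for each expanded precursor containing the edited
span, every post-edit k-mer of length 18–26 covering the edit is emitted.
"Covering" means: the substituted or inserted base for SNVs/insertions, and
both junction neighbours for deletions. The templated counterpart is
recovered by mapping the k-mer's span back through the edit to the original
precursor coordinates (so indel k-mers have templated counterparts one
base longer/shorter). Emitted sequences already present in the wild-type
table are dropped — this keeps the two key sets disjoint, which is what
makes the profiler's no-double-counting guarantee unconditional — and
identical sequences arising from multiple (variant, precursor) pairs are
merged with all generators listed. Variant rows carry no exclusivity or
repeat annotation: those attributes are defined against the reference
genome, which a variant-containing sequence by definition does not match.

## Resolution order and NTA rescue

Wild-type lookup precedes variant lookup (moot for correctness given
disjoint key sets, fixed for determinism). NTA rescue strips the terminal
homopolymer run one base at a time and re-queries the wild-type table after
each strip; the first success with a core ≥ `kmin` wins, i.e. the fewest
bases are attributed to post-transcriptional addition. Tails are
homopolymeric by design (mixed tails are out of scope in this version); an
NTA hit inherits the exclusivity and repeat classes of its templated core,
and its license plate encodes the full read sequence with the core reported
separately.

## Normalization

Two RPM denominators are emitted because no single normalization suits
every downstream analysis: `rpm_all` divides by total usable input reads
(after N/length filtering; filtered totals are tracked separately in the
summary), `rpm_mapped` by total mapped reads, so `rpm_mapped` sums to 10⁶
over any non-empty result set. With zero mapped reads `rpm_mapped` is
undefined and emitted as zero with a summary note.

## Output conventions

The TSV pair (wild-type+NTA file, separate variant file) is the lossless
form; floats use shortest round-trip repr. Row order is category, then
license plate lexicographically. mirGFF3 output maps the package's d5/d3
offsets to the mirGFF3 controlled vocabulary with the sign flip that
convention requires: `iso_5p:+N` ⇔ d5 = −N (gain at the 5′ end),
`iso_3p:±N` ⇔ d3 = ±N, plus `iso_add3p:N` for N-nt 3′ additions and
`iso_snv` for variant hits; reference-identical molecules get `Variant=NA`
and type `ref_miRNA`. Coordinates are given on the un-expanded precursor
when the isomiR fits inside it (maximizing compatibility with consumers
expecting database precursor names), else on the expanded precursor with a
`&WithFlank` seqid. The HTML page is a functional overview (summary,
sortable table, per-precursor alignment blocks), not a replica of any
particular viewer.

## License-plate codec

Plates are `prefix-length-payload` with the payload packing A/C/G/T as
00/01/10/11, five bits per symbol over the 32-character alphabet
`BD0EF1HI2JK3LM4NO5PQ6RS7UV8WX9YZ` (B–Z minus the four nucleotide letters,
digits interleaved), a trailing group of fewer than five bits taken at face
value. This is the public MINTplates scheme; the alphabet was recovered
analytically from published sequence↔plate pairs, which the test suite
pins as conformance fixtures. Decoding validates payload size against the
length field and rejects trailing symbols that encode more bits than
remain.

## Synthetic reference and what it does (not) show

The fixture generator emulates the *structural* challenges of real
profiling — multi-copy sequences (via planted decoys, guaranteeing a known
exclusive/ambiguous partition), overlapping precursors, inter-database
mature disagreements, repeat containment, common/rare/somatic variants,
NTA tails, junk and filtered reads — on a ~90 kb three-chromosome genome
small enough that the quadratic scanning oracle used in tests runs in
seconds. The background is uniform random sequence; after planting, the
generator verifies that no watched k-mer acquired an accidental extra copy
and re-draws deterministically if one did, so truth tables are exact.

What it does **not** emulate: realistic base composition, sequencing error
(inputs are pre-trimmed by contract), quality-score structure, expression
distributions, or genome-scale repeat density. Green tests therefore
demonstrate algorithmic correctness (oracle equivalence, exact ground-truth
recovery, conservation, determinism under read-order permutation) — not
performance or annotation quality on a full human genome, which depend on
the real reference inputs the builder accepts in the same formats.

## Numerical and degenerate-input choices

No floating-point computation feeds any decision; floats appear only in
reported abundances and percentages. Ties cannot arise: all orderings are
total (lexicographic sequence order; (db, name, position) for placements;
(chrom, start, strand) for instances). Degenerate inputs are defined
explicitly: empty FASTQ → empty table and all-zero summary; empty precursor
set → valid empty bundle; empty variant list → empty variant table; a table
k-mer with no genomic instance is an error (it must occur at least at its
source locus); a variant whose ref allele contradicts the genome is an
error naming the variant; truncated or version-mismatched bundle files are
errors. Palindromic k-mers yield one instance per strand at the same locus.

## Problem sizes used in the test suite

The default fixture builds 2 511 wild-type and 768 variant k-mers from six
precursor loci mirrored across two reference sets, and simulates 143 reads
across seven distinct sequences plus junk/filtered reads. Oracle-equivalence
tests compare the full table against brute-force enumeration over the whole
mini-genome for every k in 18–26. These sizes were chosen so the complete
suite — including the exhaustive length-8 plate bijection check (65 536
sequences) — exercises every code path in well under a minute.

## Known limitations

* 5′ non-templated additions, mixed-nucleotide 3′ tails and internal
  editing events are not modelled.
* Variants are single 1-nt events; haplotypes carrying two nearby variants
  produce sequences in neither table.
* The annotation input is a documented TSV dialect; converters from native
  miRBase GFF3 / miRCarta dumps are left to the user (the fixture module
  shows the expected content).
* Ambiguity is judged against the genome only; transcriptome-level
  ambiguity (e.g. spliced contexts) is out of scope.
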