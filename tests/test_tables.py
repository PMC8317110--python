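"""Table builder vs independent brute-force oracles, plus serialization."""

import itertools

import pytest

from isomirkit.reference import (
    Genome,
    MatureReference,
    Placement,
    Precursor,
    expand_precursor,
    revcomp,
)
from isomirkit.tables import (
    GenomicInstance,
    MirnaSpace,
    RepeatAnnotation,
    TableError,
    Variant,
    build_tables,
    build_variant_table,
    classify_exclusivity,
    enumerate_candidates,
    find_genomic_instances,
    annotate_repeats,
    load_bundle,
    serialize_bundle,
)

KMIN, KMAX = 18, 26


# ---------------------------------------------------------------------------
# Oracles: deliberately naive, independent of the implementation under test.


def oracle_substrings(expanded, kmin, kmax):
    """Nested-loop substring enumeration."""
    out = {}
    for xp in expanded:
        s = xp.sequence
        for k in range(kmin, kmax + 1):
            for i in range(len(s) - k + 1):
                if "N" not in s[i : i + k]:
                    out.setdefault(s[i : i + k], []).append((xp.parent.name, i + 1, k))
    return out


def oracle_genome_index(genome, kmin, kmax):
    """Position dictionary of every genome k-mer, built by direct slicing."""
    index = {}
    for chrom in genome.chroms():
        text = genome[chrom]
        for k in range(kmin, kmax + 1):
            for i in range(len(text) - k + 1):
                index.setdefault(text[i : i + k], []).append((chrom, i + 1))
    return index


def oracle_instances(seq, index):
    hits = []
    for chrom, start in index.get(seq, []):
        hits.append((chrom, "+", start, start + len(seq) - 1))
    for chrom, start in index.get(revcomp(seq), []):
        hits.append((chrom, "-", start, start + len(seq) - 1))
    return sorted(hits, key=lambda t: (t[0], t[2], t[1]))


@pytest.fixture(scope="module")
def genome_index(fixture_ref):
    return oracle_genome_index(fixture_ref.genome, KMIN, KMAX)


@pytest.fixture(scope="module")
def expanded_mc(fixture_ref):
    return [
        expand_precursor(p, fixture_ref.genome, 6)
        for p in fixture_ref.precursors
        if p.db_tag == "miRCarta"
    ]


class TestEnumeration:
    def test_placement_count_formula_single_precursor(self, expanded_mc):
        xp = next(x for x in expanded_mc if x.length == 72)
        cands = enumerate_candidates([xp], KMIN, KMAX)
        total = sum(len(pls) for pls in cands.values())
        assert total == sum(72 - k + 1 for k in range(KMIN, KMAX + 1)) == 459

    def test_key_set_and_placements_match_substring_oracle(self, expanded_mc):
        cands = enumerate_candidates(expanded_mc, KMIN, KMAX)
        oracle = oracle_substrings(expanded_mc, KMIN, KMAX)
        assert set(cands) == set(oracle)
        for seq, pls in cands.items():
            got = sorted((pl.precursor.parent.name, pl.start, pl.length) for pl in pls)
            assert got == sorted(oracle[seq])

    def test_overlapping_precursors_share_a_key_with_two_placements(self, fixture_ref, expanded_mc):
        seq = fixture_ref.truth["planted_sequences"]["overlap20"]
        cands = enumerate_candidates(expanded_mc, KMIN, KMAX)
        names = [pl.precursor.parent.name for pl in cands[seq]]
        assert names == ["mc-mir-3a", "mc-mir-3b"]

    def test_n_containing_substrings_are_excluded(self):
        genome = Genome({"c": "A" * 30 + "N" + "C" * 30})
        p = Precursor("n-prec", "other", "c", "+", 1, 61)
        cands = enumerate_candidates([expand_precursor(p, genome, 0)], 18, 26)
        assert all("N" not in seq for seq in cands)


class TestGenomeSearch:
    def test_all_table_kmers_match_index_oracle(self, fixture_ref, expanded_mc, genome_index):
        for seq in enumerate_candidates(expanded_mc, KMIN, KMAX):
            got = [(gi.chrom, gi.strand, gi.start, gi.end)
                   for gi in find_genomic_instances(seq, fixture_ref.genome)]
            assert got == oracle_instances(seq, genome_index), seq

    def test_index_oracle_agrees_with_quadratic_scan_on_samples(self, fixture_ref, genome_index):
        """Validate the dictionary oracle itself against a position-by-position scan."""
        seqs = list(fixture_ref.truth["planted_sequences"].values())[:4]
        for seq in seqs:
            k = len(seq)
            rc = revcomp(seq)
            scan = []
            for chrom in fixture_ref.genome.chroms():
                text = fixture_ref.genome[chrom]
                for i in range(len(text) - k + 1):
                    window = text[i : i + k]
                    if window == seq:
                        scan.append((chrom, "+", i + 1, i + k))
                    if window == rc:
                        scan.append((chrom, "-", i + 1, i + k))
            scan.sort(key=lambda t: (t[0], t[2], t[1]))
            assert scan == oracle_instances(seq, genome_index)

    def test_decoyed_kmer_has_two_instances(self, fixture_ref):
        seq = fixture_ref.truth["planted_sequences"]["mc1_mature"]
        inst = find_genomic_instances(seq, fixture_ref.genome)
        assert len(inst) == 2
        assert {(gi.chrom, gi.start) for gi in inst} == {("chr1", 5007), ("chr3", 12000)}

    def test_absent_sequence_gives_empty_list(self):
        genome = Genome({"c": "AC" * 50})
        assert find_genomic_instances("G" * 18, genome) == []

    def test_overlapping_occurrences_all_reported(self):
        genome = Genome({"c": "A" * 40 + "C" * 10})
        inst = find_genomic_instances("A" * 18, genome)
        assert [gi.start for gi in inst] == list(range(1, 40 - 18 + 2))
        assert all(gi.strand == "+" for gi in inst)

    def test_palindromic_sequence_reported_once_per_strand(self):
        pal = "ACGTACGTACGTACGTAT"
        pal = pal[:9] + revcomp(pal[:9])  # construct an 18-nt palindrome
        assert pal == revcomp(pal)
        genome = Genome({"c": "G" * 20 + pal + "G" * 20})
        inst = find_genomic_instances(pal, genome)
        assert [(gi.strand, gi.start) for gi in inst] == [("+", 21), ("-", 21)]


class TestExclusivity:
    def test_every_table_kmer_matches_containment_oracle(self, fixture_ref, bundle, expanded_mc):
        intervals = [(xp.parent.chrom, xp.genomic_start, xp.genomic_end) for xp in expanded_mc]
        for seq, rec in bundle.wildtype.items():
            oracle = "Y" if all(
                any(c == gi.chrom and s <= gi.start and gi.end <= e for c, s, e in intervals)
                for gi in rec.instances
            ) else "N"
            assert rec.exclusive == oracle, seq

    def test_planted_exclusive_ambiguous_partition(self, fixture_ref, bundle):
        for seq, tag in fixture_ref.truth["expected_exclusive"].items():
            assert bundle.wildtype[seq].exclusive == tag

    def test_no_third_state_and_flags_consistent(self, bundle):
        for rec in bundle.wildtype.values():
            assert rec.exclusive in ("Y", "N")
            inside = [gi.inside_mirna_space for gi in rec.instances]
            assert rec.exclusive == ("Y" if all(inside) else "N")

    def test_empty_instance_list_is_an_error(self, expanded_mc):
        with pytest.raises(TableError):
            classify_exclusivity([], MirnaSpace(expanded_mc))

    def test_ambiguous_fraction_nonincreasing_in_k(self, fixture_ref, bundle):
        by_k = {}
        for seq, rec in bundle.wildtype.items():
            n_amb, n = by_k.get(len(seq), (0, 0))
            by_k[len(seq)] = (n_amb + (rec.exclusive == "N"), n + 1)
        fracs = [n_amb / n for k, (n_amb, n) in sorted(by_k.items())]
        assert all(a >= b - 1e-12 for a, b in zip(fracs, fracs[1:]))


class TestRepeats:
    def test_classes_match_all_pairs_containment_oracle(self, fixture_ref, bundle):
        rows = fixture_ref.repeat_rows
        for seq, rec in bundle.wildtype.items():
            oracle = sorted(
                {
                    cls
                    for gi in rec.instances
                    for chrom, s, e, cls in rows
                    if chrom == gi.chrom and s <= gi.start and gi.end <= e
                }
            )
            assert rec.repeat_classes == oracle, seq

    def test_planted_repeat_classes(self, fixture_ref, bundle):
        for seq, classes in fixture_ref.truth["expected_repeat_classes"].items():
            assert bundle.wildtype[seq].repeat_classes == classes

    def test_overlap_without_containment_does_not_count(self):
        repeats = RepeatAnnotation([("c", 10, 30, "LINE")])
        inst = [GenomicInstance("c", "+", 25, 44)]  # straddles the boundary
        assert annotate_repeats(inst, repeats) == []

    def test_unknown_repeat_class_rejected_at_load(self):
        with pytest.raises(TableError):
            RepeatAnnotation([("c", 1, 10, "NotARepeatClass")])


@pytest.fixture(scope="module")
def toy_variant_setup():
    """A toy plus-strand precursor with an SNV, insertion and deletion."""
    import random

    rng = random.Random(17)
    text = "".join(rng.choice("ACGT") for _ in range(200))
    genome = Genome({"c": text})
    p = Precursor("toy", "miRCarta", "c", "+", 51, 110)
    xp = expand_precursor(p, genome, 6)
    variants = [
        Variant("snv1", "dbSNP", "c", 70, text[69], {"A": "C"}.get(text[69], "A"),
                (("AFR", 0.5),)),
        Variant("ins1", "dbSNP", "c", 80, text[79], text[79] + "T", (("EUR", 0.2),)),
        Variant("del1", "dbSNP", "c", 90, text[89:91], text[89], (("SAS", 0.3),)),
    ]
    wt = frozenset(oracle_substrings([xp], KMIN, KMAX))
    return genome, xp, variants, wt


class TestVariantTable:

    @staticmethod
    def _oracle_variant_seqs(genome, xp, v, wt):
        """Provenance-tagged string mutation: chars carry their origin so the
        covered-edit requirement needs no offset arithmetic."""
        fwd = genome[xp.parent.chrom][xp.genomic_start - 1 : xp.genomic_end]
        tagged = [(c, "wt", i) for i, c in enumerate(fwd)]
        off = v.pos - xp.genomic_start
        if v.kind == "snv":
            tagged[off] = (v.alt, "edit", off)
        elif v.kind == "ins":
            tagged = tagged[: off + 1] + [(v.alt[1], "edit", None)] + tagged[off + 1 :]
        else:  # deletion of the base at off+1: tag both junction neighbours
            tagged = tagged[: off + 1] + tagged[off + 2 :]
            tagged[off] = (tagged[off][0], "edit", tagged[off][2])
            tagged[off + 1] = (tagged[off + 1][0], "edit", tagged[off + 1][2])
        if xp.parent.strand == "-":
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            tagged = [(comp[c], tag, i) for c, tag, i in reversed(tagged)]
        out = {}
        for k in range(KMIN, KMAX + 1):
            for i in range(len(tagged) - k + 1):
                window = tagged[i : i + k]
                seq = "".join(c for c, _, _ in window)
                need = 2 if v.kind == "del" else 1
                if sum(tag == "edit" for _, tag, _ in window) >= need and seq not in wt:
                    origs = [o for _, _, o in window if o is not None]
                    out.setdefault(seq, (min(origs), max(origs)))
        return out

    @pytest.mark.parametrize("which", [0, 1, 2])
    def test_emitted_sequences_match_string_mutation_oracle(self, toy_variant_setup, which):
        genome, xp, variants, wt = toy_variant_setup
        v = variants[which]
        table = build_variant_table([xp], [v], genome, wt, KMIN, KMAX)
        oracle = self._oracle_variant_seqs(genome, xp, v, wt)
        assert set(table) == set(oracle)
        for seq, rec in table.items():
            lo, hi = oracle[seq]
            fwd = genome[xp.parent.chrom][xp.genomic_start - 1 : xp.genomic_end]
            assert rec.templated_seq == fwd[lo : hi + 1]
            assert rec.variant_ids == [(v.source, v.vid)]

    def test_minus_strand_variant_kmers_carry_the_substitution(self, fixture_ref, bundle):
        """The somatic SNV inside the minus-strand precursor yields k-mers that
        differ from their templated counterpart by one substitution."""
        recs = [r for r in bundle.variant.values() if ("COSMIC", "COSM_fix_1") in r.variant_ids]
        assert recs
        for rec in recs:
            assert len(rec.seq) == len(rec.templated_seq)
            diffs = sum(a != b for a, b in zip(rec.seq, rec.templated_seq))
            assert diffs == 1

    def test_indel_records_differ_by_one_nucleotide(self, bundle):
        for rec in bundle.variant.values():
            assert abs(len(rec.seq) - len(rec.templated_seq)) <= 1

    def test_rare_snp_is_filtered_common_and_somatic_kept(self, bundle):
        ids = {vid for rec in bundle.variant.values() for vid in rec.variant_ids}
        assert ("dbSNP", "rs_fix_1") in ids
        assert ("COSMIC", "COSM_fix_1") in ids
        assert ("dbSNP", "rs_fix_2") not in ids

    def test_variant_keys_disjoint_from_wildtype(self, bundle):
        assert not set(bundle.variant) & set(bundle.wildtype)

    def test_empty_variant_list_gives_empty_table(self, fixture_ref, expanded_mc):
        assert build_variant_table(expanded_mc, [], fixture_ref.genome, frozenset()) == {}

    def test_ref_allele_mismatch_raises_naming_the_variant(self, fixture_ref, expanded_mc):
        pos = 4015
        actual = fixture_ref.genome.slice("chr3", pos, pos)
        wrong = "A" if actual != "A" else "C"
        bad = Variant("rs_bogus", "dbSNP", "chr3", pos, wrong, actual, (("AFR", 0.5),))
        with pytest.raises(TableError, match="rs_bogus"):
            build_variant_table(expanded_mc, [bad], fixture_ref.genome, frozenset())


class TestBundleSerialization:
    def test_round_trip_is_byte_identical(self, bundle, tmp_path):
        serialize_bundle(bundle, tmp_path / "a")
        reloaded = load_bundle(tmp_path / "a")
        serialize_bundle(reloaded, tmp_path / "b")
        for name in ("metadata.json", "precursors.tsv", "wildtype.tsv", "variants.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_build_is_independent_of_input_ordering(self, fixture_ref, tmp_path):
        kwargs = dict(
            repeats=RepeatAnnotation(fixture_ref.repeat_rows),
            variants=fixture_ref.variants,
            genome_tag="synthetic-mini",
        )
        b1 = build_tables(fixture_ref.genome, fixture_ref.precursors, "miRCarta", **kwargs)
        b2 = build_tables(
            fixture_ref.genome, list(reversed(fixture_ref.precursors)), "miRCarta", **kwargs
        )
        serialize_bundle(b1, tmp_path / "fwd")
        serialize_bundle(b2, tmp_path / "rev")
        for name in ("metadata.json", "precursors.tsv", "wildtype.tsv", "variants.tsv"):
            assert (tmp_path / "fwd" / name).read_bytes() == (tmp_path / "rev" / name).read_bytes()

    def test_hand_appended_kmer_row_visible_after_load(self, bundle, tmp_path):
        serialize_bundle(bundle, tmp_path / "t")
        extra = "T" * 18
        assert extra not in bundle.wildtype
        with open(tmp_path / "t" / "wildtype.tsv", "a") as fh:
            fh.write(f"{extra}\tY\t\t\tchrX:+:1:18:1\n")
        reloaded = load_bundle(tmp_path / "t")
        assert extra in reloaded.wildtype
        assert reloaded.wildtype[extra].exclusive == "Y"

    def test_empty_precursor_set_gives_valid_empty_bundle(self, tmp_path):
        genome = Genome({"c": "ACGT" * 30})
        bundle = build_tables(genome, [], "miRCarta")
        assert bundle.wildtype == {} and bundle.variant == {}
        serialize_bundle(bundle, tmp_path / "e")
        reloaded = load_bundle(tmp_path / "e")
        assert reloaded.wildtype == {} and reloaded.variant == {}

    def test_version_mismatch_rejected(self, bundle, tmp_path):
        import json

        serialize_bundle(bundle, tmp_path / "v")
        meta = json.loads((tmp_path / "v" / "metadata.json").read_text())
        meta["format_version"] = "999"
        (tmp_path / "v" / "metadata.json").write_text(json.dumps(meta))
        with pytest.raises(TableError):
            load_bundle(tmp_path / "v")

    def test_truncated_file_rejected(self, bundle, tmp_path):
        serialize_bundle(bundle, tmp_path / "tr")
        path = tmp_path / "tr" / "wildtype.tsv"
        data = path.read_bytes()
        path.write_bytes(data[:-7])  # chop mid-row
        with pytest.raises(TableError):
            load_bundle(tmp_path / "tr")
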