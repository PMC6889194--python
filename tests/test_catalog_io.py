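"""Mutation parsing, context extraction, and pyrimidine-centric encoding."""

import numpy as np
import pytest

from factorsig.catalog_io import (
    AUTOSOMES,
    ContextUnavailable,
    MutationRecord,
    all_features,
    build_catalog,
    encode_feature,
    extract_context,
    read_catalog,
    read_mutations,
    reverse_complement,
    write_catalog,
)


class TestReadMutations:
    def test_empty_table_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("sample\tchrom\tpos\tref\talt\n")
        assert read_mutations(p) == []

    def test_indel_rows_are_skipped(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(
            "sample\tchrom\tpos\tref\talt\n"
            "s1\tchr1\t10\tC\tT\n"
            "s1\tchr1\t20\tCT\tC\n"  # indel
            "s2\tchr2\t30\tG\tA\n"
        )
        records = read_mutations(p)
        assert len(records) == 2
        assert {r.sample_id for r in records} == {"s1", "s2"}

    def test_vcf_positions_are_1_based(self, tmp_path):
        p = tmp_path / "t.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t100\t.\tC\tT\t.\t.\t.\n"
        )
        records = read_mutations(p, dialect="vcf")
        assert len(records) == 1
        assert records[0].pos == 100
        assert (records[0].ref, records[0].alt) == ("C", "T")

    def test_multiallelic_vcf_rows_are_split(self, tmp_path):
        p = tmp_path / "t.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t100\t.\tC\tT,G\t.\t.\t.\n"
        )
        records = read_mutations(p, dialect="vcf")
        assert [(r.pos, r.alt) for r in records] == [(100, "T"), (100, "G")]

    def test_unknown_dialect_raises(self, tmp_path):
        p = tmp_path / "x.tsv"
        p.write_text("sample\tchrom\tpos\tref\talt\n")
        with pytest.raises(ValueError, match="dialect"):
            read_mutations(p, dialect="bogus")


class TestRecordValidation:
    def test_ref_equals_alt_rejected(self):
        with pytest.raises(ValueError):
            MutationRecord("s", "chr1", 5, "C", "C")

    def test_position_must_be_positive(self):
        with pytest.raises(ValueError):
            MutationRecord("s", "chr1", 0, "C", "T")


class TestExtractContext:
    def test_direct_readoff(self, spec_fasta):
        rec = MutationRecord("s", "chr1", 3, "G", "A")
        assert extract_context(rec, spec_fasta) == "AAGCT"

    def test_window_underflow_is_flagged(self, spec_fasta):
        rec = MutationRecord("s", "chr1", 2, "A", "C")
        with pytest.raises(ContextUnavailable):
            extract_context(rec, spec_fasta)

    def test_window_overflow_is_flagged(self, spec_fasta):
        rec = MutationRecord("s", "chr1", 6, "A", "C")
        with pytest.raises(ContextUnavailable):
            extract_context(rec, spec_fasta)

    def test_n_in_context_is_flagged(self, tmp_path):
        from pyfaidx import Fasta

        p = tmp_path / "n.fa"
        p.write_text(">chr1\nAANCTAA\n")
        rec = MutationRecord("s", "chr1", 4, "C", "T")
        with pytest.raises(ContextUnavailable):
            extract_context(rec, Fasta(str(p)))

    def test_absent_chromosome_raises(self, spec_fasta):
        rec = MutationRecord("s", "chr9", 3, "G", "A")
        with pytest.raises(KeyError):
            extract_context(rec, spec_fasta)

    def test_middle_base_matches_listed_context(self, toy_reference):
        ref, positions = toy_reference
        for chrom, pos, ctx in positions[::7]:
            rec = MutationRecord("s", chrom, pos, ctx[2], "A" if ctx[2] != "A" else "C")
            assert extract_context(rec, ref) == ctx


class TestEncodeFeature:
    def test_purine_reference_is_reverse_complemented(self):
        feat = encode_feature("AAGCT", "G", "A", "+")
        assert feat.sub_type == "C>T"
        assert (feat.flank_m2, feat.flank_m1, feat.flank_p1, feat.flank_p2) == ("A", "G", "T", "T")
        assert feat.strand == "-"

    def test_pyrimidine_reference_kept_as_is(self):
        feat = encode_feature("AACTT", "C", "A", "+")
        assert feat.sub_type == "C>A"
        assert (feat.flank_m2, feat.flank_m1, feat.flank_p1, feat.flank_p2) == ("A", "A", "T", "T")
        assert feat.strand == "+"

    def test_missing_strand_stays_missing(self):
        feat = encode_feature("AATGG", "T", "G", None)
        assert feat.sub_type == "T>G"
        assert (feat.flank_m2, feat.flank_m1, feat.flank_p1, feat.flank_p2) == ("A", "A", "G", "G")
        assert feat.strand is None

    def test_context_ref_mismatch_raises(self):
        with pytest.raises(ValueError):
            encode_feature("AACTT", "G", "A", None)

    @pytest.mark.parametrize("seed", range(10))
    def test_involution_consistency(self, seed):
        """Encoding a purine-reference mutation equals encoding the
        reverse-complemented context with pyrimidine reference directly."""
        rng = np.random.default_rng(seed)
        bases = "ACGT"
        ctx = "".join(rng.choice(list(bases), size=5))
        ref = ctx[2]
        alt = rng.choice([b for b in bases if b != ref])
        strand = rng.choice(["+", "-"])
        direct = encode_feature(ctx, ref, alt, strand)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        flipped = encode_feature(
            reverse_complement(ctx), comp[ref], comp[alt],
            "-" if strand == "+" else "+",
        )
        assert direct == flipped


class TestFeatureSpace:
    def test_combination_counts(self):
        assert len(all_features(True)) == 3072
        assert len(all_features(False)) == 1536

    def test_enumeration_is_unique_and_pyrimidine_centric(self):
        feats = all_features(True)
        assert len(set(feats)) == 3072
        assert all(f.sub_type[0] in "CT" for f in feats)


class TestBuildCatalog:
    def _records_on(self, reference_positions, n, sample="s1", chrom_filter=None):
        recs = []
        for chrom, pos, ctx in reference_positions:
            if chrom_filter and chrom != chrom_filter:
                continue
            alt = "A" if ctx[2] != "A" else "C"
            recs.append(MutationRecord(sample, chrom, pos, ctx[2], alt))
            if len(recs) == n:
                break
        return recs

    def test_non_autosome_records_dropped(self, toy_reference):
        ref, positions = toy_reference
        recs = self._records_on(positions, 4)
        recs.append(MutationRecord("s1", "chrX", 10, "C", "T"))
        catalog = build_catalog(recs, ref, keep_chroms=AUTOSOMES)
        assert catalog.n_mutations == 4
        assert catalog.drop_counts == {"chromosome": 1}

    def test_identical_events_aggregate(self, toy_reference):
        ref, positions = toy_reference
        rec = self._records_on(positions, 1)[0]
        catalog = build_catalog([rec, rec], ref)
        assert catalog.n_features == 1
        assert catalog.counts[0, 0] == 2

    def test_row_totals_are_per_sample_counts(self, toy_reference):
        ref, positions = toy_reference
        recs = self._records_on(positions, 3, sample="a")
        recs += self._records_on(positions[5:], 2, sample="b")
        catalog = build_catalog(recs, ref)
        assert catalog.samples == ["a", "b"]
        assert list(catalog.sample_totals) == [3, 2]

    def test_conservation_of_records(self, toy_reference):
        """Catalog total plus dropped count equals the number of inputs."""
        ref, positions = toy_reference
        recs = self._records_on(positions, 6)
        recs.append(MutationRecord("s1", "chrX", 10, "C", "T"))
        recs.append(MutationRecord("s1", "chr1", 1, "A", "C"))  # window underflow
        catalog = build_catalog(recs, ref)
        assert catalog.n_mutations + sum(catalog.drop_counts.values()) == len(recs)

    def test_all_dropped_raises_with_reason(self, toy_reference):
        ref, _ = toy_reference
        recs = [MutationRecord("s1", "chrX", 10, "C", "T")]
        with pytest.raises(ValueError, match="chromosome"):
            build_catalog(recs, ref)

    def test_strand_dropped_when_any_record_lacks_it(self, toy_reference):
        ref, positions = toy_reference
        recs = self._records_on(positions, 4)
        recs[0].tx_strand = "+"  # others missing
        catalog = build_catalog(recs, ref)
        assert not catalog.includes_strand
        assert all(f.strand is None for f in catalog.features)

    def test_round_trip_through_long_table(self, tmp_path, toy_reference):
        ref, positions = toy_reference
        recs = self._records_on(positions, 8)
        catalog = build_catalog(recs, ref)
        path = tmp_path / "catalog.tsv"
        write_catalog(catalog, path)
        back = read_catalog(path)
        assert back.samples == catalog.samples
        assert back.features == catalog.features
        assert (back.counts == catalog.counts).all()
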