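import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gcusage import genome_io
from gcusage.genome_io import (
    FormatError,
    GeneAnnotation,
    GenomeRecord,
    UndefinedGCError,
    ValidationError,
    extract_cds,
    genomic_at,
    genomic_gc,
    read_fasta,
    read_profile_table,
    read_ptt,
    reverse_complement,
    write_fasta,
    write_profile_table,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=200)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

class TestReadFasta:
    def test_single_record(self, tmp_path):
        path = tmp_path / "a.fna"
        path.write_text(">chr1\nACGT\n")
        assert read_fasta(path) == [("chr1", "ACGT")]

    def test_order_preserved(self, tmp_path):
        path = tmp_path / "a.fna"
        path.write_text(">r1\nACGTAA\n>r2\nACGTACGTA\n")
        records = read_fasta(path)
        assert [r[0] for r in records] == ["r1", "r2"]
        assert [len(r[1]) for r in records] == [6, 9]

    def test_lowercase_normalised(self, tmp_path):
        path = tmp_path / "a.fna"
        path.write_text(">chr1\nacgt\n")
        assert read_fasta(path)[0][1] == "ACGT"

    def test_empty_file_is_format_error(self, tmp_path):
        path = tmp_path / "empty.fna"
        path.write_text("")
        with pytest.raises(FormatError, match="line 1"):
            read_fasta(path)

    def test_malformed_header_names_line(self, tmp_path):
        path = tmp_path / "bad.fna"
        path.write_text("\nACGT\n")
        with pytest.raises(FormatError, match="line 2"):
            read_fasta(path)

    @given(st.lists(dna, min_size=1, max_size=5))
    def test_round_trip(self, tmp_path_factory, seqs):
        path = tmp_path_factory.mktemp("fa") / "rt.fna"
        records = [(f"s{i}", seq) for i, seq in enumerate(seqs)]
        write_fasta(records, path)
        assert read_fasta(path) == records


# ---------------------------------------------------------------------------
# PTT
# ---------------------------------------------------------------------------

PTT_HEADER = (
    "Synthetic chromosome - 1..1000\n"
    "2 proteins\n"
    "Location\tStrand\tLength\tPID\tGene\tSynonym\tCode\tCOG\tProduct\n"
)


class TestReadPtt:
    def test_direct_parse(self, tmp_path):
        path = tmp_path / "a.ptt"
        path.write_text(PTT_HEADER + "190..255\t+\t21\t1\t-\tgeneA\t-\t-\tp\n")
        (ann,) = read_ptt(path, "chr")
        assert (ann.start, ann.end, ann.strand) == (190, 255, "+")
        assert ann.gene_id == "geneA"
        assert ann.replicon_id == "chr"

    def test_inverted_coordinates_skipped_with_warning(self, tmp_path, caplog):
        path = tmp_path / "a.ptt"
        path.write_text(PTT_HEADER + "10..3\t+\t2\t1\t-\tg\t-\t-\tp\n")
        with caplog.at_level("WARNING"):
            assert read_ptt(path, "chr") == []
        assert "end < start" in caplog.text

    def test_non_integer_coordinates(self, tmp_path):
        path = tmp_path / "a.ptt"
        path.write_text(PTT_HEADER + "xx..255\t+\t1\t1\t-\tg\t-\t-\tp\n")
        with pytest.raises(FormatError, match="non-integer"):
            read_ptt(path, "chr")

    def test_empty_data_section(self, tmp_path):
        path = tmp_path / "a.ptt"
        path.write_text(PTT_HEADER)
        assert read_ptt(path, "chr") == []

    def test_round_trip(self, tmp_path):
        annotations = [
            GeneAnnotation("chr", 11, 70, "+", "g1"),
            GeneAnnotation("chr", 101, 160, "-", "g2"),
        ]
        path = tmp_path / "rt.ptt"
        genome_io.write_ptt(annotations, path, "chr", 200)
        assert read_ptt(path, "chr") == annotations


# ---------------------------------------------------------------------------
# CDS extraction and reverse complement
# ---------------------------------------------------------------------------

class TestExtractCds:
    def _genome(self, annotations):
        return GenomeRecord("g", [("chr", "ATGAAACCC")], annotations)

    def test_plus_strand_slice(self):
        (cds,) = extract_cds(self._genome([GeneAnnotation("chr", 1, 6, "+", "a")]))
        assert cds.sequence == "ATGAAA"

    def test_minus_strand_reverse_complement(self):
        (cds,) = extract_cds(self._genome([GeneAnnotation("chr", 1, 6, "-", "a")]))
        assert cds.sequence == "TTTCAT"

    def test_non_triplet_gene_eliminated(self):
        assert extract_cds(self._genome([GeneAnnotation("chr", 1, 7, "+", "a")])) == []

    def test_out_of_range_excluded(self):
        assert extract_cds(self._genome([GeneAnnotation("chr", 7, 12, "+", "a")])) == []

    def test_origin_spanning_excluded(self):
        assert extract_cds(self._genome([GeneAnnotation("chr", 7, 3, "+", "a")])) == []

    def test_output_lengths_divisible_by_3(self):
        anns = [
            GeneAnnotation("chr", s, e, "+", f"g{s}")
            for s, e in [(1, 3), (1, 6), (2, 7), (1, 9), (1, 5)]
        ]
        for cds in extract_cds(self._genome(anns)):
            assert len(cds.sequence) % 3 == 0


@given(dna)
def test_reverse_complement_is_involution(seq):
    assert reverse_complement(reverse_complement(seq)) == seq


def test_reverse_complement_pairs_bases():
    assert reverse_complement("ATGC") == "GCAT"
    assert reverse_complement("AAAC") == "GTTT"


# ---------------------------------------------------------------------------
# Genomic GC
# ---------------------------------------------------------------------------

class TestGenomicGC:
    @pytest.mark.parametrize(
        "seq, expected", [("GGCC", 1.0), ("ATGC", 0.5), ("ATNN", 0.0)]
    )
    def test_examples(self, seq, expected):
        assert genomic_gc(seq) == expected

    def test_ambiguity_excluded_from_denominator(self):
        assert genomic_io_counts("ATNN") == (0, 2)

    def test_all_ambiguous_raises(self):
        with pytest.raises(UndefinedGCError):
            genomic_gc("NNNN")

    def test_multi_replicon_genome_wide(self):
        genome = GenomeRecord("g", [("c1", "GGGG"), ("c2", "AAAA")])
        assert genomic_gc(genome) == 0.5

    @given(dna)
    def test_gc_plus_at_is_one(self, seq):
        assert genomic_gc(seq) + genomic_at(seq) == pytest.approx(1.0, abs=1e-12)


def genomic_io_counts(seq):
    return genome_io.gc_base_counts(seq)


# ---------------------------------------------------------------------------
# Profile tables
# ---------------------------------------------------------------------------

class TestProfileTables:
    def test_base_round_trip_and_block_sums(self, tmp_path):
        rng = np.random.default_rng(0)
        vec = np.concatenate([rng.dirichlet(np.ones(4)) for _ in range(3)])
        path = tmp_path / "base.tsv"
        write_profile_table({"g1": vec}, "base", path)
        loaded = read_profile_table(path, "base")
        np.testing.assert_allclose(loaded["g1"], vec, atol=1e-12)
        assert loaded["g1"].reshape(3, 4).sum(axis=1) == pytest.approx([1, 1, 1])

    def test_codon_round_trip_xlsx(self, tmp_path):
        rng = np.random.default_rng(1)
        vec = rng.dirichlet(np.ones(64))
        path = tmp_path / "codon.xlsx"
        write_profile_table({"g1": vec}, "codon", path)
        np.testing.assert_allclose(
            read_profile_table(path, "codon")["g1"], vec, atol=1e-12
        )

    def test_wrong_column_count(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("genome_id\tA1\tT1\ng1\t0.5\t0.5\n")
        with pytest.raises(FormatError, match="13 columns"):
            read_profile_table(path, "base")

    def test_duplicate_genome_id(self, tmp_path):
        path = tmp_path / "gc.tsv"
        path.write_text("genome_id\tgc\ng1\t0.4\ng1\t0.5\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_profile_table(path, "gc")

    def test_frequency_outside_unit_interval(self, tmp_path):
        path = tmp_path / "gc.tsv"
        path.write_text("genome_id\tgc\ng1\t1.4\n")
        with pytest.raises(ValidationError, match=r"outside \[0, 1\]"):
            read_profile_table(path, "gc")

    def test_load_profile_dir_round_trip(self, tmp_path, small_profiles):
        from gcusage import load_profile_dir, write_profiles

        write_profiles(small_profiles, tmp_path)
        loaded = load_profile_dir(tmp_path)
        assert len(loaded) == len(small_profiles)
        by_id = {p.genome_id: p for p in small_profiles}
        for p in loaded:
            np.testing.assert_allclose(p.codon_vec, by_id[p.genome_id].codon_vec)
            assert p.gc == pytest.approx(by_id[p.genome_id].gc)
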