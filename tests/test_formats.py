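import numpy as np
import pandas as pd
import pytest

from enhmotif import formats
from enhmotif.formats import FormatError
from enhmotif.synthetic import default_motif_library


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadBed:
    def test_parses_named_interval(self, tmp_path):
        p = write(tmp_path, "a.bed", "chr1\t100\t200\tE1\n")
        (iv,) = formats.read_bed(p)
        assert (iv.chrom, iv.start, iv.end, iv.name) == ("chr1", 100, 200, "E1")

    def test_end_not_after_start_is_error_with_line_number(self, tmp_path):
        p = write(tmp_path, "a.bed", "chr1\t100\t200\tE1\nchr1\t200\t100\tE2\n")
        with pytest.raises(FormatError, match="2"):
            formats.read_bed(p)

    def test_three_column_lines_are_autonamed(self, tmp_path):
        lines = "".join(f"chr1\t{i * 100}\t{i * 100 + 50}\n" for i in range(5))
        ivs = formats.read_bed(write(tmp_path, "a.bed", lines))
        assert [iv.name for iv in ivs] == [f"region_{i + 1}" for i in range(5)]

    def test_duplicate_names_rejected(self, tmp_path):
        p = write(tmp_path, "a.bed", "chr1\t0\t10\tE\nchr1\t20\t30\tE\n")
        with pytest.raises(FormatError, match="duplicate"):
            formats.read_bed(p)

    def test_total_width_is_sum_of_spans(self, tmp_path):
        lines = "".join(f"chr1\t{i * 300}\t{i * 300 + 120}\n" for i in range(7))
        ivs = formats.read_bed(write(tmp_path, "a.bed", lines))
        assert sum(iv.width for iv in ivs) == 7 * 120


class TestMotifLibrary:
    def test_jaspar_counts_get_quarter_pseudocount(self, tmp_path):
        # count column (10,0,0,0): probability (10+.25)/(10+1) for A, .25/11 others
        pfm = ">M1 test\nA [ 10 10 ]\nC [ 0 0 ]\nG [ 0 0 ]\nT [ 0 0 ]\n"
        (pwm,) = formats.read_motif_library(write(tmp_path, "m.pfm", pfm), "jaspar-pfm")
        assert pwm.probs[0, 0] == pytest.approx(10.25 / 11)
        assert pwm.probs[0, 1] == pytest.approx(0.25 / 11)
        assert np.allclose(pwm.probs.sum(axis=1), 1.0, atol=1e-9)
        # IC uses the raw counts: deterministic columns give 2 bits each
        assert pwm.information_content == pytest.approx(4.0)

    def test_zero_total_column_is_error(self, tmp_path):
        pfm = ">M1 test\nA [ 10 0 ]\nC [ 0 0 ]\nG [ 0 0 ]\nT [ 0 0 ]\n"
        with pytest.raises(FormatError, match="zero-total"):
            formats.read_motif_library(write(tmp_path, "m.pfm", pfm), "jaspar-pfm")

    def test_meme_minimal_round_trip_is_identity(self, tmp_path):
        lib = default_motif_library(n_motifs=3, length=8)
        out = tmp_path / "lib.meme"
        formats.write_meme_minimal(lib, out)
        back = formats.read_motif_library(out, "meme-minimal")
        assert [p.motif_id for p in back] == [p.motif_id for p in lib]
        for a, b in zip(lib, back):
            assert np.allclose(a.probs, b.probs, atol=1e-9)
        # a second round trip is exactly stable
        out2 = tmp_path / "lib2.meme"
        formats.write_meme_minimal(back, out2)
        assert out.read_text() == out2.read_text()

    def test_bad_probability_column_is_error(self, tmp_path):
        meme = (
            "MEME version 4\n\nALPHABET= ACGT\n\nMOTIF BAD\n"
            "letter-probability matrix: alength= 4 w= 2\n"
            " 0.5 0.5 0.5 0.5\n 0.25 0.25 0.25 0.25\n"
        )
        with pytest.raises(FormatError, match="sums to"):
            formats.read_motif_library(write(tmp_path, "m.meme", meme), "meme-minimal")

    def test_empty_file_warns_and_returns_empty(self, tmp_path):
        p = write(tmp_path, "m.meme", "")
        with pytest.warns(UserWarning, match="empty"):
            assert formats.read_motif_library(p, "meme-minimal") == []


class TestExpressionTable:
    HEADER = "gene_id\tfpkm_a\tfpkm_b\tfold\tq_value\n"

    def test_reads_fields_verbatim(self, tmp_path):
        p = write(tmp_path, "e.tsv", self.HEADER + "Plagl1\t0.99\t45.26\t46.93\t0.001\n")
        df = formats.read_expression_table(p)
        row = df.iloc[0]
        assert row["gene_id"] == "Plagl1"
        assert row["fpkm_a"] == pytest.approx(0.99)
        assert row["fpkm_b"] == pytest.approx(45.26)
        # the supplied fold is trusted even though it is not fpkm_b/fpkm_a
        assert row["fold"] == pytest.approx(46.93)
        assert row["q_value"] == pytest.approx(0.001)

    def test_fold_recomputed_when_absent(self, tmp_path):
        p = write(tmp_path, "e.tsv",
                  "gene_id\tfpkm_a\tfpkm_b\tq_value\nA\t2.0\t10.0\t0.1\nB\t0.0\t5.0\t0.1\n")
        df = formats.read_expression_table(p)
        assert df["fold"].tolist()[0] == pytest.approx(5.0)
        assert np.isinf(df["fold"].tolist()[1])

    def test_negative_fpkm_is_error(self, tmp_path):
        p = write(tmp_path, "e.tsv", self.HEADER + "A\t-1\t5\t2\t0.1\n")
        with pytest.raises(FormatError, match="negative FPKM"):
            formats.read_expression_table(p)

    def test_duplicate_gene_named_in_error(self, tmp_path):
        p = write(tmp_path, "e.tsv", self.HEADER + "A\t1\t5\t5\t0.1\nA\t1\t5\t5\t0.1\n")
        with pytest.raises(FormatError, match="'A'"):
            formats.read_expression_table(p)

    def test_missing_column_lists_found_columns(self, tmp_path):
        p = write(tmp_path, "e.tsv", "gene_id\tfpkm_a\nA\t1\n")
        with pytest.raises(FormatError, match="fpkm_a"):
            formats.read_expression_table(p)


class TestGmt:
    def test_duplicate_genes_within_term_deduplicated(self, tmp_path):
        p = write(tmp_path, "t.gmt", "T1\tdesc\tA\tB\tA\n")
        assert formats.read_gmt(p) == {"T1": {"A", "B"}}

    def test_empty_file_gives_empty_mapping(self, tmp_path):
        assert formats.read_gmt(write(tmp_path, "t.gmt", "")) == {}

    def test_terms_sharing_genes_kept_independently(self, tmp_path):
        p = write(tmp_path, "t.gmt", "T1\td\tA\tB\nT2\td\tB\tC\n")
        terms = formats.read_gmt(p)
        assert terms["T1"] == {"A", "B"} and terms["T2"] == {"B", "C"}

    def test_short_line_is_error(self, tmp_path):
        with pytest.raises(FormatError, match="<3 fields"):
            formats.read_gmt(write(tmp_path, "t.gmt", "T1\tdesc\n"))

    def test_symbols_uppercased(self, tmp_path):
        p = write(tmp_path, "t.gmt", "T1\td\tPlagl1\tGcm1\n")
        assert formats.read_gmt(p)["T1"] == {"PLAGL1", "GCM1"}


class TestWriteResults:
    def test_empty_table_writes_header_only(self, tmp_path):
        out = tmp_path / "r.tsv"
        formats.write_results(pd.DataFrame(columns=["a", "b"]), out)
        assert out.read_text() == "a\tb\n"

    def test_same_inputs_twice_are_byte_identical(self, tmp_path):
        df = pd.DataFrame({"x": [1.234567891, 2.0], "y": ["u", "v"]})
        p1, p2 = tmp_path / "1.tsv", tmp_path / "2.tsv"
        formats.write_results(df, p1)
        formats.write_results(df.copy(), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_tiny_pvalues_survive_serialization(self, tmp_path):
        out = tmp_path / "r.tsv"
        formats.write_results(pd.DataFrame({"p": [1e-300]}), out)
        assert formats.read_results(out)["p"].iloc[0] == pytest.approx(1e-300)


class TestFastaRoundTrip:
    def test_round_trip_preserves_sequences(self, tmp_path):
        seqs = {"s1": "ACGTN" * 30, "s2": "TTTT"}
        p = tmp_path / "x.fa"
        formats.write_fasta(seqs, p)
        assert formats.read_fasta(p) == seqs

    def test_lowercase_uppercased_on_load(self, tmp_path):
        p = write(tmp_path, "x.fa", ">s\nacgt\n")
        assert formats.read_fasta(p) == {"s": "ACGT"}


class TestOrthologMap:
    def test_round_trip(self, tmp_path):
        mapping = {"e1": "o1", "e2": "o2"}
        p = tmp_path / "m.tsv"
        formats.write_ortholog_map(mapping, p)
        assert formats.read_ortholog_map(p) == mapping
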