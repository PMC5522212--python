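"""I/O round trips, schema validation and coordinate-dialect conversion."""
import numpy as np
import pandas as pd
import pytest

from lncarray import study_io
from lncarray.study_io import (
    EmptyDesignCellError,
    GeneSet,
    GeneSetCollection,
    StudyFormatError,
    TranscriptRecord,
)


class TestExpressionMatrix:
    def test_write_read_round_trip_identity(self, tmp_path, linear_matrix_factory):
        matrix = linear_matrix_factory([[1.5, 2.25], [3.125, 0.0625]])
        path = tmp_path / "m.tsv"
        study_io.write_expression_matrix(matrix, path)
        back = study_io.read_expression_matrix(path, scale="linear")
        pd.testing.assert_frame_equal(back.values, matrix.values, check_names=False)
        assert back.scale == "linear" and not back.normalized

    def test_duplicate_probe_id_is_an_error_naming_the_id(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("probe_id\ts1\np1\t1.0\np1\t2.0\n")
        with pytest.raises(StudyFormatError, match="p1"):
            study_io.read_expression_matrix(path, scale="linear")

    def test_row_with_missing_cell_dropped_and_counted(self, tmp_path):
        path = tmp_path / "miss.tsv"
        path.write_text("probe_id\ts1\ts2\np1\t1.0\t2.0\np2\t3.0\t\np3\t4.0\t5.0\n")
        matrix = study_io.read_expression_matrix(path, scale="linear")
        assert matrix.load_report.n_dropped_missing == 1
        assert matrix.load_report.dropped_probe_ids == ["p2"]
        assert matrix.probe_ids == ["p1", "p3"]

    def test_non_numeric_cell_error_names_row_and_column(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("probe_id\ts1\ts2\np1\t1.0\toops\n")
        with pytest.raises(StudyFormatError, match="p1.*s2"):
            study_io.read_expression_matrix(path, scale="linear")

    def test_empty_file_is_an_error(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("probe_id\ts1\n")
        with pytest.raises(StudyFormatError, match="empty"):
            study_io.read_expression_matrix(path, scale="linear")

    def test_negative_linear_intensity_rejected(self, linear_matrix_factory):
        with pytest.raises(StudyFormatError, match=">= 0"):
            linear_matrix_factory([[-1.0, 2.0]])


class TestSampleSheet:
    def _write_sheet(self, tmp_path, rows):
        path = tmp_path / "samples.tsv"
        body = "\n".join("\t".join(map(str, r)) for r in rows)
        path.write_text("sample_id\tcondition\ttime_point\treplicate\n" + body + "\n")
        return path

    def test_full_design_has_six_complete_cells(self, tmp_path):
        rows = [
            (f"{c}_{t}_{r}", c, t, r)
            for c in ("case", "control")
            for t in ("0h", "2h", "48h")
            for r in (1, 2, 3)
        ]
        design = study_io.read_sample_sheet(self._write_sheet(tmp_path, rows))
        assert len(design.samples) == 18
        for condition in ("case", "control"):
            for tp in ("T0", "T2", "T48"):
                assert len(design.cell(condition, tp)) == 3

    def test_time_point_aliases_accepted(self, tmp_path):
        rows = [
            ("a", "RS", "2 hrs", 1), ("b", "parental", "2hr", 1),
            ("c", "case", "T48", 1), ("d", "control", "0 h", 1),
        ]
        design = study_io.read_sample_sheet(self._write_sheet(tmp_path, rows))
        assert [s.time_point for s in design.samples] == ["T2", "T2", "T48", "T0"]
        assert [s.condition for s in design.samples] == ["case", "control", "case", "control"]

    def test_unknown_tokens_rejected(self, tmp_path):
        with pytest.raises(StudyFormatError, match="time_point"):
            study_io.read_sample_sheet(self._write_sheet(tmp_path, [("a", "case", "7h", 1)]))
        with pytest.raises(StudyFormatError, match="condition"):
            study_io.read_sample_sheet(self._write_sheet(tmp_path, [("a", "maybe", "0h", 1)]))

    def test_duplicate_sample_id_rejected(self, tmp_path):
        rows = [("a", "case", "0h", 1), ("a", "control", "0h", 1)]
        with pytest.raises(StudyFormatError, match="duplicate"):
            study_io.read_sample_sheet(self._write_sheet(tmp_path, rows))

    def test_missing_cell_errors_only_when_requested(self, tmp_path):
        rows = [("a", "case", "0h", 1), ("b", "control", "0h", 1),
                ("c", "control", "48h", 1)]
        design = study_io.read_sample_sheet(self._write_sheet(tmp_path, rows))
        assert design.cell("case", "T0") == ["a"]  # fine
        with pytest.raises(EmptyDesignCellError, match="empty design cell"):
            design.cell("case", "T48")

    def test_round_trip(self, tmp_path, design_3x3):
        path = tmp_path / "sheet.tsv"
        study_io.write_sample_sheet(design_3x3, path)
        assert study_io.read_sample_sheet(path) == design_3x3


class TestAnnotation:
    GTF = (
        'chr1\tsrc\ttranscript\t101\t400\t.\t+\t.\ttranscript_id "tx1"; gene_id "g1"; '
        'probe_id "p1"; rna_type "mRNA";\n'
        'chr1\tsrc\texon\t101\t200\t.\t+\t.\ttranscript_id "tx1";\n'
        'chr1\tsrc\texon\t301\t400\t.\t+\t.\ttranscript_id "tx1";\n'
        'chr1\tsrc\tthree_prime_utr\t351\t400\t.\t+\t.\ttranscript_id "tx1";\n'
    )

    def test_gtf_one_based_converted_to_zero_based_half_open(self, tmp_path):
        path = tmp_path / "a.gtf"
        path.write_text(self.GTF)
        ann = study_io.read_annotation(path)
        rec = ann["p1"]
        assert (rec.start, rec.end) == (100, 400)
        assert rec.exons == [(100, 200), (300, 400)]
        assert rec.utr3 == (350, 400)

    def test_gtf_and_equivalent_flat_tsv_load_identically(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text(self.GTF)
        flat = tmp_path / "a.tsv"
        flat.write_text(
            "probe_id\trna_type\ttranscript_id\tgene_id\tchrom\tstrand\tstart\tend"
            "\texons\tutr3\tclass\n"
            "p1\tmRNA\ttx1\tg1\tchr1\t+\t100\t400\t100-200;300-400\t350-400\t\n"
        )
        assert study_io.read_annotation(gtf) == study_io.read_annotation(flat)

    def test_missing_strand_rejected(self, tmp_path):
        flat = tmp_path / "a.tsv"
        flat.write_text(
            "probe_id\trna_type\ttranscript_id\tgene_id\tchrom\tstrand\tstart\tend"
            "\texons\tutr3\tclass\n"
            "p1\tmRNA\ttx1\tg1\tchr1\t.\t100\t400\t\t\t\n"
        )
        with pytest.raises(StudyFormatError, match="strand required"):
            study_io.read_annotation(flat)

    def test_gtf_inverted_coordinates_rejected(self, tmp_path):
        path = tmp_path / "bad.gtf"
        path.write_text('chr1\tsrc\ttranscript\t400\t101\t.\t+\t.\ttranscript_id "t";\n')
        with pytest.raises(StudyFormatError, match="start > end"):
            study_io.read_annotation(path)

    def test_transcript_without_exons_gets_span_exon(self, tmp_path):
        path = tmp_path / "noexon.gtf"
        path.write_text(
            'chr1\tsrc\ttranscript\t101\t400\t.\t-\t.\ttranscript_id "t1"; probe_id "p1";\n'
        )
        rec = study_io.read_annotation(path)["p1"]
        assert rec.exons == [(100, 400)]

    def test_flat_round_trip(self, tmp_path):
        rec = TranscriptRecord(
            probe_id="p9", rna_type="lncRNA", transcript_id="t9", gene_id="g9",
            chrom="chr2", strand="-", start=50, end=900,
            exons=[(50, 200), (400, 900)], utr3=None, class_label="Intergenic",
        )
        ann = study_io.TranscriptAnnotation({"p9": rec})
        path = tmp_path / "ann.tsv"
        study_io.write_annotation(ann, path)
        assert study_io.read_annotation(path) == ann

    def test_exon_ordering_and_span(self):
        rec = TranscriptRecord(
            probe_id="p", rna_type="mRNA", transcript_id="t", gene_id="g",
            chrom="chr1", strand="+", start=100, end=400,
            exons=[(300, 400), (100, 200)],
        )
        assert rec.exons == [(100, 200), (300, 400)]
        assert rec.span == (100, 400)
        assert rec.introns() == [(200, 300)]


class TestGeneSets:
    def test_members_deduplicated(self, tmp_path):
        path = tmp_path / "s.gmt"
        path.write_text("S1\tdesc\tA\tB\tA\n")
        collection = study_io.read_gene_sets(path)
        assert collection.sets[0].members == {"A", "B"}

    def test_short_line_error_reports_line_number(self, tmp_path):
        path = tmp_path / "s.gmt"
        path.write_text("S1\tdesc\tA\nS2\tdesc\n")
        with pytest.raises(StudyFormatError, match=":2"):
            study_io.read_gene_sets(path)

    def test_sets_sharing_members_load_independently(self, tmp_path):
        path = tmp_path / "s.gmt"
        path.write_text("S1\td\tA\tB\nS2\td\tB\tC\n")
        collection = study_io.read_gene_sets(path)
        assert collection.sets[0].members & collection.sets[1].members == {"B"}

    def test_duplicate_set_names_rejected(self):
        with pytest.raises(StudyFormatError, match="unique"):
            GeneSetCollection([GeneSet("S", "", frozenset("A")),
                               GeneSet("S", "", frozenset("B"))])

    def test_round_trip(self, tmp_path):
        collection = GeneSetCollection(
            [GeneSet("S1", "d1", frozenset({"A", "B"})), GeneSet("S2", "d2", frozenset({"C"}))]
        )
        path = tmp_path / "rt.gmt"
        study_io.write_gene_sets(collection, path)
        assert study_io.read_gene_sets(path) == collection


class TestFasta:
    def test_round_trip(self, tmp_path):
        sequences = {"p1": "ACGTACGT", "p2": "TTTTAAAA"}
        path = tmp_path / "seq.fasta"
        study_io.write_fasta(sequences, path)
        assert study_io.read_fasta(path) == sequences
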