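import pytest
from hypothesis import given, settings, strategies as st

from sirnakit.core import parse_modified, serialize_modified
from sirnakit.modpattern import (
    PatternTable,
    apply_full_2ome,
    apply_patterns,
    classify_energy,
    default_table,
    junction_pattern_check,
    segment,
)
from conftest import SIPCSK9_2_AS, SIPCSK9_2_12_AS_NOTATION

#: the published pattern table, frozen cell-for-cell (terminal cells keep
#: their 5'/3' prefixes); the sense-column 5'XY cell is "5'fXfX" as printed
PRINTED_TABLE = {
    "XXX": {"set1_even": "mXmXfX", "set2_odd": "mXfXmX", "sense": "fXmXmX"},
    "YYY": {"set1_even": "mYmYfY", "set2_odd": "mYfYmY", "sense": "fYmYmY"},
    "XYX": {"set1_even": "mXfYmX", "set2_odd": "fXmYfX", "sense": "fXfYmX"},
    "YXY": {"set1_even": "fYmXfY", "set2_odd": "mYfXmY", "sense": "mYmXfY"},
    "5'XY": {"set1_even": "5'mXfY", "set2_odd": "5'fXmY", "sense": "5'fXfX"},
    "5'YX": {"set1_even": "5'mYfX", "set2_odd": "5'fYmX", "sense": "5'fYfX"},
    "5'XX": {"set1_even": "5'mXmX", "set2_odd": "5'fXfX", "sense": "5'mXfX"},
    "3'XY": {"set1_even": "3'mXfY", "set2_odd": "3'fXmY", "sense": "3'mXfX"},
    "3'YX": {"set1_even": "3'fYmX", "set2_odd": "3'mYfX", "sense": "3'mYmX"},
    "3'XX": {"set1_even": "3'fXfX", "set2_odd": "3'mXmX", "sense": "3'fXmX"},
    "3'YY": {"set1_even": "3'mYmY", "set2_odd": "3'fYfY", "sense": "3'fYmY"},
}

class_strings = st.text(alphabet="XY", min_size=5, max_size=25)


class TestClassify:
    def test_basic_mapping(self):
        assert classify_energy("AUGC") == "XXYY"

    def test_published_antisense(self):
        assert classify_energy(SIPCSK9_2_AS) == "XXXXXXYXYXYYXXYYXXYYY"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classify_energy("")


class TestPatternTableData:
    def test_bundled_file_matches_printed_table(self):
        table = default_table()
        for case, row in PRINTED_TABLE.items():
            for col, cell in row.items():
                assert table.cases[case][col] == cell, (case, col)

    def test_no_5prime_yy_row(self):
        # the printed table carries no 5'YY case; faithfully absent
        assert "5'YY" not in default_table().cases

    def test_derived_split_rows(self):
        table = default_table()
        assert table.sugars_for("XXXX", "set2_odd") == "mffm"
        assert table.sugars_for("YYYY", "set2_odd") == "fmmf"

    def test_f_count_per_cell(self):
        # structural sanity of every cell: length matches case, letters m/f
        table = default_table()
        for case, row in table.cases.items():
            body = case[2:] if case[:2] in ("5'", "3'") else case
            for col in PatternTable.COLUMNS:
                sugars = table.sugars_for(case, col)
                assert len(sugars) == len(body)
                assert set(sugars) <= {"m", "f"}


class TestSegmentation:
    def test_published_antisense_partition(self):
        classes = classify_energy(SIPCSK9_2_AS)
        segs = segment(classes)
        assert segs[0].label == "5'XX" and segs[0].start == 1
        assert segs[-1].label == "3'YY" and segs[-1].start == 20
        # exact partition
        covered = []
        for s in segs:
            covered.extend(range(s.start, s.start + s.length))
        assert covered == list(range(1, len(classes) + 1))

    def test_homogeneous_run_split_into_4mers(self):
        segs = segment("X" * 21)
        labels = [s.label for s in segs]
        assert labels[0] == "5'XX" and labels[-1] == "3'XX"
        assert set(labels[1:-1]) <= {"XXX", "XXXX"}

    def test_junction_islands_merge_into_triplets(self):
        # single-base islands recruit their neighbors into XYX/YXY cases
        segs = segment("XXXXXXYXYXYXXXXXXXXXX")
        internal = [s.classes for s in segs if not s.terminal]
        known = set(default_table().cases)
        assert all(c in known for c in internal)
        assert any(c in ("XYX", "YXY") for c in internal)

    @settings(max_examples=150, derandomize=True)
    @given(class_strings)
    def test_partition_property(self, classes):
        segs = segment(classes)
        covered = []
        for s in segs:
            covered.extend(range(s.start, s.start + s.length))
        assert covered == list(range(1, len(classes) + 1))
        assert segs[0].terminal == "5'"
        assert all(2 <= s.length <= 4 for s in segs)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            segment("XXXX")


class TestApplyPatterns:
    def test_five_mer_hand_applied(self):
        # AUAUA (classes XXXXX): 5'XX -> fXfX, then XXX -> mXfXmX (set2_odd)
        oligo = apply_patterns("AUAUA", column="set2_odd")
        assert serialize_modified(oligo) == "fAfUmAfUmA"

    def test_sense_column_xxx_cell(self):
        # internal XXX under the sense column is fXmXmX
        oligo = apply_patterns("AUAAAGC", column="sense")
        # segments: 5'XX, AAA (XXX), 3'YY
        assert oligo.sugars[2:5] == "fmm"

    def test_full_2ome_control(self):
        oligo = apply_full_2ome(SIPCSK9_2_AS)
        assert set(oligo.sugars) == {"m"}
        assert oligo.bases == SIPCSK9_2_AS

    def test_base_sequence_invariant(self):
        oligo = apply_patterns(SIPCSK9_2_AS, column="set1_even", on_missing="2ome")
        assert oligo.bases == SIPCSK9_2_AS
        assert len(oligo) == len(SIPCSK9_2_AS)

    def test_missing_case_error_names_case(self):
        with pytest.raises(KeyError) as excinfo:
            apply_patterns("GCAUA", column="set2_odd")
        assert "5'YY" in excinfo.value.args[0]

    def test_on_missing_2ome_fallback(self):
        oligo = apply_patterns("GCAUA", column="set2_odd", on_missing="2ome")
        assert serialize_modified(oligo) == "mGmCmAfUmA"

    def test_round_trip_through_notation(self):
        oligo = apply_patterns("AUAUA", column="set1_even")
        assert parse_modified(serialize_modified(oligo)).residues == oligo.residues


class TestJunctionCheck:
    def test_published_design_starts_mxfx(self):
        oligo = parse_modified(SIPCSK9_2_12_AS_NOTATION)
        report = junction_pattern_check(oligo)
        assert report["five_prime_mxfx"] is True

    def test_all_m_has_no_f_motifs(self):
        report = junction_pattern_check(apply_full_2ome(SIPCSK9_2_AS))
        assert report["myfymxfx_positions"] == []
        assert report["five_prime_mxfx"] is False
        assert report["three_prime_fymy"] is False

    def test_report_fields_are_flags_and_positions(self):
        report = junction_pattern_check(parse_modified(SIPCSK9_2_12_AS_NOTATION))
        assert isinstance(report["myfymxfx_positions"], list)
        assert isinstance(report["mixed_energy_10_11"], bool)
        assert report["classes_10_11"] in ("XX", "XY", "YX", "YY")
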