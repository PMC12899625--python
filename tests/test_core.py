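import pytest
from hypothesis import given, settings, strategies as st

from sirnakit.core import (
    FastaFormatError,
    ModifiedOligo,
    NotationError,
    Residue,
    RnaStrand,
    SequenceError,
    SirnaDuplex,
    parse_modified,
    read_fasta,
    reverse_complement,
    serialize_modified,
    write_fasta,
)
from conftest import SIPCSK9_2_12_AS_NOTATION, duplex_from_sense

rna_seq = st.text(alphabet="ACGU", min_size=1, max_size=40)


class TestRnaStrand:
    def test_uppercases_and_validates(self):
        s = RnaStrand("acgu", name="x")
        assert s.seq == "ACGU"
        assert len(s) == 4
        assert s.base_at(1) == "A" and s.base_at(4) == "U"

    @pytest.mark.parametrize("bad", ["", "ACGX", "ACG N"])
    def test_rejects_bad_sequences(self, bad):
        with pytest.raises(SequenceError):
            RnaStrand(bad)


class TestReverseComplement:
    @pytest.mark.parametrize("seq,expected", [("AUGC", "GCAU"), ("UUU", "AAA"), ("ACGT", "ACGU")])
    def test_known_values(self, seq, expected):
        assert reverse_complement(seq) == expected

    @settings(max_examples=100, derandomize=True)
    @given(rna_seq)
    def test_involution_and_length(self, seq):
        rc = reverse_complement(seq)
        assert len(rc) == len(seq)
        assert reverse_complement(rc) == seq


class TestSirnaDuplex:
    def test_canonical_geometry(self):
        d = duplex_from_sense("GCAGCGCGAUUAACUUAUAUU")
        assert d.core_len == 19
        assert reverse_complement(d.sense_core) == d.antisense_core

    def test_rejects_noncomplementary_core(self):
        with pytest.raises(SequenceError):
            SirnaDuplex(sense=RnaStrand("A" * 21), antisense=RnaStrand("A" * 21))

    def test_rejects_bad_lengths(self):
        with pytest.raises(SequenceError):
            SirnaDuplex(sense=RnaStrand("AU"), antisense=RnaStrand("AU"))


class TestNotation:
    def test_parse_basic(self):
        o = parse_modified("mAfUmA")
        assert [(r.base, r.sugar, r.linkage3) for r in o.residues] == [
            ("A", "m", "po"), ("U", "f", "po"), ("A", "m", "po"),
        ]

    def test_parse_single_ribo(self):
        o = parse_modified("rA")
        assert len(o) == 1 and o.residues[0] == Residue("A", "r", "po")

    def test_parse_ps_linkage(self):
        o = parse_modified("mAsfUmG")
        assert o.residues[0].linkage3 == "ps"
        assert o.residues[1].linkage3 == "po"
        assert serialize_modified(o) == "mAsfUmG"

    def test_published_strand_round_trip(self):
        o = parse_modified(SIPCSK9_2_12_AS_NOTATION)
        assert len(o) == 21
        assert serialize_modified(o) == SIPCSK9_2_12_AS_NOTATION

    def test_case_insensitive_canonical_output(self):
        assert serialize_modified(parse_modified("MafuMA")) == "mAfUmA"

    @pytest.mark.parametrize("bad", ["", "mAx", "s", "mAs", "xA", "m"])
    def test_parse_errors(self, bad):
        with pytest.raises(NotationError):
            parse_modified(bad)

    def test_error_names_offset(self):
        with pytest.raises(NotationError, match="offset 4"):
            parse_modified("mAfUqG")

    def test_empty_oligo_rejected(self):
        with pytest.raises(NotationError):
            ModifiedOligo(())

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from("ACGU"),
                st.sampled_from("rmfd"),
                st.sampled_from(["po", "ps"]),
            ),
            min_size=1,
            max_size=30,
        )
    )
    def test_grammar_round_trip(self, spec):
        spec[-1] = (spec[-1][0], spec[-1][1], "po")  # last linkage must be po
        oligo = ModifiedOligo(tuple(Residue(*t) for t in spec))
        assert parse_modified(serialize_modified(oligo)).residues == oligo.residues


class TestFasta:
    def test_round_trip_and_t_conversion(self, tmp_path):
        path = tmp_path / "x.fasta"
        strands = [RnaStrand("ACGU" * 40, "a"), RnaStrand("ACGT", "b")]
        write_fasta(strands, path)
        back = read_fasta(path, rna=True)
        assert [s.name for s in back] == ["a", "b"]
        assert back[0].seq == "ACGU" * 40
        assert back[1].seq == "ACGU"  # T -> U in RNA mode
        # byte-stable sequence lines at wrap 60
        lines = path.read_text().splitlines()
        assert max(len(l) for l in lines if not l.startswith(">")) == 60

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        assert read_fasta(path) == []

    def test_headerless_file_rejected(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text("ACGU\n")
        with pytest.raises(FastaFormatError, match="line 1"):
            read_fasta(path)

    def test_empty_record_rejected(self, tmp_path):
        path = tmp_path / "bad2.fasta"
        path.write_text(">a\nACGU\n>b\n")
        with pytest.raises(FastaFormatError, match="record 2"):
            read_fasta(path)
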