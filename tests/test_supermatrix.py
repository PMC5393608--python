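"""Concatenation, partition recovery, and simple indel coding."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barcodekit.model import AlignedSequence, InputError, LocusAlignment, Specimen
from barcodekit.supermatrix import (
    concatenate,
    simple_indel_coding,
    with_indel_block,
)


def aln(locus, seqs):
    return LocusAlignment(
        locus, [AlignedSequence(sid, locus, r) for sid, r in seqs.items()]
    )


class TestConcatenate:
    def test_widths_and_partitions(self):
        sm = concatenate(
            [aln("L1", {"a": "ACG", "b": "ACG"}), aln("L2", {"a": "ACGT", "b": "ACGT"})]
        )
        assert sm.length == 7
        assert sm.partitions == {"L1": (0, 3), "L2": (3, 7)}

    def test_missing_locus_filled_with_question_marks(self):
        sm = concatenate(
            [aln("L1", {"a": "ACG", "b": "ACG"}), aln("L2", {"a": "ACGT"})]
        )
        assert sm.alignment["b"].residues == "ACG????"

    def test_five_barcode_aligned_lengths(self):
        """The four phylogenetic markers' aligned lengths sum to 2764."""
        widths = {"rbcL": 665, "matK": 746, "trnH-psbA": 508, "ITS": 845}
        loci = [aln(name, {"x": "A" * w}) for name, w in widths.items()]
        sm = concatenate(loci)
        assert sm.length == sum(widths.values()) == 2764

    def test_row_order_follows_metadata(self):
        specimens = [Specimen("b", "B x", "B"), Specimen("a", "A y", "A")]
        sm = concatenate([aln("L1", {"a": "ACG", "b": "TTT"})], specimens)
        assert sm.alignment.ids == ["b", "a"]

    def test_empty_loci_rejected(self):
        with pytest.raises(InputError):
            concatenate([])

    def test_partition_extraction_round_trip(self):
        l1 = aln("L1", {"a": "AC-G", "b": "ACTG"})
        l2 = aln("L2", {"b": "GG", "c": "GT"})
        sm = concatenate([l1, l2])
        assert sm.extract_partition("L1") == l1
        assert sm.extract_partition("L2") == l2

    def test_partition_writer(self, tmp_path):
        sm = concatenate(
            [aln("rbcL", {"a": "ACG"}), aln("matK", {"a": "ACGT"})]
        )
        p = tmp_path / "parts.txt"
        sm.write_partitions(p)
        assert p.read_text() == "DNA, rbcL = 1-3\nDNA, matK = 4-7\n"


class TestSimpleIndelCoding:
    def test_gapless_alignment_no_characters(self):
        table = simple_indel_coding(aln("L", {"a": "ACGT", "b": "ACGA"}))
        assert table.n_characters == 0

    def test_shared_gap_scored_present_absent(self):
        # one gap span at columns [2,5) shared by s1 and s2; s3 has residues
        table = simple_indel_coding(
            aln("L", {"s1": "AA---AAA", "s2": "CC---CCC", "s3": "GGGGGGGG"})
        )
        assert table.spans == [(2, 5)]
        assert (table.states["s1"], table.states["s2"], table.states["s3"]) == (
            "1", "1", "0",
        )

    def test_enclosing_gap_scored_missing(self):
        # sA's gap [1,7) strictly contains sB's gap [2,5)
        table = simple_indel_coding(
            aln("L", {"sA": "A------A", "sB": "AA---AAA", "sC": "AAAAAAAA"})
        )
        assert table.spans == [(1, 7), (2, 5)]
        assert table.states["sA"] == "1?"  # own span 1; encloses the other
        assert table.states["sB"] == "?1"  # overlapped without identity
        assert table.states["sC"] == "00"

    def test_terminal_gaps_never_coded(self):
        table = simple_indel_coding(
            aln("L", {"a": "---AAAAA", "b": "AAAAA---", "c": "AAAAAAAA"})
        )
        assert table.n_characters == 0

    def test_span_in_anothers_terminal_region_is_missing(self):
        # b's internal gap [1,3) lies inside a's leading missing region
        table = simple_indel_coding(
            aln("L", {"a": "----AAAA", "b": "A--AAAAA", "c": "AAAAAAAA"})
        )
        assert table.spans == [(1, 3)]
        assert table.states["a"] == "?"
        assert table.states["b"] == "1"
        assert table.states["c"] == "0"

    def test_character_count_is_distinct_spans(self):
        table = simple_indel_coding(
            aln(
                "L",
                {
                    "a": "A--AA---A",
                    "b": "A--AAAAAA",
                    "c": "AAAAA---A",
                    "d": "AAAAAAAAA",
                },
            )
        )
        assert table.spans == [(1, 3), (5, 8)]

    def test_indel_block_on_supermatrix(self):
        sm = concatenate(
            [
                aln("L1", {"a": "A--A", "b": "AAAA"}),
                aln("L2", {"a": "GG", "b": "GG"}),
            ]
        )
        sm = with_indel_block(sm)
        assert sm.indel_block.spans == [(1, 3)]  # supermatrix coordinates
        assert sm.indel_block.states == {"a": "1", "b": "0"}


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.data())
def test_indel_coding_order_invariant(data):
    """The character set is independent of sequence order."""
    n = data.draw(st.integers(3, 6))
    L = 12
    seqs = {}
    for k in range(n):
        row = list(data.draw(st.text(alphabet="ACG", min_size=L, max_size=L)))
        if data.draw(st.booleans()):
            s = data.draw(st.integers(1, L - 4))
            e = data.draw(st.integers(s + 1, min(s + 3, L - 1)))
            row[s:e] = "-" * (e - s)
        seqs[f"s{k}"] = "".join(row)
    ids = list(seqs)
    t1 = simple_indel_coding(aln("L", {i: seqs[i] for i in ids}))
    t2 = simple_indel_coding(aln("L", {i: seqs[i] for i in reversed(ids)}))
    assert t1.spans == t2.spans
    assert t1.states == t2.states
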