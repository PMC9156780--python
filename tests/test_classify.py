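"""CIGAR-complexity classification: complexity, admissibility, events, categories."""

import itertools

import pytest

from ampledit import (
    Alignment,
    CigarOp,
    Category,
    IndelEvent,
    admissible,
    cc_histogram,
    cigar_complexity,
    classify_allele,
    extract_events,
    frameshift_status,
    parse_cigar,
)
from ampledit.classify import (
    composition_counts,
    net_length_change,
    read_call_table,
    write_call_table,
)


def _aln(cigar_text: str, ref_start: int = 0, read_seq: str = None, read_id: str = "r"):
    ops = parse_cigar(cigar_text)
    if read_seq is None:
        n = sum(o.length for o in ops if o.op in "MIS")
        read_seq = "A" * n
    return Alignment(read_id, "amp", ref_start, ops, read_seq)


class TestCigarComplexity:
    @pytest.mark.parametrize(
        "cigar,expected",
        [
            ("250M", 1),
            ("100M5D145M", 3),
            ("50M2I3D50M1I1D50M", 7),  # MIDMIDM
            ("10M1I10M1D10M", 5),
        ],
    )
    def test_counts_alphabetic_ops(self, cigar, expected):
        assert cigar_complexity(parse_cigar(cigar)) == expected

    def test_empty_cigar_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cigar_complexity([])


class TestAdmissibility:
    @pytest.mark.parametrize(
        "cigar,expected",
        [
            ("20S230M", False),  # soft clip excludes
            ("230M20S", False),
            ("50M2I3D50M1I1D50M", True),  # the admitted CC-7 pattern MIDMIDM
            ("10M1I10M1D10M1I10M1D10M", False),  # CC 9
            ("250M", True),
            ("10M1D10M1I10M1D10M", False),  # CC 7 but MDMIMDM pattern... excluded
        ],
    )
    def test_rule_examples(self, cigar, expected):
        assert admissible(parse_cigar(cigar)) is expected

    def test_enumerated_patterns_match_rule_oracle(self):
        """Every canonical op pattern up to length 9 agrees with the
        brute-force statement of the rule: no S, and CC <= 6 or MIDMIDM."""
        checked = 0
        for k in range(1, 10):
            for pattern in itertools.product("MIDS", repeat=k):
                if any(a == b for a, b in zip(pattern, pattern[1:])):
                    continue  # non-canonical: adjacent ops would merge
                cigar = [CigarOp(op, 1) for op in pattern]
                want = "S" not in pattern and (
                    len(pattern) <= 6 or pattern == tuple("MIDMIDM")
                )
                assert admissible(cigar) is want, pattern
                checked += 1
        assert checked > 25_000


class TestExtractEvents:
    def test_deletion_coordinates(self):
        (e,) = extract_events(_aln("100M10D140M"))
        assert (e.kind, e.ref_pos, e.length) == ("deletion", 100, 10)

    def test_insertion_coordinates_with_offset(self):
        (e,) = extract_events(_aln("80M2I168M", ref_start=5))
        assert (e.kind, e.ref_pos, e.length) == ("insertion", 85, 2)

    def test_mixed_events_cursor_walk(self):
        events = extract_events(_aln("80M5D40M2I128M"))
        assert [(e.kind, e.ref_pos, e.length) for e in events] == [
            ("deletion", 80, 5),
            ("insertion", 125, 2),
        ]

    def test_insertion_sequence_captured(self):
        read = "A" * 80 + "GT" + "A" * 100
        (e,) = extract_events(_aln("80M2I100M", read_seq=read))
        assert e.inserted_seq == "GT"

    def test_inadmissible_alignment_rejected(self):
        with pytest.raises(ValueError, match="inadmissible"):
            extract_events(_aln("10S240M"))


class TestClassification:
    @pytest.mark.parametrize(
        "cigar,category",
        [
            ("250M", Category.WT),
            ("100M10D140M", Category.DELETION),
            ("100M3I150M", Category.INSERTION),
            ("80M5D40M2I128M", Category.MULTIPLE),
            ("50M2D50M3D50M", Category.MULTIPLE),  # two deletions
            ("50M2I50M3I50M", Category.MULTIPLE),  # two insertions
            ("20S230M", Category.EXCLUDED),
            ("10M1I10M1D10M1I10M1D10M", Category.EXCLUDED),
        ],
    )
    def test_category_assignment(self, cigar, category):
        call = classify_allele(_aln(cigar))
        assert call.category is category
        assert call.admissible is (category is not Category.EXCLUDED)

    def test_categories_exhaustive_and_exclusive(self):
        """Each enumerated pattern lands in exactly one category and
        Excluded coincides with inadmissibility."""
        for k in range(1, 8):
            for pattern in itertools.product("MIDS", repeat=k):
                if any(a == b for a, b in zip(pattern, pattern[1:])):
                    continue
                if "M" not in pattern and "I" not in pattern and "S" not in pattern:
                    continue  # pure-D CIGARs consume no read bases
                if "S" in pattern[1:-1]:
                    continue  # internal soft clips cannot be constructed
                call = classify_allele(_aln("".join(f"1{op}" for op in pattern)))
                assert (call.category is Category.EXCLUDED) == (not call.admissible)
                if call.admissible:
                    n_events = sum(1 for op in pattern if op in "ID")
                    want = (
                        Category.WT
                        if n_events == 0
                        else Category.MULTIPLE
                        if n_events > 1
                        else Category.DELETION
                        if "D" in pattern
                        else Category.INSERTION
                    )
                    assert call.category is want

    def test_partial_flag_tracks_guide_window_coverage(self, short_ref):
        window = (short_ref.guide_start, short_ref.guide_end)
        covering = _aln("300M")
        assert classify_allele(covering, window).partial is False
        partial = _aln("100M")  # spans [0, 100), window starts at 120
        assert classify_allele(partial, window).partial is True

    def test_net_length_and_frameshift_fields(self):
        call = classify_allele(_aln("100M2I50M5D98M"))
        assert call.net_length_change == -3
        assert call.frameshift is False
        call = classify_allele(_aln("100M10D150M"))
        assert call.frameshift is True


class TestFrameshift:
    @pytest.mark.parametrize(
        "events,expected",
        [
            ([IndelEvent("deletion", 0, 3)], False),
            ([IndelEvent("deletion", 0, 10)], True),
            ([IndelEvent("insertion", 0, 2, "AC"), IndelEvent("deletion", 10, 5)], False),
        ],
    )
    def test_examples(self, events, expected):
        assert frameshift_status(events) is expected

    def test_exhaustive_event_pairs_against_net_length(self):
        for dl in range(1, 7):
            for il in range(1, 7):
                events = [
                    IndelEvent("insertion", 0, il, "A" * il),
                    IndelEvent("deletion", 50, dl),
                ]
                assert frameshift_status(events) == ((il - dl) % 3 != 0)
                assert net_length_change(events) == il - dl


class TestHistogram:
    def test_all_wt_mass_at_cc1(self):
        calls = [classify_allele(_aln("250M", read_id=f"r{i}")) for i in range(10)]
        hist = cc_histogram(calls)
        assert hist[1] == 10 and sum(hist.values()) == 10

    def test_single_deletion_read_at_cc3(self):
        hist = cc_histogram([classify_allele(_aln("100M5D145M"))])
        assert hist[3] == 1

    def test_rejects_inadmissible_calls(self):
        with pytest.raises(ValueError, match="admissible"):
            cc_histogram([classify_allele(_aln("10S240M"))])

    def test_cc_level_is_2e_plus_1_for_spaced_events(self):
        # e events separated by matches over a fully spanned read
        cigars = {0: "100M", 1: "50M2D50M", 2: "40M1I40M2D40M", 3: "30M1I30M2D30M1I30M"}
        for e, text in cigars.items():
            call = classify_allele(_aln(text))
            assert call.cc_level == 2 * e + 1

    def test_composition_subcounts(self):
        calls = [
            classify_allele(_aln("50M2D50M3D50M")),
            classify_allele(_aln("80M5D40M2I128M")),
        ]
        assert composition_counts(calls) == {"2del+0ins": 1, "1del+1ins": 1}


class TestCallTable:
    def test_roundtrip(self, tmp_path):
        calls = [
            classify_allele(_aln("250M", read_id="a")),
            classify_allele(_aln("100M5D145M", read_id="b")),
            classify_allele(_aln("10S240M", read_id="c")),
        ]
        path = tmp_path / "calls.tsv"
        write_call_table(calls, str(path))
        back = read_call_table(str(path))
        assert [(c.read_id, c.category, c.cc_level, c.admissible) for c in back] == [
            (c.read_id, c.category, c.cc_level, c.admissible) for c in calls
        ]
        assert [(e.kind, e.ref_pos, e.length) for e in back[1].events] == [
            ("deletion", 100, 5)
        ]
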