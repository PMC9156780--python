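"""Aligner: DP optimality against a brute-force oracle, CIGAR invariants, SAM I/O."""

import sys
from functools import lru_cache

import numpy as np
import pytest

from ampledit import (
    Alignment,
    CigarOp,
    ScoringScheme,
    align_amplicon,
    align_for_large_deletion,
    cigar_to_string,
    parse_cigar,
    read_sam,
    write_sam,
)
from ampledit.align import align_mate_local, left_normalize
from ampledit.read_prep import ReadPair, reverse_complement
from ampledit.simulate import simulate_reads


def oracle_best_score(read: str, ref: str, sc: ScoringScheme) -> int:
    """Independent top-down scorer: best read-global/reference-local
    affine-gap alignment score by memoized recursion over (i, j, prev op).
    """
    sys.setrecursionlimit(20_000)

    @lru_cache(maxsize=None)
    def best(i: int, j: int, prev: str) -> float:
        if i == len(read):
            return 0  # reference suffix is free
        cands = []
        if j < len(ref):
            sub = sc.match if read[i] == ref[j] else sc.mismatch
            cands.append(sub + best(i + 1, j + 1, "M"))
            d_cost = sc.gap_extend_ref + (sc.gap_open_ref if prev != "D" else 0)
            cands.append(-d_cost + best(i, j + 1, "D"))
        i_cost = sc.gap_extend_read + (sc.gap_open_read if prev != "I" else 0)
        cands.append(-i_cost + best(i + 1, j, "I"))
        return max(cands)

    result = max(best(0, j0, "^") for j0 in range(len(ref) + 1))
    best.cache_clear()
    return result


def score_of(alignment: Alignment, ref: str, sc: ScoringScheme) -> int:
    """Score an emitted alignment by walking its CIGAR."""
    score = 0
    i, j = 0, alignment.ref_start
    for op in alignment.cigar:
        if op.op == "M":
            for _ in range(op.length):
                score += sc.match if alignment.read_seq[i] == ref[j] else sc.mismatch
                i += 1
                j += 1
        elif op.op == "I":
            score -= sc.gap_open_read + sc.gap_extend_read * op.length
            i += op.length
        elif op.op == "D":
            score -= sc.gap_open_ref + sc.gap_extend_ref * op.length
            j += op.length
    return score


def check_bookkeeping(alignment: Alignment, read_len: int) -> None:
    consumed = sum(o.length for o in alignment.cigar if o.op in "MIS")
    assert consumed == read_len
    for i, o in enumerate(alignment.cigar):
        if o.op == "S":
            assert i in (0, len(alignment.cigar) - 1)


class TestAlignAmplicon:
    def test_identity_read(self, short_ref):
        aln = align_amplicon(short_ref.sequence, short_ref.sequence)
        assert aln.cigar_string == "300M"
        assert aln.ref_start == 0

    def test_internal_deletion(self, short_ref):
        ref = short_ref.sequence
        read = ref[:100] + ref[105:]
        aln = align_amplicon(read, ref)
        d_ops = [o for o in aln.cigar if o.op == "D"]
        assert len(d_ops) == 1 and d_ops[0].length == 5

    def test_internal_insertion(self, short_ref):
        ref = short_ref.sequence
        insert = "TG" if ref[99] != "G" else "TC"
        read = ref[:100] + insert + ref[100:]
        aln = align_amplicon(read, ref)
        i_ops = [o for o in aln.cigar if o.op == "I"]
        assert len(i_ops) == 1 and i_ops[0].length == 2

    def test_substring_read_maps_at_offset(self, short_ref):
        read = short_ref.sequence[37:212]
        aln = align_amplicon(read, short_ref.sequence)
        assert aln.ref_start == 37
        assert aln.cigar_string == "175M"

    def test_empty_input_rejected(self, short_ref):
        with pytest.raises(ValueError, match="non-empty"):
            align_amplicon("", short_ref.sequence)

    @pytest.mark.parametrize(
        "scoring",
        [
            ScoringScheme(),
            ScoringScheme(match=2, mismatch=-3, gap_open_read=3,
                          gap_extend_read=2, gap_open_ref=5, gap_extend_ref=1),
        ],
        ids=["default", "asymmetric"],
    )
    def test_score_matches_bruteforce_oracle(self, scoring):
        # fixed enumeration of random pairs, lengths up to 12
        rng = np.random.default_rng(123)
        for _ in range(120):
            m = int(rng.integers(1, 13))
            n = int(rng.integers(1, 13))
            read = "".join("ACGT"[c] for c in rng.integers(0, 4, m))
            ref = "".join("ACGT"[c] for c in rng.integers(0, 4, n))
            aln = align_amplicon(read, ref, scoring)
            check_bookkeeping(aln, len(read))
            assert score_of(aln, ref, scoring) == oracle_best_score(read, ref, scoring)

    def test_recovered_events_equal_planted(self, short_ref, editing_pool):
        from ampledit.classify import extract_events
        from ampledit.simulate import apply_events

        for allele in editing_pool:
            seq = apply_events(short_ref.sequence, allele)
            aln = align_amplicon(seq, short_ref.sequence)
            got = [(e.kind, e.ref_pos, e.length) for e in extract_events(aln)]
            want = [(e.kind, e.ref_pos, e.length) for e in allele.events]
            assert got == want

    def test_homopolymer_deletion_left_aligned(self):
        ref = "ACGTACAAAAATGCATGCA"
        read = ref[:6] + ref[7:]  # delete one A of the homopolymer run
        aln = align_amplicon(read, ref)
        events = [(o.op, o.length) for o in aln.cigar]
        assert events == [("M", 6), ("D", 1), ("M", 12)]  # leftmost placement


class TestLeftNormalize:
    def test_shift_through_repeat(self):
        from ampledit.simulate import left_normalize_deletion

        rng = np.random.default_rng(5)
        r = "".join("ACGT"[c] for c in rng.integers(0, 4, 50))
        ref = r[:25] + "ACGACGACG" + r[25:]
        read = r[:25] + "ACGACG" + r[25:]  # one ACG unit removed
        aln = align_amplicon(read, ref)
        s = left_normalize_deletion(ref, 25, 3)
        assert aln.cigar_string == f"{s}M3D{len(ref) - s - 3}M"

    def test_noop_when_pinned(self):
        ref = "AACGTT"
        cigar = parse_cigar("2M2D2M")
        out, start = left_normalize(list(cigar), 0, "AATT", ref)
        assert cigar_to_string(out) == "2M2D2M" and start == 0


class TestLongAmpliconAlignment:
    def test_contained_mate_has_no_clip(self, long_ref):
        read = long_ref.sequence[1000:1250]
        aln = align_mate_local(read, long_ref.sequence)
        assert aln.cigar_string == "250M"
        assert aln.ref_start == 1000

    def test_junction_mate_clipped_at_midpoint(self, long_ref):
        ref = long_ref.sequence
        # 2-kb deletion [1000, 3000); mate crosses at its midpoint
        read = ref[875:1000] + ref[3000:3125]
        aln = align_mate_local(read, ref)
        s_ops = [o for o in aln.cigar if o.op == "S"]
        assert len(s_ops) == 1
        assert abs(s_ops[0].length - 125) <= 2  # junction +- chance-match creep

    def test_three_bases_past_junction(self, long_ref):
        ref = long_ref.sequence
        ds, de = 1000, 3000
        while ref[de] == ref[ds]:  # block chance-match extension at the junction
            de += 1
        read = ref[ds - 247 : ds] + ref[de : de + 3]
        aln = align_mate_local(read, ref)
        tail = aln.cigar[-1]
        assert tail.op == "S" and tail.length == 3

    def test_pair_alignment_orients_mate2(self, long_ref):
        frag = long_ref.sequence[500:1100]
        pair = ReadPair(
            "p", frag[:250], reverse_complement(frag[-250:]),
            np.full(250, 30, dtype=np.uint8), np.full(250, 30, dtype=np.uint8),
        )
        a1, a2 = align_for_large_deletion(pair, long_ref.sequence)
        assert a1.ref_start == 500 and a1.cigar_string == "250M"
        assert a2.ref_start == 850 and a2.cigar_string == "250M"


class TestSamIO:
    def test_roundtrip_identity(self, short_ref, editing_pool, tmp_path):
        from ampledit import merge_pair

        pairs, _ = simulate_reads(short_ref, editing_pool, 100, seed=31)
        alignments = [
            align_amplicon(m.seq, short_ref.sequence, read_id=m.id)
            for m in (merge_pair(p) for p in pairs)
        ]
        path1 = tmp_path / "a.sam"
        path2 = tmp_path / "b.sam"
        refs = {short_ref.id: short_ref.sequence}
        write_sam(alignments, str(path1), refs)
        back = read_sam(str(path1))
        assert len(back) == len(alignments)
        for x, y in zip(alignments, back):
            assert (x.read_id, x.ref_start, x.cigar_string, x.read_seq) == (
                y.read_id, y.ref_start, y.cigar_string, y.read_seq
            )
        write_sam(back, str(path2), refs)
        assert path1.read_bytes() == path2.read_bytes()

    def test_single_op_record(self, short_ref, tmp_path):
        aln = Alignment("r1", short_ref.id, 0, [CigarOp("M", 250)], "A" * 250)
        path = tmp_path / "one.sam"
        write_sam([aln], str(path), {short_ref.id: short_ref.sequence})
        (rec,) = read_sam(str(path))
        assert rec.cigar_string == "250M" and len(rec.cigar) == 1

    def test_hard_clip_rejected(self, tmp_path):
        path = tmp_path / "hard.sam"
        path.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:amp\tLN:300\n"
            "r1\t0\tamp\t1\t60\t10H240M\t*\t0\t0\t" + "A" * 240 + "\t*\n"
        )
        with pytest.raises(ValueError, match="r1"):
            read_sam(str(path))

    def test_unmapped_record_carried(self, tmp_path):
        path = tmp_path / "un.sam"
        path.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:amp\tLN:300\n"
            "r9\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\t*\n"
        )
        (rec,) = read_sam(str(path))
        assert rec.mapped is False and rec.read_id == "r9"


class TestCigarParsing:
    @pytest.mark.parametrize("text", ["", "*", "M", "10", "10M5"])
    def test_malformed_rejected(self, text):
        with pytest.raises(ValueError):
            parse_cigar(text)

    def test_roundtrip(self):
        assert cigar_to_string(parse_cigar("5S100M2I3D145M")) == "5S100M2I3D145M"
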