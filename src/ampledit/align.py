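"""Semi-global and local alignment of amplicon reads, plus SAM import/export.

The short-amplicon aligner is read-global / reference-local with affine
gap penalties: every read base is aligned (as M or I), while the
reference may be entered and left anywhere for free.  The long-amplicon
aligner is a per-mate local (Smith-Waterman) alignment with a
prohibitive penalty on reference gaps, so that a read crossing a
large-deletion junction is soft-clipped at the junction instead of
bridging it with a huge D operation.

Coordinates are 0-based half-open internally; user-facing interfaces
(guide windows, deletion spans) are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from ._kernels import local_align, semiglobal_align

READ_CONSUMING = frozenset("MIS")
REF_CONSUMING = frozenset("MD")
_STATE_TO_OP = "MDI"


@dataclass(frozen=True)
class CigarOp:
    """One CIGAR operation: M (match/mismatch), I, D or S."""

    op: str
    length: int

    def __post_init__(self) -> None:
        if self.op not in "MIDS":
            raise ValueError(f"unsupported CIGAR op {self.op!r}")
        if self.length < 1:
            raise ValueError("CIGAR op length must be >= 1")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.length}{self.op}"


Cigar = List[CigarOp]


def canonicalize(ops: Iterable[CigarOp]) -> Cigar:
    """Merge adjacent operations of the same kind."""
    out: Cigar = []
    for op in ops:
        if out and out[-1].op == op.op:
            out[-1] = CigarOp(op.op, out[-1].length + op.length)
        else:
            out.append(CigarOp(op.op, op.length))
    return out


def parse_cigar(text: str) -> Cigar:
    """Parse a CIGAR string such as ``"100M5D145M"``.

    Hard clips and any operation outside M/I/D/S are rejected.
    """
    if not text or text == "*":
        raise ValueError("empty CIGAR")
    ops: Cigar = []
    num = ""
    for ch in text:
        if ch.isdigit():
            num += ch
        else:
            if not num:
                raise ValueError(f"malformed CIGAR {text!r}")
            ops.append(CigarOp(ch, int(num)))
            num = ""
    if num:
        raise ValueError(f"malformed CIGAR {text!r}")
    return ops


def cigar_to_string(ops: Sequence[CigarOp]) -> str:
    return "".join(f"{o.length}{o.op}" for o in ops)


@dataclass
class ScoringScheme:
    """Alignment scores; gap penalties are positive costs.

    A gap of length L costs ``open + L * extend``.  ``gap_*_read``
    applies to insertions (extra read bases, I ops); ``gap_*_ref``
    applies to deletions (skipped reference bases, D ops).
    """

    match: int = 1
    mismatch: int = -1
    gap_open_read: int = 2
    gap_extend_read: int = 1
    gap_open_ref: int = 2
    gap_extend_ref: int = 1

    def __post_init__(self) -> None:
        if self.match <= self.mismatch:
            raise ValueError("match score must exceed mismatch score")
        for name in ("gap_open_read", "gap_extend_read", "gap_open_ref", "gap_extend_ref"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def long_amplicon(cls) -> "ScoringScheme":
        """Preset for junction detection on long amplicons.

        Reference gaps are priced out entirely (open 10000, extend
        1000) so a deletion cannot be bridged inside one alignment and
        a junction-crossing mate is soft-clipped instead.  Mismatches
        and read gaps are priced harshly (-8 and 6+3/base) so the local
        alignment cannot creep past the junction on chance matches,
        which would blur the clipped junction coordinate.
        """
        return cls(
            match=2,
            mismatch=-8,
            gap_open_read=6,
            gap_extend_read=3,
            gap_open_ref=10000,
            gap_extend_ref=1000,
        )


@dataclass
class Alignment:
    """A read placed on an amplicon reference."""

    read_id: str
    ref_id: str
    ref_start: int
    cigar: Cigar
    read_seq: str
    mapped: bool = True

    def __post_init__(self) -> None:
        if self.mapped:
            self.validate()

    def validate(self) -> None:
        if not self.cigar:
            raise ValueError(f"{self.read_id}: empty CIGAR")
        read_len = sum(o.length for o in self.cigar if o.op in READ_CONSUMING)
        if read_len != len(self.read_seq):
            raise ValueError(
                f"{self.read_id}: CIGAR consumes {read_len} read bases, "
                f"read is {len(self.read_seq)}"
            )
        for i, o in enumerate(self.cigar):
            if o.op == "S" and i not in (0, len(self.cigar) - 1):
                raise ValueError(f"{self.read_id}: internal soft clip")

    @property
    def ref_span(self) -> int:
        return sum(o.length for o in self.cigar if o.op in REF_CONSUMING)

    @property
    def ref_end(self) -> int:
        """0-based exclusive end on the reference."""
        return self.ref_start + self.ref_span

    @property
    def cigar_string(self) -> str:
        return cigar_to_string(self.cigar)


def seq_to_codes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()


def _path_to_cigar(path: np.ndarray, n: int) -> Cigar:
    ops: Cigar = []
    for k in range(n):
        op = _STATE_TO_OP[path[k]]
        if ops and ops[-1].op == op:
            ops[-1] = CigarOp(op, ops[-1].length + 1)
        else:
            ops.append(CigarOp(op, 1))
    return ops


def left_normalize(cigar: Cigar, ref_start: int, read_seq: str, ref_seq: str) -> Tuple[Cigar, int]:
    """Shift every indel as far left as score-equivalence allows.

    A deletion of ref[s:e) may move one step left when ref[s-1] ==
    ref[e-1]; an insertion of read[s:e) placed after read[s-1] may move
    left when read[s-1] == read[e-1].  Shifting trades bases between an
    indel and its flanking M runs without changing any match/mismatch
    status, so the alignment score is preserved.  Gives the
    deterministic, variant-normalisation-style placement of gaps in
    repeats and homopolymers.
    """
    ops = list(cigar)
    changed = True
    while changed:
        changed = False
        # read/ref cursors at the start of each op
        read_cur = 0
        ref_cur = ref_start
        cursors = []
        for o in ops:
            cursors.append((read_cur, ref_cur))
            if o.op in READ_CONSUMING:
                read_cur += o.length
            if o.op in REF_CONSUMING:
                ref_cur += o.length
        for idx in range(1, len(ops)):
            o = ops[idx]
            if o.op not in "ID" or idx == 0 or ops[idx - 1].op != "M":
                continue
            shift = 0
            max_shift = ops[idx - 1].length
            rc, fc = cursors[idx]
            if o.op == "D":
                s, e = fc, fc + o.length
                while shift < max_shift and s - shift > 0 and ref_seq[s - shift - 1] == ref_seq[e - shift - 1]:
                    shift += 1
            else:
                s, e = rc, rc + o.length
                while shift < max_shift and s - shift > 0 and read_seq[s - shift - 1] == read_seq[e - shift - 1]:
                    shift += 1
            if shift == 0:
                continue
            # shrink the preceding M, grow (or create) the following M
            prev = ops[idx - 1]
            ops[idx - 1] = CigarOp("M", prev.length - shift) if prev.length > shift else None
            if idx + 1 < len(ops) and ops[idx + 1].op == "M":
                ops[idx + 1] = CigarOp("M", ops[idx + 1].length + shift)
            else:
                ops.insert(idx + 1, CigarOp("M", shift))
            if ops[idx - 1] is None:
                del ops[idx - 1]
            ops = canonicalize(ops)
            changed = True
            break
    return ops, ref_start


def align_amplicon(
    read_seq: str,
    reference: str,
    scoring: Optional[ScoringScheme] = None,
    read_id: str = "read",
    ref_id: str = "amplicon",
) -> Alignment:
    """Align a merged read against the amplicon (read-global).

    The optimum is found by affine-gap dynamic programming with
    deterministic tie-breaking (M preferred over D over I; the
    leftmost reference end among equal scores) and indels are then
    left-normalised.  Reads that are exact substrings of the reference
    short-circuit to a single M operation at the leftmost occurrence.
    """
    if not read_seq or not reference:
        raise ValueError("read and reference must be non-empty")
    scoring = scoring or ScoringScheme()
    pos = reference.find(read_seq)
    if pos >= 0:
        return Alignment(read_id, ref_id, pos, [CigarOp("M", len(read_seq))], read_seq)
    score, ref_start, path, n = semiglobal_align(
        seq_to_codes(read_seq),
        seq_to_codes(reference),
        scoring.match,
        scoring.mismatch,
        scoring.gap_open_read,
        scoring.gap_extend_read,
        scoring.gap_open_ref,
        scoring.gap_extend_ref,
    )
    cigar = _path_to_cigar(path, n)
    cigar, ref_start = left_normalize(cigar, ref_start, read_seq, reference)
    return Alignment(read_id, ref_id, ref_start, cigar, read_seq)


def align_mate_local(
    read_seq: str,
    reference: str,
    scoring: Optional[ScoringScheme] = None,
    read_id: str = "read",
    ref_id: str = "amplicon",
) -> Alignment:
    """Local alignment of a single mate with terminal soft clips.

    Unaligned read prefix/suffix become S operations.  With the
    :meth:`ScoringScheme.long_amplicon` preset, a mate spanning a
    large-deletion junction is clipped at the junction.
    """
    if not read_seq or not reference:
        raise ValueError("read and reference must be non-empty")
    scoring = scoring or ScoringScheme.long_amplicon()
    score, rd_s, rd_e, rf_s, rf_e, path, n = local_align(
        seq_to_codes(read_seq),
        seq_to_codes(reference),
        scoring.match,
        scoring.mismatch,
        scoring.gap_open_read,
        scoring.gap_extend_read,
        scoring.gap_open_ref,
        scoring.gap_extend_ref,
    )
    if n == 0:
        return Alignment(read_id, ref_id, 0, [], read_seq, mapped=False)
    cigar = _path_to_cigar(path, n)
    cigar, rf_s = left_normalize(cigar, rf_s, read_seq[rd_s:rd_e], reference)
    if rd_s > 0:
        cigar = [CigarOp("S", rd_s)] + cigar
    if rd_e < len(read_seq):
        cigar = cigar + [CigarOp("S", len(read_seq) - rd_e)]
    return Alignment(read_id, ref_id, rf_s, cigar, read_seq)


def align_for_large_deletion(
    pair,
    reference: str,
    scoring: Optional[ScoringScheme] = None,
    ref_id: str = "amplicon",
) -> Tuple[Alignment, Alignment]:
    """Align both mates of a pair locally for large-deletion detection.

    Mate 2 is reverse-complemented into reference orientation first.
    """
    from .read_prep import reverse_complement

    scoring = scoring or ScoringScheme.long_amplicon()
    a1 = align_mate_local(pair.seq1, reference, scoring, f"{pair.id}/1", ref_id)
    a2 = align_mate_local(
        reverse_complement(pair.seq2), reference, scoring, f"{pair.id}/2", ref_id
    )
    return a1, a2


# ---------------------------------------------------------------------------
# SAM import/export (text SAM via pysam)
# ---------------------------------------------------------------------------


def write_sam(alignments: Iterable[Alignment], path: str, references: dict) -> None:
    """Write alignments as headered text SAM.

    ``references`` maps reference id to its sequence (lengths populate
    the @SQ lines).
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": rid, "LN": len(seq)} for rid, seq in references.items()],
    }
    with pysam.AlignmentFile(path, "w", header=header) as fh:
        for aln in alignments:
            rec = pysam.AlignedSegment(fh.header)
            rec.query_name = aln.read_id
            rec.query_sequence = aln.read_seq
            rec.query_qualities = None
            if aln.mapped:
                rec.flag = 0
                rec.reference_id = fh.header.get_tid(aln.ref_id)
                rec.reference_start = aln.ref_start
                rec.mapping_quality = 60
                rec.cigarstring = aln.cigar_string
            else:
                rec.flag = 4
                rec.reference_id = -1
                rec.reference_start = -1
                rec.mapping_quality = 0
            fh.write(rec)


def read_sam(path: str) -> List[Alignment]:
    """Read a SAM file into Alignment records.

    Unmapped records are carried with ``mapped=False``.  Hard clips and
    CIGAR operations outside M/I/D/S raise a parse error naming the
    offending record.
    """
    out: List[Alignment] = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                out.append(
                    Alignment(
                        rec.query_name, "*", 0, [], rec.query_sequence or "", mapped=False
                    )
                )
                continue
            try:
                ops = parse_cigar(rec.cigarstring)
            except ValueError as exc:
                raise ValueError(f"record {rec.query_name!r}: {exc}") from exc
            out.append(
                Alignment(
                    rec.query_name,
                    rec.reference_name,
                    rec.reference_start,
                    ops,
                    rec.query_sequence or "",
                )
            )
    return out
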