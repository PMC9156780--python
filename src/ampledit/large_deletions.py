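"""Large-deletion detection on long amplicons by soft-clip rescue.

Reads from a long (multi-kb) amplicon are aligned per mate with
reference gaps priced out, so a mate crossing a deletion junction is
soft-clipped there.  Deletions that do appear as D operations are taken
as called directly.  For each terminal soft clip, the clip-adjacent
k-mer of the clipped sequence is searched in the reference flank beyond
the mapped segment with k descending from 30 to 5; a unique exact match
re-anchors the clip and the gap between the mapped edge and the match
is called as a deletion.  Pairs whose mapping or deletion coordinates
touch the 20-bp guide window are retained.

All user-facing coordinates are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .align import Alignment

RESCUE_K_MAX = 30
RESCUE_K_MIN = 5


@dataclass(frozen=True)
class GuideWindow:
    """The 20-bp protospacer interval, 1-based inclusive."""

    ref_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end or self.start < 1:
            raise ValueError(f"bad guide window {self.start}-{self.end}")


@dataclass
class LargeDeletionCall:
    """A deletion span on the reference, 1-based inclusive."""

    read_pair_id: str
    del_start: int
    del_end: int
    evidence: str  # "cigar_deletion" | "softclip_rescue"
    rescue_k: Optional[int] = None
    discordant: bool = False

    def __post_init__(self) -> None:
        if self.del_start > self.del_end:
            raise ValueError("del_start must not exceed del_end")
        if self.evidence == "softclip_rescue":
            if self.rescue_k is None or not RESCUE_K_MIN <= self.rescue_k <= RESCUE_K_MAX:
                raise ValueError("softclip_rescue calls need rescue_k in [5, 30]")

    @property
    def length(self) -> int:
        return self.del_end - self.del_start + 1


@dataclass
class PairEvidence:
    """Mapping intervals and deletion calls collected for one read pair."""

    pair_id: str
    mate_intervals: List[Tuple[int, int]] = field(default_factory=list)
    calls: List[LargeDeletionCall] = field(default_factory=list)


def _count_occurrences(haystack: str, needle: str) -> List[int]:
    """All (possibly overlapping) match positions of needle in haystack."""
    out = []
    i = haystack.find(needle)
    while i >= 0:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def _normalize_span(reference: str, start0: int, end0: int) -> Tuple[int, int]:
    """Left-normalise a 0-based half-open deletion span."""
    s, e = start0, end0
    while s > 0 and reference[s - 1] == reference[e - 1]:
        s -= 1
        e -= 1
    return s, e


def call_from_cigar(pair_id: str, alignments: Iterable[Alignment]) -> List[LargeDeletionCall]:
    """Turn every D operation of the pair's alignments into a call."""
    calls: List[LargeDeletionCall] = []
    for aln in alignments:
        if not aln.mapped:
            continue
        ref_cur = aln.ref_start
        for op in aln.cigar:
            if op.op == "D":
                calls.append(
                    LargeDeletionCall(
                        pair_id, ref_cur + 1, ref_cur + op.length, "cigar_deletion"
                    )
                )
                ref_cur += op.length
            elif op.op == "M":
                ref_cur += op.length
    return calls


def rescue_soft_clip(
    alignment: Alignment,
    reference: str,
    pair_id: Optional[str] = None,
    k_max: int = RESCUE_K_MAX,
    k_min: int = RESCUE_K_MIN,
) -> Optional[LargeDeletionCall]:
    """Rescue one terminal soft clip into a deletion call, if unique.

    For a 3' clip the first k clipped bases are searched downstream of
    the mapped end; for a 5' clip the last k clipped bases are searched
    upstream of the mapped start.  k descends from min(30, clip length)
    to 5 and stops at the first k with exactly one exact occurrence.
    When both ends are clipped the longer clip is used.  Returns None
    when the clip is shorter than 5 bases, no k gives a unique match,
    or the unique match leaves no gap (no deletion).
    """
    if not alignment.mapped or not alignment.cigar:
        return None
    pair_id = pair_id if pair_id is not None else alignment.read_id
    head = alignment.cigar[0]
    tail = alignment.cigar[-1]
    head_len = head.length if head.op == "S" else 0
    tail_len = tail.length if tail.op == "S" else 0
    if max(head_len, tail_len) < k_min:
        return None
    three_prime = tail_len >= head_len  # longer clip wins; tie -> 3'
    if three_prime:
        clip = alignment.read_seq[len(alignment.read_seq) - tail_len :]
        mapped_edge = alignment.ref_end  # 0-based exclusive
        flank = reference[mapped_edge:]
    else:
        clip = alignment.read_seq[:head_len]
        mapped_edge = alignment.ref_start  # 0-based inclusive
        flank = reference[:mapped_edge]
    for k in range(min(k_max, len(clip)), k_min - 1, -1):
        kmer = clip[:k] if three_prime else clip[-k:]
        hits = _count_occurrences(flank, kmer)
        if len(hits) != 1:
            continue
        if three_prime:
            gap = hits[0]  # reference bases skipped between mapped end and match
            if gap == 0:
                return None
            s0, e0 = _normalize_span(reference, mapped_edge, mapped_edge + gap)
        else:
            match_end = hits[0] + k
            gap = mapped_edge - match_end
            if gap == 0:
                return None
            s0, e0 = _normalize_span(reference, match_end, mapped_edge)
        return LargeDeletionCall(
            pair_id, s0 + 1, e0, "softclip_rescue", rescue_k=k
        )
    return None


def collect_pair_evidence(
    pair_id: str, alignments: Sequence[Alignment], reference: str
) -> PairEvidence:
    """CIGAR calls plus soft-clip rescues for one pair, deduplicated.

    Identical spans from both mates collapse to one call; conflicting
    spans are all kept and flagged discordant.
    """
    ev = PairEvidence(pair_id)
    for aln in alignments:
        if aln.mapped:
            ev.mate_intervals.append((aln.ref_start + 1, aln.ref_end))
    calls = call_from_cigar(pair_id, alignments)
    for aln in alignments:
        rescued = rescue_soft_clip(aln, reference, pair_id)
        if rescued is not None:
            calls.append(rescued)
    seen: Dict[Tuple[int, int], LargeDeletionCall] = {}
    for c in calls:
        key = (c.del_start, c.del_end)
        if key not in seen:
            seen[key] = c
    unique = list(seen.values())
    if len(unique) > 1:
        for c in unique:
            c.discordant = True
    ev.calls = unique
    return ev


def _intersects(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start <= b_end and b_start <= a_end


def guide_overlap_filter(
    pairs: Iterable[PairEvidence], window: GuideWindow, ref_length: Optional[int] = None
) -> List[PairEvidence]:
    """Retain pairs whose mapping or deletion spans touch the guide window."""
    if ref_length is not None and window.end > ref_length:
        raise ValueError("guide window outside the reference")
    kept = []
    for p in pairs:
        spans = list(p.mate_intervals) + [(c.del_start, c.del_end) for c in p.calls]
        if any(_intersects(s, e, window.start, window.end) for s, e in spans):
            kept.append(p)
    return kept


def deletion_span_table(pairs: Iterable[PairEvidence]) -> pd.DataFrame:
    """Tabulate deletion calls of retained pairs, sorted by span."""
    rows = []
    for p in pairs:
        for c in p.calls:
            rows.append(
                {
                    "pair_id": p.pair_id,
                    "del_start": c.del_start,
                    "del_end": c.del_end,
                    "length": c.length,
                    "evidence": c.evidence,
                    "rescue_k": c.rescue_k,
                    "discordant": c.discordant,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "pair_id",
            "del_start",
            "del_end",
            "length",
            "evidence",
            "rescue_k",
            "discordant",
        ],
    )
    if len(df):
        df = df.sort_values(["del_start", "length", "pair_id"], kind="mergesort")
        df = df.reset_index(drop=True)
    return df


def write_bed(table: pd.DataFrame, ref_id: str, path: str) -> None:
    """Write deletion intervals as 0-based half-open BED records."""
    with open(path, "w") as fh:
        for _, row in table.iterrows():
            fh.write(
                f"{ref_id}\t{row.del_start - 1}\t{row.del_end}\t"
                f"{row.pair_id};{row.evidence}\n"
            )
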