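"""CIGAR-complexity allele classification.

The classifier works solely on the CIGAR string of each aligned allele.
CIGAR complexity (CC) is the number of alphabetic operation characters;
an alignment is admissible when it carries no soft clip and its CC is
at most 6, with one exception: the simplest CC-7 pattern, MIDMIDM, is
also admitted.  Admissible alignments are decomposed into indel events
and assigned one of four categories:

* ``WT``        - no indel event (pure M; substitutions do not count),
* ``Deletion``  - exactly one deletion and nothing else,
* ``Insertion`` - exactly one insertion and nothing else,
* ``Multiple``  - two or more events of any kinds,

plus ``Excluded`` for inadmissible alignments.  The frameshift flag is
set when the net length change (insertions minus deletions) is not a
multiple of three.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .align import Alignment, Cigar, CigarOp

MAX_CC = 6
MIDMIDM = ("M", "I", "D", "M", "I", "D", "M")


class Category(str, Enum):
    WT = "WT"
    DELETION = "Deletion"
    INSERTION = "Insertion"
    MULTIPLE = "Multiple"
    EXCLUDED = "Excluded"


@dataclass(frozen=True)
class IndelEvent:
    """One deletion or insertion extracted from an alignment.

    Coordinates follow the simulator convention: 0-based, a deletion
    starting at ``ref_pos``, an insertion placed immediately before
    reference base ``ref_pos``.
    """

    kind: str
    ref_pos: int
    length: int
    inserted_seq: str = ""

    def serialize(self) -> str:
        tag = "del" if self.kind == "deletion" else "ins"
        return f"{tag}:{self.ref_pos}:{self.length}"


@dataclass
class AlleleCall:
    """Per-read verdict of the classifier."""

    read_id: str
    admissible: bool
    cc_level: int
    category: Category
    events: List[IndelEvent] = field(default_factory=list)
    frameshift: bool = False
    net_length_change: int = 0
    partial: bool = False

    @property
    def edited(self) -> bool:
        return self.admissible and bool(self.events)


def cigar_complexity(cigar: Cigar) -> int:
    """Number of alphabetic operation characters in a canonical CIGAR."""
    if not cigar:
        raise ValueError("empty CIGAR")
    return len(cigar)


def admissible(cigar: Cigar) -> bool:
    """Exclusion rule: no soft clips, and CC <= 6 or exactly MIDMIDM."""
    if not cigar:
        return False
    pattern = tuple(o.op for o in cigar)
    if "S" in pattern:
        return False
    return len(pattern) <= MAX_CC or pattern == MIDMIDM


def extract_events(alignment: Alignment) -> List[IndelEvent]:
    """Decompose an alignment into indel events, ordered by position.

    Must only be called on admissible alignments.
    """
    if not admissible(alignment.cigar):
        raise ValueError(f"{alignment.read_id}: inadmissible alignment")
    events: List[IndelEvent] = []
    ref_cur = alignment.ref_start
    read_cur = 0
    for op in alignment.cigar:
        if op.op == "M":
            ref_cur += op.length
            read_cur += op.length
        elif op.op == "D":
            events.append(IndelEvent("deletion", ref_cur, op.length))
            ref_cur += op.length
        elif op.op == "I":
            seq = alignment.read_seq[read_cur : read_cur + op.length]
            events.append(IndelEvent("insertion", ref_cur, op.length, seq))
            read_cur += op.length
    return events


def frameshift_status(events: Sequence[IndelEvent]) -> bool:
    """True when the allele's net length change is not divisible by 3."""
    return net_length_change(events) % 3 != 0


def net_length_change(events: Sequence[IndelEvent]) -> int:
    return sum(e.length if e.kind == "insertion" else -e.length for e in events)


def classify_allele(
    alignment: Alignment, guide_window: Optional[Tuple[int, int]] = None
) -> AlleleCall:
    """Classify one alignment into an AlleleCall.

    ``guide_window`` (1-based inclusive) optionally marks calls whose
    alignment does not span the whole window as ``partial``; partial
    calls keep their category but are excluded from length statistics
    downstream.
    """
    cc = cigar_complexity(alignment.cigar) if alignment.cigar else 0
    if not alignment.mapped or not admissible(alignment.cigar):
        return AlleleCall(alignment.read_id, False, max(cc, 1), Category.EXCLUDED)
    events = extract_events(alignment)
    if not events:
        category = Category.WT
    elif len(events) > 1:
        category = Category.MULTIPLE
    elif events[0].kind == "deletion":
        category = Category.DELETION
    else:
        category = Category.INSERTION
    partial = False
    if guide_window is not None:
        gw_start0, gw_end0 = guide_window[0] - 1, guide_window[1]
        partial = not (alignment.ref_start <= gw_start0 and alignment.ref_end >= gw_end0)
    net = net_length_change(events)
    return AlleleCall(
        alignment.read_id,
        True,
        cc,
        category,
        events,
        frameshift=net % 3 != 0,
        net_length_change=net,
        partial=partial,
    )


def classify_all(
    alignments: Iterable[Alignment], guide_window: Optional[Tuple[int, int]] = None
) -> List[AlleleCall]:
    return [classify_allele(a, guide_window) for a in alignments]


def cc_histogram(calls: Iterable[AlleleCall], max_level: int = 7) -> Dict[int, int]:
    """Counts of admissible calls per CIGAR-complexity level 1..max_level."""
    hist = {level: 0 for level in range(1, max_level + 1)}
    for c in calls:
        if not c.admissible:
            raise ValueError("cc_histogram expects admissible calls only")
        hist[c.cc_level] += 1
    return hist


def composition_counts(calls: Iterable[AlleleCall]) -> Dict[str, int]:
    """Sub-counts of Multiple calls by event composition (e.g. '1del+1ins')."""
    out: Counter = Counter()
    for c in calls:
        if c.category is not Category.MULTIPLE:
            continue
        n_del = sum(1 for e in c.events if e.kind == "deletion")
        n_ins = len(c.events) - n_del
        out[f"{n_del}del+{n_ins}ins"] += 1
    return dict(out)


# ---------------------------------------------------------------------------
# Call-table I/O
# ---------------------------------------------------------------------------

_CALL_COLUMNS = [
    "read_id",
    "admissible",
    "cc",
    "category",
    "frameshift",
    "net_length_change",
    "partial",
    "events",
]


def write_call_table(calls: Iterable[AlleleCall], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_CALL_COLUMNS) + "\n")
        for c in calls:
            ev = ",".join(e.serialize() for e in c.events)
            fh.write(
                f"{c.read_id}\t{int(c.admissible)}\t{c.cc_level}\t{c.category.value}\t"
                f"{int(c.frameshift)}\t{c.net_length_change}\t{int(c.partial)}\t{ev}\n"
            )


def read_call_table(path: str) -> List[AlleleCall]:
    calls: List[AlleleCall] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _CALL_COLUMNS:
            raise ValueError(f"unexpected call-table columns in {path}")
        for line in fh:
            rid, adm, cc, cat, fs, net, partial, ev = line.rstrip("\n").split("\t")
            events = []
            if ev:
                for token in ev.split(","):
                    tag, pos, length = token.split(":")[:3]
                    kind = "deletion" if tag == "del" else "insertion"
                    events.append(IndelEvent(kind, int(pos), int(length)))
            calls.append(
                AlleleCall(
                    rid,
                    bool(int(adm)),
                    int(cc),
                    Category(cat),
                    events,
                    frameshift=bool(int(fs)),
                    net_length_change=int(net),
                    partial=bool(int(partial)),
                )
            )
    return calls
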