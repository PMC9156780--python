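"""Synthetic edited-amplicon data with per-read ground truth.

Generates random amplicon references carrying a 20-bp guide window,
builds allele pools mixing unedited sequence with deletion, insertion
and combined (``Multiple``) editing events near the predicted cut site,
and emits error-bearing 250-bp paired-end reads together with a truth
table recording, for every read, the source allele, fragment
coordinates and the planted events it covers.

Planted event coordinates are stored in left-normalised form (the same
variant-normalisation convention the aligner applies), so downstream
recovery can be compared exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .read_prep import ReadPair, reverse_complement

BASES = "ACGT"
_ASCII_TO_CODE = np.full(128, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ASCII_TO_CODE[ord(_b)] = _i


@dataclass(frozen=True)
class EventSpec:
    """One planted editing event on the reference.

    ``ref_pos`` is 0-based: a deletion removes reference bases
    [ref_pos, ref_pos + length); an insertion places ``inserted_seq``
    immediately before reference base ``ref_pos``.
    """

    kind: str
    ref_pos: int
    length: int
    inserted_seq: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("deletion", "insertion"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("event length must be >= 1")
        if self.ref_pos < 0:
            raise ValueError("ref_pos must be >= 0")
        if self.kind == "insertion":
            if len(self.inserted_seq) != self.length:
                raise ValueError("inserted_seq length must equal event length")
            if set(self.inserted_seq) - set(BASES):
                raise ValueError("inserted_seq must be over ACGT")
        elif self.inserted_seq:
            raise ValueError("deletions carry no inserted_seq")

    def serialize(self) -> str:
        tag = "del" if self.kind == "deletion" else "ins"
        base = f"{tag}:{self.ref_pos}:{self.length}"
        return f"{base}:{self.inserted_seq}" if self.kind == "insertion" else base

    @classmethod
    def deserialize(cls, text: str) -> "EventSpec":
        parts = text.split(":")
        kind = {"del": "deletion", "ins": "insertion"}[parts[0]]
        seq = parts[3] if len(parts) > 3 else ""
        return cls(kind, int(parts[1]), int(parts[2]), seq)


@dataclass
class AlleleSpec:
    """An allele as an ordered list of non-overlapping events plus its pool frequency."""

    events: List[EventSpec]
    frequency: float
    name: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError("frequency must be in [0, 1]")
        validate_events(self.events)

    @property
    def net_length_change(self) -> int:
        return sum(
            e.length if e.kind == "insertion" else -e.length for e in self.events
        )


def validate_events(events: Sequence[EventSpec]) -> None:
    """Check events are sorted by ref_pos with pairwise disjoint footprints."""
    prev_end = -1
    prev_pos = -1
    for e in events:
        if e.ref_pos <= prev_pos or e.ref_pos < prev_end:
            raise ValueError("events must be sorted and non-overlapping")
        prev_pos = e.ref_pos
        prev_end = e.ref_pos + (e.length if e.kind == "deletion" else 0)


@dataclass(frozen=True)
class AmpliconReference:
    """A reference amplicon with its 20-bp guide window (1-based inclusive)."""

    id: str
    sequence: str
    guide_start: int
    guide_end: int

    @property
    def cut_site(self) -> int:
        """0-based boundary 3 bp from the PAM-proximal guide end.

        The blunt Cas9 cut falls between protospacer positions 17 and
        18; with the guide window given 5'->3', that is 3 bp before its
        3' end.
        """
        return self.guide_end - 3

    @property
    def guide_interval0(self) -> Tuple[int, int]:
        """Guide window as 0-based half-open coordinates."""
        return self.guide_start - 1, self.guide_end


@dataclass
class TruthEntry:
    allele_index: int
    frag_start: int
    frag_end: int
    events: List[EventSpec]


@dataclass
class SimTruth:
    """Ground truth for one simulated read set."""

    reference: AmpliconReference
    pool: List[AlleleSpec]
    entries: Dict[str, TruthEntry] = field(default_factory=dict)

    def fragment_ref_start(self, read_id: str) -> int:
        """Reference coordinate where a read's fragment begins."""
        entry = self.entries[read_id]
        layout = allele_layout(
            len(self.reference.sequence), self.pool[entry.allele_index].events
        )
        return allele_to_ref(layout, entry.frag_start)


def make_reference(
    length: int,
    guide_window: Tuple[int, int],
    gc_fraction: float = 0.5,
    seed: int = 0,
    ref_id: str = "amplicon",
) -> AmpliconReference:
    """Generate a random amplicon with the guide window annotated.

    ``guide_window`` is 1-based inclusive and must lie within
    [1, length]; base composition follows ``gc_fraction``.
    Deterministic for a fixed seed.
    """
    gs, ge = guide_window
    if not (1 <= gs <= ge <= length):
        raise ValueError(f"guide window {gs}-{ge} outside reference [1, {length}]")
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError("gc_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    codes = rng.choice(4, size=length, p=p)
    seq = "".join(BASES[c] for c in codes)
    return AmpliconReference(ref_id, seq, gs, ge)


def apply_events(reference: str, allele: AlleleSpec) -> str:
    """Build an allele sequence by applying events right-to-left.

    Right-to-left application keeps every event's coordinates anchored
    to the unedited reference.
    """
    for e in allele.events:
        end = e.ref_pos + (e.length if e.kind == "deletion" else 0)
        if end > len(reference):
            raise ValueError(f"event {e.serialize()} outside the reference")
    seq = reference
    for e in reversed(allele.events):
        if e.kind == "deletion":
            seq = seq[: e.ref_pos] + seq[e.ref_pos + e.length :]
        else:
            seq = seq[: e.ref_pos] + e.inserted_seq + seq[e.ref_pos :]
    return seq


# ---------------------------------------------------------------------------
# Allele-coordinate bookkeeping
# ---------------------------------------------------------------------------


def allele_layout(ref_len: int, events: Sequence[EventSpec]) -> List[Tuple[int, int, int, str]]:
    """Segment map of an allele: (allele_start, allele_end, ref_start, kind).

    kind 'M' segments copy reference bases; kind 'I' segments are
    inserted sequence (ref_start is the insertion point).  Deletions
    appear as jumps in ref_start between consecutive M segments.
    """
    segs: List[Tuple[int, int, int, str]] = []
    ref_cur = 0
    allele_cur = 0
    for e in events:
        if e.ref_pos > ref_cur:
            n = e.ref_pos - ref_cur
            segs.append((allele_cur, allele_cur + n, ref_cur, "M"))
            allele_cur += n
            ref_cur = e.ref_pos
        if e.kind == "deletion":
            ref_cur += e.length
        else:
            segs.append((allele_cur, allele_cur + e.length, ref_cur, "I"))
            allele_cur += e.length
    if ref_cur < ref_len:
        segs.append((allele_cur, allele_cur + (ref_len - ref_cur), ref_cur, "M"))
    return segs


def allele_to_ref(layout: Sequence[Tuple[int, int, int, str]], pos: int) -> int:
    """Map an allele coordinate to the reference coordinate at/after it."""
    for a_s, a_e, r_s, kind in layout:
        if a_s <= pos < a_e:
            return r_s + (pos - a_s) if kind == "M" else r_s
    if layout:
        a_s, a_e, r_s, kind = layout[-1]
        if pos == a_e:
            return r_s + (a_e - a_s) if kind == "M" else r_s
    raise ValueError(f"allele coordinate {pos} outside layout")


def observable_events(
    ref_len: int, events: Sequence[EventSpec], frag_start: int, frag_end: int
) -> List[EventSpec]:
    """Events a fragment [frag_start, frag_end) on the allele fully displays.

    A deletion is observable when the fragment holds at least one base
    on each side of its junction; an insertion when the whole inserted
    segment plus one flanking base on each side is inside the fragment.
    """
    layout = allele_layout(ref_len, events)
    out: List[EventSpec] = []
    ins_segs = {r_s: (a_s, a_e) for a_s, a_e, r_s, k in layout if k == "I"}
    # deletion junctions: allele coordinate where the ref jumps
    junctions: Dict[int, int] = {}
    prev = None
    for seg in layout:
        if seg[3] == "M":
            if prev is not None and prev[3] == "M" and seg[2] > prev[2] + (prev[1] - prev[0]):
                junctions[seg[0]] = seg[2]
            elif prev is not None and prev[3] == "I":
                pass
        prev = seg
    for e in events:
        if e.kind == "deletion":
            # find the junction allele coordinate for this deletion
            j = None
            ref_cur = 0
            allele_cur = 0
            for ev in events:
                gap = ev.ref_pos - ref_cur
                allele_cur += gap
                ref_cur = ev.ref_pos
                if ev is e:
                    j = allele_cur
                    break
                if ev.kind == "deletion":
                    ref_cur += ev.length
                else:
                    allele_cur += ev.length
            if j is not None and frag_start < j < frag_end:
                out.append(e)
        else:
            a_s, a_e = ins_segs[e.ref_pos]
            if frag_start < a_s and frag_end > a_e:
                out.append(e)
    return out


# ---------------------------------------------------------------------------
# Pool builders
# ---------------------------------------------------------------------------


def left_normalize_deletion(reference: str, start: int, length: int) -> int:
    """Shift a deletion start left through equal flanking bases."""
    s, e = start, start + length
    while s > 0 and reference[s - 1] == reference[e - 1]:
        s -= 1
        e -= 1
    return s


def _pinned_insertion_seq(reference: str, pos: int, length: int, rng) -> str:
    """Random insert whose last base differs from ref[pos-1].

    That pins the left edge of the insertion, so the left-normalised
    alignment reproduces the planted coordinate exactly.
    """
    while True:
        seq = "".join(BASES[c] for c in rng.integers(0, 4, size=length))
        if pos == 0 or seq[-1] != reference[pos - 1]:
            return seq


def _recoverable(reference: str, events: List[EventSpec]) -> bool:
    """True when the default aligner reproduces the planted events exactly.

    A nearby insertion+deletion pair can admit a cheaper alignment (for
    instance two small deletions); such alleles have no well-defined
    CIGAR-level ground truth and are rejected by the pool builders.
    """
    from .align import align_amplicon
    from .classify import extract_events

    allele_seq = apply_events(reference, AlleleSpec(list(events), 0.0))
    aln = align_amplicon(allele_seq, reference)
    got = [(e.kind, e.ref_pos, e.length, e.inserted_seq) for e in extract_events(aln)]
    want = [(e.kind, e.ref_pos, e.length, e.inserted_seq) for e in events]
    return got == want


def make_editing_pool(
    reference: AmpliconReference,
    fractions: Dict[str, float],
    seed: int = 0,
    n_variants_per_category: int = 4,
    deletion_lengths: Sequence[int] = (1, 2, 4, 7, 10, 13),
    insertion_lengths: Sequence[int] = (1, 1, 2, 3),
) -> List[AlleleSpec]:
    """Build a short-amplicon allele pool around the cut site.

    ``fractions`` maps category names WT / Deletion / Insertion /
    Multiple to pool fractions (must sum to 1).  Each edited category is
    split evenly across ``n_variants_per_category`` distinct alleles.
    Deletion coordinates are left-normalised, insertion sequences are
    pinned so the planted coordinate is the left-normal form, and every
    allele is verified to round-trip through the aligner, so the
    planted events are the recoverable ground truth.
    """
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ValueError("category fractions must sum to 1")
    rng = np.random.default_rng(seed)
    ref = reference.sequence
    cut = reference.cut_site
    pool: List[AlleleSpec] = []
    if fractions.get("WT", 0) > 0:
        pool.append(AlleleSpec([], fractions["WT"], name="WT"))

    def _deletion(length: int, offset: int = 0) -> EventSpec:
        start = left_normalize_deletion(ref, cut - length // 2 + offset, length)
        return EventSpec("deletion", start, length)

    def _insertion(length: int, pos: int) -> EventSpec:
        return EventSpec("insertion", pos, length, _pinned_insertion_seq(ref, pos, length, rng))

    for cat in ("Deletion", "Insertion", "Multiple"):
        frac = fractions.get(cat, 0)
        if frac <= 0:
            continue
        n_var = n_variants_per_category
        for v in range(n_var):
            for attempt in range(100):
                try:
                    if cat == "Deletion":
                        L = int(deletion_lengths[(v + attempt) % len(deletion_lengths)])
                        events = [_deletion(L, attempt % 3)]
                    elif cat == "Insertion":
                        L = int(insertion_lengths[(v + attempt) % len(insertion_lengths)])
                        events = [_insertion(L, cut + (v % 2))]
                    else:
                        dL = int(deletion_lengths[(v + attempt) % len(deletion_lengths)])
                        iL = int(insertion_lengths[v % len(insertion_lengths)])
                        d = _deletion(dL, -6)
                        ins_pos = d.ref_pos + d.length + 8 + (v % 3)
                        events = [d, _insertion(iL, ins_pos)]
                    validate_events(events)
                    if _recoverable(ref, events):
                        break
                except ValueError:
                    continue
            else:  # pragma: no cover - generator misconfiguration
                raise RuntimeError("could not place recoverable events for pool")
            pool.append(AlleleSpec(events, frac / n_var, name=f"{cat.lower()}_{v}"))
    total = sum(a.frequency for a in pool)
    for a in pool:
        a.frequency /= total
    return pool


def make_large_deletion_pool(
    reference: AmpliconReference,
    deletion_sizes: Sequence[int] = (500, 1500, 3900),
    wt_fraction: float = 0.4,
    seed: int = 0,
) -> List[AlleleSpec]:
    """Long-amplicon pool: WT plus multi-kb deletions spanning the cut site."""
    ref = reference.sequence
    cut = reference.cut_site
    n = len(deletion_sizes)
    pool = [AlleleSpec([], wt_fraction, name="WT")]
    for i, size in enumerate(deletion_sizes):
        start = cut - size // 2
        start = max(50, min(start, len(ref) - size - 50))
        if start < 0 or start + size > len(ref):
            raise ValueError(f"deletion of {size} bp does not fit the reference")
        start = left_normalize_deletion(ref, start, size)
        pool.append(
            AlleleSpec(
                [EventSpec("deletion", start, size)],
                (1 - wt_fraction) / n,
                name=f"del{size}",
            )
        )
    return pool


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def _add_substitutions(seq: str, rate: float, rng) -> str:
    if rate <= 0:
        return seq
    codes = _ASCII_TO_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    hit = rng.random(codes.size) < rate
    k = int(hit.sum())
    if k == 0:
        return seq
    codes = codes.copy()
    codes[hit] = (codes[hit] + rng.integers(1, 4, size=k)) % 4
    return "".join(BASES[c] for c in codes)


def simulate_reads(
    reference: AmpliconReference,
    pool: Sequence[AlleleSpec],
    n_pairs: int,
    read_length: int = 250,
    fragment_length_mean: float = 10000.0,
    fragment_length_sd: float = 0.0,
    substitution_error_rate: float = 0.0,
    seed: int = 0,
    base_quality: int = 30,
    id_prefix: str = "sim",
) -> Tuple[List[ReadPair], SimTruth]:
    """Simulate paired 250-bp reads from an allele pool.

    Fragment lengths are normal with the stated mean/sd, truncated to
    [read_length, allele length]; the default mean exceeds any amplicon
    so fragments span the whole allele, which is the behaviour of a PCR
    amplicon library.  Mate 2 is reverse-complemented; base qualities
    are constant; substitution errors are applied per mate.
    Deterministic for a fixed seed.
    """
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    freqs = np.array([a.frequency for a in pool], dtype=float)
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError("pool frequencies must sum to 1")
    rng = np.random.default_rng(seed)
    allele_seqs = [apply_events(reference.sequence, a) for a in pool]
    for i, s in enumerate(allele_seqs):
        if len(s) < read_length:
            raise ValueError(f"allele {i} shorter than the read length")
    assignment = rng.choice(len(pool), size=n_pairs, p=freqs)
    truth = SimTruth(reference, list(pool))
    pairs: List[ReadPair] = []
    qual = np.full(read_length, base_quality, dtype=np.uint8)
    ref_len = len(reference.sequence)
    for i in range(n_pairs):
        ai = int(assignment[i])
        allele = allele_seqs[ai]
        if fragment_length_sd > 0:
            frag_len = int(round(rng.normal(fragment_length_mean, fragment_length_sd)))
        else:
            frag_len = int(round(fragment_length_mean))
        frag_len = max(read_length, min(frag_len, len(allele)))
        start = int(rng.integers(0, len(allele) - frag_len + 1))
        frag = allele[start : start + frag_len]
        seq1 = _add_substitutions(frag[:read_length], substitution_error_rate, rng)
        seq2 = _add_substitutions(
            reverse_complement(frag[-read_length:]), substitution_error_rate, rng
        )
        rid = f"{id_prefix}{i:07d}"
        pairs.append(ReadPair(rid, seq1, seq2, qual.copy(), qual.copy()))
        truth.entries[rid] = TruthEntry(
            ai,
            start,
            start + frag_len,
            observable_events(ref_len, pool[ai].events, start, start + frag_len),
        )
    return pairs, truth


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------


def write_reference_fasta(reference: AmpliconReference, path: str) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    rec = SeqRecord(
        Seq(reference.sequence),
        id=reference.id,
        description=f"guide={reference.guide_start}-{reference.guide_end}",
    )
    SeqIO.write([rec], path, "fasta")


def read_reference_fasta(path: str, guide_window: Tuple[int, int]) -> AmpliconReference:
    from Bio import SeqIO

    rec = next(SeqIO.parse(path, "fasta"))
    return AmpliconReference(rec.id, str(rec.seq).upper(), guide_window[0], guide_window[1])


def write_fastq_pair(pairs: Iterable[ReadPair], path1: str, path2: str) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            q1 = (p.qual1 + 33).tobytes().decode("ascii")
            q2 = (p.qual2 + 33).tobytes().decode("ascii")
            f1.write(f"@{p.id}/1\n{p.seq1}\n+\n{q1}\n")
            f2.write(f"@{p.id}/2\n{p.seq2}\n+\n{q2}\n")


def write_truth_tsv(truth: SimTruth, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tallele\tfrag_start\tfrag_end\tevents\n")
        for rid, e in truth.entries.items():
            ev = ",".join(x.serialize() for x in e.events)
            fh.write(f"{rid}\t{e.allele_index}\t{e.frag_start}\t{e.frag_end}\t{ev}\n")
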