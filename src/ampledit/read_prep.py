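"""Paired-end read merging and fixed end-clipping.

Mate pairs from an amplicon library overlap in the middle of the
fragment; merging scans every candidate overlap length within
configured bounds, keeps the candidate with the lowest mismatch
fraction (ties to the longest overlap), and reconciles overlap bases by
base quality.  Fixed clipping removes a set number of bases from the
5'/3' ends of a read, used for targets where a flanking feature (e.g. a
heterozygous genomic insertion next to the amplicon primer) would
otherwise contaminate the alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, List, Optional, Tuple

import numpy as np

from ._kernels import merge_scan

_COMPLEMENT = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReadPair:
    """One mate pair, both mates in sequencing orientation."""

    id: str
    seq1: str
    seq2: str
    qual1: np.ndarray
    qual2: np.ndarray

    def __post_init__(self) -> None:
        self.qual1 = np.asarray(self.qual1, dtype=np.uint8)
        self.qual2 = np.asarray(self.qual2, dtype=np.uint8)
        if len(self.seq1) != self.qual1.size or len(self.seq2) != self.qual2.size:
            raise ValueError(f"{self.id}: sequence/quality length mismatch")


@dataclass
class MergedRead:
    """A merged fragment sequence with per-base qualities."""

    id: str
    seq: str
    qual: np.ndarray
    overlap_length: int

    def __post_init__(self) -> None:
        self.qual = np.asarray(self.qual, dtype=np.uint8)
        if len(self.seq) != self.qual.size:
            raise ValueError(f"{self.id}: sequence/quality length mismatch")


def merge_pair(
    pair: ReadPair,
    min_overlap: int = 10,
    max_overlap: int = 250,
    max_mismatch_fraction: float = 0.25,
) -> Optional[MergedRead]:
    """Merge one pair by overlap; returns None on merge failure.

    Mate 2 is reverse-complemented internally.  The best overlap is the
    candidate length in [min_overlap, max_overlap] minimising the
    mismatch fraction, ties going to the longest overlap; if its
    mismatch fraction exceeds ``max_mismatch_fraction`` the pair fails
    to merge.  Overlap bases take the higher-quality call (mate 1 wins
    exact quality ties) and keep the winning base's quality.
    """
    if min_overlap > max_overlap:
        raise ValueError("min_overlap must not exceed max_overlap")
    if not pair.seq1 or not pair.seq2:
        raise ValueError(f"{pair.id}: empty mate sequence")
    seq2 = reverse_complement(pair.seq2)
    qual2 = pair.qual2[::-1]
    a = np.frombuffer(pair.seq1.encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(seq2.encode("ascii"), dtype=np.uint8)
    best_o, best_mm = merge_scan(a, b, min_overlap, max_overlap)
    if best_o < 0 or best_mm / best_o > max_mismatch_fraction:
        return None
    off = len(pair.seq1) - best_o
    merged = np.concatenate([a[:off], np.empty(best_o, np.uint8), b[best_o:]])
    qual = np.concatenate([pair.qual1[:off], np.empty(best_o, np.uint8), qual2[best_o:]])
    q1 = pair.qual1[off:]
    q2 = qual2[:best_o]
    take2 = q2 > q1
    merged[off : off + best_o] = np.where(take2, b[:best_o], a[off:])
    qual[off : off + best_o] = np.where(take2, q2, q1)
    return MergedRead(pair.id, merged.tobytes().decode("ascii"), qual, best_o)


def clip_read(read: MergedRead, five_prime_n: int = 0, three_prime_n: int = 0) -> MergedRead:
    """Remove fixed base counts from the read ends, qualities in lockstep."""
    if five_prime_n < 0 or three_prime_n < 0:
        raise ValueError("clip lengths must be >= 0")
    if five_prime_n + three_prime_n >= len(read.seq):
        raise ValueError(
            f"{read.id}: clipping {five_prime_n}+{three_prime_n} bases from a "
            f"{len(read.seq)}-bp read leaves nothing"
        )
    end = len(read.seq) - three_prime_n
    return MergedRead(
        read.id, read.seq[five_prime_n:end], read.qual[five_prime_n:end], read.overlap_length
    )


def clip_pair(pair: ReadPair, five_prime_n: int = 0, three_prime_n: int = 0) -> ReadPair:
    """Pre-merge clipping in fragment orientation.

    ``five_prime_n`` bases leave mate 1's 5' end and ``three_prime_n``
    bases leave mate 2's 5' end (the fragment's 3' end).
    """
    if five_prime_n >= len(pair.seq1) or three_prime_n >= len(pair.seq2):
        raise ValueError(f"{pair.id}: over-clipping")
    return ReadPair(
        pair.id,
        pair.seq1[five_prime_n:],
        pair.seq2[three_prime_n:],
        pair.qual1[five_prime_n:],
        pair.qual2[three_prime_n:],
    )


def merge_pairs(
    pairs: Iterable[ReadPair],
    min_overlap: int = 10,
    max_overlap: int = 250,
    max_mismatch_fraction: float = 0.25,
) -> Tuple[List[MergedRead], int]:
    """Merge a stream of pairs; returns (merged reads, failure count)."""
    merged: List[MergedRead] = []
    failures = 0
    for pair in pairs:
        m = merge_pair(pair, min_overlap, max_overlap, max_mismatch_fraction)
        if m is None:
            failures += 1
        else:
            merged.append(m)
    return merged, failures


# ---------------------------------------------------------------------------
# FASTQ I/O
# ---------------------------------------------------------------------------


def read_fastq_pairs(path1: str, path2: str) -> Iterator[ReadPair]:
    """Stream mate pairs from two FASTQ files (Phred+33)."""
    import pysam

    with pysam.FastxFile(path1) as f1, pysam.FastxFile(path2) as f2:
        for r1, r2 in zip(f1, f2):
            name1 = r1.name.split("/")[0]
            name2 = r2.name.split("/")[0]
            if name1 != name2:
                raise ValueError(f"mate id mismatch: {r1.name} vs {r2.name}")
            yield ReadPair(
                name1,
                r1.sequence,
                r2.sequence,
                np.array(r1.get_quality_array(), dtype=np.uint8),
                np.array(r2.get_quality_array(), dtype=np.uint8),
            )


def write_fastq(reads: Iterable[MergedRead], path: str) -> None:
    """Write merged reads as 4-line Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for r in reads:
            qual = (r.qual + 33).tobytes().decode("ascii")
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


def read_fastq(path: str) -> List[MergedRead]:
    """Read single-end (merged) FASTQ records."""
    import pysam

    out: List[MergedRead] = []
    with pysam.FastxFile(path) as fh:
        for rec in fh:
            out.append(
                MergedRead(
                    rec.name,
                    rec.sequence,
                    np.array(rec.get_quality_array(), dtype=np.uint8),
                    overlap_length=0,
                )
            )
    return out
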