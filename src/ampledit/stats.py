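"""Replicate-level editing statistics and the quantitation formulas.

Covers per-sample summaries (percent edited, category and
CIGAR-complexity counts, mean indel lengths by context), fold change in
editing between enzymes, the off-target fidelity ratio, the yeast CFU
survival formulas, and Welch's unequal-variance t-test with
Benjamini-Hochberg FDR adjustment.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .classify import AlleleCall, Category, cc_histogram

FIDELITY_DEPTH = 100_000


@dataclass
class SampleSummary:
    """Editing statistics for one sample (one replicate)."""

    sample_id: str
    group: str
    n_admissible: int
    n_edited: int
    percent_edited: float
    category_counts: Dict[str, int]
    cc_counts: Dict[int, int]
    length_stats: Dict[Tuple[str, str], float]
    n_excluded: int = 0

    @property
    def relative_occurrence(self) -> Dict[str, float]:
        """Edited-category counts as fractions of all edited reads."""
        if self.n_edited == 0:
            return {}
        return {
            c: self.category_counts.get(c, 0) / self.n_edited
            for c in (Category.DELETION.value, Category.INSERTION.value, Category.MULTIPLE.value)
        }

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "group": self.group,
            "n_admissible": self.n_admissible,
            "n_edited": self.n_edited,
            "n_excluded": self.n_excluded,
            "percent_edited": self.percent_edited,
            "category_counts": self.category_counts,
            "cc_counts": {str(k): v for k, v in self.cc_counts.items()},
            "length_stats": {f"{k[0]}|{k[1]}": v for k, v in self.length_stats.items()},
        }


@dataclass
class FidelityResult:
    """Unedited-fraction ratio of a test enzyme relative to the reference."""

    fidelity_test: float
    fidelity_reference: float
    test_counts: List[int]
    reference_counts: List[int]
    depth: int


@dataclass
class CFURecord:
    raw_sample_cfu: float
    raw_control_cfu: float
    normalized_cfu: float
    relative_cfu: Optional[float] = None
    fold_change: Optional[float] = None


def average_indel_length(read_counts_per_length: Mapping[int, int]) -> float:
    """Mean indel length weighted by read count.

    sum(count_n * n) / sum(count_n); NaN when no reads.
    """
    if any(v < 0 for v in read_counts_per_length.values()):
        raise ValueError("read counts must be non-negative")
    total = sum(read_counts_per_length.values())
    if total == 0:
        warnings.warn("average_indel_length of an empty count table is undefined")
        return float("nan")
    return sum(n * c for n, c in read_counts_per_length.items()) / total


def summarize_sample(
    calls: Sequence[AlleleCall], sample_id: str = "", group: str = ""
) -> SampleSummary:
    """Summarise one sample's calls.

    Edited means admissible with at least one event.  Length means are
    computed per event kind and context (``single`` = the event of a
    single-event allele, ``within_multiple`` = events inside Multiple
    alleles); partial calls are excluded from length statistics.
    """
    adm = [c for c in calls if c.admissible]
    n_excluded = len(calls) - len(adm)
    n_edited = sum(1 for c in adm if c.events)
    if not adm:
        warnings.warn(f"sample {sample_id!r}: no admissible reads, percentages undefined")
        percent = float("nan")
    else:
        percent = 100.0 * n_edited / len(adm)
    cat_counts = Counter(c.category.value for c in adm)
    length_counts: Dict[Tuple[str, str], Counter] = defaultdict(Counter)
    for c in adm:
        if c.partial or not c.events:
            continue
        context = "within_multiple" if c.category is Category.MULTIPLE else "single"
        for e in c.events:
            length_counts[(e.kind, context)][e.length] += 1
    length_stats = {
        key: average_indel_length(counts) for key, counts in length_counts.items()
    }
    return SampleSummary(
        sample_id=sample_id,
        group=group,
        n_admissible=len(adm),
        n_edited=n_edited,
        percent_edited=percent,
        category_counts=dict(cat_counts),
        cc_counts=cc_histogram(adm),
        length_stats=length_stats,
        n_excluded=n_excluded,
    )


def fold_change_editing(
    sample: Sequence[Union[SampleSummary, float]],
    reference: Sequence[Union[SampleSummary, float]],
) -> float:
    """Mean percent edited of the sample over the reference replicates."""

    def _percents(xs) -> List[float]:
        return [x.percent_edited if isinstance(x, SampleSummary) else float(x) for x in xs]

    if not sample or not reference:
        raise ValueError("need at least one replicate per side")
    ref_mean = float(np.mean(_percents(reference)))
    if ref_mean == 0:
        warnings.warn("reference editing is zero; fold change undefined")
        return float("nan")
    return float(np.mean(_percents(sample))) / ref_mean


def fidelity(
    test_counts: Sequence[int],
    reference_counts: Sequence[int],
    depth: int = FIDELITY_DEPTH,
) -> FidelityResult:
    """Off-target fidelity of a test enzyme relative to the reference.

    mean over replicates of (1 - edited_count/depth) for the test
    enzyme, divided by the same mean for the reference enzyme.  The
    reference's own ratio is 1 by construction.
    """
    if len(test_counts) != len(reference_counts):
        raise ValueError("need the same replicate count on both sides")
    for c in list(test_counts) + list(reference_counts):
        if not 0 <= c <= depth:
            raise ValueError(f"count {c} outside [0, depth={depth}]")
    test_term = float(np.mean([1 - c / depth for c in test_counts]))
    ref_term = float(np.mean([1 - c / depth for c in reference_counts]))
    if ref_term == 0:
        raise ZeroDivisionError("reference unedited fraction is zero; fidelity undefined")
    return FidelityResult(
        fidelity_test=test_term / ref_term,
        fidelity_reference=1.0,
        test_counts=list(test_counts),
        reference_counts=list(reference_counts),
        depth=depth,
    )


def scale_to_depth(count: int, total: int, depth: int, seed: int = 0) -> int:
    """Bring an edited-read count from ``total`` reads to ``depth`` reads.

    Samples hypergeometrically (seeded) when total > depth; rescales
    proportionally with a warning when total < depth.
    """
    if total == depth:
        return count
    if total > depth:
        rng = np.random.default_rng(seed)
        return int(rng.hypergeometric(count, total - count, depth))
    warnings.warn(f"sample depth {total} below normalization depth {depth}; rescaling")
    return round(count * depth / total)


# ---------------------------------------------------------------------------
# Yeast CFU formulas
# ---------------------------------------------------------------------------


def cfu_standardize(raw_sample: float, raw_control: float) -> float:
    """raw_sample / (raw_control / 100): colony count per 100 loading-control colonies."""
    if raw_sample < 0 or raw_control < 0:
        raise ValueError("colony counts must be >= 0")
    if raw_control == 0:
        raise ZeroDivisionError("zero control colony count; normalization undefined")
    return raw_sample / (raw_control / 100.0)


def cfu_relative(normalized: float, wt_normalized: Sequence[float]) -> float:
    """Normalised CFU relative to the mean normalised CFU of wild type."""
    wt_mean = float(np.mean(wt_normalized))
    if wt_mean == 0:
        raise ZeroDivisionError("wild-type mean CFU is zero")
    return normalized / wt_mean


def cfu_fold_change(
    normalized_sample: float,
    control_mean: float,
    wt_normalized: Sequence[float],
    simplified: bool = False,
) -> float:
    """Survival fold change relative to the no-enzyme control.

    The printed form multiplies (sample/control - 1) by the mean of the
    wild-type replicates' relative CFU; for a complete wild-type
    replicate set that trailing factor is identically 1, and
    ``simplified=True`` drops it.
    """
    if control_mean == 0:
        raise ZeroDivisionError("control mean CFU is zero")
    base = normalized_sample / control_mean - 1.0
    if simplified:
        return base
    wt_mean = float(np.mean(wt_normalized))
    if wt_mean == 0:
        raise ZeroDivisionError("wild-type mean CFU is zero")
    trailing = float(np.mean([w / wt_mean for w in wt_normalized]))
    return base * trailing


def cfu_table(
    raw_samples: Sequence[float],
    raw_controls: Sequence[float],
    wt_indices: Sequence[int],
    control_indices: Sequence[int],
) -> List[CFURecord]:
    """Apply the CFU formula chain to a plate of raw colony counts.

    ``wt_indices``/``control_indices`` select the wild-type enzyme and
    no-enzyme control replicates within the input order.
    """
    normalized = [cfu_standardize(s, c) for s, c in zip(raw_samples, raw_controls)]
    wt_norm = [normalized[i] for i in wt_indices]
    control_mean = float(np.mean([normalized[i] for i in control_indices]))
    out = []
    for raw_s, raw_c, norm in zip(raw_samples, raw_controls, normalized):
        out.append(
            CFURecord(
                raw_sample_cfu=raw_s,
                raw_control_cfu=raw_c,
                normalized_cfu=norm,
                relative_cfu=cfu_relative(norm, wt_norm),
                fold_change=cfu_fold_change(norm, control_mean, wt_norm),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Hypothesis testing
# ---------------------------------------------------------------------------


def welch_t(sample_a: Sequence[float], sample_b: Sequence[float]) -> Tuple[float, float]:
    """Two-tailed Welch t-test (unequal variance).

    Returns (t, p).  Two constant, identical samples have no testable
    difference: t = 0, p = 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two values per side")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, preserving input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
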