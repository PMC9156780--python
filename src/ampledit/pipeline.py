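"""End-to-end orchestration: prep -> align -> classify -> summarise.

A run is driven by a JSON config naming the reference FASTA, the guide
window, per-target clip settings, the scoring scheme, and a sample
sheet.  Each sample is processed independently (FASTQ route:
clip/merge/align/classify; SAM route: classify pre-computed
alignments), producing a per-read call table, a summary JSON and a run
manifest.  Long-amplicon mode swaps the merge/classify stages for
per-mate local alignment and large-deletion calling.
"""

from __future__ import annotations

import hashlib
import json
import os
import warnings
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from . import __version__
from .align import (
    Alignment,
    ScoringScheme,
    align_amplicon,
    align_for_large_deletion,
    read_sam,
    write_sam,
)
from .classify import AlleleCall, classify_all, write_call_table
from .large_deletions import (
    GuideWindow,
    collect_pair_evidence,
    deletion_span_table,
    guide_overlap_filter,
    write_bed,
)
from .read_prep import (
    MergedRead,
    clip_pair,
    clip_read,
    merge_pair,
    read_fastq_pairs,
)
from .simulate import read_reference_fasta
from .stats import SampleSummary, fdr_adjust, fold_change_editing, summarize_sample, welch_t

SHORT_AMPLICON = "short_amplicon"
LONG_AMPLICON = "long_amplicon"


@dataclass
class SampleSpec:
    sample_id: str
    group: str
    fastq1: Optional[str] = None
    fastq2: Optional[str] = None
    sam: Optional[str] = None


@dataclass
class RunConfig:
    reference: str
    guide_window: Tuple[int, int]
    samples: List[SampleSpec]
    mode: str = SHORT_AMPLICON
    seed: int = 0
    out_dir: str = "."
    clip5: int = 0
    clip3: int = 0
    clip_stage: str = "post_merge"  # or "pre_merge"
    min_overlap: int = 10
    max_overlap: int = 250
    max_mismatch_fraction: float = 0.25
    scoring: Optional[ScoringScheme] = None

    def __post_init__(self) -> None:
        if self.mode not in (SHORT_AMPLICON, LONG_AMPLICON):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.clip_stage not in ("pre_merge", "post_merge"):
            raise ValueError(f"unknown clip stage {self.clip_stage!r}")


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        raw = json.load(fh)
    samples = [SampleSpec(**s) for s in raw.pop("samples")]
    scoring = raw.pop("scoring", None)
    cfg = RunConfig(
        samples=samples,
        scoring=ScoringScheme(**scoring) if scoring else None,
        guide_window=tuple(raw.pop("guide_window")),
        **raw,
    )
    for s in cfg.samples:
        for p in (s.fastq1, s.fastq2, s.sam):
            if p and not os.path.exists(p):
                raise FileNotFoundError(f"sample {s.sample_id}: missing input {p}")
    if not os.path.exists(cfg.reference):
        raise FileNotFoundError(f"missing reference {cfg.reference}")
    return cfg


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(config: RunConfig, sample: SampleSpec, out_dir: str, counts: dict) -> None:
    inputs = {
        p: _digest(p)
        for p in (sample.fastq1, sample.fastq2, sample.sam, config.reference)
        if p
    }
    manifest = {
        "ampledit_version": __version__,
        "sample_id": sample.sample_id,
        "group": sample.group,
        "mode": config.mode,
        "guide_window": list(config.guide_window),
        "seed": config.seed,
        "parameters": {
            "clip5": config.clip5,
            "clip3": config.clip3,
            "clip_stage": config.clip_stage,
            "min_overlap": config.min_overlap,
            "max_overlap": config.max_overlap,
            "max_mismatch_fraction": config.max_mismatch_fraction,
            "scoring": asdict(config.scoring) if config.scoring else None,
        },
        "inputs": inputs,
        "stage_counts": counts,
    }
    with open(os.path.join(out_dir, f"{sample.sample_id}.manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _prep_and_align_sample(
    config: RunConfig, sample: SampleSpec, reference_seq: str, counts: dict
) -> List[Alignment]:
    """FASTQ or SAM route to a list of alignments (short-amplicon mode)."""
    if sample.sam:
        alignments = read_sam(sample.sam)
        counts["reads_in"] = len(alignments)
        mapped = [a for a in alignments if a.mapped]
        counts["unmapped_dropped"] = len(alignments) - len(mapped)
        return mapped
    scoring = config.scoring or ScoringScheme()
    alignments = []
    n_in = n_merged = n_failed = 0
    for pair in read_fastq_pairs(sample.fastq1, sample.fastq2):
        n_in += 1
        if config.clip_stage == "pre_merge" and (config.clip5 or config.clip3):
            pair = clip_pair(pair, config.clip5, config.clip3)
        merged = merge_pair(
            pair, config.min_overlap, config.max_overlap, config.max_mismatch_fraction
        )
        if merged is None:
            n_failed += 1
            continue
        n_merged += 1
        if config.clip_stage == "post_merge" and (config.clip5 or config.clip3):
            merged = clip_read(merged, config.clip5, config.clip3)
        alignments.append(
            align_amplicon(merged.seq, reference_seq, scoring, read_id=merged.id)
        )
    counts["reads_in"] = n_in
    counts["merged"] = n_merged
    counts["merge_failures"] = n_failed
    return alignments


def run_sample(config: RunConfig, sample: SampleSpec):
    """Process one sample; returns a SampleSummary (short mode) or the
    deletion span table (long mode).  Outputs land in config.out_dir.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    reference = read_reference_fasta(config.reference, config.guide_window)
    if config.mode == LONG_AMPLICON:
        return _run_long(config, sample, reference)
    counts: dict = {}
    alignments = _prep_and_align_sample(config, sample, reference.sequence, counts)
    calls = classify_all(alignments, config.guide_window)
    counts["aligned"] = len(alignments)
    counts["admissible"] = sum(1 for c in calls if c.admissible)
    counts["excluded"] = sum(1 for c in calls if not c.admissible)
    summary = summarize_sample(calls, sample.sample_id, sample.group)
    call_path = os.path.join(config.out_dir, f"{sample.sample_id}.calls.tsv")
    write_call_table(calls, call_path)
    with open(os.path.join(config.out_dir, f"{sample.sample_id}.summary.json"), "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)
    _write_manifest(config, sample, config.out_dir, counts)
    return summary


def _run_long(config: RunConfig, sample: SampleSpec, reference) -> pd.DataFrame:
    scoring = config.scoring or ScoringScheme.long_amplicon()
    window = GuideWindow(reference.id, *config.guide_window)
    evidence = []
    alignments = []
    n_pairs = 0
    for pair in read_fastq_pairs(sample.fastq1, sample.fastq2):
        n_pairs += 1
        a1, a2 = align_for_large_deletion(pair, reference.sequence, scoring, reference.id)
        alignments.extend([a1, a2])
        evidence.append(collect_pair_evidence(pair.id, [a1, a2], reference.sequence))
    retained = guide_overlap_filter(evidence, window, len(reference.sequence))
    table = deletion_span_table(retained)
    prefix = os.path.join(config.out_dir, sample.sample_id)
    table.to_csv(f"{prefix}.spans.tsv", sep="\t", index=False)
    write_bed(table, reference.id, f"{prefix}.deletions.bed")
    write_sam(alignments, f"{prefix}.sam", {reference.id: reference.sequence})
    _write_manifest(
        config,
        sample,
        config.out_dir,
        {"pairs_in": n_pairs, "pairs_retained": len(retained), "calls": len(table)},
    )
    return table


def run_all(config: RunConfig) -> Dict[str, List[SampleSummary]]:
    """Run every sample; returns summaries grouped by sample group."""
    grouped: Dict[str, List[SampleSummary]] = {}
    for sample in config.samples:
        result = run_sample(config, sample)
        if isinstance(result, SampleSummary):
            grouped.setdefault(sample.group, []).append(result)
    return grouped


def compare_groups(
    summaries: Dict[str, List[SampleSummary]],
    design: Sequence[Tuple[str, str]],
) -> pd.DataFrame:
    """Fold change + Welch p + BH-adjusted p for each (test, reference) pair.

    All comparisons in one invocation form a single FDR family.
    """
    rows = []
    for test_group, ref_group in design:
        if test_group not in summaries or ref_group not in summaries:
            missing = test_group if test_group not in summaries else ref_group
            raise ValueError(f"unknown group {missing!r}")
        test = [s.percent_edited for s in summaries[test_group]]
        ref = [s.percent_edited for s in summaries[ref_group]]
        fold = fold_change_editing(test, ref)
        t, p = welch_t(test, ref)
        rows.append(
            {
                "test_group": test_group,
                "ref_group": ref_group,
                "fold_change": fold,
                "t": t,
                "p": p,
            }
        )
    df = pd.DataFrame(rows, columns=["test_group", "ref_group", "fold_change", "t", "p"])
    if len(df):
        df["p_adj"] = fdr_adjust(df["p"].to_numpy())
    else:
        df["p_adj"] = []
    return df
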