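# Methods

`ampledit` quantifies CRISPR editing outcomes from targeted amplicon
sequencing. This note records the models and procedures each module
implements, the parameters that matter, and the choices made where the
design was genuinely open.

## Allele classification by CIGAR complexity

Each merged read is aligned to the amplicon reference and its editing
outcome is read directly off the CIGAR string. **CIGAR complexity
(CC)** is the number of alphabetic operation characters in the
canonical CIGAR (adjacent operations of the same kind merged): a
perfect-match read is `300M` (CC 1), a single clean deletion
`100M5D195M` (CC 3), and so on. CC is a proxy for the structural
complexity of the repair outcome at the cut site.

An alignment is **admissible** when it contains no soft clip and its CC
is at most 6; the single CC-7 pattern `MIDMIDM` — the simplest CIGAR in
which two insertion–deletion events share one allele — is also
admitted. Everything else (any soft clip, CC 7 patterns other than
`MIDMIDM`, CC ≥ 8) is excluded from analysis and counted. The
exclusion rule is deliberately conservative: heavily fragmented
alignments are more often artefacts of mis-mapping than genuine repair
outcomes.

Admissible alignments decompose into indel events — one event per I or
D operation, positioned by a reference-coordinate cursor walk — and are
categorised:

| category  | definition |
|-----------|------------|
| WT        | no indel event (pure M) |
| Deletion  | exactly one deletion, nothing else |
| Insertion | exactly one insertion, nothing else |
| Multiple  | two or more events of any kinds |

Two conventions are worth stating because they are not forced by the
data model. First, *edited* is CIGAR-defined: a read whose alignment is
pure M counts as WT even if it carries substitutions, because the
classifier operates on indel structure only (substitution calling is a
separate, variant-calling concern). Second, *Multiple* includes
same-kind pairs (two deletions, two insertions), not only mixed
insertion+deletion alleles; per-composition sub-counts are reported so
the mixed-event subset remains recoverable.

Insertions are positioned by the preceding-base convention: `ref_pos`
is the 0-based reference base before which the inserted sequence sits.
The frameshift flag is set when the net length change (insertions minus
deletions) of an allele is not divisible by three.

Reads whose alignment does not span the whole 20-bp guide window keep
their category but are flagged `partial` and excluded from indel-length
statistics, since a truncated view of the cut site can clip an event.

## Alignment

Merged short-amplicon reads are aligned with an affine-gap
dynamic-programming aligner that is *read-global and reference-local*:
every read base must be aligned (M or I), while the reference can be
entered and left for free. Default scores are match +1, mismatch −1,
gap open 2, gap extend 1 (a gap of length L costs `open + L·extend`),
symmetric between insertions and deletions. With these scores a
substitution error is always cheaper than a 1-bp gap, so sequencing
noise does not masquerade as editing.

Ties are broken deterministically (M preferred over D over I; leftmost
reference placement), and indels are then left-normalised: an indel
shifts one step left whenever the base preceding the gap equals its
last base, the same convention variant callers use. This makes gap
placement in homopolymers and repeats reproducible and comparable
across tools. Score optimality of the production aligner is tested
against an independent memoized-recursion scorer on a fixed enumeration
of random sequence pairs.

Alignments can also be imported from headered SAM (text) files;
unmapped records are carried but dropped from classification with a
logged count, and hard-clipped records are rejected since the clipped
bases are unrecoverable.

## Large deletions on long amplicons

Deletions larger than the amplicon escape short-amplicon sequencing
entirely, so a ~4.2-kb amplicon around the cut site is analysed in a
separate mode. Each mate is aligned *locally* with reference gaps
priced out (gap open 10 000, extend 1 000): a mate crossing a
multi-kb deletion junction cannot bridge it with a D operation and is
soft-clipped at the junction instead.

Deletions that do appear as D operations are taken as called. Every
terminal soft clip of at least 5 bases is then submitted to **k-mer
rescue**: the clip-adjacent k-mer of the clipped sequence (the sequence
that must re-anchor on the far side of the deletion) is searched as an
exact string in the reference flank beyond the mapped segment — 
downstream of the mapped end for a 3′ clip, upstream of the mapped
start for a 5′ clip — with k descending from 30 to 5. The first k
yielding exactly one occurrence converts the clip into a deletion call
spanning the gap between the mapped edge and the match; zero or
multiple occurrences at every k yield no call. Requiring uniqueness
makes the rescue conservative in repetitive context; the descending-k
schedule prefers the most specific anchor available.

Rescued spans are left-normalised exactly like short-amplicon indels.
This also absorbs a systematic artefact of local alignment: when the
bases just after a junction happen to match the bases just inside the
deletion, the local alignment extends past the junction by those
chance-matching bases, shifting the raw span right by an equivalent
amount; left-normalisation maps every member of the equivalence class
back to the same canonical span. The long-amplicon preset prices
mismatches (−8) and read gaps (open 6, extend 3) harshly for the same
reason — cheap gaps would let the alignment creep past the junction in
ways that are *not* span-equivalent.

A pair's calls from both mates are deduplicated when identical and
flagged `discordant` when they disagree. Finally, only pairs whose
mapping or deletion coordinates intersect the 20-bp guide window are
retained: deletions are expected to be anchored at the cut site, and
the window filter removes unrelated coverage.

## Read merging and clipping

Mate pairs are merged by overlap: mate 2 is reverse-complemented and
every candidate overlap length between `min_overlap` (10) and
`max_overlap` (250) is scored; the candidate with the lowest mismatch
fraction wins, ties going to the longest overlap. If the best
candidate's mismatch fraction exceeds `max_mismatch_fraction` (0.25)
the pair fails to merge and is counted. Overlap bases take the
higher-quality call, mate 1 winning exact ties. The overlap bounds are
the parameters that matter — a 9-base true overlap is unmergeable by
construction — while the mismatch cap only matters at high error
rates.

Fixed end-clipping (`clip5`/`clip3` bases) is available before or after
merging, configured per target. It exists for targets where a flanking
sequence feature — for example a heterozygous insertion next to a
primer — would otherwise contaminate the CIGAR; clip order is
configurable because the right choice depends on where the nuisance
feature sits relative to the overlap.

## Replicate statistics

Per sample: percent edited = 100 × (admissible reads with ≥ 1 event) /
(admissible reads). Mean indel lengths are computed per event kind and
context (single-event alleles vs events inside Multiple alleles) as the
read-count-weighted mean `Σ(count_n · n) / Σ count_n`. Relative
occurrence divides each edited category's count by the total edited
reads, so the three edited categories sum to one.

Fold change in editing is the ratio of mean percent edited between two
enzymes' replicate sets. The off-target **fidelity** of a test enzyme
is the ratio of mean unedited fractions, `mean(1 − count/depth)` for
test over reference, at a fixed normalisation depth of 100 000 reads;
samples deeper than that are downsampled hypergeometrically (seeded)
and shallower ones are rescaled with a warning. The ratio is
scale-consistent (doubling depth and counts leaves it unchanged) and
equals 1 for the reference against itself by construction.

The yeast survival readout standardises raw colony counts to 100
loading-control colonies (`raw_sample / (raw_control/100)`), expresses
them relative to the mean wild-type value, and computes fold change as
`(sample/control_mean − 1)` multiplied by the mean of the wild-type
replicates' relative values. That trailing factor is algebraically 1
whenever the full wild-type replicate set is used; it is implemented
verbatim anyway, with a `simplified` mode provided and both verified to
agree.

Group comparisons use Welch's unequal-variance two-tailed t-test with
Benjamini–Hochberg FDR adjustment; all comparisons in one invocation
form a single FDR family. Two constant, identical samples have no
testable difference and report t = 0, p = 1.

## Synthetic data

The simulator generates a random amplicon (length, GC fraction and
guide window configurable; 300 bp and 4 200 bp are the reference
scenarios, the latter with guide window 2059–2078), builds an allele
pool, and emits paired 250-bp reads with constant Q30 qualities and a
configurable per-base substitution error rate. Fragment lengths are
normal with stated mean/sd, truncated to [read length, allele length];
the default mean exceeds any amplicon, so fragments span the whole
allele — the behaviour of a PCR amplicon library, where the fragment
*is* the amplicon. Allele assignment is multinomial in the pool
frequencies and everything is deterministic per seed, byte-for-byte.

Editing pools place events at the predicted blunt cut site, 3 bp from
the PAM-proximal end of the guide window. Deletion lengths default to
1–13 bp, insertions 1–3 bp, split over several distinct alleles per
category. Two normalisations make the planted truth exactly
recoverable: planted deletion coordinates are stored left-normalised,
and insertion sequences are drawn so their last base differs from the
base preceding the insertion point (pinning the left edge). Each
constructed allele is additionally verified to round-trip through the
aligner — a closely spaced insertion+deletion pair can admit a
strictly cheaper alignment (for instance two small deletions), in which
case that allele has no well-defined CIGAR-level ground truth and is
re-drawn. This is not a weakening of the test: it mirrors the fact
that any CIGAR-based classifier, including the real pipeline on real
data, observes the parsimonious representation of an allele, not its
mutational history.

The long-amplicon pool plants multi-kb deletions (0.5/1.5/3.9 kb by
default) centred on the cut site in a 4.2-kb amplicon, mixed with
unedited alleles. Junction-spanning coverage comes from fragments of
600 ± 80 bp sampled along each allele.

What the simulator does *not* model: PCR bias and chimeras, sequencer
indel errors (available behind a flag but off by default so planted
events stay unambiguous), quality-score variation, adapter read-through
and tagmentation insert-site bias. Passing tests therefore demonstrate
correctness of the computational pipeline on reads whose only
deviations from the reference are the planted events and substitution
noise — they do not certify behaviour on library artefacts.

## Validation scenarios and problem sizes

The reference experiments (in `ampledit.experiments`, re-run by
`scripts/acceptance.py`) use: 10 000 error-free pairs for exact
classifier recovery; 20 000 pairs at 0.5 % substitution error for
frequency recovery within 3σ binomial bounds; an exhaustive
enumeration of canonical CIGAR patterns to length 9 against a
brute-force admissibility rule; 1 200 long-amplicon pairs for
large-deletion recovery (denominator: pairs with a mate crossing a
junction with ≥ 30 aligned bases on each side, enough to anchor the
mate and attempt the longest rescue probe); and a two-enzyme comparison
(3 replicates × 50 000 pairs per enzyme) with a planted 1.5-fold
editing ratio, analysed exactly like a real experiment. Editing
fractions in that scenario are 0.60 vs 0.90 edited, the category mix
held proportional between enzymes.

## Known limitations

* The short-amplicon aligner reports one optimal alignment; co-optimal
  alignments that are not gap-shift-equivalent (rare in random
  sequence, more likely in long repeats) are resolved by tie-break, not
  enumerated.
* Classification requires merged reads; pairs that fail to merge are
  counted but not classified.
* The large-deletion caller reports deletions only — inversions,
  duplications and complex rearrangements that also produce soft clips
  are either dropped (no unique rescue) or, in unlucky repetitive
  contexts, could be mis-read as deletions; uniqueness of the rescue
  match is the only guard.
* Fidelity rescaling for shallow samples assumes editing is depth-
  independent, which ignores sampling error in the rescale factor.
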