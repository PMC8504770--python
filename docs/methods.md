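# Methods

This note records the models, conventions and numerical choices behind
each stage, what the synthetic data generator does and does not emulate,
and the design decisions taken where the problem was genuinely open.

## Coordinates and formats

All intervals are 0-based half-open internally and converted to GFF3's
1-based inclusive convention only at file boundaries. TE annotations are
read from any GFF3 whose features carry a family attribute (`Target`,
first token, or `family`) and optionally a classification attribute
(`class`/`classification` with a Wicker-style order code). Features
without a family are skipped and logged, never silently dropped.
Malformed lines fail with their line number. The GFF3 layer is a small
line-oriented reader/writer of our own: the error contract (per-line
diagnostics, skip logs) is part of the stage interface, and the format
as used here is a plain 9-column table.

## Inventory accounting

Full-length-copy status is `copy_length / consensus_length > 0.95`,
evaluated exactly (the threshold is converted to a rational number, so a
copy at exactly 95% is never flagged). Library filtering applies, in
order: drop SSR consensuses; drop unclassified consensuses with fewer
than 10 copies; drop consensuses without any full-length copy. Each rule
logs what it removed.

Coverage of a group is the union length of its intervals per sequence,
summed over sequences; overlapping fragments of the *same* group count
once, while different groups may cover the same base, so grouped
percentages need not sum to the all-copies total. A raw fragment-length
sum is available as an option since published bp figures do not always
state which convention they use. Percentages divide by the total
assembly length including N runs. Display rounding is decimal half-up to
two places; bp values are kept exact. Class totals aggregated from
per-order rows recompute percentages from bp when the assembly length is
known and otherwise sum the per-row percentages, which is how the
published per-order table reproduces its printed class totals (1.73% /
2.26%), grand totals (16.84%; 16.361 → 16.36%) and class bp sums
(2,472,344 and 3,282,463 ≈ 2.5 Mb and 3.3 Mb).

## Alignment and the master–slave matrix

Copies strictly longer than 100 bp are aligned to their family consensus
with global Needleman–Wunsch under affine gap costs (Gotoh three-state
recursion; a gap of length k costs `gap_open + k·gap_extend`). Affine
gaps matter here because TE copies carry long internal deletions that a
linear cost over-penalizes. Defaults are match +1, mismatch −1, open −4,
extend −1; the source tool's parameters are not published, so these are
an explicit, configurable choice. `N` scores 0 against anything and is
excluded from all divergence counts. Traceback ties break
deterministically: diagonal, then vertical (gap in copy), then
horizontal. The DP fill runs as a numba-compiled cell loop (float32,
exact for integer-valued scores at these lengths) with a row-vectorized
numpy fallback; both fills are compared in the tests, and scores are
cross-checked against exhaustive enumeration (lengths ≤ 8) and against
an independent reference aligner on longer pairs.

Stacking is classic master–slave: columns are consensus positions; copy
characters aligned to consensus gaps (copy-only insertions) are dropped
from the matrix but counted per copy; consensus positions outside a
truncated copy read `-`. The matrix width therefore always equals the
consensus length.

## Ages, trees and bursts

The age statistic is the raw p-distance: mismatches divided by compared
sites, where a compared site is a column with neither `-` nor `N` in
either row. No multiple-hit correction is applied by default because the
statistic of interest is substitutions per base pair as observed; an
HKY85-style correction (which reduces to Kimura's two-parameter distance
under the uniform base frequencies used throughout) is available behind
a flag. Pairs sharing fewer than 50 sites are uncomparable; rows
involved in uncomparable pairs are dropped greedily (most-undefined
first) before tree building.

Family trees are neighbor-joining trees (scikit-bio) on the p-distance
matrix, with negative branch lengths clamped to zero. A full
maximum-likelihood search is deliberately not performed: only cherry
membership feeds the age statistic, and NJ cherries agree with ML
cherries on well-separated data. Two-copy families yield a single edge
whose total length is the pair distance. Cherries are leaf pairs whose
path crosses exactly one internal node — equivalently, leaves sharing a
parent in the tree as given; for the degenerate three-leaf star, where
all three pairs satisfy the path definition, only the pair with the
smallest summed branch lengths is kept so the number of cherries never
exceeds n/2. The age of a cherry is the pairwise p-distance of its two
copies (the terminal-branch-length sum is available as an option, with
no claim that it is the better reading).

Burst detection bins ages into half-open 1% divergence bins, smooths
with a centred 3-bin moving average (zero-padded edges), and reports
each maximal plateau that is strictly higher than both neighbours and
reaches at least 10% of the global smoothed maximum; a plateau reports
its raw-count argmax bin. Both window and prominence are configurable;
no published values exist for them. Two histograms are produced: the
per-copy divergence-from-consensus distribution (the repeat-landscape
statistic; this is what the burst-dating experiment is scored on) and
the cherry-age distribution. Under the generator's star-shaped families
(all copies drawn independently from the consensus) a cherry's expected
pairwise distance is close to twice the per-copy divergence
(2d − 1.375d² under the substitution model below), so the cherry
histogram peaks near twice the planted wave positions — visible in the
worked example and expected, not a defect.

## Synthetic mobilome generator

The generator is calibrated to the age statistic, not to evolutionary
time: each consensus site is substituted at most once, with probability
equal to the target divergence, so the realized p-distance to the
consensus is an unbiased estimate of the target (binomial sampling
noise only). Given a substitution, a transition is chosen with
probability κ/(κ+2) and each transversion with probability 1/(κ+2)
(HKY85-style weighting with uniform base frequencies; default κ = 2.0 —
the model family is named in the source literature but its parameters
are not). Optional per-copy events: one internal deletion (fraction
drawn from a range; `floor(f·L)` bases removed) and one terminal
truncation. The realized substitution count is recorded before
deletions, so truth divergences refer to the full-length copy.

Class II insertions are flanked by identical TSD copies written into
the host sequence (fixed motif or per-insertion random k-mer); MITE-like
families impose `suffix(t) = revcomp(prefix(t))` on their consensus.
Placement is rejection sampling against an interval tree with a
configurable inter-feature margin (default: the far-distance threshold,
so planted gene contexts cannot be confounded by neighbours; the
burst preset uses a small margin, and the MITE preset a margin larger
than the scanner's maximum element length so identical neighbouring
plants cannot be bridged by one spurious inverted repeat). Infeasible
plans fail after bounded retries naming the sequence. Gene models are
genes with 1–4 exons; planted TE–gene contexts lay out one gene and one
copy per requested category deterministically. Runs of N (assembly gaps)
are supported but off by default. All randomness flows from the single
genome seed; identical specs and seed give byte-identical bundles.

What the generator does **not** emulate: nested or overlapping
insertions, realistic indel evolution, within-family phylogenetic
structure (copies are a star around the consensus), sequencing error,
base composition bias, and segmental duplications. Passing tests
therefore demonstrate correctness of the accounting, alignment, dating,
scanning and classification machinery under known truth — not robustness
to every artefact of real draft assemblies.

## MITE scanning

The structural predicate is explicit and re-checkable: interval ends
(i, j) carry a TIR of length t when t is the largest value not exceeding
200 nor half the element length such that at most `max_mismatch` of the
inward base pairs fail to be complementary (`N` complements nothing);
candidates need t ≥ 10 (configurable) and length 50–800 bp (the window
brackets the reported median MITE size). The scan walks every (start,
length) cell with a numba-compiled loop (an anti-diagonal vectorized
fallback implements the same rule; both are tested against an O(n²)
reference). Overlapping raw hits resolve longest-TIR-first, then
leftmost. Structural scanning on raw sequence is inherently noisy —
permissive settings yield on the order of one spurious candidate per
kilobase of random sequence, which is comparable to what dedicated MITE
tools report before their own filtering; strict TSD validation and
stricter thresholds cut this sharply.

TSD validation compares flanking k-mers for k from 10 down to 2 and
records the largest duplication; candidates at the sequence edge are
rejected ("flank unavailable"), and strict mode rejects candidates with
no duplication. Boundary refinement addresses a real ambiguity:
palindromic targets such as TA are their own reverse complement, so the
inverted-repeat run absorbs them, and chance complementarity of host
bases extends the run symmetrically. Refinement therefore tests
hypotheses `[start+a, end−a)` for small shifts a, keeping per shift the
longest duplication consistent with the signature table (plus the
longest overall), and chooses by signature consistency, then smallest
shift, then longest TSD. The residual ambiguity — a chance duplication
can still shift a boundary by a few bases — is intrinsic to
single-element structural evidence; recall is accordingly assessed with
boundaries within the TSD search window rather than base-exact.

Families come from greedy centroid clustering by decreasing length at
80% global-alignment identity (identical columns over alignment
columns), considering both strands. Two exact pre-filters skip
alignments that cannot reach the threshold: the length-ratio bound
min/max < θ, and an edit-distance bound (identity ≥ θ implies edit
distance ≤ (1−θ)(|a|+|b|), checked with edlib); the scored alignment
remains the deciding criterion. The signature table is ordered and fully
overridable; its defaults encode standard TE-biology conventions for the
six superfamilies, since the source survey names the superfamilies but
not its rules.

## Gene context and orientation statistics

Nearest-gene search minimizes the unsigned edge-to-edge gap (0 on
overlap or abutment) per sequence; equidistant genes on both sides are
both reported, and the classification step breaks such ties towards the
smaller start coordinate. Categories are evaluated in a fixed order so
every TE–gene pair maps to exactly one: gene ⊆ TE (flagged for
exclusion from orientation statistics rather than dropped — such "genes"
are usually mis-annotated TE ORFs); TE ⊆ gene, sub-typed exonic if the
copy overlaps any exon, else intronic; partial overlap covering the
strand-aware transcription start (5′) or end (3′) coordinate; exact
boundary coincidence; gap < 2 kb ("next to" the gene, the distance at
which insertions can affect cis-regulation); none. 5′/3′ are
strand-aware because orientation effects are asymmetric around genes.

Orientation is sense when the TE's annotated strand equals the gene's;
`.` strands are undetermined and excluded from counts. The omnibus test
is the Pearson independence chi-square on the k×2 category-by-orientation
table (df k−1, no continuity correction), reported alongside per-category
50:50 goodness-of-fit tests (df 1); no multiple-testing correction is
applied, matching the source analysis, and the omnibus result is printed
with its df so readers can judge. On the published five-category counts
the omnibus statistic is 10.14 (df 4, p ≈ 0.038) and the 5′-region test
7.78 (p ≈ 0.005). Zero-total categories are excluded with a log entry,
and the omnibus is undefined (NaN) if either orientation column is
entirely zero.

Recency is strict: a copy counts as recently transposed only when its
divergence from consensus is < 0.02; a copy at exactly 2% is excluded.
The recent-insertion summary tabulates superfamily × site group (next to
gene, exonic, intronic, 5′ side, 3′ side) with sense/antisense totals
per group and a grand-total row equal to the sum of superfamily rows.

## Problem sizes and reproducibility

The synthetic experiments use 10 families × 30 copies × 1 kb (two-wave
burst dating; 5 seeds in the reproduction script, 20 in the test suite)
and 10 genomes × 5 perfect plants (MITE recall) — sizes chosen so each
stage's statistical behaviour is visible while a full run of suite plus
script stays in the minutes range on one core. The analysis stages
consume no randomness at all; identical inputs and configuration give
byte-identical reports, each stamped with a hash of the configuration
(output directory excluded). The reproduction script threads its single
`--seed` through every generator invocation.

## Known limitations

De novo repeat discovery, homology-based classification, ML tree
search, bootstrap support and absolute-time calibration of ages are out
of scope. Coverage bp between different groups may double-count bases by
design. NJ cherries can differ from ML cherries when families have many
near-identical copies. MITE boundary refinement can mis-place a boundary
by a few bases under palindromic TSDs, and copy-number evidence (which
dedicated MITE tools use to refine boundaries) is not consulted. The
generator's star-shaped families make cherry ages systematically ≈ 2×
the per-copy divergence, which real, serially transposing families need
not obey.
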