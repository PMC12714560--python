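# Methods

This note records the models, conventions and numerical choices behind
`deletion-scope`, and what its synthetic data do and do not establish
about real sequencing data.

## Coordinates and formats

All in-memory intervals are 0-based half-open `[start, end)`.  SAM POS
(1-based) and GFF3 (1-based inclusive) are converted only at I/O
boundaries; BED is consumed/emitted natively 0-based.  SAM/BAM parsing
goes through pysam; FASTA through Bio.SeqIO.  GFF3 reading/writing is a
small purpose-written routine restricted to the three feature types the
tool uses (`gene`, `mobile_genetic_element`,
`terminal_inverted_repeat` children carrying an `end=IRL|IRR` attribute).

## Junction extraction

A junction-spanning read is an alignment whose CIGAR contains an `N`
(reference-skip) operation; walking the CIGAR with a reference cursor
from the alignment start yields the skipped interval per `N` op (M/D/=/X
advance the cursor; I/S/H do not).  Defaults: MAPQ ≥ 60
(uniquely-mapping evidence), secondary/supplementary alignments skipped
to avoid double-counting support.  `D` operations are not junctions by
default; `min_del_as_junction` promotes long `D` ops for aligners that
encode deletions that way.  There is no soft-clip rescue and no
paired-end discordance analysis.  Duplicate reads are not removed.

## Junction collapsing and annotation

Two raw junctions are linked when both endpoint differences are at most
`tol` (default 3 bp); calls are the connected components (single
linkage), so chains merge even when the extreme members differ by more
than `tol` — this is deliberate and tested.  The representative is the
(start, end) pair with the highest read count; ties break toward the
smallest start, then end.  Alternatives considered: clique clustering
(rejected as a stricter reading than "collapse near-identical
junctions"), and a combined-distance tolerance (the two-endpoint rule is
kept and documented).  Region restriction keeps a call only when both
breakpoints lie inside one region, half-open membership.  A feature
annotates a call when its interval overlaps `[breakpoint − flank,
breakpoint + flank)` (default 50 bp) of either breakpoint; the flank is
applied per breakpoint, not across the whole deleted interval, so the
interior genes of a 40 kb deletion do not drown the boundary signal —
interior features are reported separately as "deleted features"
(half-open containment).  Minimum support defaults to 1: pooled colonies
at low fractions can legitimately yield single-read junctions.

## Microhomology and repair classification

For a deletion `[a, b)` on reference `ref`, the left extension is the
maximal m with `ref[a−1−i] == ref[b−1−i]` for all i < m, the right
extension the maximal m with `ref[a+i] == ref[b+i]`; the total is their
sum, and every left-break placement in `[a − left_ext, a + right_ext]`
yields the same derived allele (a property test asserts this string
equality).  Extensions are capped at 50 bp and at sequence bounds.  Both
sides are reported so a longest-side convention is recoverable from the
output.

Classification precedence: a breakpoint within `is_dist` (default 3 bp,
matching the calling tolerance — a breakpoint is only localized to
within tolerance plus microhomology ambiguity) of any terminal-repeat
boundary coordinate classifies the junction IS_ASSOCIATED, reporting the
nearest element, repeat end and distance; otherwise total microhomology
≥ `min_mh` (default 2 bp) classifies MICROHOMOLOGY; otherwise OTHER.
IS evidence outranks microhomology because ≥2 bp of chance microhomology
occurs at roughly a third of random junctions, while an exact
repeat-boundary hit does not.

Flank matrices count bases over a `window` (default 30 bp) upstream or
downstream of either breakpoint on the forward strand; information
content per column is `2 + Σ p log2 p` bits with `0·log 0 = 0`, no
pseudocounts and no small-sample correction (a perfectly conserved
column is 2 bits; uniform columns approach 0 from above by sampling
bias).

## Coverage spans

Depth counts only aligned bases (CIGAR M/=/X); `N` and `D` consume
reference without contributing, so a spliced junction read covers its
anchors but not its gap.  Exclusion intervals are masked, not zeroed:
masked positions drop out of the median and of run statistics entirely,
so an excluded gene can neither create nor destroy a span.

Span detection thresholds at `frac × median(unmasked depth)` (default
0.5 — pooled samples show partial, not total, dropouts).  Raw integer
depth at a pooled residual of a few reads crosses any nearby threshold
constantly by shot noise, so detection runs on a mask-aware centred
moving average (600 bp, about six read lengths; gaps between candidate
runs narrower than the smoothing scale are closed).  Each boundary is
then refined: a two-segment mean fit on raw depth (wide window), then an
iterated Poisson-likelihood changepoint on per-position read-start
counts.  Start counts are independent Poisson with a step exactly at the
breakpoint, whereas depth noise is correlated over a read length, which
is what lets the refinement land within a few tens of bases.

Localization accuracy is bounded by information, not implementation: at
the pooled study regime (30× pool depth, a 13.1 kb deletion nested
inside a 43.8 kb one, residual start rates 0.21 vs 0.09 events/bp at the
shallow boundary) the maximum-likelihood changepoint carries about
0.04–0.06 nats/bp, so roughly one simulation in ten places that boundary
more than 100 bp off.  Across simulated seeds, both boundaries fall
within one read length of truth in ~90% of runs, and the sharp boundary
(residual 0.09 vs full 0.30 events/bp) is essentially exact.  Junction
calls localize breakpoints to the base and are reconciled with spans
(`reconcile`, slack one read length); coverage spans are corroborating,
not primary, breakpoint evidence.

No GC or mappability normalization and no HMM/CBS segmentation are
applied; the method mirrors a thresholded visual read of coverage plots.

## Synthetic pooled-colony WGS

`build_genome` plants one master IS sequence (768 bp; the last 30 bp are
forced to the reverse complement of the first 30) at `n_is`
non-overlapping positions, plus genes, in a GC-controlled random
background — multi-copy identical IS elements are what make real
deletion boundaries ambiguous.  `plant_deletion` edits the reference so
the planted signature is verifiable on it: A-EJ copies the `mh_len`
bases left of the left break over the bases left of the right break
(guaranteeing `left_ext ≥ mh_len` under the scanner above, checked
against a brute-force oracle); IS_BOUNDED places one breakpoint exactly
at a terminal-repeat boundary (an `"auto"` anchor picks any element
whose boundary admits the size); BLUNT resamples deleted-interval edge
bases (which cannot change the derived allele) until total microhomology
is zero.

`simulate_pool` draws `ceil(depth × fraction × retained_length /
read_length)` single-end reads per lineage uniformly over that lineage's
derived allele.  Reads crossing planted junctions get `aM bN cM` CIGARs
with the N length equal to the deleted interval; junction-crossing reads
with any aligned segment shorter than `min_anchor` (default 10 bp) are
dropped, not soft-clipped.  All reads are MAPQ 60 except an optional
fraction at MAPQ 1 to exercise the filter; base qualities are constant;
an optional uniform substitution rate (default 0) is the only error
model.  The SAM is plain text, coordinate-sorted, with a valid header,
and byte-identical across runs at a fixed seed.

Default regime (the sequenced study conditions): 200 kb genome, four IS
elements, 30× mean depth, 100 bp reads, large deletions 13.1–47 kb,
small deletions 51–255 bp with 2–11 bp microhomology.  Per-colony
pooling proportions were not published; the canonical scenario uses
0.4/0.3/0.3 and nests the two large deletions at one element's IRR —
matching the observation that all large deletions shared a single
conserved IRR boundary, and the only configuration at those fractions in
which a fractional-of-median threshold has a span to find at all.

What the generator does **not** emulate: sequencing errors and indels,
quality variation, paired ends, mapping ambiguity between identical IS
copies (reads are placed at their true origin; real multi-mapping reads
would be MAPQ-filtered, which the MAPQ-1 fraction only gestures at),
library-preparation coverage biases, and contamination.  Passing tests
therefore establish the correctness of the *analysis* under idealized
reads, not robustness to alignment artifacts.

## Distance fraction (θ)

θ is the scalar projection of (spot − beadA) onto the bead axis divided
by the bead separation; the perpendicular offset is discarded.  Values
outside [−0.05, 1.05] are flagged off-tether and excluded from
summaries.  A tether binds in either orientation, so per video the
orientation (θ or 1 − θ) whose **median** lands closer to the configured
target position is applied uniformly to all frames of that video; the
median resists off-tether outliers, and orientation is an involution
(tested).  The target defaults to 0.558, with 0.564 given by an
alternative end-to-end estimate; the discrepancy is inherited from the
source data and surfaced in configuration rather than resolved.

Summaries report n, mean, sample SD, and a fixed-width histogram
(0.02 bins over [0, 1]).  Frames acquired during DNA stretching are
excluded when requested — the two published dataset variants (n = 224
with stretching, n = 191 without) differ only in this filter.
"Pearson's normality test" is implemented as the chi-square goodness of
fit with k = ⌈1 + log2 n⌉ equal-probability bins under the fitted
normal, statistic Σ(O−E)²/E on k − 3 degrees of freedom; its empirical
type-I error at α = 0.05 is verified by Monte Carlo to sit near the
nominal level.  The D'Agostino–Pearson K² omnibus is available behind
`normality_method="dagostino"` since the name "Pearson's normality test"
is ambiguous.  Degenerate samples (n < 8, or zero variance up to float
noise) refuse the test with a flag instead of returning a p-value.

## Determinism and problem sizes

Every stochastic routine takes an explicit seed (numpy `default_rng`);
fixed seed implies byte-identical SAM output and identical reports
(no timestamps are embedded).  The test suite and the acceptance script
run the full pooled scenario (a 200 kb genome, ~55k reads) plus 1,000
microhomology oracle triples, ~50 collapse oracle multisets per
tolerance, 100 planted classification cases and 100 normality-test
replicates of n = 200 — sizes chosen so the entire analysis reruns in a
few seconds on one CPU while still exercising every code path at the
study's stated parameter regime.
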