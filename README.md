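# deletion-scope

Detection and repair-signature analysis of CRISPR–Cas-induced genome
deletions in bacteria, from spliced whole-genome-sequencing alignments —
plus distance-fraction (θ) analysis of optical-tweezers fluorescence
tracks.

## The problem

Class 1 CRISPR–Cas effectors engineered for genome editing (a compact
type I-Fv system, and a type IV-A1 system whose CasDinG helicase carries a
fused HNH nuclease) excise large chromosomal segments from *E. coli*.
Sequencing pooled edited colonies leaves two questions for the analyst:

1. **Where exactly are the deletion boundaries?**  A read that crosses a
   deletion junction is reported by a spliced aligner with an `N`
   (reference-skip) CIGAR operation whose length is the deleted interval.
   Extracting those reads (MAPQ ≥ 60), collapsing near-identical junctions
   (tolerance 3 bp) and annotating features near each breakpoint
   (flank 50 bp) yields base-resolution junction calls.
2. **What repaired the break?**  Small deletions (tens to hundreds of bp)
   flanked by 2–11 bp of microhomology point to alternative end joining
   (A-EJ); large deletions (>10 kb) terminating precisely at the ~30 bp
   terminal inverted repeat (IRR) of a 768 bp IS1 insertion element point
   to IS-mediated resolution.  The package scores breakpoint microhomology
   (the maximal shared flank, which also defines the interval of equivalent
   breakpoint placements), associates breakpoints with annotated IS
   terminal-repeat coordinates, classifies each junction, and builds
   position-frequency matrices / information-content profiles of the
   breakpoint flanks for sequence logos.

Coverage analysis complements junction evidence: in a pooled sample a
deletion carried by a fraction of lineages appears as a run of *reduced*
(not zero) depth.  `deletion-scope` thresholds a mask-aware smoothed depth
profile at a fraction of the median (default 0.5), refines span boundaries
with a Poisson changepoint on read-start counts, and reconciles spans with
junction calls.  Intervals that must be ignored (e.g. a gene also carried
on an expression plasmid) are masked rather than zeroed.

A synthetic-data module generates the whole study regime — a reference
genome with multiple identical IS elements, planted A-EJ / IS-bounded /
blunt deletions, and pooled spliced-alignment read sets with truth tables —
so every stage is testable without downloading sequencing data.

The θ module computes, for each tracked fluorescent spot between two
trapped beads, the distance fraction θ = proj(spot − beadA) / |beadB −
beadA|, resolves the two possible tether orientations per video against a
known target position (θ vs 1 − θ, by median), and summarizes the pooled
distribution with a Pearson chi-square normality test.

## Worked example

Simulate a 50 kb genome with two IS1-like elements and one 13.1 kb
IS-bounded deletion, then run the junction stages:

```bash
deletion-scope simulate --length 50000 --n-is 2 --depth 20 --seed 11 --out-dir sim
# wrote 7376 reads, 1 planted junction(s) to sim
deletion-scope extract --bam sim/alignments.sam --out raw.tsv
# 18 raw junction(s)
deletion-scope call --junctions raw.tsv --tol 3 --flank 50 \
    --annotation sim/features.gff3 --out calls.tsv
# 1 junction call(s)
deletion-scope classify --calls calls.tsv --ref sim/reference.fasta \
    --is-annotation sim/features.gff3 --out classified.tsv
# classified 1 call(s)
cat classified.tsv
```

```
ref                   left_break  right_break  size   support  mh_left  mh_right  mh_total  mh_seq  class          element_id  end  distance
synthetic_chromosome  2535        15635        13100  18       0        0         0                 IS_ASSOCIATED  IS1_1       IRL  0
```

Reading the output: 18 junction-spanning reads support a single 13,100 bp
deletion whose left breakpoint coincides exactly (distance 0) with the
IRL boundary of element IS1_1 and which shows no breakpoint microhomology —
the IS-bounded signature.  The truth table `sim/truth.tsv` confirms the
planted event (breakpoints 2535/15635, mechanism IS_BOUNDED, 18 expected
supporting reads).

Other subcommands: `coverage` (bedGraph depth + reduced-coverage spans),
`logo` (flank position-frequency matrix with per-column information
content), `theta` (distance-fraction tracks → per-frame θ + summary JSON),
and `run` (the whole WGS pipeline from a YAML config).

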