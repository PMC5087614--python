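# Methods

This note documents the models and procedures implemented in `egakit`, the
parameters that matter, the design choices made where the design was open,
and what the synthetic-data tests do and do not demonstrate about real data.

## The analysis chain

The package targets 5′-end tag experiments (STRT/CAGE-like): each read marks
a transcription start, counts are tags per feature per well, and exogenous
RNA spike-ins of fixed concentration provide a depth estimate that is
independent of endogenous expression.  The chain is: cluster tags into
transcript far 5′-ends (TFEs) → annotate TFEs to gene models → test
differential expression between FACS-sorted GFP+ wells of an overexpressed
construct and three control sets → intersect the three call lists into a
robust target set, reduced to genes → test overlap of target sets with
embryo-activated gene sets → test promoter-motif enrichment of regulated
TFEs against non-regulated controls.

## TFE clustering and annotation

Tags on one chromosome and strand belong to the same TFE iff a chain of tags
connects them with successive gaps ≤ `max_gap` (single linkage; default
100 bp, exposed as a parameter since published pipelines defer this constant
to supplementary material).  The TFE peak is the modal tag position; ties
break toward the 5′-most position on the TFE's strand.  Annotation is by the
peak alone — 5′-tag clusters are promoter-proximal and belong to a single
region — with precedence coding-gene 5′UTR > coding exon (exonic positions
outside the 5′UTR, including the 3′UTR, fold into this class) > intron >
any part of a non-coding gene > intergenic.  Overlap is same-strand only: an
antisense tag cluster marks a novel TSS, not the opposite-strand gene.
Coordinates are 0-based half-open internally; GFF3's 1-based inclusive
convention is converted at the format boundary only.

## Differential expression

Size factors come from spike-in totals: `f_j = s_j / median(s)`, so the
median factor is 1 and a sample with zero spike counts is a hard error.
Counts are equalized by binomial down-sampling to the shallowest sample
(`Binomial(c_ij, f_min/f_j)`; a resampled count can never exceed the
observed one, unlike Poisson thinning), repeated `D = 20` times.  The
two-class statistic per TFE is the Wilcoxon rank-sum of the test class with
mid-ranks for ties, standardized by the exact tie-corrected null moments
(`Var(W) = n1·n2/(n(n−1)) · Σ(R_j − (n+1)/2)²`, which vanishes for an
all-tied row — an all-zero TFE scores 0), averaged over the D resamples.
Mid-ranks matter: tag matrices are zero-inflated and ties dominate.

Significance is a SAM-style permutation q-value.  `B = 100` label
permutations are drawn as seeded column shuffles of the sample union; the
null statistic pool uses subsets of size `min(n1, n2)`, which makes the
procedure exactly symmetric under class swap (|statistic| of a subset equals
that of its complement), so swapping labels flips directions and leaves q
unchanged.  For each observed |t| threshold,
`q_raw = median_b #{|t*_b| ≥ |t|} / #{|t| ≥ |t|}`, clipped to [0, 1] and
monotonized by a cumulative minimum from the least extreme threshold upward,
so thresholding at any q selects a contiguous top set.  A pooled permutation
p-value is reported alongside q.  Balanced permutations are not enforced:
with 3–6 wells per class they are too scarce to be useful.

A structural caveat the tests make visible: with 3-vs-3 wells the
standardized rank statistic is bounded (|t| ≤ 1.96, 20 label arrangements),
so a q below 0.1 is only reachable when almost no null feature is tie-free —
the sparse tag-data regime, where most TFEs are zero in most wells.  The
bundled power check for a single planted 8-fold TFE therefore uses a small,
heavily zero-inflated panel; recovery studies at a 2000-TFE universe use
designs with ≥ 6 test wells (see below).

## Study design defaults

The default synthetic library has 48 wells: GFP+ sorts of 75 cells in
triplicate per transfection for LEUTX_n, OTX2 and DPRX — two transfection
replicates each, i.e. 6 GFP+ wells per construct, mirroring an experiment
run as two libraries — 4×50 cells for LEUTX_R, a 3×75 mCherry fluorescent
control, per-construct GFP− triplicates and untransfected GFP− filler wells
for 23 whole-library negatives.  The three control sets per construct are
then: 3 GFP+ control wells, 6 paired GFP− wells, 23 library GFP− wells.
The 6-well test class is a deliberate design choice: a 3-vs-3 comparison
bounds the rank statistic as described above and cannot resolve q < 0.1
against a 2000-feature universe, while 6-vs-3 (84 arrangements) can.  All of
this is configurable through `ReplicateGroup` lists.

## The count simulator

Counts are gamma-Poisson: `c_ij ~ Poisson(λ)` with
`λ ~ Gamma(1/φ, μ_ij·φ)`, dispersion `φ = 0.2` by default
(`Var = μ + φμ²`), matching overdispersed tag counts.  Baseline expression
is log-normal with σ = 3 on the log scale, so most TFEs are near zero in any
well and a small head carries the library — the zero-inflation that makes
rank tests and the permutation q-value behave as they do on real tag data.
A per-sample capture efficiency (log-normal, CV 0.3) multiplies endogenous
and spike-in rows alike, so spike-ins remain informative about depth; spike
expectations are otherwise independent of the construct (verified by a
permutation test).  The spike-in mix is a fixed log-uniform ladder over ~3
decades shared by all samples, recorded in the truth object, and takes 5% of
tags; real spike chemistries differ, and the ladder is a stand-in.

Planted effects multiply `μ` by `2^lfc` in the GFP+ wells of one construct
only, with `lfc ~ N(3, 0.5)` clipped to |lfc| ≥ 2.  Planted TFEs are drawn
from features with baseline ≥ 10 tags/sample (and, when an annotation is
supplied, from coding-5′UTR TFEs): an effect planted on a never-detected
feature is unrecoverable by any method, and the target sets of interest are
genes.  Defaults plant 5% of TFEs up and 1% down per construct — at the
default 2000-TFE universe, 100 up and 20 down, the same up:down ratio as the
tens-of-thousands-TFE experiments the simulator emulates.  One seeded
generator with a documented draw order (spike ladder, baseline, capture,
planted sets, counts) makes every artifact bit-reproducible.

Embryo stage profiles cover oocyte → 4-cell → 8-cell → morula.  Activated
genes rise at the 4-cell→8-cell transition by more than `activation_fold`
(default 4×) over their oocyte level and fall at the morula; all other genes
stay flat within ±15% noise, so the activated set is exactly recoverable by
construction.  A configurable fraction (`activation_overlap`, default 0.5)
of the activated set is drawn from the planted targets of the first
construct, giving the overlap stage a known positive.

## Overlap statistics

The universe is the set of genes testable in the experiment — genes with at
least one detected coding-5′UTR TFE — supplied explicitly, never inferred:
"expected by chance" (`a·b/n`) is only meaningful against a finite tested
universe.  Association is a 1-df chi-squared on the 2×2 membership table
without continuity correction; families of (target set × dataset) tests are
Benjamini–Hochberg adjusted.  The tail probability of an observed overlap
uses `trials = |target set|` with success probability `expected/trials`
(exact binomial upper tail), or a Poisson tail when no trial count applies;
the hypergeometric tail serves as a cross-check oracle in the tests.  The
chi-squared calibration test runs in a regime (thousands-strong sets) where
the overlap count's discreteness is small against its spread; with very
small sets the 1-df approximation is visibly granular, which is why the
exact tails are the primary significance measure for small counts.

## Motif scanning

PWMs are built from IUPAC consensus strings (degeneracy codes expand to
uniform mass), site alignments, or minimal-MEME files; probabilities get an
optional pseudocount and are floored at 1e-9 before taking base-2 log-odds
against the background.  Scores are quantized to a lattice of
`granularity = 0.001` bits; the distribution of the total score of a random
background sequence is computed exactly on that lattice by positional
convolution, so the score→p-value table agrees with full enumeration to
machine precision (asserted for motif lengths ≤ 8).  The scanner works in
the same integer lattice, so table lookups are exact; `N` bases contribute
zero log-odds (background behavior).  Both strands are scanned at every
offset; a hit is any position with tail p ≤ 1e-4 (default, exposed).

Promoter windows are −2000/+500 around the TSS/TFE peak, strand-aware
(minus-strand windows are reported 5′→3′ as reverse complements) and clipped
at contig edges with a warning.  Enrichment compares equal-size window sets
(the larger set is down-sampled with a recorded seed) on the
windows-with-≥1-hit 2×2 table by chi-squared; raw hit totals and a
cumulative threshold-sweep curve are reported descriptively, because
overlapping hits are not independent counts.  The power and calibration
suites use 600 bp windows: at 2500 bp the expected ~0.5 chance hits per
window at the default threshold dominate a 0.05-vs-0.5 planting contrast,
and the property under test is sensitivity to planted signal, not background
length effects.  The 36 bp motif used in examples is a synthetic stand-in
consensus (two GGATTA paired-class homeodomain cores with degenerate
flanks); any minimal-MEME matrix can be supplied instead.

## Simulation sizes and runtime

Calibration and recovery suites use 20 independent libraries of 2000 TFEs ×
48 wells; motif calibration uses 100 simulations of 200+200 windows; the
oracle-equivalence suites use 1000-point clustering instances, 20 000-draw
Monte-Carlo overlap means, and 1000-simulation chi-squared null panels.
These sizes put the full test suite around one minute and the acceptance
script under a minute on one core, while leaving wide margins on every
threshold (e.g. recovery Jaccard ≈ 0.95 against a 0.8 bar; null call rates
< 0.1% against a 15% bar).

## What the synthetic tests do not show

The simulator emulates design structure, sparsity, overdispersion and depth
variation, but not: mapping artifacts and multi-mapping tags upstream of the
count matrix; correlated capture noise within wells; internal TSSs and
antisense transcription beyond the planted category mix; real promoter
sequence composition (windows are i.i.d. uniform ACGT, so real-genome GC and
repeat structure — notably Alu-rich regions around EGA promoters — are out
of scope); or the actual spike-in chemistry.  Passing the suites shows the
statistics are implemented correctly and calibrated under the stated model,
not that the biological conclusions of any particular experiment follow.

## Known limitations

- The DE test supports exactly two classes; paired or multi-class designs
  are out of scope.
- Gene-level reduction keeps a gene if *any* of its coding-5′UTR TFEs
  passes; alternative promoters of one gene are not distinguished.
- Direction concordance across the three comparisons is required by default
  (a set-intersection-only mode exists): a gene flipping sign between
  control sets is not treated as a coherent target.
- The exact p-value lattice bounds scores to `granularity` precision;
  1e-3 bits is far below any meaningful score difference but is not exact
  real arithmetic.
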