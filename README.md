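# egakit

Tools for nominating transcription-factor target genes in embryo genome
activation (EGA) studies from 5′-end tag sequencing (STRT/CAGE-like) data —
and for validating every step of that chain on synthetic data with known
ground truth.

Human EGA begins at the 4–8-cell stage, when paired-like (PRD-like) homeobox
factors such as LEUTX and DPRX switch on the embryo's own transcription.
The experimental readout is a tag-count experiment: hESCs overexpressing a
construct are FACS-sorted into GFP+ and GFP− wells, 5′-tag libraries with
RNA spike-ins are sequenced, and the analysis must decide which genes the
construct regulates, whether those genes are the ones activated in real
embryos, and whether their promoters share a DNA motif. `egakit`
re-implements that computational chain as a tested, reusable library:

- **TFE clustering & annotation** — tag start positions are chained into
  transcript far 5′-ends (TFEs) with a gap rule, and each TFE's modal
  position is annotated to coding-gene 5′UTR > coding exon > intron >
  non-coding gene > intergenic, same strand only.
- **Spike-in resampling differential expression** — per-sample size factors
  `f_j = s_j / median(s)` from spike-in totals `s_j` alone; counts are
  binomially down-sampled to the shallowest depth (`Binomial(c_ij, f_min/f_j)`,
  D repetitions); per TFE the standardized Wilcoxon rank-sum (mid-ranks,
  tie-corrected SD) is averaged over resamples, and significance is a
  SAM-style permutation q-value
  `q(c) = median_b #{|t*_b| ≥ c} / #{|t| ≥ c}`, monotonized.
- **Three-control target intersection** — each construct's GFP+ wells are
  tested against GFP+ fluorescent-control wells, paired GFP− wells and all
  library GFP− wells; a target must pass `q < 0.1` in all three with one
  direction, then TFE calls reduce to genes through their coding-5′UTR TFEs.
- **Overlap statistics** — expected overlap `a·b/n` in a finite tested
  universe, 1-df chi-squared association with Benjamini–Hochberg control
  across datasets, exact binomial/Poisson upper tails, 3-set Venn counts.
- **Promoter motif scanning** — strand-aware −2000/+500 windows around TSSs,
  base-2 log-odds PWM scores with an *exact* score→p-value table computed by
  dynamic programming on a quantized lattice, and enrichment of
  windows-with-hit against equal-size control sets.
- **Synthetic data with truth** — a gamma-Poisson (negative-binomial) tag
  simulator shaped like a 48-well STRT library (spike-in ladder, per-sample
  capture efficiency, planted log2 fold changes in GFP+ wells only), a toy
  genome with TFE categories known by construction, planted embryo-activated
  gene sets and planted promoter motif occurrences.

## Worked example

```python
from egakit import SimConfig, simulate_experiment, run_comparisons, \
    intersect_calls, jaccard, overlap_tail_p

matrix, sheet, truth = simulate_experiment(SimConfig(seed=1))
comparisons = run_comparisons(matrix, sheet, "LEUTX_n", seed=1)
targets = intersect_calls(comparisons, q_threshold=0.1)
print(len(targets.up_tfes), jaccard(targets.up_tfes, truth.planted_up["LEUTX_n"]))
print(overlap_tail_p(604, 257.0, trials=901))
```

prints

```
99 0.99
1.6964127310495893e-126
```

The simulated 48-well library had 100 TFEs planted as upregulated by the
LEUTX_n construct; the three-way intersection recovered 99 of them with no
false positives (Jaccard 0.99).  The second line is the exact binomial upper
tail for observing 604 overlapping genes between two 901/2090-gene target
sets when 257 are expected by chance — far below 10⁻⁶, i.e. the two factors
regulate a strongly shared gene set.

The `examples/` directory has one short narrative script per capability
(simulation, clustering/annotation, DE, intersection, overlap statistics,
motif enrichment, full pipeline); each prints the numbers it computes and
what they mean.  `run_pipeline(RunConfig(...), out_dir)` chains all stages
and writes TSV/JSON tables plus a manifest sufficient to re-run
byte-identically.

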