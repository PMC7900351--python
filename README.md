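# linamp

Simulation and benchmarking of **targeted single-primer linear amplification**
versus **exponential (two-primer PCR) amplification** in droplet scRNA-seq
library preparation.

Droplet single-cell experiments waste most of their read budget: exponential
PCR amplifies efficiently-replicated transcripts geometrically, so the fixed
NGS read space (~10⁴–10⁶ reads/cell) is spent re-reading amplified copies of
abundant molecules while low-copy transcripts drop out.  A targeted
alternative replaces the template-switching oligo with *hybrid primers* — a
14–18 nt gene-specific sequence fused to a universal 14 nt handle — and
amplifies 500–1,000 nt stretches of a chosen gene panel *linearly*: only the
original bead-bound template is primed each cycle and products are never
re-copied.  This package provides a mechanistic simulator of both chemistries
and the statistics used to compare them, for method developers and analysts
who want to size panels, read budgets and detection thresholds before (or
instead of) a sequencing run.

## The model

Per cell and gene, true molecule counts are negative binomial with mean μ_g
(abundance tiers high/medium/low, plus an *absent* tier for negative-control
targets) and dispersion θ; condition effects act multiplicatively on μ_g.
Each molecule is captured with probability *c*, receiving its cell barcode and
a uniform random UMI.  Amplification then follows one of two regimes:

* **exponential** — copies evolve as a Galton–Watson branching process,
  `copies ← copies + Binomial(copies, e_g)` per cycle with per-gene efficiency
  e_g, giving mean (1+e_g)ⁿ after n cycles.  Efficiency differences compound
  geometrically: this copy-number skew is the mechanism of amplification bias.
* **linear** — each panel molecule's template is primed once per cycle with
  probability p, so its sequenceable (handle-bearing) copies are exactly
  Binomial(n, p); the template itself is never sequenced, and off-panel
  molecules leak in with a small per-cycle off-target probability.

Sequencing draws a fixed per-cell read budget with probability proportional to
eligible copy numbers.  Downstream statistics are the standard droplet QC
vocabulary: UMI deduplication (distinct cell×UMI×gene triples), per-cell
**duplication rate** (gene-assigned reads / distinct UMIs), per-gene dropout
fractions and detection at a dropout cut-off, exact per-cell read
downsampling for depth titrations, on-target read fraction, per-gene
sensitivity folds between libraries, and pseudo-bulk **CPTT**
(counts-per-ten-thousand) log2 fold-change concordance between methods
(Pearson r and OLS slope).  A panel-design module screens hybrid primers
(Wallace-rule Tm, GC windows, amplicon geometry, cross-dimer scores) and
enforces the 300-target single-reaction capacity.

## Worked example

`examples/02_sparsity_benchmark.py` runs one shared ground truth (52-gene
panel, 3 negative controls, background transcriptome, 50 cells) through both
regimes at a matched 8k reads/cell budget:

```
      linear: on-target 96.5%, median dup rate 3.84, median UMIs/cell 2084, 49/49 panel genes detected
 exponential: on-target 26.1%, median dup rate 1.80, median UMIs/cell 4448, 49/49 panel genes detected
sensitivity fold (geometric mean over panel): 1.73x

detection vs depth (50% dropout cut-off):
     regime  depth  n_detected  n_negative_controls_detected
     linear   2000          49                             0
     linear   4000          49                             0
     linear   8000          49                             0
exponential   2000          44                             0
exponential   4000          49                             0
exponential   8000          49                             0
```

The targeted library puts ~97% of its reads on panel genes, so every panel
gene clears the 50% dropout cut-off even at 2k reads/cell, while the standard
library needs 4k+; its per-gene panel counts run 1.7× higher at matched
depth; and the absent-tier negative controls are never called detected.  The
other examples cover deduplication on a single simulated library, the
two-condition fold-change concordance, and primer panel design.

A thin CLI mirrors the pipeline: `linamp simulate|benchmark|concordance|design-panel|demo`.

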