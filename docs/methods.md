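# Methods

## Scope

`linamp` is a desk-scale, mechanistic model of droplet scRNA-seq library
preparation under two amplification chemistries, plus the benchmarking
statistics used to compare them.  It emulates the *statistical* structure of
a targeted-panel experiment — abundance tiers, negative-binomial cell-to-cell
noise, Bernoulli bead capture, branching-process PCR, fixed read budgets —
not the wet-lab chemistry (no fragmentation, size selection,
template-switching, base-called sequences, or sequencing errors).  Reads are
emitted already gene-assigned; alignment is out of scope.

## Ground truth

Genes belong to abundance tiers.  Tier membership is apportioned by largest
remainder in the fixed order high → medium → low → absent, so tier counts are
exact and testable rather than multinomial.  Within a tier, per-gene means
are log-normal around the tier mean with σ = 0.5 and a mean-preserving
correction; the *absent* tier is identically zero and models negative-control
targets (panel entries whose transcript is not present in the sample, so any
signal on them measures off-target priming).

Per-cell counts for gene g in condition k are negative binomial with mean
μ_g·m_{g,k} and dispersion θ (variance μ + μ²/θ); θ = ∞ switches to Poisson.
NB is the standard droplet-data noise assumption and gives closed-form
moments the tests verify at 10,000 cells.  Condition effects m_{g,k} are
multiplicative on the mean, matching a fold-change readout; the reference
condition is all ones.

Capture is a per-molecule Bernoulli(c) event (probe-excess beads: losses are
independent per molecule).  Captured molecules get their cell's unique
barcode (base-4 expansion of the cell index; barcode collisions are not
modelled) and a UMI drawn uniformly from 4^L sequences.  UMI collisions are
allowed and never corrected.

Default conventions (the literature states no per-tier abundances; these were
fixed once as plausible PBMC-like values and are config fields, not code
constants): tier means 1000/300/80 true molecules per cell, θ = 2, c = 0.1,
L = 8, barcode length 12.  The default panel is 52 genes (20%/30%/50% tier
split) including 3 absent-tier negative controls, over a 1,000-gene
background transcriptome (5%/25%/70%) that stands in for the rest of the
cell's cDNA — about 18k captured background molecules per cell against ~1.6k
panel molecules, i.e. the panel is ~8% of captured cDNA.  Real panels are a
smaller fraction of a real transcriptome; the simulations therefore support
*direction* claims (orderings, monotonicity, recovery), not the magnitudes a
full-size experiment would produce.

## Amplification

**Exponential (two-primer PCR).**  Every copy is a template:
`copies ← copies + Binomial(copies, e_g)` per cycle, a Galton–Watson process
with mean (1+e_g)^n and copies ≥ 1 always.  Per-gene efficiencies e_g ~
Uniform(0.7, 0.95) are the sole driver of bias — no per-molecule GC/length
effects.  All copies are sequencing-eligible.  Two sources of copy-number
skew emerge: efficiency spread across genes (compounding to ~5× over 12
cycles) and the heavy left tail of the branching process within a gene
(molecules whose early cycles failed).

**Linear (single hybrid primer).**  Only the original bead-bound template is
primed, once per cycle with probability p, so a panel molecule's
handle-bearing copies are exactly Binomial(n, p) — arithmetic growth with
binomial dispersion.  The template record stays in the pool but is not
sequencing-eligible (it lacks the library adapter); only handle-bearing
copies can be read.  Non-panel molecules are primed with a single per-cycle
off-target probability (default 0.01), identical across genes — no sequence
mechanism is modelled.  Defaults: 12 cycles, p = 0.8 in both regimes.

**Sequencing.**  Per cell, the read budget is drawn with replacement,
proportional to eligible copy numbers (post-amplification copies dwarf read
depth; without-replacement sampling is available for degenerate pools).
Cells with no eligible material yield zero reads and are flagged.

## Benchmark statistics

* **Deduplication**: count of gene g in cell c = distinct (c, g, UMI)
  triples, computed by integer key encoding; an independent set-based tally
  is the test oracle.
* **Duplication rate**: gene-assigned reads / distinct UMIs per cell (all
  simulated reads are gene-assigned; a mapped-read denominator does not
  arise here).  Undefined (NaN) for zero-UMI cells.  The identity
  rate × UMIs = reads holds exactly.
* **Detection**: a gene is detected iff its dropout fraction (share of cells
  with zero count) is ≤ the cut-off — the boundary is inclusive, reading
  "detected in half the beads" as ≥ 50%.  Default cut-off 0.5.
* **Depth ladders** use exact per-cell thinning without replacement, and the
  pipeline nests them (each depth is a subsample of the depth above, as in a
  real titration of one library), which makes detection-vs-depth monotone
  per simulation rather than only in expectation.
* **Sensitivity fold**: per-gene mean-count ratio with ε = 0; genes absent
  from both libraries are undefined, zero-denominator genes are flagged out,
  and the summary is the geometric mean over genes expressed somewhere with
  a finite positive fold.
* **Cell QC**: keep cells with ≥ 200 UMIs and ≥ 3 detected genes — invented
  conventions sized for targeted panels.
* **Concordance**: pseudo-bulk per (gene, condition) by exact integer sums;
  CPTT normalisation per column (or per cell on a matrix); log2 fold changes
  with pseudocount 1; Pearson r with two-sided p; slope/intercept by OLS of
  targeted on standard, with reduced-major-axis regression as an option for
  symmetric-noise readings.

## The two headline experiments

**Sparsity benchmark** — one shared ground truth through both regimes at a
matched budget (default 15k reads/cell, ladder 2k/4k/8k/15k, 200 cells).
The duplication-rate ordering is evaluated on *matched eligible pools*
(panel-only ground truth, both chemistries amplifying the same molecules, 12k
reads/cell): that isolates copy-number skew, the mechanism that makes the
exponential library spend more reads per molecule.  With a background
transcriptome present, the exponential library instead spreads reads over
the whole transcriptome — there the informative contrasts are the on-target
fraction, panel UMI yield, sensitivity folds, and detection across depths.

**Stimulation concordance** — two conditions, 20 panel genes with declared
log2 effects in {−2, −1, 0, 1, 2}, 500 cells/condition, 20k reads/cell in
both regimes (matched depth).  The effect assignment is compositionally
balanced (Σ fold multipliers ≈ n genes): within a closed library,
normalisation only identifies relative changes, so an unbalanced design
would shift every null gene's apparent fold change by the panel-wide total;
the balanced default keeps that common-mode shift near zero (residual ~0.05
log2 units in expectation, plus a small contribution from the log-normal
spread of realised gene means).

## Determinism and numerics

Every stage seed is derived from one master seed via
`SeedSequence([seed, crc32(stage label)])`, so configs are bit-reproducible
and adding stages never reshuffles existing ones.  Dedup keys require
cells × genes × 4^L < 2⁶², which bounds the UMI length at the defaults.
Weighted read sampling uses inverse-CDF search on the per-cell copy CDF.
Matrix-Market output is written genes-as-rows, 1-based (the droplet
exchange convention); all writers round-trip bit-exactly and are covered by
identity tests.

## Limitations

No ambient RNA, doublets, barcode swapping, UMI sequencing errors, PCR
errors, or chimeric products; duplication is purely re-sampling of true
copies, so real duplication rates would be slightly inflated relative to the
model.  Off-target priming is gene-uniform.  Clustering/embedding claims of
targeted assays are out of scope; the package reproduces marker-level
detection inputs only.  Problem sizes (200 cells for the benchmark, 24–30
cells per replicate in the 100-seed ordering experiments, 1,000-gene
background) were chosen as the package's standard desk-scale conditions;
conclusions are orderings and recoveries, which were verified stable across
100 seeded replicates, not absolute instrument-scale magnitudes.
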