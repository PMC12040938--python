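# Methods

## Scope and data model

`regmap` annotates regulatory elements in a multi-tissue epigenome given
binned read counts per tissue × replicate × mark, a gene annotation with
TSSs, TAD intervals, sequences for motif scanning, and a gene→term map.
Upstream read processing (trimming, alignment, duplicate removal, peak
calling) and TAD calling are out of scope: counts and TADs are inputs.
The bundled generator produces all inputs synthetically with known ground
truth, which is how the package tests itself.

## Signal stage

Reads are assigned to fixed-width bins by midpoint (200 bp default for
segmentation; QC runs at 1 kb). Z-scoring uses the population-SD
convention (`scipy.stats.zscore` default); a zero-variance track maps to
zeros. QC is pairwise Pearson correlation of z-scored pooled tracks plus
PCA over samples.

Binarization is per tissue × mark with a single genome-wide background:
λ̂ = mean pooled count per bin over all chromosomes (replicates pooled by
per-bin summation first), and the call threshold is the smallest integer
c ≥ 1 with P(X ≥ c | Poisson(λ̂)) ≤ p, p = 10⁻⁴ by default (exposed as a
flag). An all-zero track yields all-zero calls with a logged warning.
Note λ̂ is intentionally a *global* mean: enriched bins inflate it, so the
threshold self-tightens on marks with broad enrichment; this mirrors
standard practice and is part of why the generator keeps per-mark genome
coverage realistic (below).

## Hidden Markov model

Multivariate Bernoulli emissions over M marks, conditional independence
given the state. Implementation choices:

- Scaled forward–backward (per-bin normalisation constants) rather than
  log-space recursions so E-step weights are reused directly; safe from
  underflow for sequences up to ~10⁷ bins.
- Emissions floored to [10⁻⁶, 1−10⁻⁶] after every M-step so likelihoods
  stay finite for degenerate data.
- One model is learned jointly over all tissues and chromosomes (each an
  independent sequence sharing parameters), giving a shared state
  vocabulary across tissues; per-tissue learning is available behind a
  flag (`per_tissue_models`).
- Convergence: |Δ total log-likelihood| < 10⁻⁴, max 200 iterations; hitting
  the cap flags the model (`converged=False`) rather than raising, and the
  per-iteration trace is returned (non-decreasing up to 10⁻⁸ slack).
- Initialisation: perturbed-uniform transitions; emissions from a random
  K-way partition of the observed bins *plus* a uniform ±0.4 perturbation.
  The perturbation matters: with realistic bin counts the partition means
  all collapse onto the marginal mark frequencies, and EM started from
  that symmetric point reliably lands in poor optima (e.g. splitting the
  quiescent state instead of isolating a rare enhancer state).
- Restarts: best log-likelihood of 3 seeded restarts (seed + restart index).
- Viterbi ties break toward the lower state index; near-ties within 10⁻⁹
  in log probability are treated as ties so that exactly symmetric models
  decode deterministically instead of following one-ulp rounding noise.
- Decoding also supports per-bin posterior argmax (`method="posterior"`).

The default *learned* state count (8) deliberately exceeds the generator's
5 true emission patterns. With K equal to the true count, EM has no slack:
the rare planted-enhancer pattern (≈1.5% of bins) is cheaper to merge into
the nearest baseline state than the symmetric alternative of splitting a
large state, and recovery fails. Over-parameterization — standard in
chromatin-state practice, where 15 states are routinely fit over 5 marks —
gives every frequent pattern its own state and lets duplicates share a
name downstream. Model selection across K is intentionally out of scope.

## State naming

Names come from the 15-label vocabulary mapped to six fixed categories
(promoter, TSS-proximal transcription, enhancer, ATAC island, repressive,
quiescent). Naming is a first-match cascade over binarized emission levels
(high = E ≥ 0.5) and TSS fold enrichment (enriched = fold ≥ 2), shipped as
a versioned, editable TSV rule table; a trailing catch-all makes naming a
total function, and several learned states may share a name. TSS fold for
state k is (fraction of state-k bases within ±2 kb of a TSS) / (fraction
of the genome within ±2 kb of a TSS), with windows clipped at chromosome
ends and merged across overlapping genes; an absent state gets fold 0.

Thresholds (0.5 emission cut, fold ≥ 2, ±2 kb window) are package choices
— published analyses rarely state theirs — and are all overridable. The
weak-repressive split is relative: a state whose marks are all below the
cut but whose H3K27me3 emission reaches half the strongest H3K27me3
emission across states is ReprWk. (A split of the form "Repr but with
emission below half the max" is unsatisfiable when the Repr rule itself
requires emission ≥ 0.5, since half the max never exceeds 0.5; the
relative rule used here is the reachable variant of that idea.)

Summaries report, per state and per category: element count (intervals,
additive over tissues), mean element size both pooled and tissue-averaged
(published tables do not always say which; we report both), genome
coverage (computed per tissue, then averaged — per tissue these sum to 1
exactly), the "regulatory element" total (all non-quiescent intervals,
summed over tissues), and NRRET, the non-redundant total after merging
each state's intervals across tissues. Merging follows BED semantics with
book-ended (distance-0) intervals merged; the merge is idempotent.

## Tissue-specific modules and target genes

RRAT regions are the merged union (book-ended merge included) of all
tissues' EnhA intervals; the matrix entry for (region, tissue) is 1 iff
≥1 bp of that tissue's EnhA overlaps the region, so no row is all-zero.
Classification is an exhaustive, exclusive pattern rule: exactly one 1 →
that tissue's specific module; exactly the three uterine tissues →
uterine-common; anything else → unassigned (never forced). Region→TAD
assignment uses the region midpoint (unique even when a region straddles a
boundary), gene→TAD the TSS point; TADs must be non-overlapping (validated,
offending pair reported). A region is linked to every gene whose TSS
shares its TAD; regions outside all TADs are flagged with an empty target
set. The module report ranks each target gene's expression across tissues
and marks whether the top tissue matches the module.

## Enrichment

Motif scanning is explicit PWM log₂-odds against a background base
composition, probabilities floored at 10⁻³ before log-odds; a window is a
hit when its score reaches `score_fraction` (default 0.8) of the maximum
attainable score; both strands are scanned (reverse-complemented matrix)
with coordinates reported on the forward strand; windows containing N are
skipped. This is a statistics-transparent analog of the usual motif
tools, not a clone: the motif library and background sequences are
explicit inputs, and the counting unit is per-sequence presence/absence.

The test is the one-sided hypergeometric upper tail of foreground presence
given pooled foreground+background presence; term enrichment is the same
test over a gene universe and gene→term map (terms unannotated in the
universe are skipped). BH adjustment (statsmodels step-up) is applied
within each test family (per module), results are ranked by ascending p
with lexicographic tie-break, and the significant top-5 are reported.

## Synthetic data generator

The generator emulates a five-reproductive-tissue design: 5 tissues × 2
replicates × (4 histone marks + ATAC) count tracks plus an expression
table — with RNA counted as the sixth assay, 60 libraries. Defaults are
scaled to desk size: 2 chromosomes × 1 Mb, 200 bp bins.

- **Truth model.** Five emission patterns over the five marks (Qui, TssA,
  EnhA, Repr, EnhAHet) with probabilities in {0.05, 0.95}, every pair
  differing in ≥2 marks. The baseline Markov chain moves only through
  {Qui, Repr, EnhAHet} (Qui self-transition 0.99, others 0.92), so each
  active baseline state covers ~6% of the genome — keeping the genome-wide
  Poisson background near the true background rate.
- **Planted truth.** TssA blocks (5 bins) sit at every gene TSS in all
  tissues; EnhA blocks (10 bins) exist *only* where planted: 12 per tissue
  in exactly that tissue, plus 6 uterine-common blocks in exactly the
  three uterine tissues. Blocks sit strictly inside a TAD containing ≥1
  gene TSS, never overlap each other (≥5-bin gap), and each designates a
  target gene in its TAD (a gene serves at most one module). Zero baseline
  EnhA entry probability is deliberate: chance enhancer segments in other
  tissues would otherwise contaminate the overlap pattern of planted
  blocks and make module ground truth ambiguous.
- **Counts.** Per bin: mark presence ~ Bernoulli(E[state, mark]), then
  count ~ Poisson(6.0) if present else Poisson(0.25) per replicate
  (pooled ≈ 12 vs 0.5, a clean-peak regime ~24× background chosen so
  enriched bins clear the signal-inflated global threshold with call
  probability ≈ 0.75).
- **Expression.** Baseline 10 with log-normal noise (σ = 0.2 on the log
  scale); a planted target gene is multiplied by 8 in its module
  tissue(s).
- **Sequences.** I.i.d. uniform ACGT; the module PWM consensus is inserted
  at a random offset/strand in 90% of a module's regions when the
  enrichment stage simulates sequences; background regions get none.
- **Determinism.** Every operation derives its RNG from (config seed,
  fixed per-operation tag); identical configs give byte-identical outputs.

What the generator does *not* emulate — GC bias and mappability, read-level
artifacts, replicate batch effects, gapped/nested TADs (tiling is
contiguous), distance-dependent enhancer–promoter choice beyond TAD
co-membership, and correlated mark noise — bounds what passing tests show:
they validate the statistical machinery and the pipeline's bookkeeping on
clean, well-specified signal, not robustness to real-data artifacts.

## Numerical and edge-case contracts

- Binarization: non-negative integer counts enforced; λ̂ = 0 → all-zero
  calls + warning; threshold always ≥ 1; calls monotone in counts.
- Correlation matrices are symmetrized, clipped to [−1, 1], unit diagonal.
- Hypergeometric inputs validated (0 ≤ hits ≤ totals); BH inputs must lie
  in [0, 1]; q ≥ p elementwise by construction.
- Degenerate inputs: empty observation → empty path; sequence shorter than
  motif → no hits; motif wider than all sequences → zero hits, p = 1;
  empty target gene set → empty enrichment result.
- Pipeline stage failure aborts with the stage name and leaves a
  `FAILED.<stage>` marker beside any partial outputs; re-runs with the
  same config produce identical file checksums.

## Problem sizes used in the shipped experiments

End-to-end validation runs the full default genome (10⁴ bins × 5 tissues,
66 planted blocks). Parameter recovery uses 20 sequences × 10⁴ bins
(2×10⁵ bins total) from the well-separated 5-state truth. Oracle checks
enumerate all paths for instances with ≤8 bins, ≤3 states, ≤3 marks. Null
calibration of the enrichment test uses 2,000 simulated tests at 5,000
foreground / 20,000 background sequences with shared presence rate 0.5 —
counts large enough that the exact test's discreteness is negligible
against the nominal 0.05 level. Power uses 100 seeds at 50 foreground /
500 background 1 kb sequences with 90% planting. These sizes are the
package's validation conditions; all are configurable.
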