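# regmap

Chromatin-state segmentation and tissue-specific enhancer-module annotation
for multi-tissue epigenomes.

Functional annotation studies of reproductive tissues (ovary, oviduct, and
the three uterine compartments: cervix, cornua uteri, corpus uteri) profile
histone modifications (H3K4me3, H3K4me1, H3K27ac, H3K27me3 by CUT&Tag),
chromatin accessibility (ATAC-seq), and expression (RNA-seq), then ask
three questions: *what chromatin state is each genomic segment in*, *which
strong enhancers are specific to which tissue*, and *which genes do those
enhancers regulate*. `regmap` implements that analysis chain as a tested,
reusable library with a seeded synthetic-data generator, so every stage can
be validated against planted ground truth without any sequencing data.

## The model

**Binarization.** Per tissue and mark, replicate read counts in fixed
200 bp bins are pooled and compared against a genome-wide Poisson
background: with λ̂ the mean count per bin, a bin is called present when
its count reaches the smallest integer *c* with
P(X ≥ c | Poisson(λ̂)) ≤ 10⁻⁴.

**Segmentation.** The binary calls feed a multivariate hidden Markov model
with Bernoulli emissions: state *k* emits mark *m* with probability
E[k,m], marks conditionally independent given the state, so a bin's
emission likelihood is ∏ₘ E[k,m]^x (1−E[k,m])^(1−x). One model is learned
jointly across tissues and chromosomes by Baum–Welch (scaled
forward–backward, best of 3 random restarts), then each tissue is decoded
by Viterbi. States are named with the standard 15-label vocabulary (TssA …
Qui, six functional categories) through a versioned rule cascade over
emission levels and TSS-neighbourhood fold enrichment.

**Modules.** Strong-active-enhancer (EnhA) intervals from all tissues are
union-merged into RRAT regions ("regulatory regions across tissues"); each
region gets a 0/1 per tissue by ≥1 bp overlap. Single-tissue rows form the
five tissue-specific modules, the exact cervix+cornua+corpus pattern the
uterine-common module, everything else is left unassigned. Regions are
linked to target genes by shared-TAD co-membership and tested for motif
(PWM log-odds scanning, per-sequence presence) and term over-representation
with exact hypergeometric upper-tail p-values and Benjamini–Hochberg FDR.

## Worked example

```sh
regmap run --seed 1 --outdir demo
```

simulates the default five-tissue epigenome (2 × 1 Mb chromosomes, 2
replicates, 5 marks, 66 planted enhancer blocks), runs every stage, and
prints `demo/report.txt`:

```
model: loglik=-35424.82 iters=99 converged=True

per-state summary:
  E1  Qui       n=765    mean=10933.3  cov=0.8364
  E2  Repr      n=183    mean=2525.7   cov=0.0462
  E3  EnhA      n=79     mean=711.4    cov=0.0056
  E4  TssA      n=386    mean=403.1    cov=0.0156
  E5  TssA      n=386    mean=595.9    cov=0.0230
  E6  EnhAHet   n=265    mean=2386.4   cov=0.0632
  E7  EnhA      n=79     mean=607.6    cov=0.0048
  E8  EnhA      n=79     mean=653.2    cov=0.0052
regulatory elements (non-Qui, summed over tissues): 1457

module counts:
  ovary_specific              12
  oviduct_specific            12
  cervix_specific             12
  cornua_uteri_specific       12
  corpus_uteri_specific       13
  uterine_common              6
  unassigned                  0
five-module tissue-specific sum: 61

planted recovery: 66/66 (100.0%), uterine-as-single=0
```

Reading this: the learned model (8 states, deliberately over-parameterized)
found the quiescent background, polycomb-repressed domains, promoters
(TssA — two sub-states sharing the name, which the naming contract
expects), and the enhancer flavours; the three EnhA-named states jointly
carry the planted strong enhancers (~1.6% genome coverage). All 66 planted
blocks were recovered in their intended module, and none of the
uterine-common blocks leaked into a single-tissue module. Motif and
term tables (`motifs_<module>.tsv`, `terms_<module>.tsv`) rank each
module's planted motif first at q < 0.05.

The same stages are available individually (`regmap simulate|binarize|
learn|decode|annotate|tsr|enrich`) and as library calls
(`regmap.signal.binarize_poisson`, `regmap.hmm.learn_model`,
`regmap.tsr.build_rrat`, `regmap.enrichment.motif_enrichment`, ...).

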