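# triohet

Trio RNA-seq heterosis analysis: given a gene-level count matrix for two
inbred parents and their F1 hybrid, `triohet` performs pairwise
differential expression, classifies every differentially expressed gene
(DEG) into one of twelve inheritance patterns — additive, dominant, or
over-dominant — computes heterosis indices at the phenotype and expression
level, and tests annotation terms for hypergeometric over-representation.
A seed-deterministic synthetic trio generator with planted ground truth
makes every stage testable without sequencing data.

## Who it is for

Plant (and animal) geneticists studying hybrid vigor with a replicated
trio design: female parent F, male parent M, and their hybrid H, each
profiled with bulk RNA-seq. The motivating use case is dissecting trait
heterosis (e.g. leaf potassium content in tobacco) by asking whether the
hybrid's transcriptome behaves additively or non-additively.

## The statistics

**Heterosis indices.** With parent values P_f, P_m, high parent
HP = max(P_f, P_m), low parent LP = min(P_f, P_m) and mid-parent
MP = (P_f + P_m)/2:

    OPH% = (F1 − HP)/HP × 100
    MPH% = (F1 − MP)/MP × 100
    BPH% = (F1 − LP)/LP × 100

Per gene, expression heterosis uses genotype-mean FPKM:
FC = F1/MP and H% = (FC − 1) × 100.

**Differential expression.** Counts are normalized with median-of-ratios
size factors; each gene is modeled as negative binomial with variance
μ + dμ². The Wald statistic on log group means (method-of-moments
dispersion, Student-t reference with n_a + n_b − 2 df) gives a two-sided
p; DEGs are called at p < 0.05 and fold change > 2 or < 0.5.

**Inheritance patterns.** The three contrasts H vs F, H vs M and F vs M
give each gene a trio of significant-direction signs that maps onto
patterns P1–P12: P1–P2 additive (hybrid between the parents), P3–P6
dominant (hybrid indistinguishable from one parent while the parents
differ; paternal P3–P4, maternal P5–P6), P7–P12 over-dominant (hybrid
below both parents, P7–P9, or above both, P10–P12). Genes with no
significant differences are conserved; sign trios matching no pattern are
ambiguous.

**Enrichment.** A term with M annotated genes in a background of N, hit k
times in a study list of n genes, scores p = P(X ≥ k) with
X ~ Hypergeometric(N, M, n); q-values are Benjamini–Hochberg.

## Worked example

`python examples/run_full_pipeline.py` simulates the pinned 500-gene trio
(3 replicates per genotype, NB dispersion 0.05, planted inheritance
patterns) and runs the whole analysis:

```
DEG counts per contrast (up / down):
  H_vs_F: 88 up, 71 down of 500 tested
  H_vs_M: 87 up, 70 down of 500 tested
  F_vs_M: 90 up, 76 down of 500 tested

Inheritance-category proportions of classified DEGs:
  additive: 9.60%
  over_dominant: 49.49%
  dominant: 40.91%

Terms enriched at q < 0.05 per category: {"additive": 0, "dominant": 0, "over_dominant": 1}
```

The proportions are shares of classified DEGs; this fixture plants
10/40/50% additive/dominant/over-dominant genes among its pattern genes,
and the pipeline recovers those shares. The one enriched term is the
annotation term planted inside the above-high-parent genes.

Other examples: `phenotype_heterosis.py` (K+ content and OPH/MPH/BPH),
`expression_heterosis_table.py` (FC and H% on the built-in published gene
table), `term_enrichment.py`, `qpcr_relative_expression.py` (2^−ΔΔCt).

A thin CLI wraps the same library calls:

```sh
triohet simulate -o data/            # pinned synthetic trio
triohet run -c config.yaml           # full pipeline from a YAML config
triohet classify --de-dir results/ -o patterns.tsv
triohet enrich --study s.txt --background b.txt --annotation a.gmt -o enr.tsv
```

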