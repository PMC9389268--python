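# Methods

## The analysis model

The pipeline targets a replicated trio design: two inbred parents (female
F, male M) and their F1 hybrid H, each with ≥ 2 (typically 3) bulk RNA-seq
libraries summarized to gene-level fragment counts. All inference is
per-gene and pairwise between genotype groups; no multi-factor or batch
structure is modeled.

### Normalization and FPKM

Size factors use the median-of-ratios estimator: restrict to genes with
nonzero counts in every sample, divide each gene's counts by its
geometric mean across samples, take the per-sample median of those
ratios, and rescale so the factors have geometric mean 1. This estimator
assumes the majority of genes are not differentially expressed between
samples — the same assumption every compositional normalization makes —
and it is the reason the synthetic recovery conditions keep a conserved
majority background (see below).

FPKM is computed as counts × 10⁹ / (total × length_bp), with the
per-sample total defaulting to the column sum of the count matrix (an
explicit override accepts externally determined totals of mapped
fragments). Effective length is the annotated gene length; no
fragment-length correction is applied because counts arrive pre-aggregated
per gene. A conservation identity — Σ_g FPKM·(length/10³)·(total/10⁶)
equals the column count sum — holds to floating-point precision and is
tested.

Gene "presence" filtering keeps a gene when its mean FPKM within a
genotype exceeds a threshold (default 0) in all genotypes (configurable to
any genotype and any threshold). The all-genotypes/zero-threshold default
mirrors the common "identified in all three genotypes" bookkeeping of trio
studies.

### Differential expression

Default method `nb_wald`: per gene, counts normalized by the size factors
are modeled as negative binomial with variance μ + dμ². The dispersion d
is estimated by method of moments, pooling the within-group variance of
the two contrasted groups, and floored at 1e-8. The Wald statistic
compares log group means with the delta-method standard error
se² = Σ_groups (1/n_g)(1/(mean_g + ½) + d). The statistic is referred to a
Student-t distribution with n_a + n_b − 2 degrees of freedom rather than a
normal: with 3 replicates per group the plug-in moment dispersion is noisy
enough that a normal reference roughly doubles the nominal type-I error
(measured ≈ 0.11 at nominal 0.05 in a 20,000-gene NB null), while the
pooled-df t reference keeps it at ≈ 0.03–0.04. This is a deliberate
small-sample calibration choice.

The simpler `welch_log` alternative runs Welch's t-test on
log2(normalized count + 1); zero-variance genes get p = 1.

log2 fold changes use a pseudocount of 1 on normalized means,
log2((m_b + 1)/(m_a + 1)), making the statistic exactly antisymmetric
under group swap. DEG calls follow the fold-change-AND-p rule: up when
p < 0.05 and FC > 2, down when p < 0.05 and FC < 0.5, else ns. Raw p is
thresholded by default (BH q available by flag; BH q-values are always
reported). Genes with zero counts in every sample of both groups are
excluded from testing and reported as untested.

### Inheritance-pattern classification

Each gene's three contrasts (H vs F, H vs M, F vs M) yield a sign trio
over {+, −, 0} ("+" = first member significantly higher, 0 = not
significant). Thirteen of the 27 possible trios carry a label — the twelve
patterns P1–P12 plus the all-zero "conserved" trio — and the remaining 14
(e.g. parents differ while the hybrid differs from neither) are
"ambiguous". The mapping is listed in `triohet.patterns.PATTERN_TABLE`;
within each dominant pair the lower index is the hybrid-equals-higher-
parent case, and within each over/under-dominant triple the middle index
is the equal-parents case — a documented labeling convention. Category
aggregation (additive P1–P2, paternal/maternal dominant P3–P4/P5–P6,
below-low P7–P9, above-high P10–P12; dominant = P3–P6 and over-dominant =
P7–P12 in the three-way grouping) is invariant to within-category
renumbering, and all recovery checks operate at category level.

Classification is driven by significance calls, not raw means: a gene
numerically between its parents but significantly different from neither
is conserved, not additive. The classified universe defaults to the union
of DEGs across the three contrasts, matching how trio studies report
pattern proportions as shares of DEGs.

Parent relabeling (F ↔ M) acts on sign trios as
(s_HF, s_HM, s_FM) → (s_HM, s_HF, −s_FM) and induces the pattern
permutation P1↔P2, P3↔P6, P4↔P5, P7↔P9, P10↔P12 with P8 and P11 fixed;
this symmetry is property-tested over all 27 trios.

### Heterosis metrics

OPH/MPH/BPH are percent deviations of the hybrid value from the high-,
mid- and low-parent references; for positive values with distinct parents
OPH < MPH < BPH always. Per-gene expression heterosis uses genotype-mean
FPKM, FC = F1/MP and H% = (FC − 1)·100 — an exact identity at full
precision. The built-in published gene table stores 2-decimal printed
values; recomputing FC from the printed F1 and MP columns reproduces the
printed FC after rounding on high-expression rows, while H% recomputed
from printed inputs carries an input-rounding residual that stays below 1
percentage point whenever MP ≥ 1 (at MP near 0.1 the residual can reach
~14 points, which is why low-MP rows are not used for exact checks).

K+ content converts a flame-photometry concentration C (ppm) in V mL of
extract from G g of dry sample as K+% = C·V/(G·10⁶)·100. Relative qPCR
expression is 2^−ΔΔCt with ΔΔCt = (Ct_target − Ct_ref)_sample −
(Ct_target − Ct_ref)_calibrator.

### Enrichment

Upper-tail hypergeometric over-representation with BH correction across
reported terms, deterministic (p, term_id) ordering, and a background
defaulting to expressed genes intersected with the annotation universe.
Terms are flat gene sets; no ontology-graph propagation is performed, so
results are independent of any ontology release.

## The synthetic generator

`simulate_trio` emulates the study design: per-gene baseline means are
log-normal (default log2 mean 6, sd 1.5 — FPKM-scale bulk expression),
counts are NB with variance μ + dμ² (d = 0.05 by default, the scale of a
well-replicated inbred experiment), library sizes are log-uniform in
(0.7, 1.4) and fixed per sample, and gene lengths are uniform in 0.5–5 kb.
Planted patterns set the (μ_F, μ_H, μ_M) triple from the pattern's sign
structure with adjacent distinct levels separated by 2^effect_size
(default effect 2, i.e. 4-fold), the hybrid one level beyond the extreme
parent for over/under-dominance, and parents equal for P8/P11. The truth
table ships with every simulation, and identical config + seed reproduces
every output byte for byte (single integer RNG stream, no parallelism).

Pattern-recovery conditions plant the 60/30/10
over-dominant/dominant/additive split *among pattern genes* inside a 70%
conserved background ({conserved 0.70, P10 0.18, P3 0.09, P1 0.03}). The
conserved majority is not cosmetic: real trio studies find a few percent
of genes differentially expressed, and median-of-ratios normalization is
only identifiable when most genes are unchanged. Planting 60% of *all*
genes with a shared 4-fold shift makes the library size and the signal
mathematically confounded — no within-data normalization (including the
one DESeq2 uses) can separate them — so that configuration is not a valid
test of anything downstream of normalization.

What the generator does not emulate: GC/length biases in counting,
correlated genes, outlier samples, isoform switching, and
partial-dominance levels between the planted grid points. Passing recovery
tests therefore show the pipeline's correctness under its own model
assumptions, not robustness to real-data artifacts.

## Numerical choices

- Dispersion floor 1e-8; method-of-moments estimates that fall below it
  (underdispersed samples) are clipped rather than allowed negative.
- Wald log-mean pseudocount ½, symmetric in the two groups; reported
  log2fc pseudocount 1.
- BH ties: step-up minimum over ranks, values clipped to 1; stable
  mergesort ordering makes enrichment output deterministic under p ties.
- Degenerate inputs: all-zero genes are untested in DE and excluded from
  size factors; an all-conserved summary reports denominator 0 rather than
  raising; an empty DEG universe yields an empty assignment table.
- Problem sizes in the test suite and acceptance script (500-gene trios,
  20,000-gene null, 10 seeds) are chosen so each recovery or calibration
  quantity has sampling error well inside its tolerance band while the
  whole suite runs in seconds.

## Known limitations

- The NB Wald test is a deliberately simple, self-contained approximation:
  no information sharing across genes (no dispersion shrinkage), no fold-
  change shrinkage, no outlier handling. Its calls on real data will
  differ from DESeq2's, particularly at low counts.
- Pattern classification inherits the DE thresholds; genes near the
  significance boundary can flip between e.g. dominant and over-dominant
  with small threshold changes. Proportions should be read with that
  sensitivity in mind.
- Heterosis ratio indices are undefined for zero parent values and
  unstable for near-zero mid-parent expression; the expression-heterosis
  table drops MP = 0 genes.
- The enrichment background choice (expressed ∩ annotated) is a
  convention; conclusions can shift with a different background, which is
  why it is configurable.
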