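# Methods

`nddmeta` integrates many independent case-control RNA-seq comparisons
("datasets") of neurodevelopmental disorders (NDDs), each summarized per
gene by a Wald-style quadruple: log2 fold change, its standard error, a
two-sided P value, and a normalized mean expression level.  Count-level
differential expression is deliberately out of scope — the pipeline starts
where a per-dataset DE analysis ends.

## Dataset eligibility and stratification

A dataset enters the corpus only if it has a case-control design and at
least 3 cases and 3 controls (`min_cases`/`min_controls`, default 3 each).
When a dataset declares strata (e.g. mutation types or tissues), it is
split into one analysis unit per stratum only if *every* stratum has at
least 3 cases and 3 controls; otherwise it stays a single unstratified
unit.  The exclusion report records the first failing rule per dataset.

## Dataset ordination

Similarity between datasets i and j is the Spearman correlation of their
P-value vectors on the genes both measure, S_ij = Spearman(P_i, P_j);
distance is D_ij = 1 - S_ij.  Classical (Gower) principal coordinate
analysis double-centers the element-wise **squared** distances,
B = -1/2 J (D∘D) J, and eigendecomposes B.  D here is not Euclidean in
general; negative eigenvalues are reported but excluded from coordinates
and variance-explained (no Lingoes/Cailliez correction).  Because
"double-centering" can also be read as centering D itself, a
`center_squared=False` flag provides that variant; Gower is the default
because it is the convention of every mainstream PCoA implementation.
Axis signs are fixed by orienting each axis so its largest-magnitude
loading is positive.

## Gene set enrichment and the signed -log10 P statistic

Genes are ranked by log2FC (decreasing; exact ties broken by a
seed-recorded shuffle).  The enrichment score is the weighted
Kolmogorov-Smirnov running sum: a member at rank j adds |s_j|^q / N_R, a
non-member subtracts 1/(N - n_hits); the ES is the extremum of the running
sum with its sign.  The weight exponent q defaults to 1 (the convention of
the main GSEA implementation family); q = 0 gives the classic unweighted
statistic.

Significance uses a **gene-label permutation null** — the only null
available from summary statistics (sample permutation would need the
expression matrices).  For each set, `n_perm` random same-size sets are
drawn from the ranked universe and the one-sided P in the observed
direction is the +1-smoothed Monte-Carlo estimate

    p = (1 + #{null, same sign, |ES_null| >= |ES_obs|}) / (1 + #{null, same sign}),

never exactly zero (floor 1/(n_perm+1)); no multilevel/adaptive
refinement is applied.  P values are BH-adjusted across sets within one
dataset (one FDR family per dataset).  Null ES values are computed from
sorted hit positions only (the running sum attains its extrema adjacent to
hits), which makes 1000 permutations for 100 sets on a 20,000-gene list a
sub-second operation per dataset.

Each term in each dataset is then summarized by the signed statistic
-log10(P) · sign(ES); P = 1 maps to 0, and ES = 0 with P < 1 yields 0 with
a warning.

## Ontology term clustering

Terms are grouped by Resnik semantic similarity: IC(t) = -ln(n_t / N)
with n_t the number of genes annotated to t or any descendant (true-path
closure) and N the root count; similarity of two terms is the maximal IC
over common ancestors, normalized by the corpus-maximal IC so the 0.85
threshold lives on [0, 1].  Complete-linkage clustering on 1 - sim, cut at
height 1 - 0.85, approximately enforces within-cluster similarity above
the threshold.  Each cluster's representative is the term significant
(FDR-adjusted P < 0.05) in the most datasets, ties broken by term id.

## Imprinted-gene enrichment and the expression-matched null

Per dataset, a 2x2 table crosses set membership with differential
expression (nominal P < 0.05; directional variants additionally require
log2FC > 0 or < 0 — the DE flag is deliberately nominal, not
FDR-adjusted).  Fisher's exact two-sided P uses the minimum-likelihood
convention.  The log2 odds ratio and its Wald 95% CI use the raw cells
unless any cell is zero, in which case the Haldane-Anscombe +0.5
correction is applied to every cell.

The corpus statistic is the number of datasets with log2 OR > 0.  Its null
distribution comes from random gene sets matched to the target's
median-expression quartile composition: genes are ranked by median
expression across datasets (ties broken by gene id), split into four
rank bins whose sizes differ by at most one (remainders to the lower
bins), and each null set reproduces the target's per-bin counts exactly.
The permutation P value is (1 + #{null >= observed}) / (n_perm + 1).
Subgroup reports (in vitro vs non-in vitro model systems) run the same
test on the corresponding dataset columns.

## Random-effects meta-analysis with Hartung-Knapp adjustment

For one gene across one disorder's datasets: y_i = mu + u_i + e_i,
u_i ~ N(0, tau2), e_i ~ N(0, s_i^2).  tau2 is DerSimonian-Laird by default
(closed form, deterministic); REML is available by fixed-point iteration
(tol 1e-8, max 100 iterations) for users matching that convention.
The pooled mean uses weights 1/(s_i^2 + tau2); the Hartung-Knapp variance
q = sum w(y-mu)^2 / ((k-1) sum w) gives a t statistic with k-1 degrees of
freedom.  When q = 0 (all effects identical) the classical
inverse-variance SE replaces the zero HK SE and the row is flagged
degenerate — never silently.  The transcriptome-wide scan pools each gene
over the datasets measuring it (k reported per gene, k >= 2 required,
skipped genes listed), removes caller-supplied excluded genes (e.g. a
disorder's causative gene) before ranking, and sorts by P, ties by |t|.

## Corpus-level summaries and phenotype association

* Common alterations: terms ranked by the number of datasets reaching
  FDR-adjusted P < 0.05; top-k profiles (signed -log10 P, missing imputed
  as 0) clustered with Euclidean/Ward-D2 linkage.
* Consistent-direction ranking within a disorder: count significant
  datasets (nominal GSEA P < 0.05) per ES sign; score = larger count,
  direction = majority sign, exact ties surfaced as "ambiguous".
* Per-gene DE frequency: fraction of measuring datasets with P < 0.05 —
  denominators only count datasets where the gene was measured, since the
  corpus does not share one platform-complete gene list.
* Phenotype association: Mann-Whitney U of per-dataset signed (and
  unsigned) -log10 P between phenotype-carrying and non-carrying datasets
  (exact enumeration for tie-free total n <= 12, otherwise the
  tie-corrected normal approximation with continuity correction; the
  branch used is recorded per row), and per-gene Fisher tests of DE
  frequency across the phenotype split, BH-adjusted per named family.

## Synthetic corpus generator

The generator emulates the *output* of per-dataset Wald DE analyses, not
the counts behind them — the pipeline consumes only summary statistics, so
a Normal sampling model is the minimal sufficient emulation.  Defaults
mirror the corpus the pipeline targets: 151 datasets, 20,000 genes, 4
cases and 4 controls per dataset, the four most common disorders (RTT,
DMD, FXS, DS) covering ~43% of datasets, between-dataset heterogeneity
tau = 0.15, 10% of genes carrying a true effect with SD 0.5.  Standard
errors follow a scaled square-root-inverse-chi-square (df 8, scale 2),
shrinking with 1/sqrt(n_cases + n_controls) — about 0.75 for a 4+4
dataset, matching the small NDD studies the corpus is made of.  Mean
expression is log-normal per gene and identical across datasets, which
makes expression-quartile matching exactly testable.

Planted structure: a per-gene *global* active flag and base effect shared
across datasets (this is what the meta-analysis pools and what makes
sample-type blocks separate in PCoA); imprinted and phenotype-linked sets
receive per-dataset *additional* activation raising their non-null
probability to min(1, pi·boost); sample-type gene sets carry a block-level
effect shared within the block; `disorder_gene_effects` plants fixed
log2FC values in one disorder's datasets; `phenotype_shift` plants a
fixed-magnitude shift (per-gene sign, consistent across datasets) only in
phenotype-carrying datasets.  The between-dataset deviation N(0, tau2)
attaches only to genes with a nonzero systematic effect, so a null
configuration produces exactly uniform P values — the generator's own
calibration contract.  One global seed with fixed per-dataset substreams:
adding datasets never changes earlier ones.

What the generator does **not** model: library-size and batch effects,
count-level dispersion, correlated genes within pathways, shared samples
between stratified comparisons, and P values from non-Wald tests.  Tests
passing on this generator therefore validate the integration machinery —
calibration, ranking, matching, pooling — not robustness to those
real-data features.

## Validation designs and their problem sizes

* Oracle equivalence: Fisher vs full hypergeometric enumeration (all 2x2
  tables with margins <= 12), Mann-Whitney vs label-assignment enumeration
  (tie-free n <= 8), the ES vs an independent running-sum loop (200
  instances, N <= 50), HK pooling vs a textbook reimplementation (200
  instances, 1e-10).
* Calibration: imprinted permutation type-I error over 200 null corpora
  (20 datasets x 2000 genes, n_perm = 199 for speed); HK 95% CI coverage
  over 1000 genes (k = 6, mu = 0.5, tau = 0.3); GSEA null rejection over
  500 random sets.  The permutation test is somewhat conservative: its
  statistic is an integer count over 20 datasets, so null ties with the
  observed value are common and the inclusive +1-smoothed P overshoots.
* Imprinted power: boost 9.4 — derived from the generator's own
  DE-probability model so the expected per-dataset log2 OR is ~1 at the
  default conditions — across 20 datasets, 50 seeds.
* Meta recovery: with k = 4 the HK null P values are uniform and the
  attainable P for a true mu = 1, tau = 0.2 effect is floored near
  2·sf_t(3 df)(mu / se_HK) ≈ 2e-3, so the expected first-rank probability
  is E[(1-p)^(G-1)] — above 90% only for small gene panels.  The recovery
  simulation therefore uses a focused 15-gene panel with 50+50 samples per
  dataset and SE scale 1 (per-gene SE ≈ 0.11).
* Phenotype recovery: with 8 phenotype and 8 non-phenotype datasets, the
  per-gene Fisher P distribution bounds achievable sensitivity sharply;
  a per-dataset DE probability near 0.8 in carrying datasets caps BH
  sensitivity around 40% at any universe size.  The recovery design
  plants a fixed ±5 log2FC shift (per-dataset DE probability ≈ 0.99),
  100 genes of 2000, 16 datasets, which the per-gene Fisher stage recovers
  at >90% sensitivity with no observed false calls.
* Full-scale smoke: 151 datasets x 20,000 genes through every stage
  (GSEA: 100 sets, 1000 permutations; imprinted: set size 195, 1000
  permutations), a few minutes on one CPU thanks to the vectorized
  position-based null ES and matrix-form permutation counting.

## Numerical conventions

* BH adjustment ignores missing P values (they propagate as NaN and do not
  count toward m); every adjustment belongs to a caller-named family.
* Degenerate inputs error loudly and early: constant P vectors in the
  similarity stage (Spearman undefined), empty 2x2 margins, gene sets
  disjoint from or covering the ranked universe, fewer than 2 datasets for
  pooling.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); permutation P values are +1-smoothed and
  therefore never exactly zero.

## Known limitations

* The gene-label permutation null ignores inter-gene correlation, so GSEA
  P values are anti-conservative on strongly co-expressed sets (a known
  property of preranked GSEA with label nulls).
* Resnik similarity is normalized by the corpus-maximal IC; adding terms
  to the ontology can therefore rescale similarities.
* The PCoA distance 1 - Spearman is not metric; only the positive
  eigenspace is interpreted.
* Quartile matching controls median expression only; other confounders of
  DE propensity (gene length, GC content) are not matched.
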