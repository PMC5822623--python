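# Methods

## The question and the model

RNA-seq genomic signatures — small ordered gene sets used as classifier
features — are usually selected by differential-expression rank alone.
When several selected genes belong to the same protein-family domain,
their expression tends to be correlated, partly through genuine
co-regulation of paralogous family members and partly through read
multi-mapping between similar sequences. Correlated features are
redundant: they contribute little independent information and concentrate
the same prediction errors. `domainsig` quantifies the correlation shift,
measures its effect on cross-validated classification, and removes it by
depleting signatures of domain-sharing genes.

The package deliberately models the *co-expression* route only. Simulating
multi-mapping artifacts would require read-level simulation and an
aligner in the loop; the two effects are not separable in count data
anyway, and everything downstream of the count matrix treats them
identically.

## Synthetic data generator

Counts for gene *g* in sample *s* are drawn
`NB(mean_gs, φ)` with `Var = μ + φμ²` and

```
log mean_gs = log μ_g  +  sign_g · class_s · FC·ln2 · 1[g is DE]
             + sqrt(ρ / k_g) · Σ_{d ∋ g} f_ds  +  log L_s
```

* `μ_g` — per-gene baseline, log-uniform on `base_mean_log_range`
  (default e^1.6 ≈ 5 to 500 counts, the bulk of a filtered bulk RNA-seq
  library);
* `f_ds ~ N(0,1)` — one latent factor per domain and sample; `k_g` is the
  number of domains of gene *g* (1, occasionally 2), so two single-domain
  genes of the same family share a fraction ≈ ρ of their log-mean
  variance. ρ ∈ [0,1) is the planted co-expression strength (default
  0.5); ρ = 0 is the null;
* DE genes (`de_fraction`, default 10%) are shifted `FC` log2 units
  (default 1) between classes. The shift direction is randomized per
  gene: with all DE genes shifted the same way, the class library
  composition changes and CPM normalization smears an apparent opposite
  shift onto every non-DE gene (we measured a realized FDR near 0.45 that
  way). Balanced directions keep the null genes null, which is what the
  generator's ground truth promises;
* `L_s` — library-size factor, log-uniform on (0.7, 1.4);
* `φ` (default 0.2) — NB dispersion typical of bulk tissue replicates.

Domain structure: `round(frac_genes_with_domain · n_genes)` genes
(default half, between the one-third and two-thirds seen in gene–domain
databases) are partitioned into `n_domains` families with truncated
Poisson(≥2) sizes — a domain with fewer than two genes creates no pair —
trimmed/topped-up so the families exactly cover the pool; 10% of domain
genes receive a second random domain so motifs overlap rather than
forming disjoint cliques. Sample classes are assigned by largest-remainder
apportionment of `class_fractions`. For ≥3 classes the DE shift scales
with the integer class code.

Annotations: genes are laid out 1 kb long with 500 bp gaps across four
chromosomes; each domain occurrence is placed strictly inside its host
gene's span, so *any* sensible overlap rule recovers the true membership
— this makes the coordinate-join round-trip test implementation-independent.

Reproducibility: one root seed; each stage (baseline means, DE flags,
domain structure, latent factors, library factors, count draws) uses its
own `SeedSequence` child in a fixed spawn order, so datasets are
bit-identical per (config, seed).

What the generator does **not** emulate: multi-mapping "signal
propagation", 3'-bias, GC effects, outlier samples, or realistic domain
size distributions (Pfam families are heavy-tailed; ours are Poisson).
Passing tests therefore demonstrate that the pipeline detects and removes
planted co-expression of the assumed form, not that any particular real
dataset behaves this way.

## Gene–domain graph

Internal coordinates are 0-based half-open everywhere; GFF3 (and the
1-based-inclusive domain TSV) are converted on read/write, BED passes
through. Joins ignore strand — nested domain annotations always match
their host gene's strand — and use `min_overlap_bp = 1` (any overlap) by
default, since domain occurrences sit inside genes. Duplicate gene IDs in
an annotation are an error, not a silent merge. Ties in
`largest_domain` break to the lexicographically smallest domain ID, and
components sort by size then smallest gene ID, purely for determinism.

## Correlation comparison

Correlations are Spearman's ρ (average-rank Pearson): counts are assumed
negative-binomial, so a distribution-free monotone-association measure is
appropriate. They are computed on log2(1 + CPM) rather than raw log
counts to keep library size from inflating both arms (switchable with
`use_cpm=False` / `--no-cpm`). Constant-expression genes have undefined
rank correlation; they are excluded up front and counted, never imputed.

The domain arm samples uniformly *without replacement within one
simulation* from the set of distinct same-domain pairs (enumerated
explicitly; at study scale this set has a few thousand members). The
domain-free arm requires both genes to carry no domain at all — the
strict reading of "pairs without domains"; pairs are drawn by rejection
sampling, unique within a simulation. Histograms use 81 equal bins of
width 0.025 centered on 0 (covering [−1, 1]); the per-bin mean across
simulations is the distribution estimate and the pointwise min/max is the
simulation envelope. Because the underlying study plots distributions
without a test statistic, the two scalar summaries — pooled mean
difference and pooled two-sample KS distance — are artifact extensions,
labeled as such.

## Differential expression

Gene-wise two-sided Wilcoxon rank-sum on log-CPM (tie-corrected normal
approximation, continuity correction), BH step-up across tested genes,
significance at q ≤ α = 0.05. A rank test keeps the stage assumption-free
and self-contained; NB-GLM engines can be plugged in through
`from_external_ranking`, which adapts any `(gene_id, p_value)` table.
Genes constant across all contrasted samples get p = 1 by definition.
Low-expression genes are pre-filtered (CPM ≥ 1 in at least
min-class-size samples). Results rank by (p, gene_id) so the ordering is
deterministic under ties. Multi-class datasets are reduced to one
configured binary contrast — both the DE stage and the signature
comparison need a single contrast.

## Signature evaluation

Signature size is capped at ⌊n/2⌋ samples (Hughes phenomenon). The
with-domain signature anchors on the domain adjacent to the most
significant genes and takes those genes in DE-rank order; the
without-domain signature takes the top significant domain-free genes.
Classifier defaults (unstated in the underlying procedure, fixed here and
exposed in `ClassifierSpec`): knn k=3; SVM RBF, C=1, γ=1/n_features; one
hidden layer of 8 units, ≤500 iterations; random forest of 500 trees with
√p features per split. Cross-validation is stratified 5-fold — plain
k-fold degenerates easily at n ≈ 30 — repeated 10 times by default to
expose spread; feature standardization is fitted on training folds only
(global scaling would leak test-fold statistics). Misclassification is
pooled over the folds of a repeat: `100 · wrong / n_samples`; for
multi-class data any wrong label counts.

## Depletion

Greedy single pass down the significance ranking, admitting a gene iff it
satisfies the constraint against the already-admitted set — exactly the
"replace domain-connected genes with subsequent significant ones" recipe,
and provably the unique prefix-maximal selection (verified against
exhaustive search in tests). `pairwise_free` (default) keeps the
strongest gene of each family; `strictly_domainless` excludes all
domain-bearing genes and mirrors the evaluated without-domain arm. An
optimal constrained subset selection was considered and rejected: nothing
in the recommendation motivates giving up the significance ranking's
order.

## Problem sizes and numerical choices

The shipped study conditions are 2000 genes × 60 samples in two balanced
classes with 150 domains (co-expression study) or 60 domains of mean size
15 with 25% DE genes (classification study — larger families so the
anchor domain carries several significant genes, with identical marginal
effect size in both arms). The test suite runs the comparison at 2000
pairs × 20 simulations and seed batches of 20–50; the full 25000 × 100
defaults remain available through the API and CLI. Tolerances in tests
derive from the checked quantity: exact agreement (1e-12) for the
Spearman oracle, the normal-approximation gap (0.02) for 6v6 exact
Wilcoxon, 3 standard errors for stochastic chance-level checks.

## Known limitations

* The latent-factor copula plants exchangeable positive correlation
  within a family; real family co-expression is heterogeneous and can be
  negative.
* The Wilcoxon stage is less powerful than NB-GLM tests at very small n;
  with 3–5 samples per group its discrete p-values cannot reach small
  BH thresholds.
* The domain-free arm treats genes absent from the annotation as
  domainless, which on sparse annotations overstates the "free" pool.
* GEXF export carries node kinds but no layout; Gephi computes its own.
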