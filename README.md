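# domainsig

Genes that share a protein-family (Pfam-style) domain tend to be
co-expressed: their pairwise Spearman correlation of RNA-seq counts is
shifted to the right compared with pairs of domain-free genes. For
biomarker work this matters — a genomic signature anchored on one domain
family packs correlated, redundant features and classifies samples worse
than an equally significant set of domain-free genes. `domainsig`
implements that whole analysis as a reusable, tested pipeline, together
with the practical remedy: *depleting* a ranked gene list so that no two
selected genes share a domain.

The pipeline has five stages, each usable on its own:

1. **Gene–domain graph** (`domainsig.graph`) — a bipartite graph of gene
   and domain nodes built from GFF3/BED gene annotations and a domain
   table, joined by identifier or by genomic-coordinate overlap. Two genes
   "share a domain" iff they form a gene–domain–gene motif. Exports GEXF
   (Gephi) and edge TSV.
2. **Co-expression comparison** (`domainsig.coexpression`) — repeatedly
   samples `n_pairs` domain-sharing and domain-free gene pairs
   (default 25000 pairs × 100 simulations), computes Spearman's rank
   correlation ρ of their log-CPM vectors, and summarizes the two
   histogram distributions with min/max simulation envelopes plus two
   shift statistics: the pooled mean difference
   `Δ = mean(ρ_domain) − mean(ρ_free)` and the Kolmogorov–Smirnov
   distance of the pooled samples.
3. **Differential expression** (`domainsig.diffexpr`) — gene-wise Wilcoxon
   rank-sum test on log-CPM with tie-corrected normal approximation, BH
   adjustment, significance at α = 0.05. External DE rankings can be
   injected instead.
4. **Signature evaluation** (`domainsig.signatures`, `domainsig.evaluate`)
   — builds the two competing signatures (significant genes of the most
   DEG-connected domain vs top domain-free DEGs, both capped at
   ⌊n_samples/2⌋ against the Hughes phenomenon) and scores them with
   k-nearest neighbors, RBF SVM, a small neural network and a random
   forest under repeated stratified 5-fold cross-validation, reporting
   percent misclassified samples.
5. **Depletion & report** (`domainsig.depletion`, `domainsig.report`) —
   greedy rank-respecting replacement of domain-sharing genes by
   subsequent significant ones, and a versioned JSON report bundle.

A negative-binomial simulator (`domainsig.simulate`) generates count
matrices with *planted* domain co-expression (a per-domain latent factor
with loading √(ρ/k) on the log-mean) and planted differential expression,
plus matching GFF3/TSV annotations whose coordinate join recovers the true
memberships — so every stage is verifiable end to end without downloading
any data.

## Worked example

```bash
domainsig simulate --out data --seed 4            # synthetic study (2000 genes, 60 samples)
domainsig run-all --counts data/counts.tsv --classes data/classes.tsv \
    --genes data/genes.gff3 --domains data/domains.tsv \
    --out run --seed 4 --n-pairs 2000 --n-sims 20
```

which prints the correlation-shift summary:

```json
{
  "ks_distance": 0.9386,
  "mean_diff": 0.5443156400284104,
  "n_pairs": 2000,
  "n_sims": 20,
  "n_skipped_genes": 0
}
```

`mean_diff ≈ 0.54` is the rightward shift of the Spearman-correlation
distribution for domain-sharing pairs planted at ρ = 0.5 (it is ≈ 0 when
the simulator is run with `rho: 0`), and the KS distance near 1 says the
two pooled distributions barely overlap. `run/report.json` adds the DEG
counts split by domain status, the per-classifier mean percent of
misclassified samples for both signatures — the with-domain signature
misclassifies more for most classifiers — and the depleted signature with
the genes it replaced. `run/` also holds the Gephi-loadable
`gene_domain_graph.gexf`, the long-format stage TSVs, and
`comparison.json` with the histogram curves and envelopes.

The same analysis runs on real data by pointing `run-all` at your own
count TSV, class TSV, gene GFF3/BED and domain table (`domain_id, chrom,
start, end` or `domain_id, gene_id`).

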