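# eqtl-enrich

Tools for asking whether the SNPs that genome-wide association studies
(GWAS) keep finding are regulatory: are trait-associated SNPs more likely
than chance to be expression quantitative trait loci (eQTLs), and can eQTL
evidence be turned into a per-SNP score that prioritizes GWAS signals?

The package is aimed at statistical geneticists working with three kinds of
flat tables: a catalog of trait-associated SNPs, a SNP-by-transcript eQTL
p-value extract (e.g. from lymphoblastoid-cell-line expression scans), and
GWAS summary statistics. It provides:

* **MAF-matched resampling enrichment tests.** Trait-associated SNPs skew
  strongly toward common alleles, so a fair null must condition on minor
  allele frequency. SNPs are grouped into non-overlapping MAF bins of width
  0.05; each null replicate draws, without replacement and per bin, exactly
  the target set's bin counts from the genotyping-platform pool. The
  empirical p-value is the fraction of replicates whose eQTL count strictly
  exceeds the observed count. Variants cover *master regulators* (eQTLs
  controlling at least *n* transcripts) and LD-pruned target sets (greedy
  pruning at r² > 0.3 with a randomized keep-order, repeated over many
  prunes).
* **An eQTL function score.** For a SNP with smallest cis eQTL p-value
  `p_c` among `N_c` cis transcripts (those within 4 Mb of a gene boundary
  on the same chromosome) and smallest overall p-value `p_o` among the
  `N_o` transcripts of the study,

      S = max(0, −log10(min(1, p_c·N_c)), −log10(min(1, p_o·N_o)))

  — Bonferroni corrections applied separately to the cis and overall
  signals, truncated at zero. `S > 3` means some corrected p-value is
  below 10⁻³.
* **Score-based GWAS prioritization.** After QC (missing rate < 5 %,
  MAF ≥ 1 %, rsID present), SNPs are ranked by score (or by association
  p-value), cut into bins of 10,000, and each bin's count of sub-threshold
  association p-values (or supra-threshold scores) is compared to the
  all-SNP expectation and to 95 % bands from MAF-matched simulations.
* **A synthetic-world generator** producing complete, internally consistent
  input sets (panel, genes, truncated eQTL extract, LD blocks, catalog,
  GWAS table) with known planted enrichment, so every statistic can be
  validated against ground truth.

## Worked example

```python
from eqtl_enrich import (SyntheticConfig, generate_world, summarize_eqtls,
                         assign_maf_bins, enrichment_test, compute_score,
                         EqtlSummary)

config = SyntheticConfig(n_snps=5000, n_genes=100, n_catalog=200,
                         n_chrom=5, chrom_length=40_000_000, seed=42)
world = generate_world(config)

summaries = summarize_eqtls(world.eqtl, world.genes, world.panel,
                            n_total=config.n_genes)
by_rsid = {s.rsid: s for s in summaries}
result = enrichment_test(world.catalog_rsids, assign_maf_bins(world.panel),
                         by_rsid, eqtl_threshold=1e-4, n_reps=1000, seed=7)
print(result.summary())
```

prints

```
MAF-matched resampling enrichment test
  pool:            <unnamed>
  eQTL threshold:  p < 0.0001
  observed count:  74
  null mean (sd):  32.86 (5.08)
  null range:      18-50
  replicates:      1000
  empirical p:     < 0.001
```

The 200-SNP catalog contains 74 eQTLs at p < 10⁻⁴ where frequency-matched
random sets average 32.9; no replicate reached the observed count, so the
empirical p-value is below the 1/1000 resolution of the simulation — the
planted threefold selection weight for eQTLs is recovered decisively.
Scoring a strong cis signal (best cis p 10⁻⁸ over 50 cis transcripts, best
overall p 10⁻⁸ over 13,080 transcripts):

```python
score = compute_score(EqtlSummary("rs_demo", p_c=1e-8, p_o=1e-8,
                                  n_c=50, n_o=13_080))
# score.score == 6.3010 (cis 6.3010, trans 3.8834)
```

The cis component −log10(10⁻⁸·50) ≈ 6.30 dominates the more heavily
corrected overall component and becomes the SNP's score.

A command-line interface mirrors the library
(`eqtl-enrich validate | maf-bins | score | test | gwas-bins | simulate`);
see `eqtl-enrich --help`.

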