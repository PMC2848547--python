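# Methods

This note documents the statistical procedures the package implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that matter for
reproducing results.

## MAF-matched resampling enrichment

The question is whether a target SNP set (typically a catalog of
trait-associated SNPs) contains more eQTLs than expected by chance. Because
trait-associated SNPs are strongly shifted toward common alleles — higher
minor allele frequency means higher detection power in the GWAS that found
them — an unconditional null would conflate frequency with function. The
null therefore conditions on MAF: the panel is partitioned into
non-overlapping bins of width 0.05 covering [0, 0.5], and each of `n_reps`
replicates draws, independently per bin and without replacement, exactly
the target's per-bin counts from the pool. The test statistic is the count
of SNPs satisfying the eQTL predicate (smallest association p-value
strictly below a threshold; 10⁻⁴, 10⁻⁶ and 10⁻⁸ are the conventional
choices); the empirical p-value is the fraction of replicates whose count
*strictly exceeds* the observed one, with no +1 smoothing. Its granularity
is therefore 1/`n_reps`, and a value of 0 is reported as "< 1/n_reps" in
text output.

Two consequences of the strict-exceedance definition are worth knowing.
First, when the null count distribution is very discrete (small target
sets), ties between observed and null counts pull the empirical p-value
slightly below uniform; calibration checks in the test suite are run at a
realistic scale (20,000-SNP pool, 500-SNP target) where the count standard
deviation is large enough that ties are rare. Second, empirical p-values
can only be compared across runs with the same `n_reps`.

Bin edges are half-open `[lo, hi)` with the final bin closed at 0.5. Edges
are rounded to 12 decimals so that decimal-literal MAFs (0.05, 0.15, 0.30)
sit exactly on their nominal edge rather than one ULP below it. When a
frequency is computed from genotypes, only pedigree founders (samples with
no parents in the pedigree) contribute, since children's alleles are copies
of transmitted parental alleles; SNPs with no non-missing founder genotype
are excluded and logged.

The replicate RNG spawns one `numpy` `SeedSequence` child per replicate, so
replicate `i` is reproducible independently of execution order, and the
same seed always yields the same replicate sets.

### Master regulators and subgroups

The master-regulator variant replaces the eQTL predicate with "regulates
at least `n` distinct transcripts at the threshold" (`n` ∈ {10, 50, 100,
1000} conventionally; "at least" is inclusive, and distinct transcript
identifiers are counted, not association rows). Enrichment differences
between phenotype subgroups (e.g. autoimmune vs all other disorders) are
compared with a 1-df Pearson chi-square on the 2×2 eQTL-by-subgroup table,
*without* continuity correction — the uncorrected form reproduces the
printed significance of the canonical autoimmune comparison (17/259 vs
29/1339 eQTLs at the 10⁻⁶ threshold gives p ≈ 1.1×10⁻⁴), which pins the
convention. A zero margin returns (0, 1) with a warning rather than an
error, since downstream tabulation code should keep running.

### LD pruning

Catalogs contain redundant SNPs in mutual linkage disequilibrium. Pruning
is greedy: walk the SNPs in a keep-order and retain a SNP unless it has
r² strictly above the threshold (0.3 by default) with an already retained
SNP. The result is independent (no retained pair above threshold) and
maximal (every dropped SNP has a high-LD retained partner). Which member
of a correlated clique survives depends on the keep-order; since no
canonical order exists, the keep-order is a seeded random permutation and
the pruned analysis repeats over `n_prunes` = 100 independent prunes, each
tested with 100 MAF-matched replicates whose bin counts are recomputed
from the pruned set's own MAF distribution. Missing r² entries are treated
as unlinked (0). With `seed=None` the keep-order is positional, which makes
small worked examples deterministic.

## The eQTL function score

Per SNP the eQTL extract is digested into: `p_c`, the smallest cis
p-value; `p_o`, the smallest overall p-value; `N_c`, the number of cis
transcripts; and `N_o`, the total number of transcripts in the expression
study (13,080 in the reference lymphoblastoid dataset). *Cis* means the
SNP lies within 4 Mb of either boundary of the transcript's gene on the
same chromosome, boundary inclusive, distance zero inside the gene; 4 Mb
is deliberately wide so that long-range regulatory variation and LD with
unobserved causal SNPs still count as local. Inputs are truncated extracts:
only cis associations below 0.01 and trans associations below 10⁻⁴ are
stored, so `p_c` is absent when no cis signal beats 0.01 and `p_o` is
absent when nothing survives either truncation.

The score is

    S = max(0, −log10(min(1, p_c·N_c)), −log10(min(1, p_o·N_o)))

i.e. separate Bonferroni corrections for the cis signal (over the `N_c`
transcripts a cis scan tests for this SNP) and the overall signal (over
all `N_o`), mapped to a −log10 scale and truncated at zero. Only the
ranking of SNPs with regulatory evidence matters, not the scale; the score
is monotone in the evidence (sharper p never lowers it, more tests never
raise the corresponding component) and `S > 3` iff some corrected p-value
is below 10⁻³.

Two definitional choices were genuinely open and are configurable:

* `N_c` defaults to the number of transcripts *annotated* within the SNP's
  cis window — the number of cis tests performed — rather than the number
  with observed associations; `n_c_mode="observed"` selects the
  alternative.
* `p_o` is the overall minimum and may itself be a cis p-value; it is not
  restricted to trans signals.

All eQTL thresholds are strict `<`, matching the conventional "p < 10⁻⁴"
notation; `p·N` products are clipped at 1 before the logarithm.

## GWAS prioritization series

GWAS summary records pass QC first: missing rate strictly below 5 %, MAF
at least 1 % (boundary kept), non-empty rsID. SNPs without a score are
dropped and logged. The ranked SNPs (by score descending, or association
p ascending; ties broken by rsID so the ordering is total and every run
reproducible) are cut into consecutive bins of 10,000. Per bin the series
records the count of association p-values below 0.01 (score ordering) or
of scores strictly above a threshold (association ordering), the
expectation from the all-SNP proportion scaled by the actual bin size (a
partial final bin is kept and flagged; an alternative "remaining-SNP"
expectation is available by flag), and 95 % bands as the 2.5/97.5
empirical percentiles of 100 simulated counts.

Band simulations draw bin-sized SNP sets from the full filtered panel —
MAF-matched per bin for the score-ordered series, unmatched for the
association-ordered series. Because a without-replacement draw within a
MAF stratum makes the stratum's success count exactly hypergeometric, the
simulation samples those hypergeometric laws directly instead of
materializing SNP sets; the distribution is identical and the cost is
independent of panel size. Display truncation (the conventional first 13
bins) is a plotting option, not a data decision. A cis/trans split series
ranks on only the cis or only the trans score component, separating which
regulatory mode drives an enrichment, and a chromosome-exclusion helper
(chromosome 6 by default) checks robustness to dense high-LD regions such
as the MHC.

## The synthetic-data generator

The generator emits a full input set with known truth. Defaults describe
the study conditions used throughout the test suite: a 20,000-SNP panel on
10 chromosomes of 60 Mb, 300 genes of 50 kb placed uniformly, a 500-SNP
catalog, and a planted cis-eQTL fraction of 0.2. Panel MAFs are a folded
Beta (uniform on [0, 0.5] by default, a reasonable stand-in for the
ascertained spectrum of genotyping products). Each true eQTL SNP receives
1–3 cis target genes (a 2 % hub fraction receives 10–30 targets, cis and
trans, to exercise master-regulator logic) with p-values from Beta(0.05, 1),
a sharply small-p-concentrated alternative. The null background is emitted
in truncated form: per SNP the number of uniform p-values falling below
each storage truncation is binomial, so only survivors are drawn — the
same shape as a database extract at those truncations, at a cost
proportional to the stored rows.

Catalog SNPs are drawn without replacement with weight
`(rho if eQTL else 1) · maf^maf_bias` (defaults 3 and 1): `rho` plants the
eQTL excess the enrichment test should find and `maf_bias` shifts the
catalog toward common alleles, reproducing the frequency confounding the
MAF matching exists to remove. GWAS p-values are uniform except for
`n_true_trait` = 100 SNPs drawn with weight `kappa` (default 3) for eQTLs,
whose p-values come from Beta(0.01, 1). LD is block-constant: consecutive
same-chromosome SNPs in blocks of 5 share r² = 0.8, others 0.

What the generator does **not** emulate: genotype-level sampling noise, LD
decay with distance and cross-block correlation, ascertainment interactions
between platform membership and MAF, correlated expression phenotypes
(each transcript's signal is independent), and population structure.
Passing tests therefore demonstrate the statistical machinery —
calibration of the matched null, recovery of planted enrichment, band
coverage — under clean conditions, not robustness to the full complexity
of real genotype data.

## Numerical conventions and problem sizes

* All RNG is `numpy.random.default_rng` seeded via `SeedSequence`;
  replicate and world seeds are spawned children, so results are
  independent of execution order and reproducible bit-for-bit.
* Canonical table rendering uses 6-significant-digit floats (scores fixed
  at 6 decimals); writing a read-back table is byte-identical, which is
  what end-to-end determinism tests assert.
* The test suite runs its statistical checks at reduced but honest sizes
  chosen to keep the full suite around five minutes on one CPU: null
  calibration over 200 worlds of the default 20,000-SNP scale with 200
  replicates each; power over 100 such worlds; band coverage over 500
  compact worlds (2,000 SNPs, bins of 250, 100 simulations); the
  hypergeometric sampling oracle at 6,000 replicates; the score oracle
  against 30-digit arbitrary-precision evaluation at 10⁻¹²; pruning
  postconditions over 1,000 random graphs.

## Known limitations

* The empirical p-value's resolution is 1/`n_reps`; strong enrichments
  saturate at 0 and should be reported as bounds.
* Greedy randomized pruning approximates, but does not optimize, maximum
  independent sets in the LD graph; the 100-prune outer loop is the
  intended robustness mechanism.
* `class_proportion` and the bin series assume p-values are exact
  (untruncated) in the GWAS table; genomic-control or imputation-aware
  adjustments are out of scope.
* The enrichment pool is a single SNP universe; per-platform pools are
  expressed by passing a restricted panel rather than by a flag.
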