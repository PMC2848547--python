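"""Synthetic worlds with planted structure for exercising the pipeline.

A world is a complete, internally consistent set of inputs — SNP panel,
gene map, truncated eQTL association extract, LD (r-squared) structure,
trait catalog, and GWAS summary statistics — generated from known
parameters, so that every downstream statistic can be checked against a
planted truth. The generator emulates the salient statistical features of
the real resources:

* a panel MAF spectrum and a catalog shifted toward common alleles
  (catalog selection weight scales with ``maf ** maf_bias``);
* an excess of true eQTLs among catalog SNPs (selection weight multiplied
  by ``rho`` for eQTL SNPs; ``rho = 1`` is the null);
* block-structured LD redundancy among SNPs (constant within-block
  r-squared);
* a truncated eQTL extract, storing only cis associations below the cis
  truncation and trans associations below the trans truncation, mirroring
  the shape of a database extract at those thresholds;
* GWAS p-values whose small values preferentially land on eQTL SNPs
  (true-trait SNPs drawn with weight ``kappa`` for eQTLs; signal p-values
  from a Beta(b, 1) spike).

It does not simulate genotypes, recombination maps, or LD decay; see the
methods note for what that implies about test coverage.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import io_formats as iof
from .io_formats import (
    CatalogEntry,
    EqtlAssociation,
    GeneRecord,
    GwasRecord,
    SnpRecord,
)

_FUNCTION_CLASS_PROBS = {
    "nonsynonymous": 0.01,
    "coding-synonymous": 0.01,
    "intronic": 0.35,
    "intergenic": 0.55,
    "other": 0.05,
    "unknown": 0.03,
}
_DISEASE_CLASSES = ("autoimmune", "cancer", "neuro_psych", "other")


@dataclass(frozen=True)
class SyntheticConfig:
    """All generator parameters; ``rho``/``kappa`` = 1 give the null world."""

    n_snps: int = 20_000
    n_genes: int = 300
    n_catalog: int = 500
    n_chrom: int = 10
    chrom_length: int = 60_000_000
    gene_length: int = 50_000
    maf_law: tuple[float, float] = (1.0, 1.0)  # Beta(a, b) folded to [0, 0.5]
    ld_block_size: int = 5
    within_block_r2: float = 0.8
    f_cis_eqtl: float = 0.2
    hub_fraction: float = 0.02
    eqtl_p_shape: float = 0.05  # Beta(a, 1) for planted eQTL p-values
    rho: float = 3.0
    maf_bias: float = 1.0
    kappa: float = 3.0
    n_true_trait: int = 100
    gwas_p_shape: float = 0.01  # Beta(b, 1) for true trait-SNP p-values
    frac_missing_rsid: float = 0.005
    cis_truncation: float = 0.01
    trans_truncation: float = 1e-4
    cis_window: int = 4_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_catalog > self.n_snps:
            raise ValueError(f"n_catalog {self.n_catalog} > n_snps {self.n_snps}")
        if self.n_true_trait > self.n_snps:
            raise ValueError(f"n_true_trait {self.n_true_trait} > n_snps {self.n_snps}")
        for name in ("f_cis_eqtl", "hub_fraction", "within_block_r2", "frac_missing_rsid"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} {value} outside [0, 1]")
        if self.rho <= 0 or self.kappa <= 0:
            raise ValueError("rho and kappa must be positive (1 = null)")


@dataclass
class World:
    """One synthetic world plus the planted truth behind it."""

    config: SyntheticConfig
    panel: list[SnpRecord]
    genes: list[GeneRecord]
    eqtl: list[EqtlAssociation]
    r2: dict[tuple[str, str], float]
    catalog: list[CatalogEntry]
    gwas: list[GwasRecord]
    truth: dict = field(default_factory=dict)

    @property
    def catalog_rsids(self) -> list[str]:
        return [e.rsid for e in self.catalog]


def _weighted_choice_without_replacement(
    rng: np.random.Generator, n: int, size: int, weights: np.ndarray
) -> np.ndarray:
    total = weights.sum()
    if total <= 0:
        raise ValueError("selection weights sum to zero")
    return rng.choice(n, size=size, replace=False, p=weights / total)


def generate_world(config: SyntheticConfig) -> World:
    """Generate a complete world from ``config``; same config (including
    seed) yields a bit-identical world."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n, g = config.n_snps, config.n_genes

    # --- panel ------------------------------------------------------------
    chrom_idx = rng.integers(0, config.n_chrom, size=n)
    pos = rng.integers(1, config.chrom_length + 1, size=n)
    order = np.lexsort((pos, chrom_idx))
    chrom_idx, pos = chrom_idx[order], pos[order]
    rsids = np.array([f"rs{i + 1:07d}" for i in range(n)], dtype=object)
    chroms = np.array([str(c + 1) for c in chrom_idx], dtype=object)

    a, b = config.maf_law
    raw = rng.beta(a, b, size=n)
    maf = np.minimum(raw, 1.0 - raw)

    on_affy = rng.random(n) < 0.75
    on_illumina = rng.random(n) < 0.75
    on_affy[~(on_affy | on_illumina)] = True

    class_names = list(_FUNCTION_CLASS_PROBS)
    class_probs = np.array(list(_FUNCTION_CLASS_PROBS.values()))
    func_class = rng.choice(class_names, size=n, p=class_probs / class_probs.sum())

    panel = [
        SnpRecord(
            rsid=rsids[i],
            chrom=chroms[i],
            pos=int(pos[i]),
            maf=float(maf[i]),
            platform_flags=frozenset(
                name for name, flag in (("affy6", on_affy[i]), ("illumina1M", on_illumina[i])) if flag
            ),
            function_class=str(func_class[i]),
        )
        for i in range(n)
    ]

    # --- genes ------------------------------------------------------------
    gene_chrom_idx = rng.integers(0, config.n_chrom, size=g)
    gene_start = rng.integers(1, max(2, config.chrom_length - config.gene_length), size=g)
    gorder = np.lexsort((gene_start, gene_chrom_idx))
    gene_chrom_idx, gene_start = gene_chrom_idx[gorder], gene_start[gorder]
    gene_end = gene_start + config.gene_length - 1
    gene_ids = np.array([f"G{i + 1:05d}" for i in range(g)], dtype=object)
    genes = [
        GeneRecord(gene_ids[i], str(gene_chrom_idx[i] + 1), int(gene_start[i]), int(gene_end[i]))
        for i in range(g)
    ]

    # --- cis neighborhoods -------------------------------------------------
    window = config.cis_window
    cis_genes: list[np.ndarray] = [np.empty(0, dtype=int)] * n
    for c in range(config.n_chrom):
        snp_here = np.flatnonzero(chrom_idx == c)
        gene_here = np.flatnonzero(gene_chrom_idx == c)
        if len(snp_here) == 0 or len(gene_here) == 0:
            continue
        lo = gene_start[gene_here] - window
        hi = gene_end[gene_here] + window
        mask = (pos[snp_here][:, None] >= lo[None, :]) & (pos[snp_here][:, None] <= hi[None, :])
        for row, i in enumerate(snp_here):
            cis_genes[i] = gene_here[mask[row]]
    n_cis = np.array([len(cg) for cg in cis_genes])

    # --- planted eQTLs and the truncated association extract ----------------
    is_eqtl = (rng.random(n) < config.f_cis_eqtl) & (n_cis > 0)
    is_hub = is_eqtl & (rng.random(n) < config.hub_fraction)

    assoc_snp: list[int] = []
    assoc_gene: list[int] = []
    assoc_p: list[float] = []

    def _store(i: int, gi: int, p: float) -> None:
        trunc = config.cis_truncation if gi in cis_set else config.trans_truncation
        if 0.0 < p < trunc:
            assoc_snp.append(i)
            assoc_gene.append(gi)
            assoc_p.append(p)

    for i in np.flatnonzero(is_eqtl):
        cis_set = set(cis_genes[i].tolist())
        if is_hub[i]:
            n_targets = int(rng.integers(10, 31))
            pool = np.setdiff1d(np.arange(g), cis_genes[i][:1])
            others = rng.choice(pool, size=min(n_targets - 1, len(pool)), replace=False)
            targets = np.concatenate([cis_genes[i][:1], others])
        else:
            n_targets = int(rng.integers(1, 4))
            targets = rng.choice(cis_genes[i], size=min(n_targets, len(cis_genes[i])), replace=False)
        pvals = rng.beta(config.eqtl_p_shape, 1.0, size=len(targets))
        for gi, p in zip(targets, pvals):
            _store(i, int(gi), float(p))

    # Null background: per SNP, the number of uniform p-values falling below
    # each storage truncation is binomial, so only survivors are drawn.
    n_null_cis = rng.binomial(n_cis, config.cis_truncation)
    n_null_trans = rng.binomial(np.maximum(g - n_cis, 0), config.trans_truncation)
    for i in np.flatnonzero(n_null_cis):
        cis_set = set(cis_genes[i].tolist())
        k = int(n_null_cis[i])
        chosen = rng.choice(cis_genes[i], size=min(k, len(cis_genes[i])), replace=False)
        for gi, u in zip(chosen, rng.random(len(chosen))):
            _store(i, int(gi), float(u * config.cis_truncation))
    for i in np.flatnonzero(n_null_trans):
        cis_set = set(cis_genes[i].tolist())
        k = int(n_null_trans[i])
        chosen = rng.integers(0, g, size=k)
        for gi, u in zip(chosen, rng.random(k)):
            if int(gi) in cis_set:
                continue
            _store(i, int(gi), float(u * config.trans_truncation))

    eqtl_table = [
        EqtlAssociation(rsids[i], gene_ids[gi], max(p, 5e-324))
        for i, gi, p in zip(assoc_snp, assoc_gene, assoc_p)
    ]

    # --- block LD ----------------------------------------------------------
    r2: dict[tuple[str, str], float] = {}
    if config.within_block_r2 > 0 and config.ld_block_size > 1:
        for c in range(config.n_chrom):
            snp_here = np.flatnonzero(chrom_idx == c)
            for start in range(0, len(snp_here), config.ld_block_size):
                block = snp_here[start : start + config.ld_block_size]
                for x in range(len(block)):
                    for y in range(x + 1, len(block)):
                        key = tuple(sorted((rsids[block[x]], rsids[block[y]])))
                        r2[key] = config.within_block_r2

    # --- trait catalog -----------------------------------------------------
    with np.errstate(divide="ignore"):
        maf_weight = np.power(np.maximum(maf, 1e-6), config.maf_bias)
    weights = np.where(is_eqtl, config.rho, 1.0) * maf_weight
    cat_idx = _weighted_choice_without_replacement(rng, n, config.n_catalog, weights)
    cat_p = np.power(10.0, -rng.uniform(5.0, 12.0, size=config.n_catalog))
    cat_class = rng.choice(_DISEASE_CLASSES, size=config.n_catalog)
    catalog = [
        CatalogEntry(
            rsid=rsids[i],
            trait=f"{cls}_trait_{int(rng.integers(1, 20))}",
            disease_class=str(cls),
            reported_p=float(p),
        )
        for i, p, cls in zip(cat_idx, cat_p, cat_class)
    ]

    # --- GWAS summary ------------------------------------------------------
    gwas_weights = np.where(is_eqtl, config.kappa, 1.0)
    trait_idx = _weighted_choice_without_replacement(rng, n, config.n_true_trait, gwas_weights)
    gwas_p = rng.random(n)
    gwas_p[trait_idx] = rng.beta(config.gwas_p_shape, 1.0, size=config.n_true_trait)
    gwas_p = np.clip(gwas_p, 1e-300, 1.0)
    missing_rate = rng.beta(1.0, 50.0, size=n)
    blank_rsid = rng.random(n) < config.frac_missing_rsid
    gwas = [
        GwasRecord(
            rsid="" if blank_rsid[i] else rsids[i],
            chrom=chroms[i],
            p=float(gwas_p[i]),
            maf=float(maf[i]),
            missing_rate=float(missing_rate[i]),
        )
        for i in range(n)
    ]

    truth = {
        "eqtl_rsids": sorted(rsids[is_eqtl].tolist()),
        "hub_rsids": sorted(rsids[is_hub].tolist()),
        "trait_rsids": sorted(rsids[trait_idx].tolist()),
        "config": asdict(config),
    }
    return World(
        config=config,
        panel=panel,
        genes=genes,
        eqtl=eqtl_table,
        r2=r2,
        catalog=catalog,
        gwas=gwas,
        truth=truth,
    )


def world_to_files(world: World, directory: str | Path) -> dict[str, Path]:
    """Write every world table in its canonical dialect; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "panel": directory / "panel.tsv",
        "genes": directory / "genes.bed",
        "eqtl": directory / "eqtl.tsv",
        "catalog": directory / "catalog.tsv",
        "gwas": directory / "gwas.tsv",
        "r2": directory / "r2.tsv",
        "truth": directory / "truth.json",
    }
    iof.write_panel(world.panel, paths["panel"])
    iof.write_genes_bed(world.genes, paths["genes"])
    iof.write_eqtl_table(world.eqtl, paths["eqtl"])
    iof.write_catalog(world.catalog, paths["catalog"])
    iof.write_gwas_summary(world.gwas, paths["gwas"])
    iof.write_r2_table(world.r2, paths["r2"])
    iof.write_truth_json(world.truth, paths["truth"])
    return paths
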