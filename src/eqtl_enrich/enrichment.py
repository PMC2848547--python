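"""Resampling enrichment tests for eQTLs among trait-associated SNP sets.

The core test asks whether a target SNP set (e.g. a GWAS catalog) contains
more eQTLs than expected given its MAF distribution: the observed eQTL
count is compared against counts on MAF-matched random SNP sets drawn
without replacement from the genotyping-platform pool, and the empirical
p-value is the fraction of replicates whose count strictly exceeds the
observed one. Variants cover master regulators (SNPs regulating many
transcripts), LD-pruned target sets, and a chi-square comparison of
enrichment between phenotype subgroups.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .eqtl_scoring import EqtlSummary, is_eqtl, is_master_regulator
from .maf_tools import MafBins, matched_sample

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed count, resampling null, and empirical p for one test."""

    observed: int
    null_counts: np.ndarray
    empirical_p: float
    n_reps: int
    eqtl_threshold: float
    pool_name: str = ""

    def summary(self) -> str:
        null = np.asarray(self.null_counts)
        p_text = (
            f"< {1.0 / self.n_reps:g}" if self.empirical_p == 0.0 else f"{self.empirical_p:g}"
        )
        lines = [
            "MAF-matched resampling enrichment test",
            f"  pool:            {self.pool_name or '<unnamed>'}",
            f"  eQTL threshold:  p < {self.eqtl_threshold:g}",
            f"  observed count:  {self.observed}",
            f"  null mean (sd):  {null.mean():.2f} ({null.std(ddof=1):.2f})"
            if self.n_reps > 1
            else f"  null mean:       {null.mean():.2f}",
            f"  null range:      {int(null.min())}-{int(null.max())}",
            f"  replicates:      {self.n_reps}",
            f"  empirical p:     {p_text}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "observed": int(self.observed),
            "null_counts": [int(c) for c in np.asarray(self.null_counts)],
            "empirical_p": float(self.empirical_p),
            "n_reps": int(self.n_reps),
            "eqtl_threshold": float(self.eqtl_threshold),
            "pool_name": self.pool_name,
        }


@dataclass(frozen=True)
class PrunedEnrichment:
    """Enrichment results across independently LD-pruned target sets."""

    per_prune: tuple[EnrichmentResult, ...]
    n_prunes: int

    @property
    def median_empirical_p(self) -> float:
        return float(np.median([r.empirical_p for r in self.per_prune]))

    def summary(self) -> str:
        ps = [r.empirical_p for r in self.per_prune]
        sizes = {r.observed for r in self.per_prune}
        return "\n".join(
            [
                "LD-pruned enrichment analysis",
                f"  pruned sets:       {self.n_prunes}",
                f"  reps per set:      {self.per_prune[0].n_reps}",
                f"  observed counts:   {min(sizes)}-{max(sizes)}",
                f"  median empirical p: {self.median_empirical_p:g}",
                f"  max empirical p:    {max(ps):g}",
            ]
        )


def empirical_p_value(observed: int, null_counts: np.ndarray) -> float:
    """Fraction of replicates whose count strictly exceeds the observed."""
    return float(np.count_nonzero(null_counts > observed)) / len(null_counts)


def enrichment_test(
    target: Iterable[str],
    pool: MafBins,
    summaries: Mapping[str, EqtlSummary],
    eqtl_threshold: float,
    n_reps: int = 1000,
    seed: int | np.random.SeedSequence = 0,
    predicate: Callable[[EqtlSummary], bool] | None = None,
    pool_name: str = "",
) -> EnrichmentResult:
    """MAF-matched resampling test for eQTL excess in ``target``.

    ``target`` rsids must be assigned in ``pool`` (their MAF bins are taken
    from the pool assignment). ``predicate`` defaults to the strict-``<``
    eQTL test at ``eqtl_threshold``; replicate sets are drawn with
    :func:`eqtl_enrich.maf_tools.matched_sample`.
    """
    target = list(dict.fromkeys(target))
    if predicate is None:
        predicate = lambda s: is_eqtl(s, eqtl_threshold)

    flagged = {
        rsid for rsid, s in summaries.items() if predicate(s)
    }
    observed = sum(1 for rsid in target if rsid in flagged)
    replicates = matched_sample(pool, target, n_reps=n_reps, seed=seed)
    null_counts = np.asarray(
        [sum(1 for rsid in rep if rsid in flagged) for rep in replicates], dtype=int
    )
    return EnrichmentResult(
        observed=observed,
        null_counts=null_counts,
        empirical_p=empirical_p_value(observed, null_counts),
        n_reps=n_reps,
        eqtl_threshold=eqtl_threshold,
        pool_name=pool_name,
    )


def master_regulator_enrichment(
    target: Iterable[str],
    pool: MafBins,
    summaries: Mapping[str, EqtlSummary],
    n_targets: int,
    eqtl_threshold: float,
    n_reps: int = 1000,
    seed: int | np.random.SeedSequence = 0,
    pool_name: str = "",
) -> EnrichmentResult:
    """Enrichment of master regulators (eQTLs with >= ``n_targets`` distinct
    target transcripts at ``eqtl_threshold``) in the target set."""
    return enrichment_test(
        target,
        pool,
        summaries,
        eqtl_threshold,
        n_reps=n_reps,
        seed=seed,
        predicate=lambda s: is_master_regulator(s, eqtl_threshold, n_targets),
        pool_name=pool_name,
    )


def _high_ld_neighbors(
    snps: Sequence[str], r2: Mapping[tuple[str, str], float], threshold: float
) -> dict[str, set[str]]:
    members = set(snps)
    adj: dict[str, set[str]] = {s: set() for s in snps}
    for (a, b), value in r2.items():
        if value > threshold and a in members and b in members:
            adj[a].add(b)
            adj[b].add(a)
    return adj


def ld_prune(
    snps: Sequence[str],
    r2: Mapping[tuple[str, str], float],
    threshold: float = 0.3,
    seed: int | np.random.SeedSequence | None = None,
) -> set[str]:
    """Greedy LD pruning: keep a SNP unless it exceeds ``threshold`` r-squared
    with an already-kept SNP.

    ``r2`` is keyed by sorted rsid pair; absent pairs count as unlinked.
    With ``seed`` None the keep-order is the given positional order;
    otherwise the order is a seeded random permutation, so repeated prunes
    explore which member of each correlated set is retained. The result is
    maximal: every dropped SNP is in high LD with some retained SNP.
    """
    order = list(dict.fromkeys(snps))
    if seed is not None:
        rng = np.random.default_rng(seed)
        order = [order[i] for i in rng.permutation(len(order))]
    adj = _high_ld_neighbors(order, r2, threshold)
    kept: set[str] = set()
    for snp in order:
        if not (adj[snp] & kept):
            kept.add(snp)
    return kept


def pruned_enrichment(
    target: Sequence[str],
    pool: MafBins,
    summaries: Mapping[str, EqtlSummary],
    r2: Mapping[tuple[str, str], float],
    eqtl_threshold: float,
    prune_threshold: float = 0.3,
    n_prunes: int = 100,
    n_reps: int = 100,
    seed: int | np.random.SeedSequence = 0,
    pool_name: str = "",
) -> PrunedEnrichment:
    """Enrichment across ``n_prunes`` independently randomized LD prunes of
    the target, each tested with ``n_reps`` MAF-matched replicates whose
    bin counts reflect the pruned set's own MAF distribution."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    results = []
    for prune_ss, test_ss in zip(ss.spawn(n_prunes), ss.spawn(n_prunes)):
        pruned = ld_prune(target, r2, threshold=prune_threshold, seed=prune_ss)
        # keep deterministic ordering for the downstream bin-count pass
        results.append(
            enrichment_test(
                sorted(pruned),
                pool,
                summaries,
                eqtl_threshold,
                n_reps=n_reps,
                seed=test_ss,
                pool_name=pool_name,
            )
        )
    return PrunedEnrichment(per_prune=tuple(results), n_prunes=n_prunes)


def subgroup_chisq(a: int, n_a: int, b: int, n_b: int) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) comparing the
    eQTL proportion ``a/n_a`` in one phenotype subgroup against ``b/n_b``
    in the complement.

    Returns ``(statistic, p_value)``. A zero margin makes the table
    degenerate; the test then carries no information and (0, 1) is
    returned with a warning.
    """
    if not (0 <= a <= n_a and 0 <= b <= n_b):
        raise ValueError("counts must satisfy 0 <= a <= n_a and 0 <= b <= n_b")
    if n_a < 1 or n_b < 1:
        raise ValueError("group sizes must be >= 1")
    table = np.array([[a, n_a - a], [b, n_b - b]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("degenerate 2x2 table (zero margin); returning chi2=0, p=1")
        return 0.0, 1.0
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)
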