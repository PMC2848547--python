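"""Per-SNP eQTL digests, cis/trans classification, and the eQTL function score.

A SNP is *cis* to a gene when it lies within a fixed window (4 Mb by
default) of either gene boundary on the same chromosome, and *trans*
otherwise. The function score S condenses a SNP's eQTL evidence into one
non-negative number by Bonferroni-correcting the best cis p-value by the
number of cis transcripts and the best overall p-value by the total
transcript count, taking the better of the two on a -log10 scale, and
truncating at zero:

    S = max(0, -log10(min(1, p_c * N_c)), -log10(min(1, p_o * N_o)))

Only the ranking of SNPs with regulatory evidence matters for
prioritization, not the scale; S > 3 means some Bonferroni-corrected
p-value is below 1e-3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import EqtlAssociation, GeneRecord, SnpRecord, ValidationError

CIS_WINDOW = 4_000_000
DEFAULT_CIS_TRUNCATION = 0.01
DEFAULT_TRANS_TRUNCATION = 1e-4
DEFAULT_EQTL_THRESHOLDS = (1e-4, 1e-6, 1e-8)
MASTER_REGULATOR_TARGET_COUNTS = (10, 50, 100, 1000)


@dataclass(frozen=True)
class EqtlSummary:
    """Digest of one SNP's eQTL signal.

    ``p_c``/``p_o`` are the smallest cis / overall p-values surviving their
    storage truncations (None when nothing survives); ``n_c`` is the cis
    transcript count (the cis Bonferroni denominator) and ``n_o`` the total
    transcript count of the study. ``min_p`` is the smallest stored
    association p-value regardless of truncation class, used for the eQTL
    predicate; ``targets_at`` maps a p threshold to the number of distinct
    target transcripts below it.
    """

    rsid: str
    p_c: float | None
    p_o: float | None
    n_c: int
    n_o: int
    min_p: float | None = None
    targets_at: Mapping[float, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.p_c is not None and self.p_o is not None and self.p_o > self.p_c:
            raise ValidationError(f"{self.rsid}: p_o {self.p_o} > p_c {self.p_c}")
        if self.n_c > self.n_o:
            raise ValidationError(f"{self.rsid}: n_c {self.n_c} > n_o {self.n_o}")


@dataclass(frozen=True)
class ScoreRecord:
    """The function score and its cis / trans components for one SNP."""

    rsid: str
    score: float
    cis_component: float
    trans_component: float


def gene_distance(pos: int, gene: GeneRecord) -> int:
    """Distance from a position to the nearest gene edge; 0 inside the gene."""
    if pos < gene.start:
        return gene.start - pos
    if pos > gene.end:
        return pos - gene.end
    return 0


def classify_cis_trans(snp: SnpRecord, gene: GeneRecord, window: int = CIS_WINDOW) -> str:
    """``"cis"`` iff the SNP is on the gene's chromosome within ``window`` bp
    of either gene boundary (inclusive), else ``"trans"``.
    """
    if snp.chrom != gene.chrom:
        return "trans"
    return "cis" if gene_distance(snp.pos, gene) <= window else "trans"


def annotated_cis_counts(
    snps: Sequence[SnpRecord], genes: Sequence[GeneRecord], window: int = CIS_WINDOW
) -> dict[str, int]:
    """Number of genes whose ``window``-padded span covers each SNP.

    This is the count of transcripts a cis scan would test for the SNP,
    i.e. the cis Bonferroni denominator, independent of observed signals.
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    gene_df = pd.DataFrame(
        {
            "chrom": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
        }
    )
    for chrom, grp in gene_df.groupby("chrom", sort=False):
        starts = np.sort(grp["start"].to_numpy() - window)
        ends = np.sort(grp["end"].to_numpy() + window)
        by_chrom[chrom] = (starts, ends)
    counts: dict[str, int] = {}
    for snp in snps:
        if snp.chrom not in by_chrom:
            counts[snp.rsid] = 0
            continue
        starts, ends = by_chrom[snp.chrom]
        # genes with padded start <= pos minus genes with padded end < pos
        n = np.searchsorted(starts, snp.pos, side="right") - np.searchsorted(
            ends, snp.pos, side="left"
        )
        counts[snp.rsid] = int(n)
    return counts


def summarize_eqtls(
    associations: Sequence[EqtlAssociation],
    genes: Sequence[GeneRecord],
    snps: Sequence[SnpRecord],
    n_total: int,
    cis_truncation: float = DEFAULT_CIS_TRUNCATION,
    trans_truncation: float = DEFAULT_TRANS_TRUNCATION,
    thresholds: Sequence[float] = DEFAULT_EQTL_THRESHOLDS,
    window: int = CIS_WINDOW,
    n_c_mode: str = "annotated",
) -> list[EqtlSummary]:
    """Build one :class:`EqtlSummary` per panel SNP.

    Per SNP: ``p_c`` is the minimum p over cis associations if it beats the
    cis truncation; ``p_o`` the minimum over truncation-surviving cis and
    trans associations. ``n_c`` counts, by default, transcripts annotated
    within the SNP's cis window (``n_c_mode="annotated"``); with
    ``n_c_mode="observed"`` it counts only transcripts with an observed cis
    association. SNPs without associations get an all-absent summary.
    """
    if n_total <= 0:
        raise ValidationError(f"n_total must be positive, got {n_total}")
    if n_c_mode not in ("annotated", "observed"):
        raise ValueError(f"unknown n_c_mode {n_c_mode!r}")
    gene_by_id = {g.gene_id: g for g in genes}
    snp_by_id = {s.rsid: s for s in snps}
    bad_genes = sorted({a.gene_id for a in associations} - gene_by_id.keys())
    if bad_genes:
        raise ValidationError(f"unresolvable gene_id(s): {bad_genes}")
    bad_snps = sorted({a.rsid for a in associations} - snp_by_id.keys())
    if bad_snps:
        raise ValidationError(f"association rsid(s) not in panel: {bad_snps}")

    if n_c_mode == "annotated":
        n_c_map = annotated_cis_counts(snps, genes, window=window)
    else:
        n_c_map = {}

    per_snp: dict[str, dict] = {}
    for a in associations:
        snp = snp_by_id[a.rsid]
        is_cis = classify_cis_trans(snp, gene_by_id[a.gene_id], window=window) == "cis"
        d = per_snp.setdefault(
            a.rsid, {"min_p": np.inf, "p_c": np.inf, "p_o": np.inf, "cis_genes": set(), "pairs": []}
        )
        d["min_p"] = min(d["min_p"], a.p)
        d["pairs"].append((a.gene_id, a.p))
        if is_cis:
            d["cis_genes"].add(a.gene_id)
            d["p_c"] = min(d["p_c"], a.p)
            if a.p < cis_truncation:
                d["p_o"] = min(d["p_o"], a.p)
        elif a.p < trans_truncation:
            d["p_o"] = min(d["p_o"], a.p)

    summaries: list[EqtlSummary] = []
    for snp in snps:
        d = per_snp.get(snp.rsid)
        if n_c_mode == "annotated":
            n_c = min(n_c_map[snp.rsid], n_total)
        else:
            n_c = len(d["cis_genes"]) if d else 0
        if d is None:
            summaries.append(
                EqtlSummary(snp.rsid, None, None, n_c, n_total, None,
                            {t: 0 for t in thresholds})
            )
            continue
        p_c = d["p_c"] if d["p_c"] < cis_truncation else None
        p_o = d["p_o"] if np.isfinite(d["p_o"]) else None
        targets = {
            t: len({g for g, p in d["pairs"] if p < t}) for t in thresholds
        }
        summaries.append(
            EqtlSummary(snp.rsid, p_c, p_o, n_c, n_total, float(d["min_p"]), targets)
        )
    return summaries


def compute_score(summary: EqtlSummary) -> ScoreRecord:
    """Evaluate the function score for one SNP summary."""
    if summary.n_o <= 0:
        raise ValidationError(f"{summary.rsid}: n_o must be positive")
    cis = 0.0
    if summary.p_c is not None and summary.n_c >= 1:
        cis = -np.log10(min(1.0, summary.p_c * summary.n_c))
    trans = 0.0
    if summary.p_o is not None:
        trans = -np.log10(min(1.0, summary.p_o * summary.n_o))
    return ScoreRecord(summary.rsid, max(0.0, cis, trans), float(cis), float(trans))


def compute_scores(summaries: Sequence[EqtlSummary]) -> list[ScoreRecord]:
    return [compute_score(s) for s in summaries]


def is_eqtl(summary: EqtlSummary, threshold: float) -> bool:
    """True iff the SNP's smallest association p-value is strictly below
    ``threshold``."""
    if not 0.0 < threshold <= 1.0:
        raise ValidationError(f"threshold {threshold} not in (0, 1]")
    return summary.min_p is not None and summary.min_p < threshold


def is_master_regulator(
    summary: EqtlSummary, threshold: float, n_targets: int = 10
) -> bool:
    """True iff the SNP regulates at least ``n_targets`` distinct transcripts
    at the given p threshold."""
    if n_targets < 1:
        raise ValidationError(f"n_targets must be >= 1, got {n_targets}")
    if threshold not in summary.targets_at:
        raise ValidationError(
            f"{summary.rsid}: summary lacks target counts at threshold {threshold}; "
            f"available: {sorted(summary.targets_at)}"
        )
    return summary.targets_at[threshold] >= n_targets
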