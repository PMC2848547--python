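"""Annotating GWAS summary statistics with eQTL function scores.

SNPs are ranked either by function score (descending) or by association
p-value (ascending) and cut into consecutive fixed-size bins. Per-bin
counts of, respectively, sub-threshold association p-values or
supra-threshold scores are compared to the all-SNP expectation and to 95%
bands obtained by simulation: random (optionally MAF-matched) draws of
bin-sized SNP sets from the full filtered panel. An excess in the top bins
means score-informed prioritization concentrates true signals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .eqtl_scoring import ScoreRecord
from .io_formats import GwasRecord
from .maf_tools import DEFAULT_BIN_WIDTH

logger = logging.getLogger(__name__)

DEFAULT_BIN_SIZE = 10_000
DEFAULT_ASSOC_THRESHOLD = 0.01
DEFAULT_SCORE_THRESHOLD = 3.0
DEFAULT_N_SIMS = 100


@dataclass(frozen=True)
class BinSeries:
    """Ranked fixed-size SNP bins with observed counts, expectation, and
    simulation bands.

    ``ordering`` is ``"by_score_desc"`` or ``"by_assoc_p_asc"``;
    ``bin_sizes`` gives the actual size of each bin (the final bin may be
    partial, in which case ``last_bin_partial`` is True and its expectation
    is scaled accordingly).
    """

    ordering: str
    bin_size: int
    counts: np.ndarray
    expectation: np.ndarray
    band_low: np.ndarray
    band_high: np.ndarray
    bin_sizes: np.ndarray
    threshold: float
    n_total: int

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def last_bin_partial(self) -> bool:
        return self.n_bins > 0 and int(self.bin_sizes[-1]) < self.bin_size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": np.arange(1, self.n_bins + 1),
                "n": self.bin_sizes.astype(int),
                "count": self.counts.astype(int),
                "expectation": self.expectation,
                "band_low": self.band_low,
                "band_high": self.band_high,
            }
        )

    def summary(self, max_bins: int | None = 13) -> str:
        frame = self.to_frame()
        if max_bins is not None:
            frame = frame.head(max_bins)
        header = (
            f"Bin series ({self.ordering}, bin size {self.bin_size}, "
            f"threshold {self.threshold:g}, {self.n_total} SNPs)"
        )
        return header + "\n" + frame.to_string(index=False, float_format=lambda v: f"{v:.2f}")

    def plot(self, ax=None, max_bins: int | None = 13):
        """Scatter of per-bin counts with expectation and 95% bands."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        frame = self.to_frame()
        if max_bins is not None:
            frame = frame.head(max_bins)
        ax.scatter(frame["bin"], frame["count"], color="black", zorder=3)
        ax.plot(frame["bin"], frame["expectation"], color="grey")
        ax.plot(frame["bin"], frame["band_low"], linestyle=":", color="grey")
        ax.plot(frame["bin"], frame["band_high"], linestyle=":", color="grey")
        ax.set_xlabel("bin")
        ax.set_ylabel("count")
        return ax


def qc_filter(
    records: Sequence[GwasRecord],
    max_missing: float = 0.05,
    min_maf: float = 0.01,
) -> list[GwasRecord]:
    """Keep records with missing rate strictly below ``max_missing``, MAF at
    least ``min_maf``, and a non-empty rsid; exclusion counts are logged."""
    kept: list[GwasRecord] = []
    dropped = {"missing_rate": 0, "maf": 0, "no_rsid": 0}
    for r in records:
        if not r.rsid:
            dropped["no_rsid"] += 1
        elif not r.missing_rate < max_missing:
            dropped["missing_rate"] += 1
        elif not r.maf >= min_maf:
            dropped["maf"] += 1
        else:
            kept.append(r)
    if any(dropped.values()):
        logger.info(
            "qc_filter: dropped %d (missing rate), %d (MAF), %d (no rsid); kept %d",
            dropped["missing_rate"], dropped["maf"], dropped["no_rsid"], len(kept),
        )
    return kept


def exclude_chromosome(records: Sequence[GwasRecord], chrom: str = "6") -> list[GwasRecord]:
    """Drop all records on ``chrom`` (sensitivity analysis for high-LD
    regions such as the MHC)."""
    kept = [r for r in records if r.chrom != chrom]
    logger.info("exclude_chromosome: removed %d record(s) on chr%s", len(records) - len(kept), chrom)
    return kept


def _match_scores(
    records: Sequence[GwasRecord], scores: Mapping[str, float]
) -> pd.DataFrame:
    frame = pd.DataFrame(
        {
            "rsid": [r.rsid for r in records],
            "p": [r.p for r in records],
            "maf": [r.maf for r in records],
        }
    )
    matched = frame[frame["rsid"].isin(scores.keys())].copy()
    n_dropped = len(frame) - len(matched)
    if n_dropped:
        logger.info("bin series: dropped %d GWAS SNP(s) without a score", n_dropped)
    matched["score"] = matched["rsid"].map(scores)
    return matched


def _bin_slices(n: int, bin_size: int) -> list[slice]:
    if bin_size < 1:
        raise ValueError(f"bin_size must be >= 1, got {bin_size}")
    return [slice(i, min(i + bin_size, n)) for i in range(0, n, bin_size)]


def _matched_band_counts(
    bin_maf: np.ndarray,
    pool_maf: np.ndarray,
    pool_success: np.ndarray,
    n_sims: int,
    rng: np.random.Generator,
    width: float = DEFAULT_BIN_WIDTH,
) -> np.ndarray:
    """Simulated success counts for MAF-matched draws of one bin.

    Drawing, within each MAF stratum, the bin's stratum count without
    replacement from the pool makes the per-stratum success count exactly
    hypergeometric, so the simulation samples those laws directly.
    """
    edges = np.linspace(0.0, 0.5, int(round(0.5 / width)) + 1)
    pool_idx = np.minimum(np.searchsorted(edges, pool_maf, side="right") - 1, len(edges) - 2)
    bin_idx = np.minimum(np.searchsorted(edges, bin_maf, side="right") - 1, len(edges) - 2)
    totals = np.zeros(n_sims, dtype=int)
    for b in np.unique(bin_idx):
        k = int(np.count_nonzero(bin_idx == b))
        in_stratum = pool_idx == b
        n_good = int(np.count_nonzero(pool_success & in_stratum))
        n_bad = int(np.count_nonzero(in_stratum)) - n_good
        totals += rng.hypergeometric(n_good, n_bad, k, size=n_sims)
    return totals


def _unmatched_band_counts(
    bin_n: int, pool_success: np.ndarray, n_sims: int, rng: np.random.Generator
) -> np.ndarray:
    n_good = int(np.count_nonzero(pool_success))
    n_bad = len(pool_success) - n_good
    return rng.hypergeometric(n_good, n_bad, bin_n, size=n_sims)


def _series(
    matched: pd.DataFrame,
    success: np.ndarray,
    ordering: str,
    bin_size: int,
    threshold: float,
    n_sims: int,
    seed,
    maf_matched_bands: bool,
    expectation_mode: str,
) -> BinSeries:
    n = len(matched)
    rng = np.random.default_rng(seed)
    slices = _bin_slices(n, bin_size)
    counts = np.array([int(success[s].sum()) for s in slices])
    sizes = np.array([s.stop - s.start for s in slices])
    overall = success.mean() if n else 0.0
    if expectation_mode == "all":
        expectation = overall * sizes.astype(float)
    elif expectation_mode == "remaining":
        total = success.sum()
        with np.errstate(invalid="ignore"):
            props = np.array(
                [(total - c) / (n - sz) if n > sz else overall for c, sz in zip(counts, sizes)]
            )
        expectation = props * sizes
    else:
        raise ValueError(f"unknown expectation_mode {expectation_mode!r}")
    band_low = np.empty(len(slices))
    band_high = np.empty(len(slices))
    pool_maf = matched["maf"].to_numpy()
    for k, s in enumerate(slices):
        if maf_matched_bands:
            sims = _matched_band_counts(pool_maf[s], pool_maf, success, n_sims, rng)
        else:
            sims = _unmatched_band_counts(s.stop - s.start, success, n_sims, rng)
        band_low[k], band_high[k] = np.percentile(sims, [2.5, 97.5])
    return BinSeries(
        ordering=ordering,
        bin_size=bin_size,
        counts=counts,
        expectation=expectation,
        band_low=band_low,
        band_high=band_high,
        bin_sizes=sizes,
        threshold=threshold,
        n_total=n,
    )


def score_bin_series(
    records: Sequence[GwasRecord],
    scores: Mapping[str, float],
    bin_size: int = DEFAULT_BIN_SIZE,
    assoc_threshold: float = DEFAULT_ASSOC_THRESHOLD,
    n_sims: int = DEFAULT_N_SIMS,
    seed: int | np.random.SeedSequence = 0,
    expectation_mode: str = "all",
) -> BinSeries:
    """Bin SNPs by descending function score and count sub-threshold
    association p-values per bin.

    GWAS SNPs without a score are dropped (and logged). Ties in score break
    by rsid so the ranking is total and reproducible. Bands come from
    MAF-matched draws of bin-sized sets from the full filtered panel.
    """
    matched = _match_scores(records, scores)
    matched = matched.sort_values(["score", "rsid"], ascending=[False, True], kind="mergesort")
    success = (matched["p"].to_numpy() < assoc_threshold)
    return _series(
        matched,
        success,
        "by_score_desc",
        bin_size,
        assoc_threshold,
        n_sims,
        seed,
        maf_matched_bands=True,
        expectation_mode=expectation_mode,
    )


def assoc_bin_series(
    records: Sequence[GwasRecord],
    scores: Mapping[str, float],
    bin_size: int = DEFAULT_BIN_SIZE,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    n_sims: int = DEFAULT_N_SIMS,
    seed: int | np.random.SeedSequence = 0,
) -> BinSeries:
    """Bin SNPs by ascending association p-value and count scores strictly
    above ``score_threshold`` per bin; bands from unmatched random draws
    of bin-sized sets from the full score list."""
    matched = _match_scores(records, scores)
    matched = matched.sort_values(["p", "rsid"], ascending=[True, True], kind="mergesort")
    success = (matched["score"].to_numpy() > score_threshold)
    return _series(
        matched,
        success,
        "by_assoc_p_asc",
        bin_size,
        score_threshold,
        n_sims,
        seed,
        maf_matched_bands=False,
        expectation_mode="all",
    )


def cis_trans_split_series(
    records: Sequence[GwasRecord],
    score_records: Sequence[ScoreRecord],
    which: str,
    bin_size: int = DEFAULT_BIN_SIZE,
    assoc_threshold: float = DEFAULT_ASSOC_THRESHOLD,
    n_sims: int = DEFAULT_N_SIMS,
    seed: int | np.random.SeedSequence = 0,
    expectation_mode: str = "all",
) -> BinSeries:
    """Score-ordered bin series using only the cis or only the trans
    component of the function score, separating the regulatory mechanism
    driving an enrichment."""
    if which not in ("cis", "trans"):
        raise ValueError(f"which must be 'cis' or 'trans', got {which!r}")
    attr = "cis_component" if which == "cis" else "trans_component"
    component = {r.rsid: getattr(r, attr) for r in score_records}
    return score_bin_series(
        records,
        component,
        bin_size=bin_size,
        assoc_threshold=assoc_threshold,
        n_sims=n_sims,
        seed=seed,
        expectation_mode=expectation_mode,
    )


def class_proportion(
    records: Sequence[GwasRecord],
    classes: Mapping[str, str],
    cls: str,
    assoc_threshold: float = DEFAULT_ASSOC_THRESHOLD,
) -> float | None:
    """Proportion of SNPs of functional class ``cls`` with association p
    below ``assoc_threshold``; None when the class is empty."""
    members = [r for r in records if classes.get(r.rsid) == cls]
    if not members:
        return None
    hits = sum(1 for r in members if r.p < assoc_threshold)
    return hits / len(members)
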