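"""Minor-allele-frequency machinery: founder-only frequencies, fixed-width
MAF bins, and MAF-matched resampling of SNP sets.

The matched sampler is the engine behind every null simulation in the
package: a target SNP set is summarized by its per-bin counts, and each
replicate draws, without replacement and independently per bin, the same
number of SNPs from the pool's bins. Conditioning on MAF this way removes
the frequency confounding that otherwise dominates enrichment comparisons,
because trait-associated SNPs skew strongly toward common alleles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import SnpRecord, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 0.05


class InfeasibleSamplingError(ValueError):
    """A pool bin holds fewer SNPs than the target requires from it."""


@dataclass(frozen=True)
class PedigreeMember:
    """One pedigree row; a founder has neither parent in the pedigree."""

    sample_id: str
    father_id: str | None = None
    mother_id: str | None = None

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


def founder_allele_freq(
    genotypes: pd.DataFrame, pedigree: Sequence[PedigreeMember]
) -> dict[str, float]:
    """Minor allele frequencies from founder genotypes only.

    ``genotypes`` is samples x SNPs with allele counts {0, 1, 2} and NaN for
    missing. Children's alleles are copies of transmitted parental alleles,
    so only founders (no parents in the pedigree) enter the counts. SNPs
    with no non-missing founder genotype are excluded and logged.
    """
    by_id = {m.sample_id: m for m in pedigree}
    unknown = [s for s in genotypes.index if s not in by_id]
    if unknown:
        raise ValidationError(f"genotype samples missing from pedigree: {unknown}")
    for member in by_id.values():
        for parent in (member.father_id, member.mother_id):
            if parent is not None and parent not in by_id:
                raise ValidationError(
                    f"{member.sample_id}: parent {parent} absent from pedigree"
                )
    founders = [s for s in genotypes.index if by_id[s].is_founder]
    sub = genotypes.loc[founders]
    n_obs = sub.notna().sum(axis=0)
    freq = sub.sum(axis=0, skipna=True) / (2.0 * n_obs)
    out: dict[str, float] = {}
    for rsid in genotypes.columns:
        if n_obs[rsid] == 0:
            logger.info("founder_allele_freq: %s has no founder genotypes, excluded", rsid)
            continue
        f = float(freq[rsid])
        out[rsid] = min(f, 1.0 - f)
    return out


@dataclass
class MafBins:
    """Non-overlapping MAF bins of fixed width covering [0, 0.5].

    Bin ``k`` covers ``[k*width, (k+1)*width)``; the last bin is closed at
    0.5. ``assignment`` maps each rsid to its bin index; ``pool_by_bin``
    holds, per bin, the rsids assigned there (sorted for determinism).
    """

    width: float = DEFAULT_BIN_WIDTH
    assignment: dict[str, int] = field(default_factory=dict)
    pool_by_bin: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return int(round(0.5 / self.width))

    @property
    def edges(self) -> np.ndarray:
        # rounded so decimal-literal MAFs (0.15, 0.30, ...) sit on their edge
        return np.round(np.linspace(0.0, 0.5, self.n_bins + 1), 12)

    def bin_index(self, maf: float) -> int:
        if not 0.0 <= maf <= 0.5:
            raise ValidationError(f"maf {maf} outside [0, 0.5]")
        idx = int(np.searchsorted(self.edges, maf, side="right")) - 1
        return min(idx, self.n_bins - 1)

    @classmethod
    def from_maf_map(cls, mafs: Mapping[str, float], width: float = DEFAULT_BIN_WIDTH) -> "MafBins":
        bins = cls(width=width)
        rsids = np.asarray(list(mafs.keys()), dtype=object)
        values = np.asarray([mafs[r] for r in rsids], dtype=float)
        if values.size and (values.min() < 0.0 or values.max() > 0.5):
            bad = rsids[(values < 0.0) | (values > 0.5)][0]
            raise ValidationError(f"{bad}: maf outside [0, 0.5]")
        idx = np.searchsorted(bins.edges, values, side="right") - 1
        idx = np.minimum(idx, bins.n_bins - 1)
        bins.assignment = dict(zip(rsids.tolist(), (int(i) for i in idx)))
        for b in range(bins.n_bins):
            members = sorted(rsids[idx == b].tolist())
            if members:
                bins.pool_by_bin[b] = np.asarray(members, dtype=object)
        return bins

    def bin_counts(self, rsids: Iterable[str]) -> dict[int, int]:
        """Per-bin counts for a subset of assigned rsids."""
        counts: dict[int, int] = {}
        for rsid in rsids:
            try:
                b = self.assignment[rsid]
            except KeyError:
                raise ValidationError(f"{rsid}: not assigned to any MAF bin") from None
            counts[b] = counts.get(b, 0) + 1
        return counts


def assign_maf_bins(snps: Sequence[SnpRecord], width: float = DEFAULT_BIN_WIDTH) -> MafBins:
    """Assign panel SNPs to width-``width`` MAF bins."""
    return MafBins.from_maf_map({s.rsid: s.maf for s in snps}, width=width)


def _check_feasible(pool_bins: MafBins, target_counts: Mapping[int, int]) -> None:
    for b, needed in target_counts.items():
        available = len(pool_bins.pool_by_bin.get(b, ()))
        if needed > available:
            lo, hi = b * pool_bins.width, (b + 1) * pool_bins.width
            raise InfeasibleSamplingError(
                f"bin {b} [{lo:g}, {hi:g}): target needs {needed}, pool holds {available}"
            )


def matched_sample(
    pool_bins: MafBins,
    target: "MafBins | Mapping[int, int] | Iterable[str]",
    n_reps: int,
    seed: int | np.random.SeedSequence,
) -> list[np.ndarray]:
    """Draw ``n_reps`` MAF-matched SNP sets from the pool.

    ``target`` may be a MafBins over the target set, an explicit per-bin
    count mapping, or an iterable of rsids (binned via the pool's
    assignment). Each replicate contains, for every bin, exactly the
    target's count, drawn without replacement from that pool bin; distinct
    replicates use independent RNG substreams spawned from ``seed`` so
    replicate ``i`` is reproducible regardless of execution order.
    """
    if isinstance(target, MafBins):
        target_counts = {b: len(v) for b, v in target.pool_by_bin.items() if len(v)}
    elif isinstance(target, Mapping):
        target_counts = {int(b): int(c) for b, c in target.items() if c}
    else:
        target_counts = pool_bins.bin_counts(target)
    _check_feasible(pool_bins, target_counts)

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_reps)
    ordered_bins = sorted(target_counts)
    replicates: list[np.ndarray] = []
    for child in children:
        rng = np.random.default_rng(child)
        parts = [
            rng.choice(pool_bins.pool_by_bin[b], size=target_counts[b], replace=False)
            for b in ordered_bins
        ]
        replicates.append(np.concatenate(parts) if parts else np.asarray([], dtype=object))
    return replicates
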