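"""cis/trans classification, eQTL digests, and the function score."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from eqtl_enrich import (
    EqtlAssociation,
    EqtlSummary,
    GeneRecord,
    SnpRecord,
    classify_cis_trans,
    compute_score,
    is_eqtl,
    is_master_regulator,
    summarize_eqtls,
)
from eqtl_enrich.eqtl_scoring import gene_distance
from eqtl_enrich.io_formats import ValidationError


def _snp(rsid="rs1", chrom="1", pos=1_000_000):
    return SnpRecord(rsid, chrom, pos, 0.2, frozenset(), "unknown")


class TestClassifyCisTrans:
    def test_within_window_is_cis(self):
        gene = GeneRecord("G1", "1", 4_900_000, 5_000_000)
        assert classify_cis_trans(_snp(pos=1_000_000), gene) == "cis"

    def test_other_chromosome_is_trans(self):
        gene = GeneRecord("G1", "2", 1_000_000, 1_050_000)
        assert classify_cis_trans(_snp(chrom="1"), gene) == "trans"

    def test_window_boundary_is_inclusive(self):
        gene = GeneRecord("G1", "1", 5_000_000, 5_100_000)
        assert classify_cis_trans(_snp(pos=1_000_000), gene) == "cis"  # exactly 4 Mb
        assert classify_cis_trans(_snp(pos=999_999), gene) == "trans"

    def test_inside_gene_distance_zero(self):
        gene = GeneRecord("G1", "1", 900_000, 1_100_000)
        assert gene_distance(1_000_000, gene) == 0
        assert classify_cis_trans(_snp(pos=1_000_000), gene) == "cis"

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(200):
            snp = _snp(pos=int(rng.integers(1, 20_000_000)), chrom=str(rng.integers(1, 3)))
            start = int(rng.integers(1, 20_000_000))
            gene = GeneRecord("G", str(rng.integers(1, 3)), start, start + 50_000)
            if snp.chrom != gene.chrom:
                expected = "trans"
            else:
                d = 0 if gene.start <= snp.pos <= gene.end else min(
                    abs(snp.pos - gene.start), abs(snp.pos - gene.end)
                )
                expected = "cis" if d <= 4_000_000 else "trans"
            assert classify_cis_trans(snp, gene) == expected


def _brute_force_summaries(assocs, genes, snps, n_total, cis_trunc, trans_trunc, thresholds):
    gene_by_id = {g.gene_id: g for g in genes}
    out = {}
    for snp in snps:
        cis_ps, surv, all_ps, targets = [], [], [], {t: set() for t in thresholds}
        n_c = sum(
            1
            for g in genes
            if g.chrom == snp.chrom
            and (g.start - 4_000_000 <= snp.pos <= g.end + 4_000_000)
        )
        for a in assocs:
            if a.rsid != snp.rsid:
                continue
            gene = gene_by_id[a.gene_id]
            cis = classify_cis_trans(snp, gene) == "cis"
            all_ps.append(a.p)
            if cis:
                cis_ps.append(a.p)
                if a.p < cis_trunc:
                    surv.append(a.p)
            elif a.p < trans_trunc:
                surv.append(a.p)
            for t in thresholds:
                if a.p < t:
                    targets[t].add(a.gene_id)
        out[snp.rsid] = dict(
            p_c=min(cis_ps) if cis_ps and min(cis_ps) < cis_trunc else None,
            p_o=min(surv) if surv else None,
            n_c=min(n_c, n_total),
            min_p=min(all_ps) if all_ps else None,
            targets_at={t: len(v) for t, v in targets.items()},
        )
    return out


class TestSummarizeEqtls:
    def _world(self, rng, n_snps=20, n_genes=15):
        snps = [
            SnpRecord(f"rs{i}", str(rng.integers(1, 3)), int(rng.integers(1, 30_000_000)),
                      0.2, frozenset(), "unknown")
            for i in range(n_snps)
        ]
        genes = []
        for j in range(n_genes):
            start = int(rng.integers(1, 30_000_000))
            genes.append(GeneRecord(f"G{j}", str(rng.integers(1, 3)), start, start + 40_000))
        assocs = []
        for _ in range(60):
            p = float(10 ** -rng.uniform(0, 8))
            assocs.append(
                EqtlAssociation(f"rs{rng.integers(0, n_snps)}", f"G{rng.integers(0, n_genes)}", p)
            )
        return snps, genes, assocs

    def test_trans_association_above_truncation_vanishes(self):
        snps = [_snp("rs1", "1", 1_000_000)]
        genes = [GeneRecord("G1", "2", 1, 50_000)]
        assocs = [EqtlAssociation("rs1", "G1", 0.5)]
        (s,) = summarize_eqtls(assocs, genes, snps, n_total=100)
        assert s.p_c is None and s.p_o is None and s.n_c == 0
        assert s.min_p == 0.5  # still recorded for the untruncated eQTL predicate

    def test_minima_by_definition(self):
        snps = [_snp("rs1", "1", 1_000_000)]
        genes = [
            GeneRecord("Gcis", "1", 2_000_000, 2_050_000),
            GeneRecord("Gtrans", "2", 1, 50_000),
        ]
        assocs = [
            EqtlAssociation("rs1", "Gcis", 1e-5),
            EqtlAssociation("rs1", "Gtrans", 1e-6),
        ]
        (s,) = summarize_eqtls(assocs, genes, snps, n_total=100)
        assert s.p_c == 1e-5
        assert s.p_o == 1e-6

    def test_unresolvable_gene_listed(self):
        with pytest.raises(ValidationError, match="Gmissing"):
            summarize_eqtls(
                [EqtlAssociation("rs1", "Gmissing", 0.001)],
                [GeneRecord("G1", "1", 1, 2)],
                [_snp()],
                n_total=10,
            )

    def test_matches_exhaustive_enumeration(self, rng):
        thresholds = (1e-4, 1e-6)
        for _ in range(10):
            snps, genes, assocs = self._world(rng)
            got = summarize_eqtls(assocs, genes, snps, n_total=50, thresholds=thresholds)
            expected = _brute_force_summaries(assocs, genes, snps, 50, 0.01, 1e-4, thresholds)
            for s in got:
                e = expected[s.rsid]
                assert s.p_c == e["p_c"]
                assert s.p_o == e["p_o"]
                assert s.n_c == e["n_c"]
                assert s.min_p == e["min_p"]
                assert dict(s.targets_at) == e["targets_at"]

    def test_observed_mode_counts_only_seen_cis_transcripts(self):
        snps = [_snp("rs1", "1", 1_000_000)]
        genes = [
            GeneRecord("G1", "1", 2_000_000, 2_050_000),
            GeneRecord("G2", "1", 3_000_000, 3_050_000),
        ]
        assocs = [EqtlAssociation("rs1", "G1", 1e-3)]
        (annotated,) = summarize_eqtls(assocs, genes, snps, n_total=10)
        (observed,) = summarize_eqtls(assocs, genes, snps, n_total=10, n_c_mode="observed")
        assert annotated.n_c == 2
        assert observed.n_c == 1


class TestComputeScore:
    def test_no_surviving_signal_scores_zero(self):
        s = EqtlSummary("rs1", None, None, 5, 100)
        assert compute_score(s).score == 0.0

    def test_worked_example(self):
        s = EqtlSummary("rs1", 1e-8, 1e-8, 50, 13_080)
        rec = compute_score(s)
        assert rec.cis_component == pytest.approx(-math.log10(5e-7), abs=1e-10)
        assert rec.trans_component == pytest.approx(-math.log10(1.308e-4), abs=1e-10)
        assert rec.score == pytest.approx(6.30103, abs=1e-5)

    def test_corrected_p_of_one_scores_zero(self):
        s = EqtlSummary("rs1", None, 1e-2, 0, 100)  # p_o * N_o = 1 exactly
        assert compute_score(s).score == 0.0

    def test_score_above_three_iff_corrected_p_below_1e3(self):
        below = EqtlSummary("rs1", None, 0.9e-5, 0, 100)
        above = EqtlSummary("rs2", None, 1.1e-5, 0, 100)
        assert compute_score(below).score > 3
        assert compute_score(above).score < 3

    @given(
        st.floats(1e-30, 0.0099, allow_nan=False),
        st.integers(1, 100),
        st.floats(0.1, 0.9),
    )
    def test_monotone_in_p_and_n(self, p_c, n_c, shrink):
        base = EqtlSummary("rs1", p_c, p_c, n_c, 200)
        sharper = EqtlSummary("rs1", p_c * shrink, p_c * shrink, n_c, 200)
        assert compute_score(sharper).score >= compute_score(base).score
        if n_c + 1 <= 200:
            wider = EqtlSummary("rs1", p_c, p_c, n_c + 1, 200)
            assert compute_score(wider).cis_component <= compute_score(base).cis_component


class TestPredicates:
    def test_eqtl_threshold_is_strict(self):
        s = EqtlSummary("rs1", None, None, 0, 10, min_p=9.9e-5)
        t = EqtlSummary("rs2", None, None, 0, 10, min_p=1e-4)
        assert is_eqtl(s, 1e-4)
        assert not is_eqtl(t, 1e-4)
        assert not is_eqtl(EqtlSummary("rs3", None, None, 0, 10), 1e-4)

    @pytest.mark.parametrize("count,expected", [(12, True), (10, True), (9, False)])
    def test_master_regulator_at_least_inclusive(self, count, expected):
        s = EqtlSummary("rs1", None, None, 0, 10, min_p=1e-9, targets_at={1e-4: count})
        assert is_master_regulator(s, 1e-4, n_targets=10) is expected

    def test_missing_threshold_is_an_error(self):
        s = EqtlSummary("rs1", None, None, 0, 10, targets_at={1e-4: 3})
        with pytest.raises(ValidationError, match="1e-06"):
            is_master_regulator(s, 1e-6)
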