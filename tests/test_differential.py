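"""DMR overlap screens, the two-group F-test, Storey q-values and the DEG filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from epiblocks.differential import (
    DEGCriteria,
    ExpressionMatrix,
    MethylRegion,
    deg_filter,
    deg_locus_overlap,
    load_dmr_fixture,
    overlap_report,
    storey_qvalues,
    two_group_f_test,
)
from epiblocks.intervals import GenomicInterval, IntervalSet
from epiblocks.risk_loci import GeneRecord, LDBlock, RiskSNP, load_risk_blocks

# frozen oracle: independent step-by-step computation of the q-value formula
# (lambda = 0.5) for ten fixed p-values; pi0_hat = 4 / (0.5 * 10) = 0.8
ORACLE_PS = [0.001, 0.009, 0.02, 0.03, 0.2, 0.35, 0.55, 0.65, 0.8, 0.95]
ORACLE_QS = [
    0.008,
    0.036,
    0.05333333333333334,
    0.06,
    0.32,
    0.4666666666666667,
    0.6285714285714286,
    0.65,
    0.7111111111111111,
    0.76,
]


def _matrix(values: np.ndarray, n_control: int, n_case: int) -> ExpressionMatrix:
    samples = [f"c{i}" for i in range(n_control)] + [f"t{i}" for i in range(n_case)]
    frame = pd.DataFrame(
        values, index=[f"g{i}" for i in range(values.shape[0])], columns=samples
    )
    groups = pd.Series(["control"] * n_control + ["case"] * n_case, index=samples)
    return ExpressionMatrix(frame, groups)


class TestOverlapReport:
    def test_packaged_dmrs_pair_with_printed_blocks(self):
        blocks = load_risk_blocks()
        dmrs = load_dmr_fixture()
        report = overlap_report(blocks, IntervalSet([d.interval for d in dmrs]))
        assert report.n_regions == 4
        assert report.n_regions_hit == 4
        assert report.n_blocks_hit == 3
        pairing = dict(zip(report.pairs["region"], report.pairs["block_rsid"]))
        assert pairing["chr2:198173194-198173317"] == "rs1429412"
        assert pairing["chr4:148413287-148413410"] == "rs6841581"
        assert pairing["chr20:17595355-17595478"] == "rs1132274"
        assert pairing["chr20:17595448-17595571"] == "rs1132274"

    def test_empty_region_set(self):
        report = overlap_report(load_risk_blocks(), IntervalSet())
        assert report.pairs.empty
        assert (report.n_regions_hit, report.n_blocks_hit) == (0, 0)

    def test_direction_carried_but_unused(self):
        region = MethylRegion(GenomicInterval("chr1", 0, 10), direction="hyper")
        assert region.direction == "hyper"
        with pytest.raises(ValueError):
            MethylRegion(GenomicInterval("chr1", 0, 10), direction="up")


class TestTwoGroupFTest:
    def test_equal_means_give_f_near_zero(self, nprng):
        base = nprng.normal(0, 1, size=(5, 12))
        base[:, 6:] = base[:, :6]  # identical groups
        result = two_group_f_test(_matrix(base, 6, 6))
        assert np.allclose(result["F"], 0.0)
        assert np.allclose(result["p_value"], 1.0)

    def test_matches_squared_t_statistic(self, nprng):
        values = nprng.normal(0, 1, size=(100, 14))
        values[:30, 7:] += nprng.uniform(0.5, 2.0, size=(30, 1))
        matrix = _matrix(values, 7, 7)
        result = two_group_f_test(matrix)
        t, p = stats.ttest_ind(values[:, 7:], values[:, :7], axis=1, equal_var=True)
        assert np.allclose(result["F"], t**2, rtol=1e-10)
        assert np.allclose(result["p_value"], p, rtol=1e-10)

    def test_degenerate_rows(self):
        values = np.zeros((2, 8))
        values[0, 4:] = 1.0  # zero variance, unequal means
        result = two_group_f_test(_matrix(values, 4, 4))
        assert result["p_value"].iloc[0] == 0.0
        assert result["p_value"].iloc[1] == 1.0

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(8)
        values = rng.normal(0, 0.5, size=(200, 20))
        values[:, 10:] += 2.0
        result = two_group_f_test(_matrix(values, 10, 10))
        assert (result["p_value"] < 0.001).mean() >= 0.95


class TestStoreyQvalues:
    def test_frozen_oracle(self):
        q = storey_qvalues(ORACLE_PS)
        assert np.allclose(q, ORACLE_QS, rtol=1e-12)

    def test_single_p(self):
        assert storey_qvalues([0.04]) == pytest.approx([0.04])

    def test_identical_ps(self):
        q = storey_qvalues([0.2] * 7)
        assert np.allclose(q, q[0])

    def test_empty(self):
        assert storey_qvalues([]).size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            storey_qvalues([0.5, 1.2])

    def test_reduces_to_benjamini_hochberg_when_pi0_is_one(self, nprng):
        # all p > lambda would force pi0 = 1; equivalently compare directly
        # against statsmodels BH on a p-set whose pi0_hat equals 1
        p = nprng.uniform(0.5, 1.0, size=40)
        from statsmodels.stats.multitest import multipletests

        _, q_bh, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(storey_qvalues(p), q_bh, rtol=1e-12)

    @given(st.permutations(list(range(10))))
    def test_permutation_equivariance(self, perm):
        base = np.array(ORACLE_PS)
        q_base = storey_qvalues(base)
        q_perm = storey_qvalues(base[perm])
        assert np.allclose(q_perm, q_base[perm])

    def test_monotone_in_p(self, nprng):
        p = nprng.uniform(0, 1, size=50)
        q = storey_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestDegFilter:
    def test_threshold_edges(self):
        # log2FC 1.32 (~2.5x) with tiny q kept; 0.85 (~1.8x) dropped
        rng = np.random.default_rng(3)
        values = rng.normal(0, 0.05, size=(60, 12))
        values[0, 6:] += 1.32
        values[1, 6:] += 0.85
        degs = deg_filter(_matrix(values, 6, 6))
        assert "g0" in degs.index
        assert "g1" not in degs.index

    def test_null_matrix_rarely_yields_degs(self):
        rng = np.random.default_rng(11)
        values = rng.normal(0, 0.5, size=(500, 20))
        degs = deg_filter(_matrix(values, 10, 10))
        assert len(degs) <= 2

    def test_shrinks_as_thresholds_tighten(self):
        rng = np.random.default_rng(5)
        values = rng.normal(0, 0.5, size=(300, 20))
        values[:40, 10:] += rng.uniform(0.8, 2.5, size=(40, 1))
        matrix = _matrix(values, 10, 10)
        loose = set(deg_filter(matrix, DEGCriteria(1.5, 0.2)).index)
        mid = set(deg_filter(matrix, DEGCriteria(2.0, 0.2)).index)
        tight = set(deg_filter(matrix, DEGCriteria(2.0, 0.01)).index)
        assert tight <= mid <= loose

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            DEGCriteria(fold_change_min=1.0)
        with pytest.raises(ValueError):
            DEGCriteria(q_max=0.0)


class TestExpressionMatrix:
    def test_requires_two_samples_per_group(self):
        values = pd.DataFrame(
            np.zeros((3, 3)), columns=["a", "b", "c"], index=["g1", "g2", "g3"]
        )
        groups = pd.Series(["control", "control", "case"], index=["a", "b", "c"])
        with pytest.raises(ValueError, match="case"):
            ExpressionMatrix(values, groups)

    def test_rejects_missing_values(self):
        values = pd.DataFrame(
            [[0.0, np.nan, 1.0, 2.0]], columns=list("abcd"), index=["g1"]
        )
        groups = pd.Series(["control", "control", "case", "case"], index=list("abcd"))
        with pytest.raises(ValueError, match="missing"):
            ExpressionMatrix(values, groups)


class TestDegLocusOverlap:
    annotation = [
        GeneRecord("COL1A2", GenomicInterval("chr7", 94043238, 94049356)),
        GeneRecord("FAR", GenomicInterval("chr7", 1_000_000, 1_010_000)),
    ]

    def test_empty_deg_list(self):
        hits, unmapped = deg_locus_overlap([], self.annotation, load_risk_blocks())
        assert hits.empty and unmapped == 0

    def test_gene_in_block_reported(self):
        hits, unmapped = deg_locus_overlap(
            ["COL1A2", "FAR"], self.annotation, load_risk_blocks()
        )
        assert list(hits.itertuples(index=False)) == [("COL1A2", "rs42524")]
        assert unmapped == 0

    def test_unmappable_gene_tallied(self):
        hits, unmapped = deg_locus_overlap(
            ["COL1A2", "NOWHERE"], self.annotation, load_risk_blocks()
        )
        assert len(hits) == 1 and unmapped == 1
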