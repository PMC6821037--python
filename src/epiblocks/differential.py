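"""Overlap screens against differential methylation/expression, and the DEG filter.

Two screens ask whether independently derived differential signals coincide
with the risk blocks: (1) differentially methylated regions (DMRs) from
tissue methylation arrays, as genomic intervals; (2) loci of differentially
expressed genes (DEGs). The DEG filter itself is the classic microarray
recipe: per-gene two-group F-test on log2 normalized expression, Storey
q-values for FDR control, and a fold-change cut — a gene survives with
|log2 fold change| > log2(2) and q < 0.05 by default (both strict).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .enrichment import ContingencyTable, RandomRegionConfig, build_contingency, fisher_exact
from .intervals import GenomicInterval, IntervalSet, which_queries_hit
from .risk_loci import GeneRecord, LDBlock

__all__ = [
    "MethylRegion",
    "ExpressionMatrix",
    "DEGCriteria",
    "load_dmr_fixture",
    "overlap_report",
    "OverlapReport",
    "two_group_f_test",
    "storey_qvalues",
    "deg_filter",
    "deg_locus_overlap",
]

DMR_FIXTURE = "ia_dmr_regions.tsv"


@dataclass(frozen=True)
class MethylRegion:
    """A differentially methylated interval; direction is carried, not used."""

    interval: GenomicInterval
    direction: str | None = None  # {"hyper", "hypo", None}

    def __post_init__(self) -> None:
        if self.direction not in (None, "hyper", "hypo"):
            raise ValueError(f"invalid direction {self.direction!r}")


class ExpressionMatrix:
    """Genes x samples matrix of log2 normalized expression with group labels."""

    def __init__(self, values: pd.DataFrame, groups: pd.Series):
        groups = groups.reindex(values.columns)
        if groups.isna().any():
            missing = list(groups.index[groups.isna()])
            raise ValueError(f"samples without group label: {missing}")
        bad = set(groups.unique()) - {"control", "case"}
        if bad:
            raise ValueError(f"group labels must be control/case, got {sorted(bad)}")
        if values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        for label in ("control", "case"):
            if (groups == label).sum() < 2:
                raise ValueError(f"need >= 2 samples in group {label!r}")
        self.values = values
        self.groups = groups

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def group_values(self, label: str) -> np.ndarray:
        return self.values.loc[:, self.groups == label].to_numpy(dtype=float)

    @classmethod
    def from_files(cls, matrix_path: str | Path, groups_path: str | Path) -> "ExpressionMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        groups = pd.read_csv(
            groups_path, sep="\t", index_col=0, comment="#"
        ).iloc[:, 0]
        return cls(values, groups)


@dataclass(frozen=True)
class DEGCriteria:
    """DEG thresholds: fold change (linear scale) and q-value bound."""

    fold_change_min: float = 2.0
    q_max: float = 0.05

    def __post_init__(self) -> None:
        if self.fold_change_min <= 1:
            raise ValueError("fold_change_min must be > 1")
        if not (0 < self.q_max < 1):
            raise ValueError("q_max must be in (0, 1)")


def load_dmr_fixture(source: str | Path | None = None) -> list[MethylRegion]:
    """Load DMRs from a TSV (1-based inclusive); default: the packaged set."""
    if source is None:
        source = Path(resources.files("epiblocks").joinpath("data", DMR_FIXTURE))
    table = pd.read_csv(source, sep="\t", comment="#", dtype={"chrom": str})
    out = []
    for row in table.itertuples(index=False):
        direction = getattr(row, "direction", None)
        out.append(
            MethylRegion(
                GenomicInterval(row.chrom, int(row.start) - 1, int(row.stop)),
                direction=None if direction in (None, "-") or pd.isna(direction) else direction,
            )
        )
    return out


@dataclass(frozen=True)
class OverlapReport:
    """Pairing of regions with the blocks they hit, plus summary counts."""

    pairs: pd.DataFrame  # columns: region, block_rsid
    n_regions: int
    n_regions_hit: int
    n_blocks_hit: int
    p_value: float | None = None
    table: ContingencyTable | None = None


def overlap_report(
    blocks: list[LDBlock],
    regions: IntervalSet,
    background: RandomRegionConfig | None = None,
    alternative: str = "two-sided",
) -> OverlapReport:
    """List every (region, block) overlap and summarize.

    When ``background`` is given, the same enrichment machinery used for
    peak tracks supplies a p-value: the regions play the role of the peak
    track, and block hits are compared with random-region hits.
    """
    rows = []
    hit_regions = set()
    hit_blocks = set()
    for region in regions:
        for block in blocks:
            if region.chrom == block.interval.chrom and max(
                region.start, block.interval.start
            ) < min(region.end, block.interval.end):
                rows.append(
                    {"region": region.span_1based(), "block_rsid": block.rsid}
                )
                hit_regions.add(region)
                hit_blocks.add(block.rsid)
    pairs = pd.DataFrame(rows, columns=["region", "block_rsid"])
    p_value = None
    table = None
    if background is not None:
        from .enrichment import generate_random_regions

        random_regions = generate_random_regions(background)
        table = build_contingency(blocks, random_regions, regions)
        p_value = fisher_exact(table, alternative=alternative)
    return OverlapReport(
        pairs=pairs,
        n_regions=len(regions),
        n_regions_hit=len(hit_regions),
        n_blocks_hit=len(hit_blocks),
        p_value=p_value,
        table=table,
    )


def two_group_f_test(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene one-way F statistic (case vs control) and upper-tail p.

    With two groups the statistic is the square of the equal-variance t
    statistic, so p-values coincide with the two-sided pooled t-test. Edge
    cases: zero within-group variance with unequal means -> p = 0; all
    values identical -> p = 1.
    """
    from scipy import stats

    x = matrix.group_values("control")
    y = matrix.group_values("case")
    n1, n2 = x.shape[1], y.shape[1]
    n = n1 + n2
    mean1, mean2 = x.mean(axis=1), y.mean(axis=1)
    grand = (n1 * mean1 + n2 * mean2) / n
    ss_between = n1 * (mean1 - grand) ** 2 + n2 * (mean2 - grand) ** 2
    ss_within = ((x - mean1[:, None]) ** 2).sum(axis=1) + (
        (y - mean2[:, None]) ** 2
    ).sum(axis=1)
    df_between, df_within = 1, n - 2
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within

    with np.errstate(divide="ignore", invalid="ignore"):
        f = ms_between / ms_within
    p = stats.f.sf(f, df_between, df_within)
    # degenerate rows: no within-group variance
    zero_within = ms_within == 0
    p[zero_within & (ss_between > 0)] = 0.0
    p[zero_within & (ss_between == 0)] = 1.0
    f[zero_within & (ss_between == 0)] = 0.0
    f[zero_within & (ss_between > 0)] = np.inf
    return pd.DataFrame({"F": f, "p_value": p}, index=matrix.genes)


def storey_qvalues(pvals: Sequence[float], lambda_: float = 0.5) -> np.ndarray:
    """Storey q-values with a single-lambda null-proportion estimate.

    pi0_hat = min(1, #{p > lambda} / ((1 - lambda) m)), floored at 1/m so a
    small set with every p below lambda (which would zero out all q-values)
    still assumes at least one null test. The q-value of the i-th ordered p
    is min over j >= i of pi0_hat * m * p_(j) / j. Output is returned in the
    original order. With pi0_hat forced to 1 this is exactly the
    Benjamini-Hochberg step-up q-value.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([])
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    pi0 = min(1.0, max((p > lambda_).sum() / ((1.0 - lambda_) * m), 1.0 / m))
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    ranks = np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate((pi0 * m * p_sorted / ranks)[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def deg_filter(
    matrix: ExpressionMatrix, criteria: DEGCriteria = DEGCriteria()
) -> pd.DataFrame:
    """Differentially expressed genes by fold change and Storey FDR.

    Fold change is the difference of group means on the log2 scale (the
    standard reading for RMA-style normalized microarray values). Both
    thresholds are strict: |log2FC| > log2(fold_change_min) AND q < q_max.
    Returns a table (gene, log2FC, F, p_value, q_value) of survivors.
    """
    tests = two_group_f_test(matrix)
    log2fc = matrix.group_values("case").mean(axis=1) - matrix.group_values(
        "control"
    ).mean(axis=1)
    q = storey_qvalues(tests["p_value"].to_numpy())
    full = tests.assign(log2FC=log2fc, q_value=q)
    keep = (np.abs(full["log2FC"]) > np.log2(criteria.fold_change_min)) & (
        full["q_value"] < criteria.q_max
    )
    return full.loc[keep, ["log2FC", "F", "p_value", "q_value"]]


def deg_locus_overlap(
    deg_genes: Sequence[str],
    annotation: list[GeneRecord],
    blocks: list[LDBlock],
) -> tuple[pd.DataFrame, int]:
    """Which DEG loci fall inside any risk block; unmappable genes are tallied.

    Genes without an annotation entry cannot be placed on the genome; they
    are excluded from the overlap screen and counted, mirroring the standard
    practice of reporting how many transcripts were dropped.
    """
    loci = {g.symbol: g.interval for g in annotation}
    block_set = IntervalSet([b.interval for b in blocks])
    rows = []
    n_unmapped = 0
    for gene in deg_genes:
        iv = loci.get(gene)
        if iv is None:
            n_unmapped += 1
            continue
        if block_set.overlaps_interval(iv):
            hits = [
                b.rsid
                for b in blocks
                if b.interval.chrom == iv.chrom
                and max(b.interval.start, iv.start) < min(b.interval.end, iv.end)
            ]
            for rsid in hits:
                rows.append({"gene": gene, "block_rsid": rsid})
    return pd.DataFrame(rows, columns=["gene", "block_rsid"]), n_unmapped
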