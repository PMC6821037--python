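"""Model/Results surface over the enrichment and expression machinery.

Two small model classes present the package's core computations the way
statistical modelling libraries do: construct a model object from data,
call ``fit()``, get a results object with estimates, uncertainties and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .differential import (
    DEGCriteria,
    ExpressionMatrix,
    deg_filter,
    storey_qvalues,
    two_group_f_test,
)
from .enrichment import (
    DEFAULT_N_REGIONS,
    DEFAULT_REGION_LENGTH,
    EnrichmentResult,
    RandomRegionConfig,
    enrichment_scan,
    results_to_frame,
)
from .intervals import ChromSizes, IntervalSet
from .presence import PresenceMatrix
from .risk_loci import LDBlock

__all__ = [
    "RegionEnrichment",
    "RegionEnrichmentResults",
    "TwoGroupExpression",
    "ExpressionResults",
]


class RegionEnrichment:
    """Enrichment of a region set for peak-track overlap vs a random background.

    Parameters
    ----------
    blocks
        The query regions (risk LD blocks).
    tracks
        Mapping ``(cell_type, feature) -> IntervalSet`` of peak tracks;
        ``None`` marks a track that does not exist for that cell type.
    chrom_sizes
        Genome the random background is drawn from.
    n_random, region_length
        Background sampler settings (defaults 10,000 regions of 32,312 bp).
    alternative
        ``"two-sided"`` (default) or ``"greater"``.
    alpha
        Significance level for flagging (default 0.05; no multiplicity
        correction — the result table carries the number of tests run).
    """

    def __init__(
        self,
        blocks: Sequence[LDBlock],
        tracks: Mapping[tuple[str, str], IntervalSet | None],
        chrom_sizes: ChromSizes,
        n_random: int = DEFAULT_N_REGIONS,
        region_length: int = DEFAULT_REGION_LENGTH,
        alternative: str = "two-sided",
        alpha: float = 0.05,
    ):
        self.blocks = list(blocks)
        self.tracks = dict(tracks)
        self.chrom_sizes = chrom_sizes
        self.n_random = n_random
        self.region_length = region_length
        self.alternative = alternative
        self.alpha = alpha

    def fit(self, seed: int | None = None) -> "RegionEnrichmentResults":
        config = RandomRegionConfig(
            chrom_sizes=self.chrom_sizes,
            n_regions=self.n_random,
            region_length=self.region_length,
            seed=seed,
        )
        results, presence = enrichment_scan(
            self.blocks,
            self.tracks,
            config,
            alpha=self.alpha,
            alternative=self.alternative,
        )
        return RegionEnrichmentResults(self, results, presence, seed)


@dataclass
class RegionEnrichmentResults:
    """Per-track contingency tables, Fisher p-values and the presence grid."""

    model: RegionEnrichment
    results: list[EnrichmentResult]
    presence: PresenceMatrix
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        return results_to_frame(self.results)

    def summary(self) -> str:
        frame = self.to_frame()
        for col in ("a_blocks_hit", "b_random_hit", "c_blocks_miss", "d_random_miss"):
            frame[col] = frame[col].map(
                lambda v: "-" if pd.isna(v) else str(int(v))
            )
        lines = [
            "Region-set enrichment vs random genomic background",
            f"  blocks: {len(self.model.blocks)}   random regions: "
            f"{self.model.n_random} x {self.model.region_length} bp   "
            f"alternative: {self.model.alternative}   alpha: {self.model.alpha}   "
            f"seed: {self.seed}",
            "",
            frame.to_string(
                index=False, na_rep="-", float_format=lambda v: f"{v:.3g}"
            ),
        ]
        return "\n".join(lines)

    def plot_presence(self, ax=None):
        return self.presence.plot(ax=ax)


class TwoGroupExpression:
    """Two-group differential expression on a log2 normalized matrix.

    ``fit()`` runs the per-gene F-test (equivalent to the pooled two-sample
    t-test squared), Storey q-values, and log2 fold changes; the results
    object applies DEG thresholds.
    """

    def __init__(self, matrix: ExpressionMatrix):
        self.matrix = matrix

    @classmethod
    def from_dataframe(cls, values: pd.DataFrame, groups: pd.Series) -> "TwoGroupExpression":
        return cls(ExpressionMatrix(values, groups))

    def fit(self) -> "ExpressionResults":
        tests = two_group_f_test(self.matrix)
        log2fc = self.matrix.group_values("case").mean(axis=1) - self.matrix.group_values(
            "control"
        ).mean(axis=1)
        q = storey_qvalues(tests["p_value"].to_numpy())
        table = tests.assign(log2FC=log2fc, q_value=q)[
            ["log2FC", "F", "p_value", "q_value"]
        ]
        return ExpressionResults(self, table)


@dataclass
class ExpressionResults:
    model: TwoGroupExpression
    table: pd.DataFrame  # per gene: log2FC, F, p_value, q_value

    def degs(self, criteria: DEGCriteria = DEGCriteria()) -> pd.DataFrame:
        keep = (np.abs(self.table["log2FC"]) > np.log2(criteria.fold_change_min)) & (
            self.table["q_value"] < criteria.q_max
        )
        return self.table.loc[keep]

    def summary(self, criteria: DEGCriteria = DEGCriteria()) -> str:
        n = len(self.table)
        degs = self.degs(criteria)
        groups = self.model.matrix.groups
        lines = [
            "Two-group differential expression (F-test + Storey FDR)",
            f"  genes: {n}   samples: {int((groups == 'control').sum())} control / "
            f"{int((groups == 'case').sum())} case",
            f"  DEG criteria: fold change > {criteria.fold_change_min} "
            f"and q < {criteria.q_max}",
            f"  DEGs: {len(degs)}",
            "",
            degs.head(20).to_string(float_format=lambda v: f"{v:.3g}"),
        ]
        return "\n".join(lines)
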