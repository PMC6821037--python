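"""Risk-SNP / LD-block data model and the packaged risk-locus table.

An LD (linkage disequilibrium) block is the haplotype region of variants
correlated (r^2 >= threshold, default 0.9) with an index GWAS SNP; the causal
variant may lie anywhere within it, so all downstream annotation treats the
whole block as the unit of analysis. The packaged table carries the 16
intracranial-aneurysm risk blocks (GRCh37) used throughout the package's
worked analyses; any user table with the same columns is accepted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .intervals import ChromSizes, GenomicInterval, IntervalSet

__all__ = [
    "RiskSNP",
    "LDBlock",
    "GeneRecord",
    "load_risk_blocks",
    "mean_block_length",
    "extend_around_snps",
    "genes_in_regions",
]

_RSID_RE = re.compile(r"^rs\d+$")
_LOCATION_CLASSES = {"exonic", "intronic", "intergenic"}

RISK_BLOCK_FIXTURE = "ia_risk_ld_blocks.tsv"


@dataclass(frozen=True)
class RiskSNP:
    """An index GWAS SNP tagging a risk haplotype."""

    rsid: str
    chrom: str | None = None
    position: int | None = None  # 1-based coordinate when known
    location_class: str | None = None
    nearest_gene: str | None = None

    def __post_init__(self) -> None:
        if not _RSID_RE.match(self.rsid):
            raise ValueError(f"invalid rsid: {self.rsid!r}")
        if self.location_class is not None and self.location_class not in _LOCATION_CLASSES:
            raise ValueError(
                f"location_class must be one of {sorted(_LOCATION_CLASSES)}, "
                f"got {self.location_class!r}"
            )


@dataclass(frozen=True)
class LDBlock:
    """A risk haplotype region tagged with its index SNP."""

    interval: GenomicInterval
    snp: RiskSNP
    r2_threshold: float = 0.9

    def __post_init__(self) -> None:
        if not (0 < self.r2_threshold <= 1):
            raise ValueError(f"r2_threshold must be in (0, 1], got {self.r2_threshold}")
        if self.snp.position is not None and self.snp.chrom is not None:
            pos0 = self.snp.position - 1
            inside = (
                self.snp.chrom == self.interval.chrom
                and self.interval.start <= pos0 < self.interval.end
            )
            if not inside:
                raise ValueError(
                    f"SNP {self.snp.rsid} at {self.snp.chrom}:{self.snp.position} "
                    f"lies outside its block {self.interval.span_1based()}"
                )

    @property
    def rsid(self) -> str:
        return self.snp.rsid


@dataclass(frozen=True)
class GeneRecord:
    symbol: str
    interval: GenomicInterval
    coding: bool = True


def _fixture_path() -> Path:
    return Path(resources.files("epiblocks").joinpath("data", RISK_BLOCK_FIXTURE))


def load_risk_blocks(source: str | Path | None = None, r2_threshold: float = 0.9) -> list[LDBlock]:
    """Load LD blocks from a TSV (1-based inclusive start/stop).

    With ``source=None`` the packaged intracranial-aneurysm table is used,
    yielding the 16 blocks with their printed coordinates. Required columns:
    ``rsid, chrom, start, stop``; optional ``location_class, nearest_gene``
    ("-" means none). Duplicate rsids and inverted coordinates are errors.
    """
    path = _fixture_path() if source is None else Path(source)
    table = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    required = {"rsid", "chrom", "start", "stop"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"risk-block table missing columns: {sorted(missing)}")
    if table.empty:
        return []
    if table["rsid"].duplicated().any():
        dupes = table.loc[table["rsid"].duplicated(), "rsid"].tolist()
        raise ValueError(f"duplicate rsid(s) in risk-block table: {dupes}")

    blocks: list[LDBlock] = []
    for row in table.itertuples(index=False):
        start_1, stop_1 = int(row.start), int(row.stop)
        if start_1 >= stop_1:
            raise ValueError(f"{row.rsid}: start {start_1} >= stop {stop_1}")
        loc = getattr(row, "location_class", None)
        gene = getattr(row, "nearest_gene", None)
        snp = RiskSNP(
            rsid=row.rsid,
            chrom=row.chrom,
            location_class=None if loc in (None, "-") or pd.isna(loc) else str(loc).lower(),
            nearest_gene=None if gene in (None, "-") or pd.isna(gene) else str(gene),
        )
        interval = GenomicInterval(row.chrom, start_1 - 1, stop_1, name=row.rsid)
        blocks.append(LDBlock(interval=interval, snp=snp, r2_threshold=r2_threshold))
    return blocks


def mean_block_length(blocks: list[LDBlock]) -> int:
    """Mean block span in bp, rounded to the nearest integer.

    Length is the half-open ``end - start`` of the internal form, i.e. the
    inclusive span ``stop - start + 1`` of the printed 1-based coordinates.
    """
    if not blocks:
        raise ValueError("mean_block_length of an empty block list")
    total = sum(b.interval.length for b in blocks)
    return round(total / len(blocks))


def extend_around_snps(
    blocks: list[LDBlock], flank: int, chrom_sizes: ChromSizes
) -> IntervalSet:
    """One interval per block: the SNP anchor +/- ``flank`` bp, clipped.

    The anchor is the SNP position when the table supplies one; otherwise the
    block midpoint (a deterministic, documented fallback — the printed risk
    table gives block spans, not SNP coordinates). The result spans
    ``[anchor - flank, anchor + flank]`` inclusive of the anchor base, so an
    unclipped interval has length ``2 * flank + 1``.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    out = []
    for block in blocks:
        iv = block.interval
        if iv.chrom not in chrom_sizes:
            raise KeyError(f"chromosome {iv.chrom!r} not in chrom sizes")
        if block.snp.position is not None:
            anchor = block.snp.position - 1
        else:
            anchor = (iv.start + iv.end) // 2
        start = max(0, anchor - flank)
        end = min(chrom_sizes[iv.chrom], anchor + flank + 1)
        out.append(GenomicInterval(iv.chrom, start, end, name=block.rsid))
    return IntervalSet(out)


def genes_in_regions(regions: IntervalSet, annotation: list[GeneRecord]) -> list[str]:
    """Deduplicated, sorted symbols of genes overlapping any region.

    This list is the deliverable handed to external ontology tools; the
    enrichment query itself happens outside the package.
    """
    hits = {
        gene.symbol
        for gene in annotation
        if regions.overlaps_interval(gene.interval)
    }
    return sorted(hits)
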