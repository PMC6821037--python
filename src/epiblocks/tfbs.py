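"""Promoter/distal classification of TF binding sites in marked block segments.

A TF ChIP-seq site is a "promoter" site when it overlaps the window from
5 kb upstream to 1 kb downstream of any transcription start site (TSS),
measured along the gene's strand; everything else is "distal". Distal sites
inside enhancer-marked (H3K4me1/H3K27ac) segments of risk blocks are the
signature of distal regulatory activity; promoter sites suggest the risk
region overlaps transcription machinery directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .intervals import GenomicInterval, IntervalSet, intersect_regions, overlaps
from .risk_loci import LDBlock

__all__ = [
    "TSSRecord",
    "TFBindingSite",
    "PromoterWindowRule",
    "promoter_window",
    "classify_site",
    "tf_block_summary",
    "summary_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TSSRecord:
    """A stranded transcription start site (0-based internal coordinate)."""

    chrom: str
    position: int
    strand: str | None = "+"
    gene: str | None = None

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError("TSS position must be >= 0")
        if self.strand not in ("+", "-", None):
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class TFBindingSite:
    tf: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if not self.tf:
            raise ValueError("tf name must be non-empty")


@dataclass(frozen=True)
class PromoterWindowRule:
    """TSS window defining promoter territory: upstream/downstream in bp."""

    upstream: int = 5_000
    downstream: int = 1_000

    def __post_init__(self) -> None:
        if self.upstream < 0 or self.downstream < 0:
            raise ValueError("window extents must be >= 0")


def promoter_window(tss: TSSRecord, rule: PromoterWindowRule) -> GenomicInterval | None:
    """The promoter interval around a TSS, oriented by strand, clipped at 0.

    Plus strand: ``[position - upstream, position + downstream)``; minus
    strand mirrors it. Unstranded records fall back to the plus-strand rule
    (logged once per call site): "upstream" is undefined without a strand.
    A degenerate rule (window covering no base after clipping) yields None.
    """
    strand = tss.strand
    if strand is None:
        logger.warning(
            "TSS %s at %s:%d has no strand; applying the + strand window rule",
            tss.gene or "?",
            tss.chrom,
            tss.position,
        )
        strand = "+"
    if strand == "+":
        start, end = tss.position - rule.upstream, tss.position + rule.downstream
    else:
        start, end = tss.position - rule.downstream, tss.position + rule.upstream
    start = max(0, start)
    if end <= start:
        return None
    return GenomicInterval(tss.chrom, start, end, name=tss.gene)


def classify_site(
    site: TFBindingSite,
    tss_set: Iterable[TSSRecord],
    rule: PromoterWindowRule = PromoterWindowRule(),
) -> str:
    """``"promoter"`` iff the site overlaps >= 1 TSS window, else ``"distal"``.

    An empty TSS catalogue makes every site distal.
    """
    for tss in tss_set:
        if tss.chrom != site.interval.chrom:
            continue
        window = promoter_window(tss, rule)
        if window is not None and overlaps(site.interval, window):
            return "promoter"
    return "distal"


def tf_block_summary(
    blocks: list[LDBlock],
    histone_marked: IntervalSet,
    tf_tracks: Mapping[str, IntervalSet],
    tss_set: Iterable[TSSRecord],
    rule: PromoterWindowRule = PromoterWindowRule(),
    both_marks: IntervalSet | None = None,
) -> dict[str, dict[str, dict[str, bool]]]:
    """Per-block, per-TF presence of distal/promoter sites in marked segments.

    ``histone_marked`` is the union of enhancer-mark peak segments (e.g.
    H3K4me1 plus H3K27ac); ``both_marks`` optionally carries the subset of
    segments bearing both marks, so each call can be flagged as sitting in a
    doubly-marked segment. For every block, each TF track is restricted to
    the histone-marked portion of the block; each surviving (clipped) site is
    classified promoter/distal against the TSS windows. Blocks whose marked
    portion contains no sites yield an empty row.

    Returns ``{rsid: {tf: {"distal": bool, "promoter": bool,
    "distal_both_marks": bool, "promoter_both_marks": bool}}}``.
    """
    tss_list = list(tss_set)
    summary: dict[str, dict[str, dict[str, bool]]] = {}
    for block in blocks:
        block_set = IntervalSet([block.interval])
        marked_in_block = intersect_regions(block_set, histone_marked)
        row: dict[str, dict[str, bool]] = {}
        if marked_in_block:
            for tf, track in tf_tracks.items():
                surviving = intersect_regions(track, marked_in_block)
                for fragment in surviving:
                    call = classify_site(TFBindingSite(tf, fragment), tss_list, rule)
                    entry = row.setdefault(
                        tf,
                        {
                            "distal": False,
                            "promoter": False,
                            "distal_both_marks": False,
                            "promoter_both_marks": False,
                        },
                    )
                    entry[call] = True
                    if both_marks is not None and both_marks.overlaps_interval(fragment):
                        entry[f"{call}_both_marks"] = True
        summary[block.rsid] = row
    return summary


def summary_to_frame(summary: dict[str, dict[str, dict[str, bool]]]) -> pd.DataFrame:
    """Flatten a block summary into a table with comma-joined TF lists.

    TFs whose call came from a doubly-marked (H3K4me1 + H3K27ac) segment are
    suffixed with ``*``; ``-`` marks an empty cell.
    """

    def _cell(row: dict[str, dict[str, bool]], kind: str) -> str:
        tfs = []
        for tf in sorted(row):
            if row[tf][kind]:
                star = "*" if row[tf][f"{kind}_both_marks"] else ""
                tfs.append(tf + star)
        return ",".join(tfs) if tfs else "-"

    records = [
        {"rsid": rsid, "distal": _cell(row, "distal"), "promoter": _cell(row, "promoter")}
        for rsid, row in summary.items()
    ]
    return pd.DataFrame(records).set_index("rsid")
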