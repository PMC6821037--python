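"""Loaders for the packaged result-table fixtures.

Besides the risk-block and DMR tables (see :mod:`epiblocks.risk_loci` and
:mod:`epiblocks.differential`), the package ships the published per-block
presence calls for histone marks and CTCF and the per-block TF binding-site
calls, so the summary/counting code paths can be exercised against known
printed results without any peak downloads.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .presence import PresenceMatrix
from .risk_loci import load_risk_blocks

__all__ = [
    "load_histone_presence",
    "load_ctcf_presence",
    "load_tfbs_calls",
    "tfbs_column_counts",
]


def _data_path(name: str) -> Path:
    return Path(resources.files("epiblocks").joinpath("data", name))


def _load_presence(name: str) -> PresenceMatrix:
    matrix = PresenceMatrix.from_tsv(_data_path(name))
    spans = {b.rsid: b.interval.span_1based() for b in load_risk_blocks()}
    matrix.block_spans.update(spans)
    return matrix


def load_histone_presence() -> PresenceMatrix:
    """H3K4me1/H3K27ac presence per block across four cell types."""
    return _load_presence("histone_presence.tsv")


def load_ctcf_presence() -> PresenceMatrix:
    """CTCF binding-site presence per block (endothelial cells, monocytes)."""
    return _load_presence("ctcf_presence.tsv")


def load_tfbs_calls() -> pd.DataFrame:
    """Per-block distal/promoter TF call table (``-`` = none, ``*`` = both marks)."""
    return pd.read_csv(_data_path("tfbs_calls.tsv"), sep="\t", comment="#", index_col="rsid")


def _parse_cell(cell: str) -> list[tuple[str, bool]]:
    if cell == "-" or pd.isna(cell):
        return []
    out = []
    for token in str(cell).split(","):
        token = token.strip()
        both = token.endswith("*")
        out.append((token.rstrip("*"), both))
    return out


def tfbs_column_counts(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-TF block counts: distal, promoter, and distal-or-promoter."""
    tfs: dict[str, dict[str, set]] = {}
    for rsid, row in calls.iterrows():
        for kind in ("distal", "promoter"):
            for tf, _both in _parse_cell(row[kind]):
                entry = tfs.setdefault(tf, {"distal": set(), "promoter": set()})
                entry[kind].add(rsid)
    records = []
    for tf in sorted(tfs):
        d, p = tfs[tf]["distal"], tfs[tf]["promoter"]
        records.append(
            {
                "tf": tf,
                "distal_blocks": len(d),
                "promoter_blocks": len(p),
                "distal_or_promoter_blocks": len(d | p),
            }
        )
    return pd.DataFrame(records).set_index("tf")
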