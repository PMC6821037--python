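"""End-to-end pipeline orchestration, report tables, and the run manifest.

``run_pipeline`` executes whichever stages the run configuration enables —
peak-track enrichment, TF-site classification, methylation-region overlap,
and the DEG filter plus DEG-locus overlap — and writes plain-text (TSV)
report tables plus a JSON manifest carrying the seed, all parameters, input
checksums and the package version, enough to reproduce the run exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .differential import (
    DEGCriteria,
    ExpressionMatrix,
    deg_filter,
    deg_locus_overlap,
    overlap_report,
)
from .enrichment import RandomRegionConfig, enrichment_scan, results_to_frame
from .intervals import ChromSizes, IntervalSet, read_bed
from .risk_loci import GeneRecord, LDBlock, load_risk_blocks
from .tfbs import PromoterWindowRule, TSSRecord, summary_to_frame, tf_block_summary

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is recorded on the instance."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Validated run settings; every referenced file must exist at run start."""

    output_dir: Path
    chrom_sizes: Path
    blocks: Path | None = None  # None -> packaged risk-block table
    tracks: dict[tuple[str, str], Path | None] = field(default_factory=dict)
    n_random: int = 10_000
    region_length: int = 32_312
    seed: int | None = None
    alpha: float = 0.05
    alternative: str = "two-sided"
    exclude_regions: Path | None = None
    # TF classification stage
    tfbs_tracks: dict[str, Path] = field(default_factory=dict)
    tss: Path | None = None
    histone_marked: Path | None = None
    both_marks: Path | None = None
    promoter_upstream: int = 5_000
    promoter_downstream: int = 1_000
    # differential stages
    methylation: Path | None = None
    methylation_one_based: bool = False
    expression: Path | None = None
    groups: Path | None = None
    fold_change_min: float = 2.0
    q_max: float = 0.05
    gene_annotation: Path | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = Path(path).parent

        def _p(value):
            return None if value is None else (base / value if not Path(value).is_absolute() else Path(value))

        tracks = {}
        for cell_type, features in (raw.get("tracks") or {}).items():
            for feature, track_path in (features or {}).items():
                tracks[(cell_type, feature)] = _p(track_path)
        tfbs = raw.get("tfbs") or {}
        expression = raw.get("expression") or {}
        config = cls(
            output_dir=_p(raw["output_dir"]),
            chrom_sizes=_p(raw["chrom_sizes"]),
            blocks=_p(raw.get("blocks")),
            tracks=tracks,
            n_random=int(raw.get("n_random", 10_000)),
            region_length=int(raw.get("region_length", 32_312)),
            seed=raw.get("seed"),
            alpha=float(raw.get("alpha", 0.05)),
            alternative=raw.get("alternative", "two-sided"),
            exclude_regions=_p(raw.get("exclude_regions")),
            tfbs_tracks={tf: _p(p) for tf, p in (tfbs.get("tracks") or {}).items()},
            tss=_p(tfbs.get("tss")),
            histone_marked=_p(tfbs.get("histone_marked")),
            both_marks=_p(tfbs.get("both_marks")),
            promoter_upstream=int(tfbs.get("upstream", 5_000)),
            promoter_downstream=int(tfbs.get("downstream", 1_000)),
            methylation=_p(raw.get("methylation")),
            methylation_one_based=bool(raw.get("methylation_one_based", False)),
            expression=_p(expression.get("matrix")),
            groups=_p(expression.get("groups")),
            fold_change_min=float(expression.get("fold_change_min", 2.0)),
            q_max=float(expression.get("q_max", 0.05)),
            gene_annotation=_p(raw.get("gene_annotation")),
        )
        config.validate()
        return config

    def input_paths(self) -> dict[str, Path]:
        paths: dict[str, Path] = {"chrom_sizes": self.chrom_sizes}
        if self.blocks:
            paths["blocks"] = self.blocks
        for (cell, feat), p in self.tracks.items():
            if p is not None:
                paths[f"track:{cell}:{feat}"] = p
        for tf, p in self.tfbs_tracks.items():
            paths[f"tf:{tf}"] = p
        for label in (
            "tss",
            "histone_marked",
            "both_marks",
            "methylation",
            "expression",
            "groups",
            "gene_annotation",
            "exclude_regions",
        ):
            p = getattr(self, label)
            if p is not None:
                paths[label] = p
        return paths

    def validate(self) -> None:
        missing = [str(p) for p in self.input_paths().values() if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _read_tss(path: Path) -> list[TSSRecord]:
    """TSS records from BED6 (position = start for +, end-1 for -)."""
    records = []
    for iv in read_bed(path):
        if iv.strand == "-":
            pos = iv.end - 1
        else:
            pos = iv.start
        records.append(TSSRecord(iv.chrom, pos, iv.strand or None, gene=iv.name))
    return records


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run all configured stages; returns the mapping of output names to paths.

    On a stage failure the outputs written so far are retained, a ``FAILED``
    marker naming the stage is left in the output directory, and a
    :class:`PipelineError` is raised.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stage = "setup"
    try:
        chrom_sizes = ChromSizes.from_file(config.chrom_sizes)
        blocks = load_risk_blocks(config.blocks)

        if config.tracks:
            stage = "enrichment"
            logger.info("enrichment scan over %d tracks", len(config.tracks))
            tracks = {
                key: (None if p is None else read_bed(p))
                for key, p in config.tracks.items()
            }
            exclude = (
                read_bed(config.exclude_regions) if config.exclude_regions else None
            )
            rr_config = RandomRegionConfig(
                chrom_sizes=chrom_sizes,
                n_regions=config.n_random,
                region_length=config.region_length,
                seed=config.seed,
                exclude=exclude,
            )
            results, presence = enrichment_scan(
                blocks, tracks, rr_config, alpha=config.alpha, alternative=config.alternative
            )
            outputs["enrichment_results"] = outdir / "enrichment_results.tsv"
            results_to_frame(results).to_csv(
                outputs["enrichment_results"], sep="\t", index=False
            )
            outputs["presence_matrix"] = outdir / "presence_matrix.tsv"
            presence.to_tsv(outputs["presence_matrix"])

        if config.tfbs_tracks:
            stage = "tfbs_classification"
            logger.info("TF classification over %d factors", len(config.tfbs_tracks))
            if config.histone_marked is None or config.tss is None:
                raise ValueError("tfbs stage needs histone_marked and tss inputs")
            summary = tf_block_summary(
                blocks,
                read_bed(config.histone_marked),
                {tf: read_bed(p) for tf, p in config.tfbs_tracks.items()},
                _read_tss(config.tss),
                PromoterWindowRule(config.promoter_upstream, config.promoter_downstream),
                both_marks=read_bed(config.both_marks) if config.both_marks else None,
            )
            outputs["tfbs_summary"] = outdir / "tfbs_summary.tsv"
            summary_to_frame(summary).to_csv(outputs["tfbs_summary"], sep="\t")

        if config.methylation:
            stage = "methylation_overlap"
            regions = read_bed(config.methylation, one_based=config.methylation_one_based)
            background = RandomRegionConfig(
                chrom_sizes=chrom_sizes,
                n_regions=config.n_random,
                region_length=config.region_length,
                seed=config.seed,
            )
            report = overlap_report(blocks, regions, background=background,
                                    alternative=config.alternative)
            outputs["methylation_pairs"] = outdir / "methylation_overlap_pairs.tsv"
            report.pairs.to_csv(outputs["methylation_pairs"], sep="\t", index=False)
            outputs["methylation_summary"] = outdir / "methylation_overlap_summary.tsv"
            pd.DataFrame(
                [
                    {
                        "n_regions": report.n_regions,
                        "n_regions_hit": report.n_regions_hit,
                        "n_blocks_hit": report.n_blocks_hit,
                        "p_value": report.p_value,
                    }
                ]
            ).to_csv(outputs["methylation_summary"], sep="\t", index=False)

        if config.expression:
            stage = "deg_filter"
            if config.groups is None:
                raise ValueError("expression stage needs a groups file")
            matrix = ExpressionMatrix.from_files(config.expression, config.groups)
            criteria = DEGCriteria(config.fold_change_min, config.q_max)
            degs = deg_filter(matrix, criteria)
            outputs["deg_table"] = outdir / "deg_table.tsv"
            degs.to_csv(outputs["deg_table"], sep="\t", index_label="gene")
            if config.gene_annotation:
                stage = "deg_locus_overlap"
                annotation = [
                    GeneRecord(symbol=iv.name or f"gene_{i}", interval=iv)
                    for i, iv in enumerate(read_bed(config.gene_annotation))
                ]
                hits, n_unmapped = deg_locus_overlap(
                    list(degs.index), annotation, blocks
                )
                outputs["deg_block_hits"] = outdir / "deg_block_hits.tsv"
                hits.to_csv(outputs["deg_block_hits"], sep="\t", index=False)
                outputs["deg_overlap_summary"] = outdir / "deg_overlap_summary.tsv"
                pd.DataFrame(
                    [
                        {
                            "n_degs": len(degs),
                            "n_unmappable": n_unmapped,
                            "n_hits": len(hits),
                        }
                    ]
                ).to_csv(outputs["deg_overlap_summary"], sep="\t", index=False)

        stage = "manifest"
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "parameters": {
                "n_random": config.n_random,
                "region_length": config.region_length,
                "alpha": config.alpha,
                "alternative": config.alternative,
                "promoter_upstream": config.promoter_upstream,
                "promoter_downstream": config.promoter_downstream,
                "fold_change_min": config.fold_change_min,
                "q_max": config.q_max,
            },
            "inputs": {
                name: {"path": str(p), "sha256": _sha256(Path(p))}
                for name, p in config.input_paths().items()
            },
            "outputs": {name: str(p) for name, p in outputs.items()},
        }
        outputs["manifest"] = outdir / "manifest.json"
        with open(outputs["manifest"], "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        logger.error("pipeline failed at stage %s: %s", stage, exc)
        raise PipelineError(stage, exc) from exc
    return outputs
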