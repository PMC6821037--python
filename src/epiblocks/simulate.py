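"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates, at desk scale, the kinds of data the pipeline
consumes: peak tracks laid down as a Poisson process with an elevated rate
inside designated risk blocks, stranded TSS catalogues, methylation-region
sets with a controlled in-block fraction, and a two-group log2 expression
matrix with a planted fraction of true DEGs. Ground-truth labels ride along
with every dataset so recall, FDR and power are computable without
re-deriving the truth.

The default toy genome is three chromosomes (50, 30, 20 Mb) carrying 16
non-overlapping risk blocks whose lengths are the real risk-block spectrum
(a few kb to ~90 kb), placed deterministically. Defaults for the expression
generator (2,000 genes, 10 samples per group, 5% planted DEGs with a 2-unit
log2 shift, noise sd 0.5) are the fixed simulation regime used by the
calibration and power checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import ChromSizes, GenomicInterval, IntervalSet, write_bed
from .risk_loci import LDBlock, RiskSNP, load_risk_blocks
from .tfbs import TSSRecord

__all__ = [
    "SimulationConfig",
    "toy_chrom_sizes",
    "toy_risk_blocks",
    "simulate_peaks",
    "simulate_tss",
    "simulate_methylation",
    "simulate_expression",
    "write_bundle",
]


def toy_chrom_sizes() -> ChromSizes:
    """Three-chromosome desk-scale genome: 50 + 30 + 20 Mb."""
    return ChromSizes({"chr1": 50_000_000, "chr2": 30_000_000, "chr3": 20_000_000})


def toy_risk_blocks() -> list[LDBlock]:
    """16 synthetic risk blocks with the real block-length spectrum.

    Lengths are taken from the packaged risk-block table; placement is
    deterministic (evenly spaced anchors, 8 blocks on chr1, 5 on chr2, 3 on
    chr3), so every run sees the same blocks without a seed.
    """
    lengths = [b.interval.length for b in load_risk_blocks()]
    layout = [("chr1", 8, 5_000_000), ("chr2", 5, 5_000_000), ("chr3", 3, 5_500_000)]
    blocks: list[LDBlock] = []
    i = 0
    for chrom, count, spacing in layout:
        for k in range(count):
            start = (k + 1) * spacing
            blocks.append(
                LDBlock(
                    interval=GenomicInterval(
                        chrom, start, start + lengths[i], name=f"rs9{i + 1:05d}"
                    ),
                    snp=RiskSNP(rsid=f"rs9{i + 1:05d}"),
                )
            )
            i += 1
    return blocks


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for every generator; defaults are the fixed study conditions."""

    chrom_sizes: ChromSizes = field(default_factory=toy_chrom_sizes)
    risk_blocks: tuple[LDBlock, ...] = field(
        default_factory=lambda: tuple(toy_risk_blocks())
    )
    peak_rate: float = 30.0  # peaks per Mb, background
    enrichment_factor: float = 1.0  # rate multiplier inside risk blocks
    peak_length: int | tuple[int, int] = 600  # bp, fixed or (min, max) uniform
    n_tss: int = 300
    n_genes: int = 2_000
    n_samples_per_group: int = 10
    deg_fraction: float = 0.05
    log2fc_effect: float = 2.0
    noise_sd: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.peak_rate < 0 or self.enrichment_factor < 0:
            raise ValueError("peak_rate and enrichment_factor must be >= 0")
        if not (0 <= self.deg_fraction <= 1):
            raise ValueError("deg_fraction must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


def _block_segments(config: SimulationConfig) -> dict[str, list[tuple[int, int, bool]]]:
    """Partition each chromosome into (start, end, inside_block) segments."""
    by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in config.chrom_sizes}
    for block in config.risk_blocks:
        by_chrom.setdefault(block.interval.chrom, []).append(
            (block.interval.start, block.interval.end)
        )
    segments: dict[str, list[tuple[int, int, bool]]] = {}
    for chrom, size in config.chrom_sizes.items():
        merged: list[tuple[int, int]] = []
        for start, end in sorted(by_chrom.get(chrom, [])):
            if merged and start <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], end))
            else:
                merged.append((start, end))
        segs: list[tuple[int, int, bool]] = []
        cursor = 0
        for start, end in merged:
            if start > cursor:
                segs.append((cursor, start, False))
            segs.append((start, min(end, size), True))
            cursor = min(end, size)
        if cursor < size:
            segs.append((cursor, size, False))
        segments[chrom] = segs
    return segments


def _draw_lengths(rng: np.random.Generator, spec, n: int) -> np.ndarray:
    if isinstance(spec, tuple):
        lo, hi = spec
        return rng.integers(lo, hi + 1, size=n)
    return np.full(n, int(spec), dtype=np.int64)


def simulate_peaks(config: SimulationConfig) -> tuple[IntervalSet, dict]:
    """Poisson peak placement with an elevated rate inside risk blocks.

    Peak midpoints follow a piecewise-homogeneous Poisson process: rate
    ``peak_rate`` per Mb outside risk blocks, ``peak_rate x
    enrichment_factor`` inside. Peaks extend half a length either side of
    the midpoint, clipped to the chromosome. Names encode the origin
    (``bg_*`` / ``risk_*``); truth counts come back alongside the set.
    """
    rng = np.random.default_rng(config.seed)
    out: list[GenomicInterval] = []
    n_inside = n_outside = 0
    for chrom, segs in _block_segments(config).items():
        size = config.chrom_sizes[chrom]
        for start, end, inside in segs:
            rate = config.peak_rate * (config.enrichment_factor if inside else 1.0)
            expected = rate * (end - start) / 1e6
            count = rng.poisson(expected) if expected > 0 else 0
            if count == 0:
                continue
            mids = rng.integers(start, end, size=count)
            lengths = _draw_lengths(rng, config.peak_length, count)
            for j, (mid, length) in enumerate(zip(mids, lengths)):
                s = max(0, int(mid) - int(length) // 2)
                e = min(size, s + int(length))
                tag = "risk" if inside else "bg"
                if inside:
                    n_inside += 1
                else:
                    n_outside += 1
                out.append(GenomicInterval(chrom, s, e, name=f"{tag}_{chrom}_{start}_{j}"))
    truth = {"n_inside": n_inside, "n_outside": n_outside}
    return IntervalSet(out), truth


def simulate_tss(config: SimulationConfig) -> list[TSSRecord]:
    """Uniformly placed stranded TSSs (fair-coin strand), seeded."""
    rng = np.random.default_rng(None if config.seed is None else config.seed + 1)
    chroms = list(config.chrom_sizes)
    sizes = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    records = []
    chosen = rng.choice(len(chroms), size=config.n_tss, p=probs)
    for i, ci in enumerate(chosen):
        pos = int(rng.integers(0, int(sizes[ci])))
        strand = "+" if rng.random() < 0.5 else "-"
        records.append(TSSRecord(chroms[ci], pos, strand, gene=f"GENE{i + 1}"))
    return records


def simulate_methylation(
    config: SimulationConfig,
    n_regions: int,
    fraction_in_blocks: float,
    region_length: int = 125,
) -> tuple[IntervalSet, dict]:
    """Methylation-style regions with a controlled in-block fraction.

    Exactly ``round(n_regions * fraction_in_blocks)`` regions are placed
    fully inside (uniformly chosen) risk blocks; the rest land uniformly on
    the genome and are re-drawn until they are disjoint from every block, so
    the in/out counts are exact for any seed.
    """
    if not (0 <= fraction_in_blocks <= 1):
        raise ValueError("fraction_in_blocks must be in [0, 1]")
    rng = np.random.default_rng(None if config.seed is None else config.seed + 2)
    n_in = round(n_regions * fraction_in_blocks)
    blocks = [b.interval for b in config.risk_blocks if b.interval.length >= region_length]
    if n_in > 0 and not blocks:
        raise ValueError("no risk block can contain a region of the requested length")
    out: list[GenomicInterval] = []
    for i in range(n_in):
        block = blocks[int(rng.integers(0, len(blocks)))]
        s = int(rng.integers(block.start, block.end - region_length + 1))
        out.append(GenomicInterval(block.chrom, s, s + region_length, name=f"dmr_in_{i}"))
    chroms = list(config.chrom_sizes)
    sizes = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    all_blocks = IntervalSet([b.interval for b in config.risk_blocks])
    for i in range(n_regions - n_in):
        while True:
            ci = int(rng.choice(len(chroms), p=probs))
            s = int(rng.integers(0, int(sizes[ci]) - region_length + 1))
            candidate = GenomicInterval(chroms[ci], s, s + region_length, name=f"dmr_out_{i}")
            if not all_blocks.overlaps_interval(candidate):
                out.append(candidate)
                break
    truth = {"n_in_blocks": n_in, "n_outside": n_regions - n_in}
    return IntervalSet(out), truth


def simulate_expression(config: SimulationConfig) -> tuple["ExpressionMatrix", np.ndarray]:
    """Two-group log2 expression with a planted DEG fraction.

    Null genes: both groups centred at 0 with Normal(0, noise_sd^2) noise.
    Planted genes (the first ``round(deg_fraction * n_genes)`` rows): case
    mean shifted by ``log2fc_effect``. Returns the matrix plus a boolean
    truth vector (True = planted).
    """
    from .differential import ExpressionMatrix

    rng = np.random.default_rng(None if config.seed is None else config.seed + 3)
    n_genes, n_per = config.n_genes, config.n_samples_per_group
    n_deg = round(config.deg_fraction * n_genes)
    truth = np.zeros(n_genes, dtype=bool)
    truth[:n_deg] = True
    values = rng.normal(0.0, config.noise_sd, size=(n_genes, 2 * n_per))
    values[:n_deg, n_per:] += config.log2fc_effect
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    samples = [f"ctrl_{i + 1}" for i in range(n_per)] + [f"case_{i + 1}" for i in range(n_per)]
    frame = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)
    groups = pd.Series(
        ["control"] * n_per + ["case"] * n_per, index=samples, name="group"
    )
    return ExpressionMatrix(frame, groups), truth


def write_bundle(
    config: SimulationConfig,
    outdir: str | Path,
    n_methyl_regions: int = 40,
    methyl_fraction_in_blocks: float = 0.1,
) -> dict[str, Path]:
    """Emit a full synthetic input bundle (all plain text) into a directory.

    Files: chrom.sizes, blocks.tsv (1-based dialect), peaks.bed, tss.bed,
    methylation.bed, expression.tsv, groups.tsv, expression_truth.tsv.
    Every file is readable by the package's own readers.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["chrom_sizes"] = outdir / "chrom.sizes"
    config.chrom_sizes.to_file(paths["chrom_sizes"])

    paths["blocks"] = outdir / "blocks.tsv"
    with open(paths["blocks"], "w") as fh:
        fh.write("rsid\tchrom\tstart\tstop\n")
        for b in config.risk_blocks:
            fh.write(
                f"{b.rsid}\t{b.interval.chrom}\t{b.interval.start + 1}\t{b.interval.end}\n"
            )

    peaks, _ = simulate_peaks(config)
    paths["peaks"] = outdir / "peaks.bed"
    write_bed(peaks, paths["peaks"])

    tss = simulate_tss(config)
    paths["tss"] = outdir / "tss.bed"
    with open(paths["tss"], "w") as fh:
        for rec in tss:
            fh.write(
                f"{rec.chrom}\t{rec.position}\t{rec.position + 1}\t{rec.gene}\t0\t{rec.strand}\n"
            )

    methyl, _ = simulate_methylation(config, n_methyl_regions, methyl_fraction_in_blocks)
    paths["methylation"] = outdir / "methylation.bed"
    write_bed(methyl, paths["methylation"])

    matrix, truth = simulate_expression(config)
    paths["expression"] = outdir / "expression.tsv"
    matrix.values.to_csv(paths["expression"], sep="\t")
    paths["groups"] = outdir / "groups.tsv"
    matrix.groups.to_frame().to_csv(paths["groups"], sep="\t")
    paths["expression_truth"] = outdir / "expression_truth.tsv"
    pd.DataFrame({"gene": matrix.genes, "planted": truth}).to_csv(
        paths["expression_truth"], sep="\t", index=False
    )
    return paths
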