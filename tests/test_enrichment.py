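"""Random background sampler, contingency building and Fisher machinery."""

import numpy as np
import pytest
from scipy import stats

from epiblocks.enrichment import (
    ContingencyTable,
    RandomRegionConfig,
    build_contingency,
    enrichment_scan,
    fisher_exact,
    generate_random_regions,
)
from epiblocks.intervals import ChromSizes, GenomicInterval, IntervalSet
from epiblocks.risk_loci import LDBlock, RiskSNP

from conftest import fisher_greater_oracle, fisher_two_sided_oracle


def _blocks(n, length=1000, spacing=10_000, chrom="chr1"):
    return [
        LDBlock(
            GenomicInterval(chrom, (i + 1) * spacing, (i + 1) * spacing + length),
            RiskSNP(f"rs{i + 1}"),
        )
        for i in range(n)
    ]


class TestGenerateRandomRegions:
    def test_zero_regions(self, toy_sizes):
        config = RandomRegionConfig(chrom_sizes=toy_sizes, n_regions=0)
        assert len(generate_random_regions(config)) == 0

    def test_bounds_and_length(self):
        sizes = ChromSizes({"chrA": 100_000})
        config = RandomRegionConfig(
            chrom_sizes=sizes, n_regions=50, region_length=1000, seed=3
        )
        regions = generate_random_regions(config)
        assert len(regions) == 50
        for iv in regions:
            assert iv.length == 1000
            assert 0 <= iv.start <= 99_000

    def test_too_long_rejected(self):
        config = RandomRegionConfig(
            chrom_sizes=ChromSizes({"chrA": 100}), region_length=200
        )
        with pytest.raises(ValueError):
            generate_random_regions(config)

    def test_seed_determinism(self, toy_sizes):
        config = RandomRegionConfig(chrom_sizes=toy_sizes, n_regions=200, seed=11)
        assert generate_random_regions(config) == generate_random_regions(config)

    def test_chromosome_weighting(self):
        # 9:1 Mb genome, length-1 regions: small-chromosome fraction ~ 0.1
        sizes = ChromSizes({"big": 9_000_000, "small": 1_000_000})
        config = RandomRegionConfig(
            chrom_sizes=sizes, n_regions=20_000, region_length=1, seed=5
        )
        regions = generate_random_regions(config)
        frac = sum(iv.chrom == "small" for iv in regions) / 20_000
        sd = np.sqrt(0.1 * 0.9 / 20_000)
        assert abs(frac - 0.1) < 3 * sd

    def test_start_uniformity_chi_square(self):
        # 20-bin chi-square on start positions of 50,000 draws
        sizes = ChromSizes({"chrA": 2_000_000})
        config = RandomRegionConfig(
            chrom_sizes=sizes, n_regions=50_000, region_length=1000, seed=7
        )
        starts = np.array([iv.start for iv in generate_random_regions(config)])
        counts, _ = np.histogram(starts, bins=20, range=(0, 2_000_000 - 999))
        _, p = stats.chisquare(counts)
        assert p > 0.001

    def test_exclude_regions_respected(self):
        sizes = ChromSizes({"chrA": 100_000})
        exclude = IntervalSet([GenomicInterval("chrA", 0, 60_000)])
        config = RandomRegionConfig(
            chrom_sizes=sizes, n_regions=30, region_length=500, seed=2,
            exclude=exclude,
        )
        regions = generate_random_regions(config)
        assert len(regions) == 30
        assert all(iv.start >= 60_000 for iv in regions)


class TestBuildContingency:
    def test_empty_peaks(self, toy_sizes):
        blocks = _blocks(16)
        random_regions = generate_random_regions(
            RandomRegionConfig(chrom_sizes=toy_sizes, n_regions=100, region_length=50, seed=0)
        )
        t = build_contingency(blocks, random_regions, IntervalSet())
        assert (t.a, t.b, t.c, t.d) == (0, 0, 16, 100)

    def test_saturating_peaks(self, toy_sizes):
        blocks = _blocks(16)
        random_regions = generate_random_regions(
            RandomRegionConfig(chrom_sizes=toy_sizes, n_regions=100, region_length=50, seed=0)
        )
        genome = IntervalSet(
            [GenomicInterval(c, 0, toy_sizes[c]) for c in toy_sizes]
        )
        t = build_contingency(blocks, random_regions, genome)
        assert (t.a, t.c) == (16, 0) and (t.b, t.d) == (100, 0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(a=-1, b=0, c=0, d=0)


class TestFisherExact:
    def test_balanced_table(self):
        assert fisher_exact(ContingencyTable(5, 5, 5, 5)) == 1.0

    def test_zero_feature_margin(self):
        assert fisher_exact(ContingencyTable(0, 0, 16, 10_000)) == 1.0

    def test_example_against_enumeration(self):
        t = ContingencyTable(a=12, b=300, c=4, d=9_700)
        expected = fisher_two_sided_oracle(12, 300, 4, 9_700)
        assert fisher_exact(t) == pytest.approx(expected, rel=1e-9)

    def test_many_random_tables_against_oracle(self, nprng):
        for _ in range(300):
            n1, n2 = int(nprng.integers(1, 50)), int(nprng.integers(1, 50))
            a = int(nprng.integers(0, n1 + 1))
            b = int(nprng.integers(0, n2 + 1))
            t = ContingencyTable(a=a, b=b, c=n1 - a, d=n2 - b)
            assert fisher_exact(t, "two-sided") == pytest.approx(
                fisher_two_sided_oracle(a, b, n1 - a, n2 - b), rel=1e-9
            )
            assert fisher_exact(t, "greater") == pytest.approx(
                fisher_greater_oracle(a, b, n1 - a, n2 - b), rel=1e-9
            )

    def test_one_sided_monotone_in_a(self):
        # fixed margins: moving a block from miss to hit never raises p(greater)
        n1, n2, m1 = 16, 100, 30
        previous = 1.0
        for a in range(max(0, m1 - n2), min(n1, m1) + 1):
            p = fisher_exact(
                ContingencyTable(a=a, b=m1 - a, c=n1 - a, d=n2 - (m1 - a)),
                "greater",
            )
            assert p <= previous + 1e-12
            previous = p


class TestEnrichmentScan:
    def _scan(self, tracks, seed=0):
        sizes = ChromSizes({"chr1": 1_000_000})
        blocks = _blocks(4, length=2000, spacing=100_000)
        config = RandomRegionConfig(
            chrom_sizes=sizes, n_regions=200, region_length=2000, seed=seed
        )
        return enrichment_scan(blocks, tracks, config)

    def test_all_empty_tracks(self):
        results, matrix = self._scan(
            {("huvec", "H3K4me1"): IntervalSet(), ("m0", "CTCF"): IntervalSet()}
        )
        assert all(r.p_value == 1.0 for r in results)
        assert (matrix.cells == "N").all().all()

    def test_unavailable_track(self):
        results, matrix = self._scan({("pbmc", "H3K27ac"): None})
        (r,) = results
        assert not r.available and r.p_value is None and r.significant is None
        assert (matrix.cells["pbmc:H3K27ac"] == "unavailable").all()

    def test_presence_marks_hit_blocks(self):
        track = IntervalSet([GenomicInterval("chr1", 100_500, 100_600)])
        _, matrix = self._scan({("huvec", "H3K4me1"): track})
        assert list(matrix.cells["huvec:H3K4me1"]) == ["Y", "N", "N", "N"]

    def test_deterministic_given_seed(self):
        track = IntervalSet(
            [GenomicInterval("chr1", s, s + 500) for s in range(0, 900_000, 7_000)]
        )
        r1, m1 = self._scan({("huvec", "H3K4me1"): track}, seed=9)
        r2, m2 = self._scan({("huvec", "H3K4me1"): track}, seed=9)
        assert [x.p_value for x in r1] == [x.p_value for x in r2]
        assert m1.cells.equals(m2.cells)
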