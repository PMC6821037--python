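"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's own code paths (and
scipy's Fisher implementation): pairwise scans for interval work and exact
integer hypergeometric enumeration for the 2x2 test, so they can arbitrate.
"""

from __future__ import annotations

import math
import random

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from epiblocks.intervals import ChromSizes, GenomicInterval, IntervalSet

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


# ---------------------------------------------------------------- oracles


def brute_overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    if a.chrom != b.chrom:
        return False
    shared = min(a.end, b.end) - max(a.start, b.start)
    return shared >= 1


def brute_count_queries_hit(queries, peaks) -> int:
    return sum(1 for q in queries if any(brute_overlaps(q, p) for p in peaks))


def brute_intersect(a, b) -> list[tuple[str, int, int]]:
    out = []
    for x in a:
        for y in b:
            if brute_overlaps(x, y):
                out.append((x.chrom, max(x.start, y.start), min(x.end, y.end)))
    return sorted(out)


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p by integer enumeration over fixed margins.

    Sums hypergeometric point masses of every table whose point probability
    is <= the observed one (1 + 1e-7 relative tolerance for ties).
    """
    from fractions import Fraction

    n1, n2 = a + c, b + d
    m1 = a + b
    weights = {}
    for k in range(max(0, m1 - n2), min(n1, m1) + 1):
        weights[k] = math.comb(n1, k) * math.comb(n2, m1 - k)
    total = sum(weights.values())
    observed = weights[a]
    # exact integer tie tolerance: w <= observed * (1 + 1e-7)
    kept = sum(
        w for w in weights.values() if w * 10**7 <= observed * (10**7 + 1)
    )
    return float(Fraction(kept, total))


def fisher_greater_oracle(a: int, b: int, c: int, d: int) -> float:
    from fractions import Fraction

    n1, n2 = a + c, b + d
    m1 = a + b
    total = math.comb(n1 + n2, m1)
    num = sum(
        math.comb(n1, k) * math.comb(n2, m1 - k)
        for k in range(a, min(n1, m1) + 1)
    )
    return float(Fraction(num, total))


def random_interval_set(rng: random.Random, n: int, chroms=("chrA", "chrB"),
                        max_pos: int = 1000) -> IntervalSet:
    out = []
    for i in range(n):
        start = rng.randrange(0, max_pos - 1)
        end = rng.randrange(start + 1, min(start + 60, max_pos) + 1)
        out.append(GenomicInterval(rng.choice(chroms), start, end, name=f"iv{i}"))
    return IntervalSet(out)


# ---------------------------------------------------------------- fixtures


@pytest.fixture(scope="session")
def toy_sizes() -> ChromSizes:
    return ChromSizes({"chr1": 1_000_000, "chr2": 500_000})


@pytest.fixture()
def rng() -> random.Random:
    return random.Random(20190431 % 2**31)


@pytest.fixture()
def nprng() -> np.random.Generator:
    return np.random.default_rng(42)
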