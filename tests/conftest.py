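"""Shared fixtures and synthetic-profile helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from hrdscar import (
    GenomeBuild,
    Segment,
    SegmentProfile,
    make_default_genome,
    make_test_genome,
)

# states used by the random-profile generator: mixes balanced, LOH,
# imbalanced, and homozygous-deletion segments
_STATES = [(1, 1), (1, 0), (2, 0), (2, 1), (2, 2), (3, 1), (3, 0), (0, 0), (4, 2)]


@pytest.fixture(scope="session")
def genome() -> GenomeBuild:
    return make_default_genome()


@pytest.fixture(scope="session")
def small_genome() -> GenomeBuild:
    """Two 100 Mb chromosomes with a 45-55 Mb centromere."""
    return make_test_genome(2, 100_000_000, (45_000_000, 55_000_000))


def random_profile(
    genome: GenomeBuild,
    rng: np.random.Generator,
    max_segments: int = 30,
) -> SegmentProfile:
    """A random valid profile with <= max_segments segments.

    Segments are scattered over random chromosomes with random gaps (possibly
    zero, possibly > 3 Mb), random lengths from sub-Mb slivers to tens of Mb,
    and random states, so all scar-rule branches get exercised.
    """
    n = int(rng.integers(1, max_segments + 1))
    per_chrom: dict[str, int] = {}
    names = genome.names
    for _ in range(n):
        c = names[int(rng.integers(len(names)))]
        per_chrom[c] = per_chrom.get(c, 0) + 1

    segments: list[Segment] = []
    for chrom, k in per_chrom.items():
        length = genome[chrom].length
        pos = int(rng.integers(0, max(1, length // 4)))
        for _ in range(k):
            gap = int(rng.choice([0, 1, 500_000, 2_000_000, 5_000_000, 20_000_000]))
            seg_len = int(
                rng.choice(
                    [400_000, 2_500_000, 8_000_000, 12_000_000, 18_000_000,
                     30_000_000, 60_000_000]
                )
            )
            start = pos + gap
            end = start + seg_len
            if end >= length:
                break
            major, minor = _STATES[int(rng.integers(len(_STATES)))]
            segments.append(Segment(chrom, start, end, major, minor))
            pos = end
    if not segments:  # extremely unlikely; keep the profile valid
        segments.append(Segment(names[0], 0, 20_000_000, 1, 1))
    return SegmentProfile(sample_id="random", segments=tuple(segments))


def diploid_profile(genome: GenomeBuild) -> SegmentProfile:
    """Copy-neutral (1,1) coverage of every chromosome."""
    return SegmentProfile(
        sample_id="diploid",
        segments=tuple(
            Segment(c.name, 0, c.length, 1, 1) for c in genome
        ),
    )
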