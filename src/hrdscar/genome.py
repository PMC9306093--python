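"""Genome geometry and allele-specific copy-number segment containers.

Coordinates are 0-based half-open integers in base pairs throughout; "15 Mb"
means exactly 15,000,000 bp.  The default genome build contains the 22 human
autosomes only: allele-specific copy-number states are ill-defined on the sex
chromosomes of male patients, so X and Y never enter scar counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

__all__ = [
    "ChromosomeInfo",
    "GenomeBuild",
    "Segment",
    "SegmentProfile",
    "ScarParams",
    "make_default_genome",
    "make_test_genome",
    "merge_adjacent",
]


@dataclass(frozen=True)
class ChromosomeInfo:
    """One chromosome: total length and the centromere interval.

    The p arm is ``[0, centromere_start)`` and the q arm is
    ``[centromere_end, length)``.
    """

    name: str
    length: int
    centromere_start: int
    centromere_end: int

    def __post_init__(self) -> None:
        if not (0 < self.centromere_start < self.centromere_end < self.length):
            raise ValueError(
                f"{self.name}: centromere interval "
                f"[{self.centromere_start}, {self.centromere_end}) must lie "
                f"strictly inside (0, {self.length})"
            )

    @property
    def p_arm(self) -> tuple[int, int]:
        return (0, self.centromere_start)

    @property
    def q_arm(self) -> tuple[int, int]:
        return (self.centromere_end, self.length)

    @property
    def arms(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return (self.p_arm, self.q_arm)


@dataclass(frozen=True)
class GenomeBuild:
    """Ordered collection of chromosomes with unique names."""

    chromosomes: tuple[ChromosomeInfo, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        object.__setattr__(self, "_by_name", {c.name: c for c in self.chromosomes})

    def __getitem__(self, name: str) -> ChromosomeInfo:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self):
        return iter(self.chromosomes)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)


@dataclass(frozen=True, order=True)
class Segment:
    """A genomic interval with integer allele-specific copy numbers.

    ``major_cn >= minor_cn >= 0`` (canonical ordering).  LOH is
    ``minor_cn == 0 and major_cn >= 1``; allelic imbalance is
    ``major_cn != minor_cn``.  ``(0, 0)`` (homozygous deletion) is neither
    LOH nor allelic imbalance, but it is a distinct state for break counting.
    """

    chromosome: str
    start: int
    end: int
    major_cn: int
    minor_cn: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"segment start {self.start} must be < end {self.end}")
        if self.start < 0:
            raise ValueError("segment start must be >= 0")
        if self.major_cn < 0 or self.minor_cn < 0:
            raise ValueError("copy numbers must be >= 0")
        if self.minor_cn > self.major_cn:
            raise ValueError(
                f"minor_cn {self.minor_cn} > major_cn {self.major_cn}: "
                "use canonical ordering minor <= major"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def state(self) -> tuple[int, int]:
        return (self.major_cn, self.minor_cn)

    @property
    def is_loh(self) -> bool:
        return self.minor_cn == 0 and self.major_cn >= 1

    @property
    def is_imbalanced(self) -> bool:
        return self.major_cn != self.minor_cn


@dataclass(frozen=True)
class SegmentProfile:
    """One sample's ordered, non-overlapping segments plus purity/ploidy.

    Gaps between segments are allowed: uncovered genome is treated as missing,
    and gaps wider than :attr:`ScarParams.merge_max_gap` break region
    continuity in all scar rules.
    """

    sample_id: str
    segments: tuple[Segment, ...]
    purity: float | None = None
    ploidy: float | None = None

    def __post_init__(self) -> None:
        segs = tuple(sorted(self.segments, key=lambda s: (s.chromosome, s.start)))
        prev: Segment | None = None
        for s in segs:
            if prev is not None and s.chromosome == prev.chromosome and s.start < prev.end:
                raise ValueError(
                    f"overlapping segments on {s.chromosome}: "
                    f"[{prev.start},{prev.end}) and [{s.start},{s.end})"
                )
            prev = s
        object.__setattr__(self, "segments", segs)
        if self.purity is not None and not (0.0 <= self.purity <= 1.0):
            raise ValueError("purity must be in [0, 1]")
        if self.ploidy is not None and self.ploidy <= 0:
            raise ValueError("ploidy must be > 0")

    def by_chromosome(self) -> dict[str, list[Segment]]:
        out: dict[str, list[Segment]] = {}
        for s in self.segments:
            out.setdefault(s.chromosome, []).append(s)
        return out

    @property
    def covered_length(self) -> int:
        return sum(s.length for s in self.segments)

    def mean_copy_number(self) -> float:
        """Length-weighted mean total copy number over covered genome."""
        cov = self.covered_length
        if cov == 0:
            raise ValueError("empty profile has no mean copy number")
        return sum((s.major_cn + s.minor_cn) * s.length for s in self.segments) / cov


@dataclass(frozen=True)
class ScarParams:
    """Length thresholds for the three scar rules.

    loh_min_len
        An LOH region must be strictly longer than this (15 Mb) and shorter
        than the chromosome's covered extent to count.
    lst_min_seg
        Both regions flanking a large-scale state transition must be at least
        this long (10 Mb).
    lst_smooth_len
        Segments shorter than this (3 Mb) are removed before break counting,
        and a break is only counted when the gap between its flanks does not
        exceed this.
    tai_min_len
        Minimum length of a telomeric allelic-imbalance region (11 Mb, the
        convention of the telomeric-imbalance literature).
    merge_max_gap
        Same-state segments separated by an uncovered gap up to this wide are
        fused when building regions; wider gaps break continuity.
    telomere_tolerance
        A region boundary within this distance of a chromosome end (or at the
        first/last covered position) counts as reaching the telomere.
    """

    loh_min_len: int = 15_000_000
    lst_min_seg: int = 10_000_000
    lst_smooth_len: int = 3_000_000
    tai_min_len: int = 11_000_000
    merge_max_gap: int = 3_000_000
    telomere_tolerance: int = 1_000_000

    def __post_init__(self) -> None:
        for name in (
            "loh_min_len",
            "lst_min_seg",
            "lst_smooth_len",
            "tai_min_len",
            "merge_max_gap",
            "telomere_tolerance",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


# hg19 autosome lengths with centromere intervals from the UCSC gap track.
_HG19_AUTOSOMES: tuple[tuple[str, int, int, int], ...] = (
    ("chr1", 249_250_621, 121_535_434, 124_535_434),
    ("chr2", 243_199_373, 92_326_171, 95_326_171),
    ("chr3", 198_022_430, 90_504_854, 93_504_854),
    ("chr4", 191_154_276, 49_660_117, 52_660_117),
    ("chr5", 180_915_260, 46_405_641, 49_405_641),
    ("chr6", 171_115_067, 58_830_166, 61_830_166),
    ("chr7", 159_138_663, 58_054_331, 61_054_331),
    ("chr8", 146_364_022, 43_838_887, 46_838_887),
    ("chr9", 141_213_431, 47_367_679, 50_367_679),
    ("chr10", 135_534_747, 39_254_935, 42_254_935),
    ("chr11", 135_006_516, 51_644_205, 54_644_205),
    ("chr12", 133_851_895, 34_856_694, 37_856_694),
    ("chr13", 115_169_878, 16_000_000, 19_000_000),
    ("chr14", 107_349_540, 16_000_000, 19_000_000),
    ("chr15", 102_531_392, 17_000_000, 20_000_000),
    ("chr16", 90_354_753, 35_335_801, 38_335_801),
    ("chr17", 81_195_210, 22_263_006, 25_263_006),
    ("chr18", 78_077_248, 15_460_898, 18_460_898),
    ("chr19", 59_128_983, 24_681_782, 27_681_782),
    ("chr20", 63_025_520, 26_369_569, 29_369_569),
    ("chr21", 48_129_895, 11_288_129, 14_288_129),
    ("chr22", 51_304_566, 13_000_000, 16_000_000),
)


def make_default_genome() -> GenomeBuild:
    """The 22 human autosomes (hg19 lengths and centromere intervals)."""
    return GenomeBuild(
        tuple(ChromosomeInfo(*row) for row in _HG19_AUTOSOMES)
    )


def make_test_genome(
    n_chrom: int, chrom_length: int, centromere: tuple[int, int]
) -> GenomeBuild:
    """Miniature genome of ``n_chrom`` identical chromosomes for tests."""
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    cs, ce = int(centromere[0]), int(centromere[1])
    chrom_length = int(chrom_length)
    if not (0 < cs < ce < chrom_length):
        raise ValueError(
            f"centromere ({cs}, {ce}) must lie strictly inside (0, {chrom_length})"
        )
    return GenomeBuild(
        tuple(
            ChromosomeInfo(f"chr{i + 1}", chrom_length, cs, ce)
            for i in range(n_chrom)
        )
    )


def merge_adjacent(profile: SegmentProfile, max_gap: int = 3_000_000) -> SegmentProfile:
    """Fuse same-state neighbours separated by at most ``max_gap``.

    Adjacent segments on the same chromosome with identical
    ``(major_cn, minor_cn)`` and an uncovered gap of at most ``max_gap`` bp
    become one segment spanning both (the gap is bridged).  Idempotent; never
    changes any allele-specific state.
    """
    merged: list[Segment] = []
    for chrom, segs in profile.by_chromosome().items():
        current = segs[0]
        for s in segs[1:]:
            if s.state == current.state and s.start - current.end <= max_gap:
                current = replace(current, end=s.end)
            else:
                merged.append(current)
                current = s
        merged.append(current)
    return SegmentProfile(
        sample_id=profile.sample_id,
        segments=tuple(merged),
        purity=profile.purity,
        ploidy=profile.ploidy,
    )
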