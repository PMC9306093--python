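"""Genomic-scar scores: HRD-LOH, HRD-TAI, HRD-LST and their sum.

The HRD score is the sum of three counts derived from an allele-specific
copy-number profile:

* **LOH** — intermediate-size loss-of-heterozygosity regions: ``minor_cn == 0``
  with at least one copy retained, strictly longer than 15 Mb but shorter than
  the chromosome's whole covered extent.
* **TAI** — telomeric allelic-imbalance regions: ``major_cn != minor_cn``
  runs reaching one (and only one) telomere without crossing the centromere,
  at least 11 Mb long.
* **LST** — large-scale state transitions: per chromosome arm, after removing
  segments shorter than 3 Mb, breaks between adjacent regions of different
  allele-specific state where both flanks are at least 10 Mb and the gap
  between them at most 3 Mb.  Breaks are never counted across the centromere.

Purity and ploidy enter upstream: the integer allele-specific copy numbers
are inferred under the fitted purity/ploidy (see :mod:`hrdscar.allele`), so
no post-hoc rescaling of the counts is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

from .genome import GenomeBuild, ScarParams, Segment, SegmentProfile, merge_adjacent

__all__ = ["ScarScores", "HrdCall", "compute_loh", "compute_tai", "compute_lst",
           "compute_scar_scores", "classify_hrd"]


@dataclass(frozen=True)
class ScarScores:
    """The three scar counts, their sum, and the purity/ploidy used."""

    loh_score: int
    tai_score: int
    lst_score: int
    hrd_score: int
    purity_used: float | None = None
    ploidy_used: float | None = None

    def __post_init__(self) -> None:
        if self.hrd_score != self.loh_score + self.tai_score + self.lst_score:
            raise ValueError("hrd_score must equal loh + tai + lst")


@dataclass(frozen=True)
class HrdCall:
    """Dichotomized HRD status at a given cutoff (positive iff score >= cutoff)."""

    score: int
    cutoff: int
    positive: bool


@dataclass(frozen=True)
class _Region:
    """A maximal run of same-predicate segments with bridged small gaps."""

    chromosome: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _ensure_merged(profile: SegmentProfile, params: ScarParams) -> SegmentProfile:
    merged = merge_adjacent(profile, params.merge_max_gap)
    if len(merged.segments) != len(profile.segments):
        warnings.warn(
            f"profile {profile.sample_id!r} was not merged; merge_adjacent "
            "applied internally",
            stacklevel=3,
        )
    return merged


def _maximal_regions(segs: list[Segment], predicate, max_gap: int) -> list[_Region]:
    """Maximal runs of consecutive predicate-true segments, gaps <= max_gap.

    A predicate-false segment, or an uncovered gap wider than ``max_gap``,
    terminates the run.
    """
    regions: list[_Region] = []
    run_start = run_end = None
    prev_end = None
    for s in segs:
        gap_break = prev_end is not None and s.start - prev_end > max_gap
        if predicate(s):
            if run_start is None or gap_break:
                if run_start is not None:
                    regions.append(_Region(s.chromosome, run_start, run_end))
                run_start, run_end = s.start, s.end
            else:
                run_end = s.end
        else:
            if run_start is not None:
                regions.append(_Region(s.chromosome, run_start, run_end))
                run_start = run_end = None
        prev_end = s.end
    if run_start is not None:
        regions.append(_Region(segs[-1].chromosome, run_start, run_end))
    return regions


def compute_loh(
    profile: SegmentProfile,
    genome: GenomeBuild,
    params: ScarParams = ScarParams(),
) -> int:
    """Count intermediate-size LOH regions.

    A region qualifies when it is strictly longer than ``params.loh_min_len``
    and does not span the whole covered extent of its chromosome (whole-
    chromosome LOH reflects aneuploidy rather than recombination scarring).
    """
    profile = _ensure_merged(profile, params)
    count = 0
    for chrom, segs in profile.by_chromosome().items():
        if chrom not in genome:
            continue
        first_cov = segs[0].start
        last_cov = segs[-1].end
        for r in _maximal_regions(segs, lambda s: s.is_loh, params.merge_max_gap):
            if r.length <= params.loh_min_len:
                continue
            if r.start == first_cov and r.end == last_cov:
                continue  # spans the chromosome's whole covered extent
            count += 1
    return count


def compute_tai(
    profile: SegmentProfile,
    genome: GenomeBuild,
    params: ScarParams = ScarParams(),
) -> int:
    """Count telomeric allelic-imbalance regions.

    A maximal allelic-imbalance run qualifies when its outer boundary reaches
    exactly one telomere (within ``telomere_tolerance`` of a chromosome end,
    or at the chromosome's first/last covered position — SNP panels rarely
    reach the terminal base), it does not overlap the centromere interval,
    and it is at least ``tai_min_len`` long.
    """
    profile = _ensure_merged(profile, params)
    count = 0
    for chrom, segs in profile.by_chromosome().items():
        if chrom not in genome:
            continue
        info = genome[chrom]
        first_cov = segs[0].start
        last_cov = segs[-1].end
        for r in _maximal_regions(segs, lambda s: s.is_imbalanced, params.merge_max_gap):
            at_p_telo = r.start <= params.telomere_tolerance or r.start == first_cov
            at_q_telo = (
                r.end >= info.length - params.telomere_tolerance or r.end == last_cov
            )
            if not (at_p_telo or at_q_telo):
                continue
            if at_p_telo and at_q_telo:
                continue  # whole-chromosome imbalance is not subchromosomal
            if r.start < info.centromere_end and r.end > info.centromere_start:
                continue  # crosses / touches the centromere
            if r.length < params.tai_min_len:
                continue
            count += 1
    return count


def _clip_to_arm(segs: list[Segment], arm: tuple[int, int]) -> list[Segment]:
    lo, hi = arm
    out = []
    for s in segs:
        a, b = max(s.start, lo), min(s.end, hi)
        if a < b:
            out.append(replace(s, start=a, end=b))
    return out


def _smooth_arm(segs: list[Segment], params: ScarParams) -> list[Segment]:
    """Iteratively drop sub-3 Mb segments and re-fuse same-state neighbours."""
    current = list(segs)
    while True:
        kept = [s for s in current if s.length >= params.lst_smooth_len]
        fused: list[Segment] = []
        for s in kept:
            if (
                fused
                and s.state == fused[-1].state
                and s.start - fused[-1].end <= params.lst_smooth_len
            ):
                fused[-1] = replace(fused[-1], end=s.end)
            else:
                fused.append(s)
        if fused == current:
            return fused
        current = fused


def compute_lst(
    profile: SegmentProfile,
    genome: GenomeBuild,
    params: ScarParams = ScarParams(),
) -> int:
    """Count large-scale state transitions per chromosome arm.

    Segments are clipped to arms (so breaks are never counted across the
    centromere), smoothed by dropping sub-``lst_smooth_len`` segments, and an
    ordered adjacent pair with different allele-specific states counts as one
    break when both flanks are >= ``lst_min_seg`` and the uncovered gap
    between them is <= ``lst_smooth_len``.
    """
    profile = _ensure_merged(profile, params)
    count = 0
    for chrom, segs in profile.by_chromosome().items():
        if chrom not in genome:
            continue
        for arm in genome[chrom].arms:
            arm_segs = _smooth_arm(_clip_to_arm(segs, arm), params)
            for left, right in zip(arm_segs, arm_segs[1:]):
                if (
                    left.state != right.state
                    and right.start - left.end <= params.lst_smooth_len
                    and left.length >= params.lst_min_seg
                    and right.length >= params.lst_min_seg
                ):
                    count += 1
    return count


def compute_scar_scores(
    profile: SegmentProfile,
    genome: GenomeBuild,
    params: ScarParams = ScarParams(),
) -> ScarScores:
    """LOH + TAI + LST counts and their sum for one sample."""
    merged = merge_adjacent(profile, params.merge_max_gap)
    loh = compute_loh(merged, genome, params)
    tai = compute_tai(merged, genome, params)
    lst = compute_lst(merged, genome, params)
    return ScarScores(
        loh_score=loh,
        tai_score=tai,
        lst_score=lst,
        hrd_score=loh + tai + lst,
        purity_used=profile.purity,
        ploidy_used=profile.ploidy,
    )


def classify_hrd(score: int, cutoff: int) -> HrdCall:
    """Dichotomize an HRD score: positive iff ``score >= cutoff``."""
    if score < 0 or cutoff < 0:
        raise ValueError("score and cutoff must be >= 0")
    return HrdCall(score=score, cutoff=cutoff, positive=score >= cutoff)
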