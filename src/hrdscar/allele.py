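"""Allele-specific copy number under a tumor/normal mixture model.

A specimen of purity ``rho`` mixes tumor cells carrying integer allele copies
``(major_cn, minor_cn)`` with diploid normal cells.  At a heterozygous SNP the
expected B-allele frequency and log R ratio are::

    baf  = (1 - rho + rho * minor_cn) / (2 (1 - rho) + rho * (major_cn + minor_cn))
    logr = log2( (2 (1 - rho) + rho * total_cn) / (2 (1 - rho) + rho * psi) )

with ``psi`` the tumor's mean ploidy.  Since SNP phase is unknown, BAF is used
folded (mirrored about 0.5) everywhere downstream.

The module inverts this model: it segments per-SNP (BAF, logR) tracks into
piecewise-constant regions, grid-searches purity/ploidy by demanding the
implied real-valued allele copies fall near nonnegative integers, and calls
integer allele-specific copy numbers per segment.  The scar counts are then
purity/ploidy-adjusted by construction, with no post-hoc score rescaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeBuild, Segment, SegmentProfile

__all__ = [
    "SNPSite",
    "SegmentSummary",
    "PurityPloidyFit",
    "NonIdentifiableFitError",
    "expected_baf_logr",
    "snp_frame",
    "segment_snps",
    "fit_purity_ploidy",
    "call_integer_cn",
]

SNP_COLUMNS = ["chromosome", "position", "baf", "logr"]


class SNPSite(NamedTuple):
    """One heterozygous SNP observation."""

    chromosome: str
    position: int
    baf: float
    logr: float


@dataclass(frozen=True)
class SegmentSummary:
    """Piecewise-constant summary of one segmented region.

    ``baf_dev`` is the noise-corrected mean allelic-imbalance deviation
    |BAF - 0.5| (see :func:`segment_snps`); ``logr`` is the mean log R ratio.
    """

    chromosome: str
    start: int
    end: int
    n_snps: int
    baf_dev: float
    logr: float
    baf_noise_sd: float = 0.0  # global robust SNP-level noise estimates,
    logr_noise_sd: float = 0.0  # stamped on every segment by segment_snps

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PurityPloidyFit:
    """Result of the purity/ploidy grid search."""

    purity: float | None
    ploidy: float | None
    fit_error: float
    identifiable: bool


class NonIdentifiableFitError(ValueError):
    """Raised when integer copy calls are requested from a flat profile."""


def expected_baf_logr(
    major_cn: int,
    minor_cn: int,
    purity: float,
    ploidy: float,
    gamma: float = 1.0,
) -> tuple[float, float]:
    """Expected (BAF, logR) for an allele-specific state under the mixture.

    ``gamma`` is the logR compression factor (1.0 = no compression).  A total
    copy number of zero at purity 1 has no reads supporting either allele:
    the BAF is returned as NaN (flagged missing) and logR as ``-inf``.
    """
    if not 0.0 <= purity <= 1.0:
        raise ValueError("purity must be in [0, 1]")
    if ploidy <= 0:
        raise ValueError("ploidy must be > 0")
    if major_cn < 0 or minor_cn < 0:
        raise ValueError("copy numbers must be >= 0")
    total = major_cn + minor_cn
    depth = 2.0 * (1.0 - purity) + purity * total
    depth_ref = 2.0 * (1.0 - purity) + purity * ploidy
    if depth == 0.0:
        return (math.nan, -math.inf)
    baf = (1.0 - purity + purity * minor_cn) / depth
    logr = gamma * math.log2(depth / depth_ref)
    return (baf, logr)


def snp_frame(sites: Sequence[SNPSite] | pd.DataFrame) -> pd.DataFrame:
    """Normalize SNP input (list of sites or DataFrame) to a sorted frame."""
    if isinstance(sites, pd.DataFrame):
        df = sites.loc[:, SNP_COLUMNS].copy()
    else:
        df = pd.DataFrame(list(sites), columns=SNP_COLUMNS)
    return df.sort_values(["chromosome", "position"], kind="stable").reset_index(
        drop=True
    )


def _robust_sd(values: np.ndarray) -> float:
    """Noise scale from successive differences (insensitive to level shifts)."""
    if len(values) < 3:
        return 0.0
    d = np.abs(np.diff(values))
    return float(np.median(d)) / (math.sqrt(2.0) * 0.674489750196082)


def _binary_segment(cost_y: np.ndarray, penalty: float, min_size: int) -> list[int]:
    """Recursive binary change-point splitting.

    ``cost_y`` is an (n, k) array of normalized channels; the cost of a block
    is its summed squared deviation from the block mean over all channels.  A
    split is accepted only when it reduces total cost by more than ``penalty``.
    Returns sorted interior breakpoint indices (split before index b).
    """
    n, _ = cost_y.shape
    csum = np.vstack([np.zeros(cost_y.shape[1]), np.cumsum(cost_y, axis=0)])
    csum2 = np.vstack([np.zeros(cost_y.shape[1]), np.cumsum(cost_y**2, axis=0)])

    def block_cost(lo: int, hi: int) -> float:
        # SSE around the mean, summed over channels, for y[lo:hi]
        m = hi - lo
        s = csum[hi] - csum[lo]
        s2 = csum2[hi] - csum2[lo]
        return float(np.sum(s2 - s * s / m))

    def best_split(lo: int, hi: int) -> tuple[float, int] | None:
        if hi - lo < 2 * min_size:
            return None
        cuts = np.arange(lo + min_size, hi - min_size + 1)
        m_left = cuts - lo
        m_right = hi - cuts
        s_left = csum[cuts] - csum[lo]
        s2_left = csum2[cuts] - csum2[lo]
        s_right = csum[hi] - csum[cuts]
        s2_right = csum2[hi] - csum2[cuts]
        cost = np.sum(
            s2_left - s_left**2 / m_left[:, None], axis=1
        ) + np.sum(s2_right - s_right**2 / m_right[:, None], axis=1)
        i = int(np.argmin(cost))
        return float(cost[i]), int(cuts[i])

    breaks: list[int] = []
    stack = [(0, n)]
    while stack:
        lo, hi = stack.pop()
        split = best_split(lo, hi)
        if split is None:
            continue
        child_cost, b = split
        if block_cost(lo, hi) - child_cost > penalty:
            breaks.append(b)
            stack.append((lo, b))
            stack.append((b, hi))
    return sorted(breaks)


def segment_snps(
    snps: Sequence[SNPSite] | pd.DataFrame,
    penalty: float | None = None,
    min_size: int = 3,
    gap_break: int = 3_000_000,
    genome: GenomeBuild | None = None,
) -> list[SegmentSummary]:
    """Segment per-SNP (folded BAF, logR) tracks into constant regions.

    Per chromosome, SNPs are split into coverage blocks wherever consecutive
    positions are more than ``gap_break`` apart (a panel's uncovered gap);
    each block is segmented by recursive binary splitting on the joint
    normalized cost of (|BAF - 0.5|, logR), accepting a split only when it
    reduces total cost by more than ``penalty`` (default ``6 log n`` per
    chromosome on the noise-normalized scale).  Returned intervals cover each
    block without overlap; boundaries between SNPs fall at midpoints.

    The per-segment ``baf_dev`` is bias-corrected:
    ``sqrt(max(mean((baf-0.5)^2) - sigma^2, 0))`` with ``sigma`` the robust
    SNP-level BAF noise, because the naive mean |BAF - 0.5| of a balanced
    segment is inflated by folding the noise.
    """
    df = snp_frame(snps)
    if df.empty:
        return []

    # global robust noise scales from within-chromosome successive differences
    dev_all = np.abs(df["baf"].to_numpy() - 0.5)
    sd_baf = _robust_sd(df["baf"].to_numpy())
    sd_logr = _robust_sd(df["logr"].to_numpy())
    floor = 1e-9
    sd_baf_n = max(sd_baf, floor)
    sd_logr_n = max(sd_logr, floor)

    out: list[SegmentSummary] = []
    for chrom, g in df.groupby("chromosome", sort=False):
        pos = g["position"].to_numpy()
        dev = np.abs(g["baf"].to_numpy() - 0.5)
        logr = g["logr"].to_numpy()
        n_chrom = len(g)
        pen = penalty if penalty is not None else 6.0 * math.log(max(n_chrom, 2))

        # coverage blocks: break where consecutive SNP spacing > gap_break
        block_edges = [0] + list(np.flatnonzero(np.diff(pos) > gap_break) + 1) + [n_chrom]
        chrom_len = genome[chrom].length if genome is not None and chrom in genome else None
        for blo, bhi in zip(block_edges, block_edges[1:]):
            bpos = pos[blo:bhi]
            y = np.column_stack(
                [dev[blo:bhi] / sd_baf_n, logr[blo:bhi] / sd_logr_n]
            )
            breaks = _binary_segment(y, pen, min_size) if len(bpos) >= 2 * min_size else []
            idx = [0] + breaks + [len(bpos)]

            spacing = np.diff(bpos)
            pad = int(np.median(spacing) // 2) if len(spacing) else 1
            block_start = max(0, int(bpos[0]) - pad)
            block_end = int(bpos[-1]) + pad + 1
            if chrom_len is not None:
                block_end = min(block_end, chrom_len)
            for lo, hi in zip(idx, idx[1:]):
                start = block_start if lo == 0 else int((bpos[lo - 1] + bpos[lo]) // 2) + 1
                end = block_end if hi == len(bpos) else int((bpos[hi - 1] + bpos[hi]) // 2) + 1
                seg_dev = dev[blo + lo : blo + hi]
                msq = float(np.mean(seg_dev**2))
                corrected = math.sqrt(max(msq - sd_baf**2, 0.0))
                out.append(
                    SegmentSummary(
                        chromosome=str(chrom),
                        start=start,
                        end=end,
                        n_snps=hi - lo,
                        baf_dev=corrected,
                        logr=float(np.mean(logr[blo + lo : blo + hi])),
                        baf_noise_sd=sd_baf,
                        logr_noise_sd=sd_logr,
                    )
                )
    return out


def _is_flat(
    segments: Sequence[SegmentSummary],
    z: float = 4.5,
    min_snps: int = 10,
) -> bool:
    """A profile is flat (compatible with purity 0) when no segment carries
    allelic-imbalance or logR signal clearly above its own noise level.

    A segment witnesses signal when its mean logR exceeds ``z`` standard
    errors, or its corrected BAF deviation exceeds what a ``z``-standard-error
    excursion of the mean squared deviation would produce.  The thresholds
    shrink with segment size, so large aberrant regions are detected while
    the maximum over many pure-noise segments stays below them.  Segments
    with fewer than ``min_snps`` sites are ignored.
    """
    for s in segments:
        n = s.n_snps
        if n < min_snps:
            continue
        dev_thresh = max(1e-6, s.baf_noise_sd * math.sqrt(z * math.sqrt(2.0 / n)))
        logr_thresh = max(1e-6, z * s.logr_noise_sd / math.sqrt(n))
        if s.baf_dev > dev_thresh or abs(s.logr) > logr_thresh:
            return False
    return True


def fit_purity_ploidy(
    segments: Sequence[SegmentSummary],
    rho_grid: np.ndarray | None = None,
    psi_grid: np.ndarray | None = None,
    gamma: float = 1.0,
) -> PurityPloidyFit:
    """Exhaustive grid search for tumor purity and ploidy.

    For each candidate (rho, psi) the observed per-segment (baf_dev, logR)
    pair is inverted to real-valued allele-specific copies; the objective is
    the length-weighted mean squared distance of those copies to their nearest
    nonnegative integers, judged relative to the noise floor propagated from
    the SNP-level noise.  Candidate solutions near the best noise-consistency
    are resolved by ploidy parsimony, then fit quality, then higher purity,
    so the output is deterministic.  A flat profile (all segments
    within the noise floor, i.e. compatible with rho ~ 0) is reported with
    ``identifiable=False`` and undefined purity/ploidy rather than an error.
    """
    segments = list(segments)
    if not segments or _is_flat(segments):
        return PurityPloidyFit(None, None, math.inf, identifiable=False)

    if rho_grid is None:
        rho_grid = np.round(np.arange(0.05, 1.0 + 1e-9, 0.01), 2)
    if psi_grid is None:
        psi_grid = np.round(np.arange(1.0, 5.5 + 1e-9, 0.05), 2)

    w = np.array([s.length for s in segments], dtype=float)
    w /= w.sum()
    dev = np.array([s.baf_dev for s in segments])
    logr = np.array([s.logr for s in segments])

    rho = rho_grid[:, None, None]  # (R, 1, 1)
    psi = psi_grid[None, :, None]  # (1, P, 1)
    ratio = np.power(2.0, logr[None, None, :] / gamma)  # (1, 1, S)

    depth_ref = 2.0 * (1.0 - rho) + rho * psi
    depth = depth_ref * ratio  # (R, P, S)
    major = ((0.5 + dev[None, None, :]) * depth - (1.0 - rho)) / rho
    minor = ((0.5 - dev[None, None, :]) * depth - (1.0 - rho)) / rho
    err = (major - np.clip(np.round(major), 0, None)) ** 2
    err += (minor - np.clip(np.round(minor), 0, None)) ** 2
    total_err = err @ w  # (R, P)

    # The raw integer-distance surface is degenerate: every profile admits
    # exact reparameterizations with scaled copy numbers (all copies doubled
    # at doubled ploidy, at either a lower or a higher purity), a near-flat
    # fit at purity ~1 with slightly fractional copies, and a trivial fit at
    # very low purity where noise amplification makes every integer reachable.
    # The discriminating quantity is the ratio of the residual to the noise
    # floor propagated from the SNP-level noise: the near-flat purity-1 fit
    # has a tiny floor and a huge ratio, while the trivial low-purity fit has
    # a floor so large that the residual carries no information and the cell
    # is excluded outright.  The scaled-copy reparameterizations match the
    # data exactly, so the remaining tie is broken by ploidy parsimony
    # (doubling the copies doubles the ploidy), then by the ratio, then
    # toward higher purity.
    n_eff = np.array([max(s.n_snps, 1) for s in segments], dtype=float)
    var_dev = np.array([s.baf_noise_sd**2 for s in segments]) / n_eff
    var_lr = np.array([s.logr_noise_sd**2 for s in segments]) / n_eff
    ddev = (depth / rho) ** 2 * var_dev[None, None, :]
    lr_scale = (depth * math.log(2.0) / (gamma * rho)) ** 2 * var_lr[None, None, :]
    expected = (
        2.0 * ddev
        + ((0.5 + dev[None, None, :]) ** 2 + (0.5 - dev[None, None, :]) ** 2) * lr_scale
    )
    # grid-discretization slack: quantizing rho/psi leaves a small residual
    # even for noiseless data
    expected_err = expected @ w + 3e-4

    # cells whose noise floor approaches the variance of a uniformly random
    # distance-to-integer (1/12 per allele) fit anything and decide nothing
    informative = expected_err <= 0.05
    # the copy-number ladder is also shift-ambiguous: subtracting one copy
    # from every allele is an exact reparameterization at lower ploidy, but it
    # sends the bulk of the genome to total copy zero, which no viable tumor
    # carries; reject cells implying a substantial zero-copy genome fraction
    total_rounded = np.clip(np.round(major), 0, None) + np.clip(np.round(minor), 0, None)
    zero_frac = (total_rounded == 0).astype(float) @ w
    viable = informative & (zero_frac <= 0.05)
    if not viable.any():
        viable = np.ones_like(expected_err, dtype=bool)
    score = np.where(viable, total_err / expected_err, math.inf)

    best = float(score.min())
    cand_i, cand_j = np.nonzero(score <= max(2.0, 1.5 * best))
    psi_min = psi_grid[cand_j].min()
    keep = psi_grid[cand_j] <= psi_min + 0.1 + 1e-9
    cand_i, cand_j = cand_i[keep], cand_j[keep]
    order = sorted(
        range(len(cand_i)),
        key=lambda k: (
            float(score[cand_i[k], cand_j[k]]),
            -float(rho_grid[cand_i[k]]),
            float(psi_grid[cand_j[k]]),
        ),
    )
    i, j = int(cand_i[order[0]]), int(cand_j[order[0]])
    return PurityPloidyFit(
        purity=float(rho_grid[i]),
        ploidy=float(psi_grid[j]),
        fit_error=float(total_err[i, j]),
        identifiable=True,
    )


def call_integer_cn(
    segments: Sequence[SegmentSummary],
    fit: PurityPloidyFit,
    sample_id: str = "sample",
    max_cn: int = 12,
    gamma: float = 1.0,
) -> SegmentProfile:
    """Assign each segment the best-fitting integer allele-specific state.

    Minimizes the squared deviation of the state's expected
    (|BAF - 0.5|, logR) from the observed summary over all states with
    ``minor <= major <= max_cn``.  Ties go to the lower total copy number,
    then lower major (deterministic).  Refuses non-identifiable fits.
    """
    if not fit.identifiable or fit.purity is None or fit.ploidy is None:
        raise NonIdentifiableFitError(
            "purity/ploidy fit is not identifiable; integer copy numbers "
            "cannot be called"
        )
    states = [
        (major, minor)
        for major in range(max_cn + 1)
        for minor in range(major + 1)
    ]
    exp = np.array(
        [expected_baf_logr(ma, mi, fit.purity, fit.ploidy, gamma) for ma, mi in states]
    )
    exp_dev = np.abs(exp[:, 0] - 0.5)
    exp_logr = exp[:, 1]
    # a (0,0) state at purity 1 has NaN BAF / -inf logR: never selected
    bad = ~np.isfinite(exp_dev) | ~np.isfinite(exp_logr)

    out: list[Segment] = []
    for s in segments:
        cost = (exp_dev - s.baf_dev) ** 2 + (exp_logr - s.logr) ** 2
        cost[bad] = math.inf
        order = np.lexsort(
            (
                [ma for ma, _ in states],
                [ma + mi for ma, mi in states],
                cost,
            )
        )
        major, minor = states[int(order[0])]
        out.append(
            Segment(
                chromosome=s.chromosome,
                start=s.start,
                end=s.end,
                major_cn=major,
                minor_cn=minor,
            )
        )
    return SegmentProfile(
        sample_id=sample_id,
        segments=tuple(out),
        purity=fit.purity,
        ploidy=fit.ploidy,
    )
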