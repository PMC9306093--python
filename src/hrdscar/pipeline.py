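"""End-to-end scoring: SNP table -> segmentation -> purity/ploidy fit ->
integer allele-specific copy numbers -> scar scores."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .allele import (
    NonIdentifiableFitError,
    PurityPloidyFit,
    call_integer_cn,
    fit_purity_ploidy,
    segment_snps,
)
from .genome import GenomeBuild, ScarParams, SegmentProfile, make_default_genome
from .scars import ScarScores, compute_scar_scores

__all__ = ["ScoredSample", "score_snp_table", "score_profile"]


@dataclass(frozen=True)
class ScoredSample:
    """Result of scoring one sample from SNP-level data."""

    sample_id: str
    fit: PurityPloidyFit
    profile: SegmentProfile | None
    scores: ScarScores | None

    @property
    def identifiable(self) -> bool:
        return self.fit.identifiable


def score_snp_table(
    snps: pd.DataFrame,
    sample_id: str = "sample",
    genome: GenomeBuild | None = None,
    params: ScarParams = ScarParams(),
    penalty: float | None = None,
    gamma: float = 1.0,
    rho_grid=None,
    psi_grid=None,
) -> ScoredSample:
    """Run the full SNP-to-score pipeline for one sample.

    When the purity/ploidy fit is non-identifiable (flat profile, e.g. a pure
    normal specimen) the sample is returned flagged, with no profile and no
    scores, rather than raising.
    """
    genome = genome or make_default_genome()
    summaries = segment_snps(snps, penalty=penalty, gap_break=params.merge_max_gap,
                             genome=genome)
    fit = fit_purity_ploidy(summaries, rho_grid=rho_grid, psi_grid=psi_grid,
                            gamma=gamma)
    if not fit.identifiable:
        return ScoredSample(sample_id=sample_id, fit=fit, profile=None, scores=None)
    profile = call_integer_cn(summaries, fit, sample_id=sample_id, gamma=gamma)
    scores = compute_scar_scores(profile, genome, params)
    return ScoredSample(sample_id=sample_id, fit=fit, profile=profile, scores=scores)


def score_profile(
    profile: SegmentProfile,
    genome: GenomeBuild | None = None,
    params: ScarParams = ScarParams(),
) -> ScarScores:
    """Score an already-segmented allele-specific copy-number profile."""
    genome = genome or make_default_genome()
    return compute_scar_scores(profile, genome, params)
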