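"""Mixture model, segmentation, purity/ploidy fitting, and integer CN calls."""

import math

import numpy as np
import pandas as pd
import pytest

from hrdscar import (
    NonIdentifiableFitError,
    PurityPloidyFit,
    Segment,
    SegmentProfile,
    call_integer_cn,
    emit_snps,
    expected_baf_logr,
    fit_purity_ploidy,
    segment_snps,
    simulate_profile,
)
from hrdscar.allele import SegmentSummary
from hrdscar.simulate import ScarEventSpec

MB = 1_000_000


class TestExpectedBafLogr:
    def test_diploid_balanced(self):
        for rho in (0.0, 0.3, 1.0):
            baf, logr = expected_baf_logr(1, 1, rho, 2.0)
            assert baf == pytest.approx(0.5)
            assert logr == pytest.approx(0.0)

    def test_pure_normal_is_flat(self):
        baf, logr = expected_baf_logr(3, 0, 0.0, 2.7)
        assert (baf, logr) == (pytest.approx(0.5), pytest.approx(0.0))

    def test_cn_loh_at_half_purity(self):
        baf, logr = expected_baf_logr(2, 0, 0.5, 2.0)
        assert baf == pytest.approx(0.25)
        assert logr == pytest.approx(0.0)

    def test_total_zero_at_purity_one_flagged_missing(self):
        baf, logr = expected_baf_logr(0, 0, 1.0, 2.0)
        assert math.isnan(baf)
        assert logr == -math.inf

    def test_baf_monotone_in_minor_at_fixed_total(self):
        bafs = [expected_baf_logr(4 - m, m, 0.6, 2.0)[0] for m in range(3)]
        assert bafs == sorted(bafs)

    def test_logr_monotone_in_total(self):
        logrs = [expected_baf_logr(t, 0, 0.6, 2.0)[1] for t in range(1, 6)]
        assert logrs == sorted(logrs)

    def test_argument_validation(self):
        with pytest.raises(ValueError):
            expected_baf_logr(1, 1, 1.5, 2.0)
        with pytest.raises(ValueError):
            expected_baf_logr(1, 1, 0.5, 0.0)
        with pytest.raises(ValueError):
            expected_baf_logr(-1, 0, 0.5, 2.0)


def _step_track(n=600, step_at=300, logr_step=1.0, noise=0.05, seed=0):
    rng = np.random.default_rng(seed)
    pos = np.arange(n) * 50_000 + 10_000
    logr = np.where(np.arange(n) >= step_at, logr_step, 0.0)
    return pd.DataFrame(
        {
            "chromosome": "chr1",
            "position": pos,
            "baf": 0.5 + rng.normal(0, noise, n),
            "logr": logr + rng.normal(0, noise, n),
        }
    )


class TestSegmentation:
    def test_constant_signal_one_segment(self):
        df = _step_track(logr_step=0.0)
        segs = segment_snps(df)
        assert len(segs) == 1

    def test_single_step_recovered_within_5_spacings(self):
        df = _step_track()
        segs = segment_snps(df)
        assert len(segs) == 2
        # breakpoint between SNP 299 and 300: positions 14.96-15.01 Mb
        boundary = segs[0].end
        truth = 10_000 + 300 * 50_000
        assert abs(boundary - truth) <= 5 * 50_000

    def test_two_steps_three_segments(self):
        rng = np.random.default_rng(1)
        n = 900
        pos = np.arange(n) * 50_000
        logr = np.where((np.arange(n) >= 300) & (np.arange(n) < 600), 0.8, 0.0)
        df = pd.DataFrame(
            {
                "chromosome": "chr1",
                "position": pos,
                "baf": 0.5 + rng.normal(0, 0.05, n),
                "logr": logr + rng.normal(0, 0.05, n),
            }
        )
        assert len(segment_snps(df)) == 3

    def test_empty_input_empty_output(self):
        assert segment_snps(pd.DataFrame(columns=["chromosome", "position",
                                                  "baf", "logr"])) == []

    def test_wide_snp_gap_breaks_blocks(self):
        df = _step_track(logr_step=0.0)
        df.loc[df.index >= 300, "position"] += 10 * MB  # 10 Mb coverage hole
        segs = segment_snps(df)
        assert len(segs) == 2
        assert segs[1].start - segs[0].end > 3 * MB


class TestFitPurityPloidy:
    def test_noiseless_recovery_exact(self, genome):
        profile, _ = simulate_profile(genome, ScarEventSpec(3, 2, 4, seed=7))
        snps = emit_snps(profile, 0.6, n_snps=12_000, noise_sd=(0.0, 0.0), seed=1)
        fit = fit_purity_ploidy(segment_snps(snps, genome=genome))
        assert fit.identifiable
        assert fit.purity == pytest.approx(0.60)
        assert fit.ploidy == pytest.approx(2.0, abs=0.051)

    def test_aneuploid_recovery_within_one_grid_step(self, genome):
        rng = np.random.default_rng(3)
        states = [(2, 1), (2, 2), (3, 1), (2, 1), (1, 1)]
        segs = tuple(
            Segment(c.name, 0, c.length, *states[int(rng.integers(len(states)))])
            for c in genome
        )
        profile = SegmentProfile("aneu", segs)
        true_psi = profile.mean_copy_number()
        snps = emit_snps(profile, 0.3, n_snps=12_000, noise_sd=(0.0, 0.0), seed=4)
        fit = fit_purity_ploidy(segment_snps(snps, genome=genome))
        assert fit.purity == pytest.approx(0.30, abs=0.011)
        assert fit.ploidy == pytest.approx(true_psi, abs=0.051)

    def test_pure_normal_not_identifiable(self, genome):
        profile, _ = simulate_profile(genome, ScarEventSpec(3, 2, 4, seed=7))
        snps = emit_snps(profile, 0.0, n_snps=12_000, seed=2)
        fit = fit_purity_ploidy(segment_snps(snps, genome=genome))
        assert not fit.identifiable
        assert fit.purity is None

    def test_empty_input_not_identifiable(self):
        fit = fit_purity_ploidy([])
        assert not fit.identifiable

    def test_noise_degradation_is_monotone(self, genome):
        profile, _ = simulate_profile(genome, ScarEventSpec(3, 2, 4, seed=7))
        errs = []
        for noise in ((0.01, 0.03), (0.05, 0.15)):
            snps = emit_snps(profile, 0.5, n_snps=12_000, noise_sd=noise, seed=3)
            fit = fit_purity_ploidy(segment_snps(snps, genome=genome))
            assert fit.identifiable
            assert fit.purity == pytest.approx(0.5, abs=0.03)
            errs.append(fit.fit_error)
        assert errs[0] < errs[1]


class TestCallIntegerCn:
    def test_round_trip_single_state(self):
        baf, logr = expected_baf_logr(2, 1, 0.8, 2.0)
        seg = SegmentSummary("chr1", 0, 10 * MB, 100, abs(baf - 0.5), logr)
        fit = PurityPloidyFit(0.8, 2.0, 0.0, True)
        called = call_integer_cn([seg], fit).segments[0]
        assert (called.major_cn, called.minor_cn) == (2, 1)

    def test_balanced_at_full_purity(self):
        seg = SegmentSummary("chr1", 0, 10 * MB, 100, 0.0, 0.0)
        fit = PurityPloidyFit(1.0, 2.0, 0.0, True)
        called = call_integer_cn([seg], fit).segments[0]
        assert (called.major_cn, called.minor_cn) == (1, 1)

    def test_refuses_non_identifiable_fit(self):
        seg = SegmentSummary("chr1", 0, 10 * MB, 100, 0.0, 0.0)
        with pytest.raises(NonIdentifiableFitError):
            call_integer_cn([seg], PurityPloidyFit(None, None, math.inf, False))

    def test_exhaustive_round_trip_total_le_8(self):
        for rho in (0.3, 0.6, 1.0):
            fit = PurityPloidyFit(rho, 2.0, 0.0, True)
            for major in range(9):
                for minor in range(major + 1):
                    if major + minor > 8:
                        continue
                    baf, logr = expected_baf_logr(major, minor, rho, 2.0)
                    if not math.isfinite(logr):
                        continue
                    seg = SegmentSummary("chr1", 0, 10 * MB, 100,
                                         abs(baf - 0.5), logr)
                    called = call_integer_cn([seg], fit).segments[0]
                    assert (called.major_cn, called.minor_cn) == (major, minor)


class TestFullPipelineClosure:
    def test_closure_at_low_purity(self, genome):
        """SNP emission and re-scoring is exact at the 20% purity floor."""
        from hrdscar import score_snp_table

        profile, planted = simulate_profile(genome, ScarEventSpec(3, 2, 4, seed=7))
        snps = emit_snps(profile, 0.2, n_snps=12_000, noise_sd=(0.0, 0.0), seed=11)
        result = score_snp_table(snps, genome=genome)
        assert result.scores is not None
        assert result.scores.hrd_score == planted.hrd_score
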