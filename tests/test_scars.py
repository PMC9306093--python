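"""Scar-rule unit tests: worked examples, properties, and oracle equivalence."""

import numpy as np
import pytest

from hrdscar import (
    ScarParams,
    ScarScores,
    Segment,
    SegmentProfile,
    classify_hrd,
    compute_loh,
    compute_lst,
    compute_scar_scores,
    compute_tai,
)

from .conftest import diploid_profile, random_profile
from .oracle import oracle_scores

MB = 1_000_000
PARAMS = ScarParams()


def _profile(*segs: Segment) -> SegmentProfile:
    return SegmentProfile("t", tuple(segs))


class TestLoh:
    def test_interstitial_20mb_loh_counts(self, small_genome):
        p = _profile(
            Segment("chr1", 0, 20 * MB, 1, 0),
            Segment("chr1", 20 * MB, 100 * MB, 1, 1),
        )
        assert compute_loh(p, small_genome, PARAMS) == 1

    def test_whole_covered_extent_excluded(self, small_genome):
        p = _profile(Segment("chr1", 0, 100 * MB, 1, 0))
        assert compute_loh(p, small_genome, PARAMS) == 0

    def test_short_loh_excluded(self, small_genome):
        p = _profile(
            Segment("chr1", 0, 10 * MB, 1, 0),
            Segment("chr1", 10 * MB, 100 * MB, 1, 1),
        )
        assert compute_loh(p, small_genome, PARAMS) == 0

    def test_exactly_15mb_excluded_strict_inequality(self, small_genome):
        p = _profile(
            Segment("chr1", 0, 15 * MB, 1, 0),
            Segment("chr1", 15 * MB, 100 * MB, 1, 1),
        )
        assert compute_loh(p, small_genome, PARAMS) == 0

    def test_distinct_loh_states_form_one_region(self, small_genome):
        # (1,0) adjoining (2,0): both LOH, one maximal region
        p = _profile(
            Segment("chr1", 0, 10 * MB, 1, 0),
            Segment("chr1", 10 * MB, 20 * MB, 2, 0),
            Segment("chr1", 20 * MB, 100 * MB, 1, 1),
        )
        assert compute_loh(p, small_genome, PARAMS) == 1

    def test_homozygous_deletion_is_not_loh(self, small_genome):
        p = _profile(
            Segment("chr1", 0, 20 * MB, 0, 0),
            Segment("chr1", 20 * MB, 100 * MB, 1, 1),
        )
        assert compute_loh(p, small_genome, PARAMS) == 0

    def test_empty_profile_zero(self, small_genome):
        p = _profile(Segment("chr1", 0, 100 * MB, 1, 1))
        assert compute_loh(p, small_genome, PARAMS) == 0

    def test_unmerged_profile_warns_and_recovers(self, small_genome):
        p = _profile(
            Segment("chr1", 0, 10 * MB, 1, 0),
            Segment("chr1", 10 * MB, 20 * MB, 1, 0),
            Segment("chr1", 20 * MB, 100 * MB, 1, 1),
        )
        with pytest.warns(UserWarning, match="not merged"):
            assert compute_loh(p, small_genome, PARAMS) == 1


class TestTai:
    def test_telomeric_12mb_imbalance_counts(self, small_genome):
        p = _profile(
            Segment("chr1", 0, 12 * MB, 2, 1),
            Segment("chr1", 12 * MB, 100 * MB, 1, 1),
        )
        assert compute_tai(p, small_genome, PARAMS) == 1

    def test_centromere_crossing_excluded(self, small_genome):
        # centromere is 45-55 Mb; q-telomeric run crossing it does not count
        p = _profile(
            Segment("chr1", 0, 40 * MB, 1, 1),
            Segment("chr1", 40 * MB, 100 * MB, 2, 1),
        )
        assert compute_tai(p, small_genome, PARAMS) == 0

    def test_interstitial_imbalance_excluded(self, small_genome):
        p = _profile(
            Segment("chr1", 0, 10 * MB, 1, 1),
            Segment("chr1", 10 * MB, 30 * MB, 2, 1),
            Segment("chr1", 30 * MB, 100 * MB, 1, 1),
        )
        assert compute_tai(p, small_genome, PARAMS) == 0

    def test_whole_chromosome_imbalance_excluded(self, small_genome):
        p = _profile(Segment("chr1", 0, 100 * MB, 2, 1))
        assert compute_tai(p, small_genome, PARAMS) == 0

    def test_balanced_profile_zero(self, small_genome):
        assert compute_tai(diploid_profile(small_genome), small_genome, PARAMS) == 0

    def test_short_telomeric_run_excluded(self, small_genome):
        p = _profile(
            Segment("chr1", 0, 10 * MB, 2, 1),  # 10 Mb < 11 Mb minimum
            Segment("chr1", 10 * MB, 100 * MB, 1, 1),
        )
        assert compute_tai(p, small_genome, PARAMS) == 0

    def test_covered_extremity_counts_as_telomere(self, small_genome):
        # coverage starts at 5 Mb (> tolerance), run starts at first covered bp
        p = _profile(
            Segment("chr1", 5 * MB, 20 * MB, 2, 1),
            Segment("chr1", 20 * MB, 100 * MB, 1, 1),
        )
        assert compute_tai(p, small_genome, PARAMS) == 1

    def test_q_telomere_counts(self, small_genome):
        p = _profile(
            Segment("chr1", 0, 80 * MB, 1, 1),
            Segment("chr1", 80 * MB, 100 * MB, 2, 1),
        )
        assert compute_tai(p, small_genome, PARAMS) == 1


class TestLst:
    def test_simple_break_counts(self, small_genome):
        p = _profile(
            Segment("chr1", 0, 20 * MB, 1, 1),
            Segment("chr1", 20 * MB, 45 * MB, 2, 1),
        )
        assert compute_lst(p, small_genome, PARAMS) == 1

    def test_sliver_smoothed_away(self, small_genome):
        p = _profile(
            Segment("chr1", 0, 20 * MB, 1, 1),
            Segment("chr1", 20 * MB, 22 * MB, 5, 5),
            Segment("chr1", 22 * MB, 45 * MB, 2, 1),
        )
        assert compute_lst(p, small_genome, PARAMS) == 1

    def test_single_segment_arm_zero(self, small_genome):
        p = _profile(Segment("chr1", 0, 45 * MB, 2, 1))
        assert compute_lst(p, small_genome, PARAMS) == 0

    def test_short_flank_excluded(self, small_genome):
        p = _profile(
            Segment("chr1", 0, 8 * MB, 1, 1),  # 8 Mb < 10 Mb flank
            Segment("chr1", 8 * MB, 45 * MB, 2, 1),
        )
        assert compute_lst(p, small_genome, PARAMS) == 0

    def test_break_not_counted_across_centromere(self, small_genome):
        p = _profile(
            Segment("chr1", 0, 45 * MB, 1, 1),
            Segment("chr1", 55 * MB, 100 * MB, 2, 1),
        )
        assert compute_lst(p, small_genome, PARAMS) == 0

    def test_wide_gap_between_flanks_excluded(self, small_genome):
        p = _profile(
            Segment("chr1", 0, 20 * MB, 1, 1),
            Segment("chr1", 24 * MB, 45 * MB, 2, 1),  # 4 Mb > 3 Mb gap
        )
        assert compute_lst(p, small_genome, PARAMS) == 0

    def test_homozygous_deletion_is_a_state_change(self, small_genome):
        p = _profile(
            Segment("chr1", 0, 20 * MB, 1, 1),
            Segment("chr1", 20 * MB, 45 * MB, 0, 0),
        )
        assert compute_lst(p, small_genome, PARAMS) == 1


class TestScoresAndClassification:
    def test_diploid_profile_scores_zero(self, genome):
        s = compute_scar_scores(diploid_profile(genome), genome)
        assert (s.loh_score, s.tai_score, s.lst_score, s.hrd_score) == (0, 0, 0, 0)

    def test_sum_invariant_enforced(self):
        with pytest.raises(ValueError):
            ScarScores(loh_score=1, tai_score=2, lst_score=3, hrd_score=7)

    def test_classify_hrd(self):
        assert classify_hrd(21, 21).positive
        assert not classify_hrd(20, 21).positive
        assert not classify_hrd(0, 21).positive
        with pytest.raises(ValueError):
            classify_hrd(-1, 21)

    def test_permutation_invariance(self, genome):
        rng = np.random.default_rng(11)
        for _ in range(20):
            p = random_profile(genome, rng)
            shuffled = list(p.segments)
            rng.shuffle(shuffled)
            q = SegmentProfile(p.sample_id, tuple(shuffled))
            assert compute_scar_scores(p, genome) == compute_scar_scores(q, genome)

    def test_loh_monotone_in_converted_region(self, small_genome):
        base = _profile(
            Segment("chr1", 0, 20 * MB, 1, 0),
            Segment("chr1", 20 * MB, 40 * MB, 1, 1),
            Segment("chr1", 60 * MB, 100 * MB, 1, 1),
        )
        more = _profile(
            Segment("chr1", 0, 20 * MB, 1, 0),
            Segment("chr1", 20 * MB, 40 * MB, 1, 1),
            Segment("chr1", 60 * MB, 100 * MB, 2, 0),  # converted to LOH
        )
        assert compute_loh(more, small_genome, PARAMS) >= compute_loh(
            base, small_genome, PARAMS
        )

    def test_lst_monotone_in_added_break(self, small_genome):
        base = _profile(
            Segment("chr1", 55 * MB, 100 * MB, 1, 1),
        )
        more = _profile(
            Segment("chr1", 55 * MB, 75 * MB, 1, 1),
            Segment("chr1", 75 * MB, 100 * MB, 3, 1),
        )
        assert compute_lst(more, small_genome, PARAMS) >= compute_lst(
            base, small_genome, PARAMS
        )


class TestOracleEquivalence:
    def test_scores_match_brute_force_on_random_profiles(self, genome):
        rng = np.random.default_rng(2024)
        for i in range(120):
            p = random_profile(genome, rng)
            s = compute_scar_scores(p, genome)
            assert (s.loh_score, s.tai_score, s.lst_score) == oracle_scores(
                p, genome, PARAMS
            ), f"profile {i} diverged from brute force"
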