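import dataclasses

import numpy as np
import pytest

from hrdscar.cn_io import Segment, SegmentProfile
from hrdscar.hrd_scoring import (
    HRDResult,
    ScoringParams,
    classify_hr,
    normalize_profile,
    score_hrd,
    score_hrd_loh,
    score_lst,
    score_ntai,
)

from .conftest import MB, make_profile, random_profile
from .oracles import oracle_hrd_loh, oracle_lst, oracle_ntai

PARAMS = ScoringParams()


class TestClassifyHr:
    @pytest.mark.parametrize(
        "score,status",
        [(43, "deficient"), (41, "proficient"), (42, "deficient"), (0, "proficient")],
    )
    def test_threshold_rule(self, score, status):
        assert classify_hr(score) == status

    def test_negative_score_rejected(self):
        with pytest.raises(ValueError):
            classify_hr(-1)


class TestNormalize:
    def test_adjacent_same_state_merged(self, toy_build):
        p = make_profile([(1, 1, 10 * MB, 1, 1), (1, 10 * MB + 1, 20 * MB, 1, 1)])
        n = normalize_profile(p, toy_build)
        assert n.segments == [Segment("1", 1, 20 * MB, 1, 1)]

    def test_centromere_spanning_segment_split(self, toy_build):
        cs, ce = toy_build.centromere("1")
        p = make_profile([(1, 1, 200 * MB, 2, 1)])
        n = normalize_profile(p, toy_build)
        assert [(s.start, s.end) for s in n.segments] == [(1, cs - 1), (ce + 1, 200 * MB)]

    def test_idempotent(self, toy_build):
        rng = np.random.default_rng(11)
        for _ in range(20):
            p = random_profile(rng, toy_build)
            once = normalize_profile(p, toy_build)
            twice = normalize_profile(once, toy_build)
            assert once.segments == twice.segments

    def test_sex_chromosomes_dropped(self, toy_build):
        p = SegmentProfile("S", [Segment("X", 1, 10, 1, 1), Segment("1", 1, 10, 1, 1)])
        assert {s.chrom for s in normalize_profile(p, toy_build).segments} == {"1"}

    def test_segment_beyond_chromosome_end_rejected(self, toy_build):
        p = make_profile([(1, 1, 300 * MB, 1, 1)])
        with pytest.raises(ValueError, match="out of bounds"):
            normalize_profile(p, toy_build)


class TestNtai:
    def test_all_diploid_genome_scores_zero(self, toy_build):
        p = make_profile([(c, 1, l, 1, 1) for c, l in toy_build.lengths.items()])
        assert score_ntai(normalize_profile(p, toy_build), toy_build) == 0

    def test_terminal_parm_imbalance_counts_once(self, toy_build):
        p = make_profile([(1, 1, 8 * MB, 2, 1), (1, 8 * MB + 1, 200 * MB, 1, 1)])
        n = normalize_profile(p, toy_build)
        assert score_ntai(n, toy_build) == oracle_ntai(p, toy_build, PARAMS) == 1

    def test_whole_chromosome_imbalance_excluded(self, toy_build):
        p = make_profile([(1, 1, 200 * MB, 2, 1)])
        n = normalize_profile(p, toy_build)
        assert score_ntai(n, toy_build) == oracle_ntai(p, toy_build, PARAMS) == 0

    def test_centromere_crossing_terminal_segment_excluded(self, toy_build):
        # first segment runs from the telomere across the centromere
        p = make_profile([(1, 1, 120 * MB, 2, 1), (1, 120 * MB + 1, 200 * MB, 1, 1)])
        n = normalize_profile(p, toy_build)
        assert score_ntai(n, toy_build) == oracle_ntai(p, toy_build, PARAMS) == 0

    def test_min_length_filter(self, toy_build):
        p = make_profile([(1, 1, 8 * MB, 2, 1), (1, 8 * MB + 1, 200 * MB, 1, 1)])
        n = normalize_profile(p, toy_build)
        strict = ScoringParams(ntai_min_len=9 * MB)
        assert score_ntai(n, toy_build, strict) == 0


class TestHrdLoh:
    def test_interstitial_16mb_loh_counts(self, toy_build):
        p = make_profile(
            [(1, 1, 100 * MB, 1, 1), (1, 100 * MB + 1, 116 * MB, 1, 0),
             (1, 116 * MB + 1, 200 * MB, 1, 1)]
        )
        n = normalize_profile(p, toy_build)
        assert score_hrd_loh(n, toy_build) == oracle_hrd_loh(p, toy_build, PARAMS) == 1

    def test_14mb_below_cutoff(self, toy_build):
        p = make_profile(
            [(1, 1, 100 * MB, 1, 1), (1, 100 * MB + 1, 114 * MB, 1, 0),
             (1, 114 * MB + 1, 200 * MB, 1, 1)]
        )
        n = normalize_profile(p, toy_build)
        assert score_hrd_loh(n, toy_build) == oracle_hrd_loh(p, toy_build, PARAMS) == 0

    def test_whole_chromosome_loh_excluded(self, toy_build):
        p = make_profile([(1, 1, 200 * MB, 1, 0)])
        n = normalize_profile(p, toy_build)
        assert score_hrd_loh(n, toy_build) == oracle_hrd_loh(p, toy_build, PARAMS) == 0

    def test_runs_merge_across_major_changes(self, toy_build):
        # 9 Mb of 1+0 contiguous with 9 Mb of 2+0: one 18 Mb LOH region
        p = make_profile(
            [(2, 1, 30 * MB, 1, 1), (2, 30 * MB + 1, 39 * MB, 1, 0),
             (2, 39 * MB + 1, 48 * MB, 2, 0), (2, 48 * MB + 1, 150 * MB, 1, 1)]
        )
        n = normalize_profile(p, toy_build)
        assert score_hrd_loh(n, toy_build) == oracle_hrd_loh(p, toy_build, PARAMS) == 1

    def test_homozygous_deletion_breaks_run_by_default(self, toy_build):
        rows = [
            (2, 1, 30 * MB, 1, 1), (2, 30 * MB + 1, 39 * MB, 1, 0),
            (2, 39 * MB + 1, 40 * MB, 0, 0), (2, 40 * MB + 1, 48 * MB, 1, 0),
            (2, 48 * MB + 1, 150 * MB, 1, 1),
        ]
        n = normalize_profile(make_profile(rows), toy_build)
        assert score_hrd_loh(n, toy_build) == 0  # both runs < 15 Mb
        permissive = ScoringParams(loh_allow_homdel=True)
        assert score_hrd_loh(n, toy_build, permissive) == 1


class TestLst:
    def test_three_large_blocks_two_transitions(self, toy_build):
        ce = toy_build.centromere("1")[1]
        p = make_profile(
            [(1, ce + 1, ce + 20 * MB, 1, 1),
             (1, ce + 20 * MB + 1, ce + 50 * MB, 2, 1),
             (1, ce + 50 * MB + 1, ce + 75 * MB, 2, 2)]
        )
        n = normalize_profile(p, toy_build)
        assert score_lst(n, toy_build) == oracle_lst(p, toy_build, PARAMS) == 2

    def test_small_interruption_smoothed_away(self, toy_build):
        ce = toy_build.centromere("1")[1]
        p = make_profile(
            [(1, ce + 1, ce + 20 * MB, 1, 1),
             (1, ce + 20 * MB + 1, ce + 22 * MB, 3, 1),
             (1, ce + 22 * MB + 1, ce + 52 * MB, 1, 1)]
        )
        n = normalize_profile(p, toy_build)
        assert score_lst(n, toy_build) == oracle_lst(p, toy_build, PARAMS) == 0

    def test_short_flank_disqualifies_pair(self, toy_build):
        ce = toy_build.centromere("1")[1]
        p = make_profile(
            [(1, ce + 1, ce + 9 * MB, 1, 1),
             (1, ce + 9 * MB + 1, ce + 39 * MB, 2, 2)]
        )
        n = normalize_profile(p, toy_build)
        assert score_lst(n, toy_build) == oracle_lst(p, toy_build, PARAMS) == 0

    def test_gap_wider_than_3mb_disqualifies_pair(self, toy_build):
        ce = toy_build.centromere("1")[1]
        p = make_profile(
            [(1, ce + 1, ce + 20 * MB, 1, 1),
             (1, ce + 24 * MB + 1, ce + 50 * MB, 2, 1)]  # 4 Mb coverage gap
        )
        n = normalize_profile(p, toy_build)
        assert score_lst(n, toy_build) == oracle_lst(p, toy_build, PARAMS) == 0

    def test_transitions_counted_per_arm_not_across_centromere(self, toy_build):
        cs, ce = toy_build.centromere("1")
        p = make_profile(
            [(1, 1, cs - 1, 1, 1), (1, ce + 1, 200 * MB, 2, 1)]
        )
        n = normalize_profile(p, toy_build)
        assert score_lst(n, toy_build) == oracle_lst(p, toy_build, PARAMS) == 0


class TestScoreHrd:
    def test_sum_threshold_and_contributions(self, toy_build):
        # components land at (1, 1, 2) on this constructed profile
        ce = toy_build.centromere("1")[1]
        p = make_profile(
            [(1, 1, 20 * MB, 2, 1),
             (1, 20 * MB + 1, 200 * MB, 1, 1),
             (2, 1, 60 * MB - 1, 1, 1),
             (2, 64 * MB + 1, 90 * MB, 1, 1),
             (2, 90 * MB + 1, 110 * MB, 1, 0),
             (2, 110 * MB + 1, 150 * MB, 1, 1)]
        )
        r = score_hrd(p, toy_build)
        # chr1: terminal 2+1 -> 1 NtAI plus 1 LST against its p-arm flank;
        # chr2: interstitial 20 Mb LOH -> 1 HRD-LOH plus 2 LSTs
        assert (r.ntai, r.hrd_loh, r.lst) == (1, 1, 3)
        assert r.hrd_score == 5 and r.hr_status == "proficient"
        assert r.contributions["ntai"] == pytest.approx(20.0)
        assert sum(r.contributions.values()) == pytest.approx(100.0)

    def test_zero_genome_scores_zero_with_zero_contributions(self, toy_build):
        p = make_profile([(c, 1, l, 1, 1) for c, l in toy_build.lengths.items()])
        r = score_hrd(p, toy_build)
        assert r.hrd_score == 0 and r.hr_status == "proficient"
        assert all(v == 0.0 for v in r.contributions.values())

    def test_equal_components_contribute_a_third_each(self):
        r = HRDResult("S", 14, 14, 14, 42, "deficient",
                      {"ntai": 100 / 3, "hrd_loh": 100 / 3, "lst": 100 / 3})
        assert r.contributions["lst"] == pytest.approx(33.333, abs=1e-3)

    def test_inconsistent_sum_rejected(self):
        with pytest.raises(ValueError):
            HRDResult("S", 1, 1, 1, 4, "proficient", {})


class TestOracleEquivalence:
    def test_random_profiles_match_bruteforce(self, toy_build):
        """Each component equals a literal rule enumerator on random
        profiles with up to 12 segments per chromosome."""
        rng = np.random.default_rng(2024)
        for i in range(250):
            p = random_profile(rng, toy_build, sample_id=f"R{i}")
            n = normalize_profile(p, toy_build)
            assert score_ntai(n, toy_build) == oracle_ntai(p, toy_build, PARAMS), i
            assert score_hrd_loh(n, toy_build) == oracle_hrd_loh(p, toy_build, PARAMS), i
            assert score_lst(n, toy_build) == oracle_lst(p, toy_build, PARAMS), i


class TestScoringProperties:
    @staticmethod
    def _random_split(profile, rng):
        segs = list(profile.segments)
        k = int(rng.integers(len(segs)))
        s = segs[k]
        if s.length < 2:
            return profile
        cut = int(rng.integers(s.start, s.end))
        segs[k : k + 1] = [
            dataclasses.replace(s, end=cut),
            dataclasses.replace(s, start=cut + 1),
        ]
        return SegmentProfile(profile.sample_id, segs)

    def test_split_invariance(self, toy_build):
        """Splitting any segment into two same-state halves never changes
        any component count or the summed score."""
        rng = np.random.default_rng(7)
        for i in range(60):
            p = random_profile(rng, toy_build, sample_id=f"P{i}")
            base = score_hrd(p, toy_build)
            q = p
            for _ in range(4):
                q = self._random_split(q, rng)
            split = score_hrd(q, toy_build)
            assert (base.ntai, base.hrd_loh, base.lst) == (
                split.ntai, split.hrd_loh, split.lst,
            ), i

    def test_adding_interstitial_loh_is_monotone(self, toy_build):
        """Adding one qualifying interstitial LOH region into diploid
        territory never decreases the LOH count or the summed score."""
        rng = np.random.default_rng(42)
        checked = 0
        for i in range(60):
            p = random_profile(rng, toy_build, max_segments=4, sample_id=f"M{i}")
            n = normalize_profile(p, toy_build)
            # find a diploid segment long enough to host the region with
            # >= 14 Mb of flank remaining on both sides, on one arm
            host = None
            for s in n.segments:
                cs, ce = toy_build.centromeres[s.chrom]
                on_one_arm = s.end < cs or s.start > ce
                if s.state == (1, 1) and s.length >= 48 * MB and on_one_arm:
                    host = s
                    break
            if host is None:
                continue
            checked += 1
            base = score_hrd(n, toy_build)
            lo = host.start + 14 * MB
            extra = Segment(host.chrom, lo, lo + 20 * MB - 1, 1, 0)
            segs = [s for s in n.segments if s is not host]
            segs += [
                dataclasses.replace(host, end=extra.start - 1),
                extra,
                dataclasses.replace(host, start=extra.end + 1),
            ]
            more = score_hrd(SegmentProfile(n.sample_id, segs), toy_build)
            assert more.hrd_loh >= base.hrd_loh + 1, i
            assert more.hrd_score >= base.hrd_score, i
        assert checked >= 10  # the property was actually exercised
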