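"""Breakpoint extraction, matching, identity scoring and null
calibration."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_breakpoints
from felclone.breakpoints import (calibrate_cutoff, extract_breakpoints,
                                  make_exclusion_regions,
                                  match_breakpoints, pair_relatedness,
                                  partial_identity_score)
from felclone.datamodel import (CalibrationError, ExclusionRegions,
                                Segment, SegmentProfile)


def brute_force_max_matching(a, b, tolerance):
    """Exhaustive maximum one-to-one matching size (independent oracle):
    dynamic programming over subsets of b, assigning each a in turn."""
    from functools import lru_cache

    adjacency = tuple(
        tuple(j for j, y in enumerate(b)
              if x.chrom == y.chrom
              and abs(x.boundary_pos - y.boundary_pos) <= tolerance)
        for x in a)

    @lru_cache(maxsize=None)
    def rec(i, used_b):
        if i == len(a):
            return 0
        best = rec(i + 1, used_b)
        for j in adjacency[i]:
            if not used_b & (1 << j):
                best = max(best, 1 + rec(i + 1, used_b | (1 << j)))
        return best

    return rec(0, 0)


class TestExtraction:
    def test_internal_boundary_is_breakpoint(self):
        prof = SegmentProfile.from_segments("L", [
            Segment("chr16", 1, 10_000_000, 2),
            Segment("chr16", 10_000_001, 90_000_000, 1)])
        (bp,) = extract_breakpoints(prof, ExclusionRegions())
        assert bp.boundary_pos == 10_000_000

    def test_excluded_window_removes_breakpoint(self):
        prof = SegmentProfile.from_segments("L", [
            Segment("chr16", 1, 10_000_000, 2),
            Segment("chr16", 10_000_001, 90_000_000, 1)])
        excl = ExclusionRegions(intervals=(("chr16", 9_000_000,
                                            11_000_000),))
        assert extract_breakpoints(prof, excl) == []

    def test_whole_chromosome_loss_has_no_breakpoints(self):
        prof = SegmentProfile.from_segments("L", [
            Segment("chr17", 1, 81_195_210, 1)])
        assert extract_breakpoints(prof, ExclusionRegions()) == []

    def test_default_windows_filter_telomeric_and_centromeric(self):
        excl = make_exclusion_regions({"chr1": 100_000_000},
                                      {"chr1": 50_000_000})
        prof = SegmentProfile.from_segments("L", [
            Segment("chr1", 1, 2_000_000, 1),          # telomeric boundary
            Segment("chr1", 2_000_001, 49_000_000, 2),  # pericentromeric
            Segment("chr1", 49_000_001, 70_000_000, 3),  # kept at 70 Mb
            Segment("chr1", 70_000_001, 100_000_000, 2)])
        kept = extract_breakpoints(prof, excl)
        assert [bp.boundary_pos for bp in kept] == [70_000_000]

    def test_five_lesion_filtered_counts(self, five_lesion_case,
                                         default_exclusions):
        counts = {lid: len(extract_breakpoints(p, default_exclusions))
                  for lid, p in five_lesion_case["profiles"].items()}
        assert counts == {"FA1": 1, "FA2": 1, "FA3": 5,
                          "BenignPT": 0, "MalignantPT": 6}


class TestMatching:
    def test_identical_sets_match_fully_at_zero_tolerance(self):
        a = make_breakpoints([1_000_000, 2_000_000, 3_000_000])
        assert match_breakpoints(a, list(a), tolerance=0) == 3

    def test_tolerance_threshold(self):
        a = make_breakpoints([10_000_000])
        b = make_breakpoints([10_400_000])
        assert match_breakpoints(a, b, tolerance=500_000) == 1
        assert match_breakpoints(a, b, tolerance=100_000) == 0

    def test_chromosome_must_agree(self):
        a = make_breakpoints([("chr1", 10_000_000)])
        b = make_breakpoints([("chr2", 10_000_000)])
        assert match_breakpoints(a, b, tolerance=10**9) == 0

    def test_interleaved_instance_needs_maximum_matching(self):
        # nearest-first greedy would pair 6-5 and strand both 0 and 11
        a = make_breakpoints([0 + 10_000_000, 6 + 10_000_000])
        b = make_breakpoints([5 + 10_000_000, 11 + 10_000_000])
        assert match_breakpoints(a, b, tolerance=5) == 2

    @given(st.data())
    @settings(derandomize=True, max_examples=150, deadline=None)
    def test_equals_exhaustive_oracle(self, data):
        positions = st.lists(st.integers(0, 40), min_size=0, max_size=8)
        tol = data.draw(st.integers(0, 10))
        chrom_pool = ("chr1", "chr2")
        a = make_breakpoints(
            [(data.draw(st.sampled_from(chrom_pool)), p)
             for p in data.draw(positions)])
        b = make_breakpoints(
            [(data.draw(st.sampled_from(chrom_pool)), p)
             for p in data.draw(positions)])
        assert match_breakpoints(a, b, tol) == \
            brute_force_max_matching(a, b, tol)


class TestIdentityScore:
    def test_disjoint_sets_score_zero(self):
        a = make_breakpoints([10_000_000])
        b = make_breakpoints([50_000_000])
        assert partial_identity_score(a, b).score == 0.0

    def test_identical_sets_score_one(self):
        a = make_breakpoints([10_000_000, 50_000_000])
        assert partial_identity_score(a, list(a)).score == 1.0

    def test_worked_example(self):
        a = make_breakpoints([i * 3_000_000 + 10_000_000
                              for i in range(10)])
        b = make_breakpoints([i * 3_000_000 + 10_000_000
                              for i in range(3)]
                             + [("chr9", i * 3_000_000 + 10_000_000)
                                for i in range(10)])
        res = partial_identity_score(a, b, tolerance=0)
        assert (res.matched_breakpoints, res.n_a, res.n_b) == (3, 10, 13)
        assert res.score == pytest.approx(2 * 3 / 23)

    def test_rarity_weighted_variant(self):
        a = make_breakpoints([10_000_000, 50_000_000])
        b = make_breakpoints([10_000_000, 80_000_000])
        weights = {("chr1", 10): 0.5}   # the matched bin is common
        unweighted = partial_identity_score(a, b)
        weighted = partial_identity_score(a, b, weights=weights)
        assert weighted.weighted and not unweighted.weighted
        assert weighted.score == pytest.approx((0.5 + 0.5) / 3.0)
        assert weighted.score < unweighted.score

    @given(na=st.integers(0, 8), nb=st.integers(0, 8),
           seed=st.integers(0, 100))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_symmetry_and_bounds(self, na, nb, seed):
        rng = np.random.default_rng(seed)
        a = make_breakpoints(rng.integers(0, 60, size=na) * 10**6)
        b = make_breakpoints(rng.integers(0, 60, size=nb) * 10**6)
        ab = partial_identity_score(a, b)
        ba = partial_identity_score(b, a)
        assert 0.0 <= ab.score <= 1.0
        assert ab.score == pytest.approx(ba.score)
        assert ab.matched_breakpoints == ba.matched_breakpoints

    def test_monotonicity_in_matches_and_private_breakpoints(self):
        a = make_breakpoints([10_000_000, 50_000_000])
        b = make_breakpoints([10_000_000, 80_000_000])
        base = partial_identity_score(a, b).score
        # adding a matched pair to both sides raises the score
        a2 = a + make_breakpoints([("chr5", 30_000_000)])
        b2 = b + make_breakpoints([("chr5", 30_000_000)])
        assert partial_identity_score(a2, b2).score > base
        # adding a private breakpoint to one side lowers it
        a3 = a + make_breakpoints([("chr8", 30_000_000)])
        assert partial_identity_score(a3, b).score < base


class TestCalibration:
    def test_degenerate_null_gives_its_value(self):
        cal = calibrate_cutoff([0.02, 0.02, 0.02])
        assert cal.sd == 0.0 and cal.cutoff == pytest.approx(0.02)

    def test_normal_ci_hand_computed(self):
        scores = [0.0, 0.0, 0.0, 0.04]
        cal = calibrate_cutoff(scores, method="normal_ci", level=0.95)
        mean = 0.01
        sd = float(np.std(scores, ddof=1))
        assert cal.mean == pytest.approx(mean)
        assert cal.cutoff == pytest.approx(mean + 1.959963985 * sd)

    def test_percentile_method(self):
        scores = [0.0] * 38 + [0.1, 0.2]
        cal = calibrate_cutoff(scores, method="percentile", level=0.95)
        assert cal.cutoff == pytest.approx(
            np.quantile(scores, 0.975))
        assert min(scores) <= cal.cutoff <= max(scores)

    def test_minimum_sample_sizes(self):
        with pytest.raises(CalibrationError, match="3"):
            calibrate_cutoff([0.0, 0.1], method="normal_ci")
        with pytest.raises(CalibrationError, match="20"):
            calibrate_cutoff([0.0] * 19, method="percentile")

    def test_cutoff_not_below_mean(self):
        rng = np.random.default_rng(11)
        scores = rng.uniform(0, 0.2, size=50).tolist()
        cal = calibrate_cutoff(scores, method="normal_ci")
        assert cal.cutoff >= cal.mean


class TestPairRelatedness:
    @pytest.fixture()
    def reference_profiles(self):
        from felclone.simulate import (SimulationConfig,
                                       simulate_reference_cohort)
        return simulate_reference_cohort(SimulationConfig(seed=5),
                                         n_profiles=22)

    def test_profile_vs_itself_is_related(self, five_lesion_case,
                                          default_exclusions,
                                          reference_profiles):
        fa3 = five_lesion_case["profiles"]["FA3"]
        rel = pair_relatedness(fa3, fa3, reference_profiles,
                               excl=default_exclusions)
        assert rel.result.score == 1.0
        assert rel.status == "ok" and rel.verdict is True

    def test_flat_profile_is_non_informative(self, five_lesion_case,
                                             default_exclusions,
                                             reference_profiles):
        benign = five_lesion_case["profiles"]["BenignPT"]
        fa2 = five_lesion_case["profiles"]["FA2"]
        rel = pair_relatedness(fa2, benign, reference_profiles,
                               excl=default_exclusions)
        assert rel.status == "non_informative"
        assert rel.verdict is None
        assert rel.result.score == 0.0

    def test_empty_reference_set_yields_no_verdict(self, five_lesion_case,
                                                   default_exclusions):
        profiles = five_lesion_case["profiles"]
        rel = pair_relatedness(profiles["FA3"], profiles["MalignantPT"],
                               [], excl=default_exclusions)
        assert rel.status == "no_reference" and rel.verdict is None

    def test_shared_breakpoints_exceed_null(self, five_lesion_case,
                                            default_exclusions,
                                            reference_profiles):
        profiles = five_lesion_case["profiles"]
        rel = pair_relatedness(profiles["FA3"], profiles["MalignantPT"],
                               reference_profiles,
                               excl=default_exclusions)
        assert rel.result.matched_breakpoints == 3
        assert rel.result.score == pytest.approx(6 / 11)
        assert rel.verdict is True
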