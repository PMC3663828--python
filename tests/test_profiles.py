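"""Read-to-profile construction, filters, smoothing, and normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucleoform import (
    FilterMask,
    GenomeAssembly,
    MappedRead,
    SmoothingParams,
    cutsite_filter,
    gap_filter,
    gaussian_smooth,
    high_coverage_filter,
    normalize_to_probability,
    normalized_occupancy,
    paired_to_start_profile,
    reads_to_start_profile,
)
from nucleoform.profiles import ReadStartProfile, coverage_from_starts


@pytest.fixture
def flat_genome():
    return GenomeAssembly({"c1": "A" * 10_000})


# ---------------------------------------------------------------------------
# start profiles


class TestReadsToStartProfile:
    def test_forward_read_contributes_at_first_base(self, flat_genome):
        prof = reads_to_start_profile(
            [MappedRead("c1", 100, 136, "+")], flat_genome, 147)
        assert prof.data["c1"][100] == 1.0
        assert prof.total_weight == 1.0

    def test_reverse_read_last_base_is_nucleosome_end(self, flat_genome):
        # last base 246 (read [211, 247)) -> start 246 - 147 + 1 = 100
        prof = reads_to_start_profile(
            [MappedRead("c1", 211, 247, "-")], flat_genome, 147)
        assert prof.data["c1"][100] == 1.0

    def test_fractional_weights_add(self, flat_genome):
        reads = [MappedRead("c1", 500, 536, "+", 0.5),
                 MappedRead("c1", 500, 536, "+", 0.5)]
        prof = reads_to_start_profile(reads, flat_genome, 147)
        assert prof.data["c1"][500] == 1.0
        assert prof.total_weight == 1.0

    def test_unknown_chromosome_rejected_with_warning(self, flat_genome, caplog):
        prof = reads_to_start_profile(
            [MappedRead("nope", 0, 36, "+")], flat_genome, 147)
        assert prof.total_weight == 0.0
        assert "unknown chromosome" in caplog.text

    def test_out_of_range_start_dropped_and_counted(self, flat_genome):
        # reverse read near the chromosome start maps to a negative start
        prof = reads_to_start_profile(
            [MappedRead("c1", 0, 36, "-")], flat_genome, 147)
        assert prof.total_weight == 0.0
        assert prof.n_dropped == 1.0

    def test_bad_footprint_raises(self, flat_genome):
        with pytest.raises(ValueError):
            reads_to_start_profile([], flat_genome, 0)


class TestPairedToStartProfile:
    @pytest.mark.parametrize("start,end,expect", [
        (1000, 1146, 1000),   # symmetric 146-bp fragment, midpoint 1073
        (1000, 1147, 1000),   # odd span
    ])
    def test_midpoint_dyad_assignment(self, flat_genome, start, end, expect):
        pairs = pd.DataFrame({"chrom": ["c1"], "start": [start], "end": [end]})
        prof = paired_to_start_profile(pairs, flat_genome, 147)
        assert prof.data["c1"][expect] == 1.0

    @pytest.mark.parametrize("span", [129, 201])
    def test_span_outside_bounds_discarded(self, flat_genome, span):
        pairs = pd.DataFrame({"chrom": ["c1"], "start": [1000],
                              "end": [1000 + span]})
        prof = paired_to_start_profile(pairs, flat_genome, 147)
        assert prof.total_weight == 0.0

    def test_boundary_spans_kept(self, flat_genome):
        pairs = pd.DataFrame({"chrom": ["c1", "c1"], "start": [1000, 2000],
                              "end": [1130, 2200]})
        prof = paired_to_start_profile(pairs, flat_genome, 147)
        assert prof.total_weight == 2.0


# ---------------------------------------------------------------------------
# filters


def naive_gap_mask(v, min_gap):
    mask = np.zeros(len(v), dtype=bool)
    i = 0
    while i < len(v):
        if v[i] == 0:
            j = i
            while j < len(v) and v[j] == 0:
                j += 1
            if j - i >= min_gap:
                mask[i:j] = True
            i = j
        else:
            i += 1
    return mask


class TestGapFilter:
    @pytest.mark.parametrize("run,masked", [(1200, True), (999, False)])
    def test_zero_run_threshold(self, run, masked):
        v = np.ones(5000)
        v[2000:2000 + run] = 0.0
        prof = ReadStartProfile({"c1": v}, 147)
        m = gap_filter(prof, 1000)
        assert m["c1"][2000:2000 + run].all() == masked
        assert m["c1"].sum() == (run if masked else 0)

    def test_no_zeros_empty_mask(self):
        prof = ReadStartProfile({"c1": np.ones(3000)}, 147)
        assert gap_filter(prof).n_masked() == 0

    def test_matches_naive_reference(self, rng):
        v = (rng.random(20_000) < 0.002) * 1.0
        prof = ReadStartProfile({"c1": v}, 147)
        m = gap_filter(prof, 300)
        np.testing.assert_array_equal(m["c1"], naive_gap_mask(v, 300))


def naive_high_coverage_mask(v, halfwidth, fold, ext):
    """Scalar reference loop implementing the published scan verbatim."""
    L = len(v)
    mean = v.mean()
    runavg = np.array([v[max(0, i - halfwidth):min(L, i + halfwidth + 1)].mean()
                       for i in range(L)])
    mask = np.zeros(L, dtype=bool)
    for i in range(L):
        if runavg[i] > fold * mean:
            left = i
            while left > 0 and runavg[left] > mean:
                left -= 1
            if runavg[left] <= mean:
                left += 1
            right = i
            while right < L - 1 and runavg[right] > mean:
                right += 1
            if runavg[right] <= mean:
                right -= 1
            mask[max(0, left - ext):right + 1] = True
    return mask


class TestHighCoverageFilter:
    def test_flat_coverage_empty(self):
        m = high_coverage_filter({"c1": np.full(5000, 2.0)})
        assert m.n_masked() == 0

    def test_below_threshold_empty(self):
        v = np.ones(5000)
        v[100:200] = 2.5  # stays below 3x mean
        assert high_coverage_filter({"c1": v}).n_masked() == 0

    def test_rectangular_spike_matches_reference(self):
        v = np.ones(8000)
        v[3000:3500] = 10.0 * v.mean()
        m = high_coverage_filter({"c1": v}, 75, 3.0, 146)
        ref = naive_high_coverage_mask(v, 75, 3.0, 146)
        np.testing.assert_array_equal(m["c1"], ref)
        # spike itself plus flanks plus upstream extension are masked
        assert m["c1"][3000:3500].all()
        assert m["c1"].sum() > 500 + 146

    def test_random_profile_matches_reference(self, rng):
        v = rng.poisson(1.0, 4000).astype(float)
        v[1000:1100] += 20
        m = high_coverage_filter({"c1": v}, 25, 3.0, 50)
        np.testing.assert_array_equal(
            m["c1"], naive_high_coverage_mask(v, 25, 3.0, 50))

    def test_empty_chromosome(self):
        assert high_coverage_filter({"c1": np.empty(0)}).n_masked() == 0


class TestCutsiteFilter:
    def test_gtac_masks_200bp_flanks(self):
        seq = "A" * 5000 + "GTAC" + "A" * 5000
        g = GenomeAssembly({"c1": seq})
        m = cutsite_filter(g, "GTAC", 200)
        expect = np.zeros(len(seq), dtype=bool)
        expect[4800:5204] = True
        np.testing.assert_array_equal(m["c1"], expect)

    @pytest.mark.parametrize("hexamer", ["GTCAAC", "GTTGAC", "GTCGAC",
                                         "GTTAAC"])
    def test_gtyrac_degeneracy(self, hexamer):
        g = GenomeAssembly({"c1": "A" * 300 + hexamer + "A" * 300})
        m = cutsite_filter(g, "GTYRAC", 10)
        assert m["c1"][300 - 10:306 + 10].all()
        assert m["c1"].sum() == 6 + 20

    def test_no_match_empty(self):
        g = GenomeAssembly({"c1": "A" * 1000})
        assert cutsite_filter(g, "GTAC").n_masked() == 0

    def test_invalid_iupac_raises(self):
        g = GenomeAssembly({"c1": "ACGT" * 10})
        with pytest.raises(ValueError):
            cutsite_filter(g, "GTXC")

    def test_mask_monotone_in_flank(self):
        g = GenomeAssembly({"c1": ("ACGT" * 200) + "GTAC" + ("TGCA" * 200)})
        m100 = cutsite_filter(g, "GTAC", 100)["c1"]
        m200 = cutsite_filter(g, "GTAC", 200)["c1"]
        assert (m200 | m100 == m200).all()  # enlarging flank never unmasks


class TestMaskAlgebra:
    def test_union_commutative_and_idempotent(self, rng):
        a = FilterMask({"c1": rng.random(500) < 0.2})
        b = FilterMask({"c1": rng.random(500) < 0.2})
        np.testing.assert_array_equal((a | b)["c1"], (b | a)["c1"])
        np.testing.assert_array_equal((a | a)["c1"], a["c1"])

    def test_interval_round_trip(self):
        m = FilterMask.from_intervals({"c1": 100}, [("c1", 10, 20),
                                                    ("c1", 15, 30)])
        assert m.to_intervals() == [("c1", 10, 30)]


# ---------------------------------------------------------------------------
# smoothing and normalization


class TestGaussianSmooth:
    def test_unit_read_peak_value(self):
        prof = ReadStartProfile({"c1": np.eye(1, 2001, 1000).ravel()}, 147)
        sm = gaussian_smooth(prof, SmoothingParams(2))
        assert sm.data["c1"][1000] == pytest.approx(1 / (2 * np.sqrt(2 * np.pi)),
                                                    rel=1e-3)

    def test_mass_conserved(self, rng):
        v = np.zeros(4000)
        v[500:3500] = rng.random(3000)
        prof = ReadStartProfile({"c1": v}, 147)
        for sigma in (2, 20):
            sm = gaussian_smooth(prof, SmoothingParams(sigma))
            assert sm.total_weight == pytest.approx(prof.total_weight,
                                                    abs=1e-4 * prof.total_weight)

    def test_two_close_reads_approximate_double_gaussian(self):
        v1 = np.zeros(4000)
        v1[2000] = 1.0
        v2 = np.zeros(4000)
        v2[2000] = 1.0
        v2[2001] = 1.0
        p = SmoothingParams(20)
        s1 = gaussian_smooth(ReadStartProfile({"c": v1}, 147), p).data["c"]
        s2 = gaussian_smooth(ReadStartProfile({"c": v2}, 147), p).data["c"]
        assert np.abs(s2 - (s1 + np.roll(s1, 1))).max() < 1e-12
        assert np.abs(s2 - 2 * s1).max() < 1e-3  # 1-bp shift is negligible at sigma=20

    def test_truncation_radius_validation(self):
        with pytest.raises(ValueError):
            SmoothingParams(20, truncation_radius=50)


class TestNormalizeToProbability:
    def test_flat_profile_unit_occupancy(self):
        prof = ReadStartProfile({"c1": np.full(2000, 0.3)}, 147)
        pair = normalize_to_probability(prof, None, 147)
        mid = pair.O["c1"][500:1500]
        np.testing.assert_allclose(mid, 1.0, atol=1e-12)

    def test_max_unmasked_occupancy_is_one(self, rng):
        v = rng.random(3000)
        prof = ReadStartProfile({"c1": v}, 147)
        mask = FilterMask({"c1": np.arange(3000) < 200})
        pair = normalize_to_probability(prof, mask, 147)
        assert pair.O["c1"][200:].max() == pytest.approx(1.0)

    def test_consistency_invariant_after_scaling(self, rng):
        prof = ReadStartProfile({"c1": rng.random(2000)}, 21)
        pair = normalize_to_probability(prof, None, 21)
        assert pair.consistency_error() < 1e-9

    def test_coverage_difference_identity(self, rng):
        """O_i - O_{i-1} = P_i - P_{i-footprint} at interior positions."""
        a = 21
        P = rng.random(1000)
        O = coverage_from_starts(P, a)
        i = np.arange(a, 990)
        np.testing.assert_allclose(O[i] - O[i - 1], P[i] - P[i - a],
                                   atol=1e-12)

    def test_all_masked_chromosome_skipped(self, caplog):
        prof = ReadStartProfile({"c1": np.ones(500)}, 147)
        mask = FilterMask({"c1": np.ones(500, dtype=bool)})
        pair = normalize_to_probability(prof, mask, 147)
        assert "c1" not in pair.P


class TestNormalizedOccupancy:
    def test_three_point_profile(self):
        out = normalized_occupancy({"c1": np.array([1.0, 2.0, 3.0])})
        np.testing.assert_allclose(out["c1"], [-1.2247448, 0.0, 1.2247448],
                                   atol=1e-6)

    def test_constant_profile_raises(self):
        with pytest.raises(ValueError, match="variance"):
            normalized_occupancy({"c1": np.full(100, 2.0)})

    def test_mean_zero_var_one_over_unmasked(self, rng):
        O = {"c1": rng.random(1000), "c2": rng.random(500)}
        mask = FilterMask({"c1": rng.random(1000) < 0.3,
                           "c2": np.zeros(500, dtype=bool)})
        out = normalized_occupancy(O, mask)
        pooled = np.concatenate([out["c1"][~mask["c1"]], out["c2"]])
        assert abs(pooled.mean()) < 1e-9
        assert abs(pooled.var() - 1.0) < 1e-9
        assert np.isnan(out["c1"][mask["c1"]]).all()


@settings(max_examples=25, deadline=None, derandomize=True)
@given(weights=st.lists(st.floats(0.1, 1.0), min_size=2, max_size=30),
       sigma=st.sampled_from([2.0, 20.0]))
def test_smoothing_conserves_arbitrary_read_mass(weights, sigma):
    """Smoothing is linear and mass-conserving for any read placement."""
    v = np.zeros(2000)
    pos = np.linspace(300, 1700, len(weights)).astype(int)
    for p, w in zip(pos, weights):
        v[p] += w
    prof = ReadStartProfile({"c": v}, 147)
    sm = gaussian_smooth(prof, SmoothingParams(sigma))
    assert abs(sm.total_weight - prof.total_weight) < 1e-4 * prof.total_weight
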