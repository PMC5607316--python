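"""Temporal-stability statistics against independent scalar oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dielbias import (
    build_stability_profile,
    mean_relative_difference,
    middle_ranks,
    optimal_interval,
    rank_hours,
    relative_difference,
    sd_mrd,
)
from dielbias.flux_io import EmptyInputError
from dielbias.temporal_stability import (
    DegenerateCampaignError,
    HourStability,
    RDProfile,
    StabilityProfile,
)

from conftest import make_campaign


# ------------------------------------------------------------------- oracles

def oracle_rd(fluxes):
    """Scalar-by-scalar relative difference: (x_i - mean)/mean."""
    m = sum(fluxes) / len(fluxes)
    return [(x - m) / m for x in fluxes]


def oracle_mean(values):
    return sum(values) / len(values)


def oracle_sample_sd(values):
    m = oracle_mean(values)
    return math.sqrt(sum((v - m) ** 2 for v in values) / (len(values) - 1))


def oracle_ranks(mrd):
    """Stable sort by (value, hour); rank = 1-based position."""
    ordered = sorted(sorted(mrd), key=lambda h: mrd[h])  # stable on hour
    return {h: i + 1 for i, h in enumerate(ordered)}


def oracle_best_run(mrd, threshold):
    """Exhaustive scan over every start hour and circular run length."""
    good = {h for h, v in mrd.items() if abs(v) <= threshold}
    best = None
    for start in sorted(good):
        for length in range(1, 25):
            hours = [(start + k) % 24 for k in range(length)]
            if all(h in good for h in hours):
                if best is None or length > best[1]:
                    best = (start, length)
            else:
                break
    return best


# ------------------------------------------------------------ RD (per hour)

class TestRelativeDifference:
    def test_constant_series_has_zero_rd_everywhere(self):
        profile = relative_difference(make_campaign([2.0] * 24))
        assert all(v == 0.0 for v in profile.rd.values())
        assert profile.campaign_mean == 2.0

    def test_two_point_campaign(self):
        profile = relative_difference(make_campaign([1.0, 3.0]))
        assert profile.campaign_mean == 2.0
        assert profile.rd[9] == -0.5
        assert profile.rd[10] == 0.5

    def test_matches_scalar_oracle_on_random_fluxes(self):
        rng = np.random.default_rng(7)
        fluxes = list(rng.uniform(0.2, 3.0, 24))
        profile = relative_difference(make_campaign(fluxes, start_hour=0))
        expected = oracle_rd(fluxes)
        for hour in range(24):
            assert profile.rd[hour] == pytest.approx(expected[hour], rel=1e-12)
        assert abs(sum(profile.rd.values())) < 1e-12

    def test_zero_mean_rejected(self):
        with pytest.raises(DegenerateCampaignError):
            relative_difference(make_campaign([1.0, -1.0]))

    def test_negative_mean_rejected_with_guidance(self):
        with pytest.raises(DegenerateCampaignError, match="inspect the data"):
            relative_difference(make_campaign([-1.0, -3.0]))

    def test_single_slot_rejected(self):
        with pytest.raises(ValueError):
            relative_difference(make_campaign([1.0]))

    @settings(derandomize=True, max_examples=200)
    @given(
        st.lists(
            st.floats(min_value=0.01, max_value=50.0, allow_nan=False),
            min_size=24, max_size=24,
        )
    )
    def test_complete_campaign_rd_sums_to_zero(self, fluxes):
        profile = relative_difference(make_campaign(fluxes))
        assert abs(sum(profile.rd.values()) / 24.0) < 1e-12

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=50.0, allow_nan=False),
            min_size=2, max_size=24,
        ).filter(lambda xs: sum(xs) > 0)
    )
    def test_rd_bounded_below_for_nonnegative_fluxes(self, fluxes):
        profile = relative_difference(make_campaign(fluxes))
        assert all(v >= -1.0 for v in profile.rd.values())


# --------------------------------------------------------------- MRD / SDMRD

def _random_profiles(n, seed, hours=range(24)):
    rng = np.random.default_rng(seed)
    profiles = []
    for k in range(n):
        fluxes = rng.uniform(0.2, 3.0, len(list(hours)))
        profiles.append(relative_difference(make_campaign(list(fluxes), start_hour=0)))
    return profiles


class TestMeanRelativeDifference:
    def test_single_profile_collapses_to_rd(self):
        (profile,) = _random_profiles(1, seed=2)
        mrd = mean_relative_difference([profile])
        assert {h: v for h, (v, _) in mrd.items()} == profile.rd
        assert all(n == 1 for _, n in mrd.values())

    def test_symmetric_profiles_cancel(self):
        a = RDProfile("a", "t", {9: 0.2}, 1.0)
        b = RDProfile("b", "t", {9: -0.2}, 1.0)
        mrd = mean_relative_difference([a, b])
        assert mrd[9] == (pytest.approx(0.0), 2)

    def test_matches_brute_force_mean_per_hour(self):
        profiles = _random_profiles(5, seed=11)
        mrd = mean_relative_difference(profiles)
        for hour, (value, n) in mrd.items():
            contributions = [p.rd[hour] for p in profiles if hour in p.rd]
            assert n == len(contributions)
            assert value == pytest.approx(oracle_mean(contributions), rel=1e-12)

    def test_hours_unobserved_by_all_campaigns_absent(self):
        a = RDProfile("a", "t", {9: 0.1, 10: -0.1}, 1.0)
        b = RDProfile("b", "t", {10: 0.3, 11: -0.3}, 1.0)
        mrd = mean_relative_difference([a, b])
        assert set(mrd) == {9, 10, 11}
        assert mrd[10] == (pytest.approx(0.1), 2)

    def test_empty_input_rejected(self):
        with pytest.raises(EmptyInputError):
            mean_relative_difference([])


class TestSdMrd:
    def test_identical_profiles_have_zero_spread(self):
        (profile,) = _random_profiles(1, seed=5)
        profiles = [profile, profile, profile]
        mrd = mean_relative_difference(profiles)
        sd = sd_mrd(profiles, mrd)
        assert all(v == pytest.approx(0.0, abs=1e-14) for v in sd.values())

    def test_two_point_sample_sd(self):
        a = RDProfile("a", "t", {9: 0.1}, 1.0)
        b = RDProfile("b", "t", {9: 0.3}, 1.0)
        mrd = mean_relative_difference([a, b])
        sd = sd_mrd([a, b], mrd)
        assert sd[9] == pytest.approx(0.1414213562, abs=1e-9)

    def test_matches_brute_force_sample_sd(self):
        profiles = _random_profiles(8, seed=3)
        mrd = mean_relative_difference(profiles)
        sd = sd_mrd(profiles, mrd)
        for hour in mrd:
            values = [p.rd[hour] for p in profiles if hour in p.rd]
            assert sd[hour] == pytest.approx(oracle_sample_sd(values), rel=1e-12)

    def test_single_contributor_hour_left_unset(self):
        a = RDProfile("a", "t", {9: 0.1, 10: 0.2}, 1.0)
        b = RDProfile("b", "t", {9: 0.3}, 1.0)
        mrd = mean_relative_difference([a, b])
        sd = sd_mrd([a, b], mrd)
        assert sd[10] is None
        assert sd[9] is not None


# -------------------------------------------------------------------- ranking

class TestRankHours:
    def test_sorted_input_keeps_hour_order(self):
        mrd = {h: -0.5 + h * 0.04 for h in range(24)}
        ranks = rank_hours(mrd)
        assert ranks == {h: h + 1 for h in range(24)}

    def test_middle_ranks_for_24_hours(self):
        assert middle_ranks(24) == {12, 13}

    def test_middle_rank_for_odd_count(self):
        assert middle_ranks(5) == {3}

    def test_ties_resolved_by_earlier_hour_matches_stable_sort(self):
        rng = np.random.default_rng(5)
        mrd = {h: round(float(rng.uniform(-0.3, 0.3)), 2) for h in range(24)}
        mrd[7] = mrd[19] = 0.05  # forced exact tie
        ranks = rank_hours(mrd)
        assert ranks == oracle_ranks(mrd)
        assert ranks[7] < ranks[19]
        assert sorted(ranks.values()) == list(range(1, 25))

    @settings(derandomize=True, max_examples=500)
    @given(
        st.dictionaries(
            st.integers(min_value=0, max_value=23),
            st.floats(min_value=-1.0, max_value=1.0, allow_nan=False),
            min_size=1, max_size=24,
        )
    )
    def test_ranks_are_always_a_permutation(self, mrd):
        ranks = rank_hours(mrd)
        assert sorted(ranks.values()) == list(range(1, len(mrd) + 1))


# ----------------------------------------------------------- optimal interval

def _profile_from_mrd(mrd, sdmrd=None):
    ranks = rank_hours(mrd)
    return StabilityProfile(
        treatment="t", season_scope="all",
        hours={
            h: HourStability(
                mrd=v, n_campaigns=2, rank=ranks[h],
                sdmrd=(sdmrd or {}).get(h, 0.0),
            )
            for h, v in mrd.items()
        },
    )


class TestOptimalInterval:
    def test_unique_zero_wins(self):
        mrd = {h: 0.2 for h in range(24)}
        mrd[20] = 0.0
        report = optimal_interval(_profile_from_mrd(mrd))
        assert report.best_hour_by_mrd == 20

    def test_abs_mrd_tie_broken_by_lower_sdmrd(self):
        mrd = {h: 0.5 for h in range(24)}
        mrd[5] = 0.02
        mrd[17] = -0.02
        sd = {5: 0.10, 17: 0.05}
        report = optimal_interval(_profile_from_mrd(mrd, sd))
        assert report.best_hour_by_mrd == 17

    def test_full_tie_broken_by_earlier_hour(self):
        mrd = {h: 0.1 for h in range(24)}
        report = optimal_interval(_profile_from_mrd(mrd))
        assert report.best_hour_by_mrd == 0

    def test_middle_rank_hours_for_24h_profile(self):
        mrd = {h: -0.5 + h * 0.04 for h in range(24)}
        report = optimal_interval(_profile_from_mrd(mrd))
        ranks = rank_hours(mrd)
        assert {ranks[h] for h in report.middle_rank_hours} == {12, 13}

    def test_circular_run_wraps_midnight(self):
        mrd = {h: 0.5 for h in range(24)}
        for h in (22, 23, 0, 1):
            mrd[h] = 0.01
        report = optimal_interval(_profile_from_mrd(mrd), run_threshold=0.05)
        assert report.best_consecutive_run == (22, 4)

    def test_matches_exhaustive_scan_on_random_profile(self):
        rng = np.random.default_rng(9)
        mrd = {h: float(rng.uniform(-0.12, 0.12)) for h in range(24)}
        report = optimal_interval(_profile_from_mrd(mrd), run_threshold=0.05)
        assert report.best_consecutive_run == oracle_best_run(mrd, 0.05)
        best = min(mrd, key=lambda h: (abs(mrd[h]), h))
        assert report.best_hour_by_mrd == best

    def test_no_hour_below_threshold_gives_no_run(self):
        mrd = {h: 0.5 for h in range(24)}
        report = optimal_interval(_profile_from_mrd(mrd), run_threshold=0.05)
        assert report.best_consecutive_run is None


# ------------------------------------------------------------ end-to-end MRD

class TestGroundTruthRecovery:
    def test_noise_free_campaigns_recover_true_profile(self, noise_free_campaigns):
        campaigns, truth = noise_free_campaigns
        profile = build_stability_profile(
            [relative_difference(c) for c in campaigns], "trench"
        )
        for hour in range(24):
            assert profile.hours[hour].mrd == pytest.approx(
                truth.relative_profile[hour], abs=1e-10
            )
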