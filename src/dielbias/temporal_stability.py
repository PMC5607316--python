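"""Temporal-stability statistics: RD, MRD, SDMRD, ranking, optimal hours.

The temporal-stability framework asks whether the deviation of each hour's
soil-respiration flux from the daily mean persists across days.  For one
24-hr campaign the *relative difference* at hour i is

    RD_i = (x_i - m) / m,        m = mean of the campaign's hourly fluxes.

Averaging RD_i over N campaigns gives the *mean relative difference*
MRD_i (the systematic sampling-time bias at hour i) and its sample standard
deviation SDMRD_i (the precision of that bias).  Hours are ranked by MRD in
ascending order; the most representative sampling time is the hour whose
MRD is closest to zero with the lowest SDMRD, and the "ideal" hour under the
rank rule is the one holding the middle rank (12 or 13 of 24).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .flux_io import Campaign, EmptyInputError

logger = logging.getLogger("dielbias")


class DegenerateCampaignError(ValueError):
    """The campaign mean is zero or negative, so RD is undefined or inverted."""


@dataclass(frozen=True)
class RDProfile:
    """Per-hour relative differences for one campaign.

    ``rd`` maps hour of day (0-23) to the dimensionless relative difference;
    for a complete campaign the rd values average to zero by construction.
    """

    campaign_id: str
    treatment: str
    rd: dict[int, float]
    campaign_mean: float
    season: str = ""


@dataclass(frozen=True)
class HourStability:
    """MRD/SDMRD/rank summary for one hour of day."""

    mrd: float
    n_campaigns: int
    rank: int
    sdmrd: float | None = None


@dataclass(frozen=True)
class StabilityProfile:
    """Per-hour MRD, SDMRD and rank for one treatment and season scope."""

    treatment: str
    season_scope: str  # "all" | season label
    hours: dict[int, HourStability]

    @property
    def n_hours(self) -> int:
        return len(self.hours)


@dataclass(frozen=True)
class OptimalWindowReport:
    """Most representative sampling hours for a stability profile."""

    best_hour_by_mrd: int
    middle_rank_hours: frozenset[int]
    best_consecutive_run: tuple[int, int] | None  # (start hour, length)
    threshold: float


def relative_difference(c: Campaign) -> RDProfile:
    """Compute the per-hour relative difference profile of a campaign.

    Raises
    ------
    DegenerateCampaignError
        If the campaign mean flux is zero (undefined denominator) or
        negative (RD sign semantics invert; inspect the data).
    ValueError
        If the campaign has fewer than two slots.
    """
    if c.n < 2:
        raise ValueError(f"campaign {c.campaign_id} has n={c.n}; need n >= 2")
    m = sum(s.flux for s in c.hourly_flux) / c.n
    if m == 0.0:
        raise DegenerateCampaignError(
            f"campaign {c.campaign_id} has zero mean flux; RD undefined"
        )
    if m < 0.0:
        raise DegenerateCampaignError(
            f"campaign {c.campaign_id} has negative mean flux ({m:g}); "
            "RD sign semantics invert — inspect the data"
        )
    rd = {s.hour_of_day: (s.flux - m) / m for s in c.hourly_flux}
    for hour, value in rd.items():
        if value > 1.0:
            logger.warning(
                "campaign %s hour %d: RD=%.3f exceeds 1 (flux > 2x daily mean)",
                c.campaign_id, hour, value,
            )
    return RDProfile(
        campaign_id=c.campaign_id,
        treatment=c.treatment,
        rd=rd,
        campaign_mean=m,
    )


def mean_relative_difference(
    profiles: list[RDProfile],
) -> dict[int, tuple[float, int]]:
    """Per-hour mean RD across campaigns: hour → (mrd, n_campaigns).

    Each hour is averaged over only the campaigns that observed it; hours
    observed by no campaign are absent.  With a single profile the result
    collapses to that profile's RD elementwise.
    """
    if not profiles:
        raise EmptyInputError("mean_relative_difference needs >= 1 profile")
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for p in profiles:
        for hour, value in p.rd.items():
            sums[hour] = sums.get(hour, 0.0) + value
            counts[hour] = counts.get(hour, 0) + 1
    return {h: (sums[h] / counts[h], counts[h]) for h in sorted(sums)}


def sd_mrd(
    profiles: list[RDProfile], mrd: dict[int, tuple[float, int]]
) -> dict[int, float | None]:
    """Per-hour sample SD of RD across campaigns (None where < 2 contribute)."""
    out: dict[int, float | None] = {}
    for hour, (mean_value, n_h) in mrd.items():
        if n_h < 2:
            out[hour] = None
            continue
        ss = sum(
            (p.rd[hour] - mean_value) ** 2 for p in profiles if hour in p.rd
        )
        out[hour] = math.sqrt(ss / (n_h - 1))
    return out


def rank_hours(mrd: dict[int, float]) -> dict[int, int]:
    """Assign ranks 1..H to hours in ascending MRD order.

    Rank 1 is the most negative MRD, rank H the most positive; exact ties
    are broken by the earlier hour of day, so the output is deterministic
    and always a permutation of 1..H.
    """
    if not mrd:
        raise EmptyInputError("rank_hours needs >= 1 hour")
    ordered = sorted(mrd, key=lambda h: (mrd[h], h))
    return {hour: i + 1 for i, hour in enumerate(ordered)}


def build_stability_profile(
    profiles: list[RDProfile],
    treatment: str,
    season_scope: str = "all",
) -> StabilityProfile:
    """Combine RD profiles into a ranked per-hour stability profile."""
    mrd = mean_relative_difference(profiles)
    sd = sd_mrd(profiles, mrd)
    ranks = rank_hours({h: v for h, (v, _) in mrd.items()})
    return StabilityProfile(
        treatment=treatment,
        season_scope=season_scope,
        hours={
            h: HourStability(mrd=v, n_campaigns=n, rank=ranks[h], sdmrd=sd[h])
            for h, (v, n) in mrd.items()
        },
    )


def middle_ranks(n_hours: int) -> set[int]:
    """Middle rank(s) of 1..H: {⌈H/2⌉, ⌈H/2⌉+1} for even H, one rank for odd."""
    lower = math.ceil(n_hours / 2)
    return {lower} if n_hours % 2 == 1 else {lower, lower + 1}


def optimal_interval(
    p: StabilityProfile, run_threshold: float = 0.05
) -> OptimalWindowReport:
    """Select the most representative sampling hours from a profile.

    ``best_hour_by_mrd`` minimizes |MRD|, ties broken by lower SDMRD then
    earlier hour (absent SDMRD sorts last).  ``middle_rank_hours`` holds the
    hour(s) with the middle rank(s).  ``best_consecutive_run`` is the longest
    circular run of hours (wrapping 23 → 0) whose |MRD| stays at or below
    ``run_threshold``; ties go to the earliest start hour.
    """
    if not p.hours:
        raise EmptyInputError("optimal_interval needs a non-empty profile")

    def _key(h: int) -> tuple[float, float, int]:
        hs = p.hours[h]
        sd = hs.sdmrd if hs.sdmrd is not None else math.inf
        return (abs(hs.mrd), sd, h)

    best = min(p.hours, key=_key)
    targets = middle_ranks(p.n_hours)
    middle = frozenset(h for h, hs in p.hours.items() if hs.rank in targets)

    good = {h for h, hs in p.hours.items() if abs(hs.mrd) <= run_threshold}
    best_run: tuple[int, int] | None = None
    for start in sorted(good):
        length = 0
        h = start
        while h in good and length < 24:
            length += 1
            h = (h + 1) % 24
        if best_run is None or length > best_run[1]:
            best_run = (start, length)
    return OptimalWindowReport(
        best_hour_by_mrd=best,
        middle_rank_hours=middle,
        best_consecutive_run=best_run,
        threshold=run_threshold,
    )
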