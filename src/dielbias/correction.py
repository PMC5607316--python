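"""Sampling-time bias correction and seasonal/annual budget aggregation.

A flux measured at a non-representative hour can be adjusted to its
daily-mean equivalent by dividing out the systematic bias at that hour:

    Rs_hat = Rs_i / (1 + MRD_i)

Season-specific correction tables map (treatment, season, hour) to the MRD
offset; routine monitoring series (e.g. monthly mid-day surveys) are
corrected record by record, then aggregated into seasonal and
hydrological-year means with corrected-vs-uncorrected percent differences.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

from .flux_io import EmptyInputError, MonitoringRecord, SeasonSpec
from .temporal_stability import StabilityProfile

logger = logging.getLogger("dielbias")


@dataclass(frozen=True)
class TableEntry:
    mrd: float
    interpolated: bool = False


@dataclass
class CorrectionTable:
    """(treatment, season, hour) → MRD offset, with interpolation flags.

    Hours missing from the source stability profile are filled by circular
    linear interpolation between the nearest defined hours (the "window
    rule") and flagged, so lookups are total over declared
    treatment/season pairs.
    """

    entries: dict[tuple[str, str, int], TableEntry]
    provenance: str = ""

    def lookup(self, treatment: str, season: str, hour: int) -> TableEntry | None:
        return self.entries.get((treatment, season, hour))

    def declared_scopes(self) -> set[tuple[str, str]]:
        return {(t, s) for (t, s, _) in self.entries}


@dataclass(frozen=True)
class CorrectedRecord:
    """A monitoring record with its bias-corrected flux alongside the original."""

    record: MonitoringRecord
    flux_corrected: float
    offset_used: float | None
    flagged: bool  # True when uncorrected fall-through or interpolated offset


@dataclass(frozen=True)
class BudgetRow:
    treatment: str
    scope: str  # hydro-year label or season label
    variant: str  # "corrected" | "uncorrected"
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class BudgetReport:
    rows: list[BudgetRow]
    percent_differences: dict[tuple[str, str], float]  # (treatment, scope) → %


def correct_flux(rs: float, mrd: float) -> float:
    """Divide a flux by (1 + MRD); requires mrd > −1 so the divisor is positive."""
    if mrd <= -1.0:
        raise ValueError(f"mrd must exceed -1 for a positive divisor, got {mrd}")
    return rs / (1.0 + mrd)


def percent_difference(corrected_mean: float, uncorrected_mean: float) -> float:
    """100·(corrected − uncorrected)/uncorrected. Full precision; round for display."""
    if uncorrected_mean == 0.0:
        raise ValueError("uncorrected mean is zero; percent difference undefined")
    return 100.0 * (corrected_mean - uncorrected_mean) / uncorrected_mean


def _circular_interpolate(hours: dict[int, float], target: int) -> float:
    # nearest defined hours on each side of the 24-h circle, linear in between
    defined = sorted(hours)
    prev = max((h for h in defined if h < target), default=defined[-1])
    nxt = min((h for h in defined if h > target), default=defined[0])
    gap_prev = (target - prev) % 24
    gap_total = (nxt - prev) % 24
    if gap_total == 0:  # single defined hour
        return hours[prev]
    w = gap_prev / gap_total
    return (1.0 - w) * hours[prev] + w * hours[nxt]


def build_correction_table(
    profiles: dict[tuple[str, str], StabilityProfile],
    provenance: str = "",
) -> CorrectionTable:
    """Copy per-hour MRD from stability profiles into a correction table.

    ``profiles`` is keyed by (treatment, season label).  Hours 0–23 absent
    from a profile are filled by the window rule and flagged interpolated.
    """
    if not profiles:
        raise EmptyInputError("build_correction_table needs >= 1 profile")
    entries: dict[tuple[str, str, int], TableEntry] = {}
    for (treatment, season), profile in profiles.items():
        if not profile.hours:
            raise EmptyInputError(
                f"profile for ({treatment}, {season}) has no ranked hours"
            )
        mrd_by_hour = {h: hs.mrd for h, hs in profile.hours.items()}
        for hour in range(24):
            if hour in mrd_by_hour:
                entries[(treatment, season, hour)] = TableEntry(mrd_by_hour[hour])
            else:
                entries[(treatment, season, hour)] = TableEntry(
                    _circular_interpolate(mrd_by_hour, hour), interpolated=True
                )
    return CorrectionTable(entries=entries, provenance=provenance)


def apply_correction_series(
    records: list[MonitoringRecord],
    table: CorrectionTable,
    window: tuple[int, int] | None = None,
) -> list[CorrectedRecord]:
    """Correct each monitoring record's flux by its sampling-hour MRD offset.

    The offset is the mean of table offsets over the clock hours overlapped
    by the record's measurement window (``window=(start, end)`` hours,
    end-exclusive); with no window, the single clock hour of the timestamp.
    Records whose (treatment, season) is absent from the table pass through
    uncorrected and flagged.
    """
    scopes = table.declared_scopes()
    out: list[CorrectedRecord] = []
    n_uncorrected = 0
    for rec in records:
        if (rec.treatment, rec.season) not in scopes:
            out.append(CorrectedRecord(rec, rec.flux, None, True))
            n_uncorrected += 1
            continue
        if window is None:
            hours = [rec.timestamp.hour]
        else:
            start, end = window
            hours = [h % 24 for h in range(start, end)]
        entries = [table.lookup(rec.treatment, rec.season, h) for h in hours]
        entries = [e for e in entries if e is not None]
        if not entries:
            out.append(CorrectedRecord(rec, rec.flux, None, True))
            n_uncorrected += 1
            continue
        offset = sum(e.mrd for e in entries) / len(entries)
        flagged = any(e.interpolated for e in entries)
        out.append(
            CorrectedRecord(rec, correct_flux(rec.flux, offset), offset, flagged)
        )
    if n_uncorrected:
        logger.warning(
            "apply_correction_series: %d record(s) passed through uncorrected",
            n_uncorrected,
        )
    return out


def _mean_sd(values: list[float]) -> tuple[float, float]:
    n = len(values)
    m = sum(values) / n
    sd = math.sqrt(sum((v - m) ** 2 for v in values) / (n - 1)) if n > 1 else 0.0
    return m, sd


def aggregate_budget(
    corrected: list[CorrectedRecord],
    spec: SeasonSpec,
    groupings: tuple[str, ...] = ("all-year", "season"),
) -> BudgetReport:
    """Summarize corrected/uncorrected fluxes by hydro-year and season.

    Per group and variant: unweighted record mean and sample SD (no
    time-weighted integration — the budget mirrors means of monthly
    measurements).  "all-year" groups key on hydro-year labels; "season"
    groups key on season labels.
    """
    if not corrected:
        raise EmptyInputError("aggregate_budget needs >= 1 record")
    groups: dict[tuple[str, str], list[CorrectedRecord]] = {}
    for cr in corrected:
        keys = []
        if "all-year" in groupings:
            keys.append(cr.record.hydro_year)
        if "season" in groupings:
            keys.append(cr.record.season)
        for scope in keys:
            groups.setdefault((cr.record.treatment, scope), []).append(cr)

    rows: list[BudgetRow] = []
    pct: dict[tuple[str, str], float] = {}
    for (treatment, scope), members in sorted(groups.items()):
        unc = [cr.record.flux for cr in members]
        cor = [cr.flux_corrected for cr in members]
        mu_c, sd_c = _mean_sd(cor)
        mu_u, sd_u = _mean_sd(unc)
        rows.append(BudgetRow(treatment, scope, "corrected", mu_c, sd_c, len(cor)))
        rows.append(BudgetRow(treatment, scope, "uncorrected", mu_u, sd_u, len(unc)))
        if mu_u != 0.0:
            pct[(treatment, scope)] = percent_difference(mu_c, mu_u)
        else:
            logger.warning(
                "aggregate_budget: zero uncorrected mean for (%s, %s); "
                "percent difference omitted", treatment, scope,
            )
    return BudgetReport(rows=rows, percent_differences=pct)
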