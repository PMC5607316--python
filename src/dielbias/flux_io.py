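"""Data model, CSV ingestion, campaign assembly, and calendar logic.

Chamber measurements of soil CO2 efflux (Rs) arrive as long-format CSV rows:
one row per collar per time point, with optional soil temperature and
volumetric water content.  This module turns those rows into *campaigns* —
treatment-level series of consecutive hourly mean fluxes — and attaches the
calendar labels (season, hydrological year) used by the downstream
temporal-stability and budget analyses.

The canonical CSV dialect is comma-separated UTF-8 with header
``timestamp,treatment,plot,collar,flux,tsoil,swc``, ISO-8601 timestamps and
``repr``-style floats.  Lines starting with ``#`` are treated as comments.
Alternative column names can be supplied through a schema mapping.
"""

from __future__ import annotations

import csv
import io
import logging
import math
import os
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger("dielbias")

#: canonical column order for read/write round-trips
CANONICAL_COLUMNS = ("timestamp", "treatment", "plot", "collar", "flux", "tsoil", "swc")

#: required logical fields; the rest are optional
REQUIRED_FIELDS = ("timestamp", "treatment", "collar", "flux")


class ConfigurationError(ValueError):
    """A required column or configuration key is missing or malformed."""


class EmptyInputError(ValueError):
    """An operation received no usable input."""


@dataclass(frozen=True)
class FluxObservation:
    """One chamber measurement of soil CO2 efflux.

    Attributes
    ----------
    timestamp : datetime
        Local date-time of the measurement, minute resolution.
    treatment : str
        Experimental treatment label (e.g. ``"trench"``, ``"shrub"``).
    plot : str
        Plot label; may be empty.
    collar : str
        Collar (chamber base) label within the plot.
    flux : float
        Soil CO2 efflux in µmol CO2 m⁻² s⁻¹.
    soil_temperature : float or None
        Soil temperature in °C, if measured.
    soil_moisture : float or None
        Volumetric water content in m³ m⁻³ (0–1), if measured.
    """

    timestamp: datetime
    treatment: str
    collar: str
    flux: float
    plot: str = ""
    soil_temperature: float | None = None
    soil_moisture: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.flux):
            raise ValueError(f"flux must be finite, got {self.flux!r}")
        if self.soil_moisture is not None and not (0.0 <= self.soil_moisture <= 1.0):
            raise ValueError(
                f"soil_moisture must lie in [0, 1] m3/m3, got {self.soil_moisture!r}"
            )


@dataclass(frozen=True)
class CampaignSlot:
    """One hourly interval of a campaign: treatment-mean flux across collars."""

    hour_of_day: int
    flux: float
    collar_count: int


@dataclass
class Campaign:
    """One treatment's run of consecutive hourly mean fluxes for one date.

    A *complete* campaign covers 24 consecutive clock hours (wrapping across
    midnight is allowed, matching field campaigns run 9:00 → 8:00 next day).
    Shorter runs are retained but flagged incomplete; the relative-difference
    statistic is well defined for any ``n >= 2``.
    """

    campaign_id: str
    treatment: str
    start: datetime
    hourly_flux: list[CampaignSlot]
    complete: bool = False

    @property
    def n(self) -> int:
        return len(self.hourly_flux)

    def __post_init__(self) -> None:
        hours = [s.hour_of_day for s in self.hourly_flux]
        if len(set(hours)) != len(hours):
            raise ValueError("each hour_of_day may appear at most once in a campaign")
        if self.n > 24:
            raise ValueError(f"campaign cannot exceed 24 hourly slots, got {self.n}")


DEFAULT_MONTH_TO_SEASON: dict[int, str] = {
    m: ("dry" if 5 <= m <= 10 else "wet") for m in range(1, 13)
}


@dataclass(frozen=True)
class SeasonSpec:
    """Month → season map plus the hydrological-year start month.

    The default map follows a Mediterranean climate (warm-dry summers,
    cool-moist winters): dry = May–October, wet = November–April.  The
    hydrological year starts in November by default, so Nov 2013 – Oct 2014
    is labelled ``"HY2014"``.
    """

    month_to_season: Mapping[int, str] = field(
        default_factory=lambda: dict(DEFAULT_MONTH_TO_SEASON)
    )
    hydro_year_start_month: int = 11

    def __post_init__(self) -> None:
        if set(self.month_to_season) != set(range(1, 13)):
            raise ConfigurationError("month_to_season must map every month 1-12")
        labels = set(self.month_to_season.values())
        if len(labels) > 2:
            raise ConfigurationError(
                f"season map must use at most two labels, got {sorted(labels)}"
            )
        if not 1 <= self.hydro_year_start_month <= 12:
            raise ConfigurationError("hydro_year_start_month must be in 1-12")


@dataclass(frozen=True)
class MonitoringRecord:
    """One routine-survey flux measurement with derived calendar labels."""

    timestamp: datetime
    treatment: str
    collar: str
    flux: float
    season: str
    hydro_year: str


@dataclass(frozen=True)
class RowRejection:
    """Report entry for a CSV row that could not be parsed."""

    row_number: int
    reason: str


def classify_season(d: date, spec: SeasonSpec) -> str:
    """Return the season label for a date under a :class:`SeasonSpec`."""
    return spec.month_to_season[d.month]


def assign_hydro_year(d: date, start_month: int = 11) -> str:
    """Label a date with its hydrological year.

    Months >= ``start_month`` belong to the hydro-year named after the
    following calendar year, so with the default November start,
    2013-11-15 → ``"HY2014"`` and 2014-10-15 → ``"HY2014"``.  With
    ``start_month=1`` the hydro-year equals the calendar year.
    """
    if not 1 <= start_month <= 12:
        raise ConfigurationError("start_month must be in 1-12")
    year = d.year + 1 if d.month >= start_month and start_month != 1 else d.year
    return f"HY{year}"


def _parse_timestamp(raw: str) -> datetime:
    return datetime.fromisoformat(raw.strip())


def _fmt_float(x: float | None) -> str:
    return "" if x is None else repr(x)


def read_flux_csv(
    path: str | os.PathLike[str] | io.TextIOBase,
    schema: Mapping[str, str] | None = None,
) -> tuple[list[FluxObservation], list[RowRejection]]:
    """Read chamber-flux observations from a CSV file.

    Parameters
    ----------
    path : path or text stream
        CSV file with a header row; ``#``-prefixed lines are skipped.
    schema : mapping, optional
        Logical-field → column-name mapping for non-canonical headers,
        e.g. ``{"flux": "co2_efflux"}``.  Unmapped fields use canonical names.

    Returns
    -------
    (observations, rejections)
        One :class:`FluxObservation` per well-formed data row; rows with an
        unparseable timestamp or non-numeric flux are reported in
        ``rejections`` with their 1-based data-row number and a reason.

    Raises
    ------
    ConfigurationError
        If a required column cannot be resolved.
    EmptyInputError
        If the file has no header row.
    """
    colmap = {name: name for name in CANONICAL_COLUMNS}
    if schema:
        colmap.update(schema)

    if isinstance(path, io.TextIOBase):
        return _read_stream(path, colmap)
    with open(path, "r", encoding="utf-8", newline="") as fh:
        return _read_stream(fh, colmap)


def _read_stream(fh, colmap) -> tuple[list[FluxObservation], list[RowRejection]]:
    reader = csv.reader(line for line in fh if not line.startswith("#"))
    try:
        header = next(reader)
    except StopIteration:
        raise EmptyInputError("CSV file is empty (no header row)") from None
    index: dict[str, int] = {}
    for field_name, col in colmap.items():
        if col in header:
            index[field_name] = header.index(col)
    missing = [f for f in REQUIRED_FIELDS if f not in index]
    if missing:
        raise ConfigurationError(
            f"required column(s) not found: {missing}; header was {header}"
        )

    observations: list[FluxObservation] = []
    rejections: list[RowRejection] = []
    for row_number, row in enumerate(reader, start=1):
        if not row or all(not c.strip() for c in row):
            continue
        try:
            ts = _parse_timestamp(row[index["timestamp"]])
        except (ValueError, IndexError):
            rejections.append(RowRejection(row_number, "unparseable timestamp"))
            continue
        try:
            flux = float(row[index["flux"]])
            if not math.isfinite(flux):
                raise ValueError
        except (ValueError, IndexError):
            rejections.append(RowRejection(row_number, "non-numeric flux"))
            continue

        def _opt(field_name: str) -> float | None:
            i = index.get(field_name)
            if i is None or i >= len(row) or not row[i].strip():
                return None
            return float(row[i])

        try:
            obs = FluxObservation(
                timestamp=ts,
                treatment=row[index["treatment"]],
                plot=row[index["plot"]] if "plot" in index else "",
                collar=row[index["collar"]],
                flux=flux,
                soil_temperature=_opt("tsoil"),
                soil_moisture=_opt("swc"),
            )
        except ValueError as exc:
            rejections.append(RowRejection(row_number, str(exc)))
            continue
        observations.append(obs)
    if rejections:
        logger.warning("read_flux_csv: rejected %d row(s)", len(rejections))
    return observations, rejections


def write_flux_csv(
    observations: Iterable[FluxObservation],
    path: str | os.PathLike[str] | io.TextIOBase,
    header_comment: str | None = None,
) -> None:
    """Write observations in the canonical CSV dialect (see module docstring)."""

    def _write(fh) -> None:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(CANONICAL_COLUMNS)
        for o in observations:
            writer.writerow(
                [
                    o.timestamp.isoformat(sep="T", timespec="minutes"),
                    o.treatment,
                    o.plot,
                    o.collar,
                    repr(o.flux),
                    _fmt_float(o.soil_temperature),
                    _fmt_float(o.soil_moisture),
                ]
            )

    if isinstance(path, io.TextIOBase):
        _write(path)
    else:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            _write(fh)


def assemble_campaigns(
    observations: Sequence[FluxObservation],
    window_hours: int = 24,
    min_collars: int = 1,
) -> list[Campaign]:
    """Bin observations to clock hours and build per-treatment campaigns.

    Observations are floored to the clock hour in local time (no DST
    handling).  Within each (treatment, hour-bin), flux is the unweighted
    mean across collars.  Maximal runs of consecutive hour-bins with at
    least ``min_collars`` contributing collars become campaigns; runs are
    chunked at ``window_hours`` so no campaign repeats an hour of day.
    Runs shorter than ``window_hours`` are kept but flagged incomplete.
    """
    bins: dict[tuple[str, datetime], list[FluxObservation]] = {}
    for obs in observations:
        hour_bin = obs.timestamp.replace(minute=0, second=0, microsecond=0)
        bins.setdefault((obs.treatment, hour_bin), []).append(obs)

    by_treatment: dict[str, list[tuple[datetime, float, int]]] = {}
    for (treatment, hour_bin), group in bins.items():
        collars = {o.collar for o in group}
        if len(collars) < min_collars:
            continue
        mean_flux = sum(o.flux for o in group) / len(group)
        by_treatment.setdefault(treatment, []).append(
            (hour_bin, mean_flux, len(collars))
        )

    campaigns: list[Campaign] = []
    one_hour = timedelta(hours=1)
    for treatment in sorted(by_treatment):
        slots = sorted(by_treatment[treatment])
        runs: list[list[tuple[datetime, float, int]]] = []
        for slot in slots:
            if runs and slot[0] - runs[-1][-1][0] == one_hour:
                runs[-1].append(slot)
            else:
                runs.append([slot])
        for run in runs:
            for i in range(0, len(run), window_hours):
                chunk = run[i : i + window_hours]
                start = chunk[0][0]
                campaigns.append(
                    Campaign(
                        campaign_id=f"{treatment}:{start.isoformat(timespec='hours')}",
                        treatment=treatment,
                        start=start,
                        hourly_flux=[
                            CampaignSlot(t.hour, f, c) for (t, f, c) in chunk
                        ],
                        complete=len(chunk) == window_hours,
                    )
                )
    return campaigns


def monitoring_records(
    observations: Iterable[FluxObservation], spec: SeasonSpec
) -> list[MonitoringRecord]:
    """Attach season and hydro-year labels to routine-survey observations."""
    return [
        MonitoringRecord(
            timestamp=o.timestamp,
            treatment=o.treatment,
            collar=o.collar,
            flux=o.flux,
            season=classify_season(o.timestamp.date(), spec),
            hydro_year=assign_hydro_year(
                o.timestamp.date(), spec.hydro_year_start_month
            ),
        )
        for o in observations
    ]
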