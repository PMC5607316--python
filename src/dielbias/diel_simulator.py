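"""Synthetic diel-cycle generator for soil-respiration campaigns and surveys.

Ground truth is a Q10 temperature response driven by a sinusoidal soil
temperature cycle, optionally damped by Michaelis-type moisture saturation:

    T(h)  = T_mean + A·cos(2π(h − h_peak)/24)
    Rs(h) = R_base · Q10^((T(h) − 10)/10) · θ/(θ + K_θ)

Observation noise is multiplicative lognormal with a mean-1 correction
(chamber-flux scatter scales with flux magnitude); additive Gaussian noise
is available as an option.  Every draw is driven by the configured seed, so
simulations are exactly reproducible.

Defaults emulate the field design the analysis was built around: eight 24-hr
campaigns (hourly means from 9:00 to 8:00 the next day) spread over wet and
dry seasons of a Mediterranean shrubland, and monthly mid-day (12:00–14:00)
monitoring across a November–October hydrological year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta

import numpy as np

from .flux_io import FluxObservation, MonitoringRecord, SeasonSpec

#: campaign dates mirroring the eight field campaigns (2014-2016)
DEFAULT_CAMPAIGN_DATES = (
    date(2014, 3, 15), date(2014, 4, 15), date(2014, 6, 15), date(2014, 10, 15),
    date(2014, 11, 15), date(2015, 11, 15), date(2016, 1, 15), date(2016, 4, 15),
)

#: monthly monitoring over one hydrological year (Nov 2014 - Oct 2015)
DEFAULT_MONITORING_DATES = tuple(
    date(2014 + (m > 2), ((10 + m - 1) % 12) + 1, 15) for m in range(1, 13)
)


@dataclass
class SimulationConfig:
    """Ground-truth diel cycle plus sampling schedule and noise model.

    Parameters
    ----------
    t_mean, t_amplitude : float
        Mean and half-range of the soil-temperature sinusoid, °C.
    t_peak_hour : float
        Clock hour of the temperature maximum (soil thermal lag puts this
        mid-afternoon; default 14.0).
    q10 : float
        Multiplicative response per 10 °C warming.
    r_base : float
        Flux at the 10 °C reference temperature, µmol CO2 m⁻² s⁻¹.
    moisture_level : float
        Constant volumetric water content, m³ m⁻³.
    moisture_halfsat : float
        Half-saturation constant of the moisture modifier, m³ m⁻³.
    noise_cv : float
        Coefficient of variation of the multiplicative lognormal noise.
    noise_additive_sd : float
        SD of optional additive Gaussian noise (default off).
    collars : int
        Chamber bases measured per treatment per time point.
    """

    t_mean: float = 15.0
    t_amplitude: float = 5.0
    t_peak_hour: float = 14.0
    q10: float = 2.0
    r_base: float = 1.0
    moisture_level: float = 0.20
    moisture_halfsat: float = 0.05
    noise_cv: float = 0.10
    noise_additive_sd: float = 0.0
    collars: int = 3
    treatment: str = "trench"
    campaign_dates: tuple[date, ...] = DEFAULT_CAMPAIGN_DATES
    campaign_start_hour: int = 9
    monitoring_dates: tuple[date, ...] = DEFAULT_MONITORING_DATES
    monitoring_window: tuple[float, float] = (12.0, 14.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.q10 <= 0 or self.r_base <= 0:
            raise ValueError("q10 and r_base must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.collars < 1:
            raise ValueError("collars must be >= 1")
        lo, hi = self.monitoring_window
        if not (0 <= lo < hi <= 24):
            raise ValueError("monitoring_window must satisfy 0 <= start < end <= 24")


@dataclass(frozen=True)
class GroundTruth:
    """Noise-free diel profile: the target the MRD estimator should recover."""

    hourly_flux: dict[int, float]
    daily_mean: float
    relative_profile: dict[int, float]  # (flux(h) − mean)/mean; averages to 0


def soil_temperature(hour: float, cfg: SimulationConfig) -> float:
    """Sinusoidal soil temperature at a fractional clock hour, °C."""
    return cfg.t_mean + cfg.t_amplitude * math.cos(
        2.0 * math.pi * (hour - cfg.t_peak_hour) / 24.0
    )


def diel_flux(hour: float, cfg: SimulationConfig) -> float:
    """Noise-free flux at a fractional clock hour (Q10 × moisture response)."""
    temp = soil_temperature(hour, cfg)
    moisture = cfg.moisture_level / (cfg.moisture_level + cfg.moisture_halfsat)
    return cfg.r_base * cfg.q10 ** ((temp - 10.0) / 10.0) * moisture


def ground_truth(cfg: SimulationConfig) -> GroundTruth:
    """Noise-free hourly fluxes, their daily mean, and the relative profile."""
    hourly = {h: diel_flux(float(h), cfg) for h in range(24)}
    mean = sum(hourly.values()) / 24.0
    return GroundTruth(
        hourly_flux=hourly,
        daily_mean=mean,
        relative_profile={h: (f - mean) / mean for h, f in hourly.items()},
    )


def _noise_sigma(noise_cv: float) -> float:
    # lognormal multiplier with mean 1 and CV = noise_cv
    return math.sqrt(math.log1p(noise_cv * noise_cv))


def _noisy(value: float, cfg: SimulationConfig, rng: np.random.Generator) -> float:
    if cfg.noise_cv > 0:
        sigma = _noise_sigma(cfg.noise_cv)
        value *= math.exp(rng.normal(-sigma * sigma / 2.0, sigma))
    if cfg.noise_additive_sd > 0:
        value += rng.normal(0.0, cfg.noise_additive_sd)
    return value


def simulate_campaigns(
    cfg: SimulationConfig,
) -> tuple[list[FluxObservation], GroundTruth]:
    """Generate hourly chamber observations for every configured campaign.

    Each campaign covers 24 consecutive hours starting at
    ``campaign_start_hour`` on its date; each collar gets an independent
    noise draw per hour.  All randomness flows from ``cfg.seed``.
    """
    if not cfg.campaign_dates:
        raise ValueError("need >= 1 campaign date")
    rng = np.random.default_rng(cfg.seed)
    truth = ground_truth(cfg)
    observations: list[FluxObservation] = []
    for day in cfg.campaign_dates:
        start = datetime(day.year, day.month, day.day, cfg.campaign_start_hour)
        for step in range(24):
            ts = start + timedelta(hours=step)
            clean = truth.hourly_flux[ts.hour]
            for collar_idx in range(cfg.collars):
                observations.append(
                    FluxObservation(
                        timestamp=ts,
                        treatment=cfg.treatment,
                        plot="p1",
                        collar=f"c{collar_idx + 1}",
                        flux=_noisy(clean, cfg, rng),
                        soil_temperature=soil_temperature(float(ts.hour), cfg),
                        soil_moisture=cfg.moisture_level,
                    )
                )
    return observations, truth


def simulate_monitoring(
    cfg: SimulationConfig,
    spec: SeasonSpec | None = None,
) -> tuple[list[MonitoringRecord], dict[date, float]]:
    """Generate routine-survey records within the monitoring window.

    One record per collar per monitoring date, at a uniformly drawn time
    inside ``monitoring_window``.  Returns the records plus each date's
    true (noise-free) daily mean flux.
    """
    if not cfg.monitoring_dates:
        raise ValueError("need >= 1 monitoring date")
    from .flux_io import assign_hydro_year, classify_season

    spec = spec or SeasonSpec()
    rng = np.random.default_rng(cfg.seed + 1)  # independent of campaign stream
    truth = ground_truth(cfg)
    records: list[MonitoringRecord] = []
    true_means: dict[date, float] = {}
    lo, hi = cfg.monitoring_window
    for day in cfg.monitoring_dates:
        true_means[day] = truth.daily_mean
        for collar_idx in range(cfg.collars):
            hour = float(rng.uniform(lo, hi))
            ts = datetime(day.year, day.month, day.day) + timedelta(hours=hour)
            ts = ts.replace(second=0, microsecond=0)
            records.append(
                MonitoringRecord(
                    timestamp=ts,
                    treatment=cfg.treatment,
                    collar=f"c{collar_idx + 1}",
                    flux=_noisy(diel_flux(hour, cfg), cfg, rng),
                    season=classify_season(day, spec),
                    hydro_year=assign_hydro_year(day, spec.hydro_year_start_month),
                )
            )
    return records, true_means
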