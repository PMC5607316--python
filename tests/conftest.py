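from datetime import datetime, timedelta

import pytest

from dielbias import (
    Campaign,
    SeasonSpec,
    SimulationConfig,
    assemble_campaigns,
    simulate_campaigns,
)
from dielbias.flux_io import CampaignSlot


def make_campaign(fluxes, treatment="trench", start_hour=9):
    """Build a campaign from a flat flux list starting at a given clock hour."""
    slots = [
        CampaignSlot(hour_of_day=(start_hour + i) % 24, flux=f, collar_count=1)
        for i, f in enumerate(fluxes)
    ]
    return Campaign(
        campaign_id="test",
        treatment=treatment,
        start=datetime(2015, 6, 1, start_hour),
        hourly_flux=slots,
        complete=len(slots) == 24,
    )


@pytest.fixture
def season_spec():
    return SeasonSpec()


@pytest.fixture
def noise_free_config():
    return SimulationConfig(noise_cv=0.0, collars=1, seed=0)


@pytest.fixture
def noise_free_campaigns(noise_free_config):
    observations, truth = simulate_campaigns(noise_free_config)
    return assemble_campaigns(observations), truth
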