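import datetime as dt

import numpy as np
import pytest

from checklist_bias.ingest import Checklist
from checklist_bias.synthetic import CommunityModel, ObserverModel, simulate_community


@pytest.fixture
def small_community() -> CommunityModel:
    return simulate_community(20, sigma=1.0, seed=11)


@pytest.fixture
def uniform_community() -> CommunityModel:
    """Equal abundances and a flat 0.05/min encounter rate for closed forms."""
    s = 20
    return CommunityModel(
        species_count_true=s,
        abundance_weights=np.full(s, 1.0 / s),
        detection_rates=np.full(s, 0.05),
        seed=0,
    )


@pytest.fixture
def perfect_observer() -> ObserverModel:
    return ObserverModel(skill=1.0, weather_penalty=1.0)


def make_checklist(event_id="EV1", **overrides) -> Checklist:
    """A checklist that passes every alignment rule unless overridden."""
    base = dict(
        event_id=event_id,
        protocol="stationary",
        date=dt.date(2014, 5, 15),
        start_time=dt.time(7, 0),
        duration_minutes=60.0,
        distance_km=0.0,
        latitude=23.5,
        longitude=121.0,
        location_name="some valley",
        group_id=None,
        complete_flag=True,
        approved_flag=True,
        observations=[("sp0001", 2), ("sp0002", 1)],
    )
    base.update(overrides)
    return Checklist(**base)


def fixed_sunrise(date, lat, lon) -> dt.time:
    """Deterministic provider for filter fixtures: sunrise at 05:30 sharp."""
    return dt.time(5, 30)
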