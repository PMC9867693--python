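"""Synthetic paired survey data with known true species richness.

The generator emulates the statistical structure the comparison pipeline
assumes: a bird community with a log-normal rank-abundance distribution,
an independent per-species Poisson encounter process so a species with
encounter rate r is detected on a t-minute survey with probability
1 - exp(-r * skill * weather * t), and two sampling designs on top of it —
structured point-count visits (10 points x 6 min, twice a year over eight
years) and semi-structured checklists of 6-200 minutes submitted by
observers of varying skill.  Detected species receive a zero-truncated
Poisson count with mean proportional to abundance x duration, which
produces the singleton inflation at short durations that drives Chao1
behaviour.

Group-shared checklists, "X" counts, missing counts and survey-named
locations are injected at configurable rates so the culling rules have
something to remove.  Everything is seeded and reproducible.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .ingest import (
    BBSObservation,
    BBSSite,
    BBSVisit,
    Checklist,
    write_bbs_sites,
    write_bbs_visits,
    write_checklists,
    write_species_table,
)
from .sunrise import NoaaSunriseProvider


@dataclass(frozen=True)
class CommunityModel:
    """A fixed community: true richness, relative abundances, encounter rates."""

    species_count_true: int
    abundance_weights: np.ndarray  # descending, sums to 1
    detection_rates: np.ndarray  # per-species encounters per minute
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.species_count_true < 1:
            raise ValueError("species_count_true must be >= 1")
        if len(self.abundance_weights) != self.species_count_true:
            raise ValueError("abundance_weights length must equal species_count_true")
        if np.any(self.detection_rates <= 0):
            raise ValueError("all detection rates must be strictly positive")

    @property
    def species_ids(self) -> List[str]:
        return [f"sp{i:04d}" for i in range(self.species_count_true)]


@dataclass(frozen=True)
class ObserverModel:
    """Observer effect: multiplicative skill and weather penalties on rates."""

    skill: float = 1.0
    weather_penalty: float = 1.0

    def __post_init__(self) -> None:
        for name, v in (("skill", self.skill), ("weather_penalty", self.weather_penalty)):
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")

    @property
    def rate_multiplier(self) -> float:
        return self.skill * self.weather_penalty


def simulate_community(
    species_count_true: int,
    sigma: float = 1.0,
    rate_min: float = 0.005,
    rate_max: float = 0.08,
    seed: Optional[int] = None,
) -> CommunityModel:
    """Draw a community with log-normal rank abundances.

    Weights are sorted descending and normalised to sum to 1.  Encounter
    rates interpolate from ``rate_max`` (most abundant) to ``rate_min``
    (rarest) by abundance rank, so common species are also the easiest to
    detect.
    """
    if species_count_true < 1:
        raise ValueError("species_count_true must be >= 1")
    if sigma < 0 or rate_min <= 0 or rate_max < rate_min:
        raise ValueError("invalid distribution parameters")
    rng = np.random.default_rng(seed)
    raw = rng.lognormal(mean=0.0, sigma=sigma, size=species_count_true)
    weights = np.sort(raw)[::-1]
    weights = weights / weights.sum()
    if species_count_true == 1:
        rates = np.array([rate_max])
    else:
        rates = np.linspace(rate_max, rate_min, species_count_true)
    return CommunityModel(
        species_count_true=species_count_true,
        abundance_weights=weights,
        detection_rates=rates,
        seed=seed,
    )


def _zero_truncated_poisson(rng: np.random.Generator, lam: float) -> int:
    """Exact zero-truncated Poisson draw (first-arrival conditioning trick)."""
    if lam <= 0:
        return 1
    u = rng.random()
    t = -math.log1p(-u * (1.0 - math.exp(-lam)))
    return 1 + int(rng.poisson(max(lam - t, 0.0)))


def detect_species(
    community: CommunityModel,
    observer: ObserverModel,
    duration_minutes: float,
    rng: np.random.Generator,
    count_intensity: float = 3.0,
) -> List[Tuple[str, int]]:
    """Sample (species, count) detections for one survey bout."""
    if duration_minutes <= 0:
        raise ValueError("duration must be positive")
    p = 1.0 - np.exp(
        -community.detection_rates * observer.rate_multiplier * duration_minutes
    )
    detected = rng.random(community.species_count_true) < p
    obs: List[Tuple[str, int]] = []
    ids = community.species_ids
    for i in np.flatnonzero(detected):
        lam = count_intensity * community.abundance_weights[i] * duration_minutes
        obs.append((ids[i], _zero_truncated_poisson(rng, lam)))
    return obs


def expected_observed_richness(
    community: CommunityModel, observer: ObserverModel, duration_minutes: float
) -> float:
    """Closed-form E[S_obs] = sum_s 1 - exp(-r_s * skill * weather * t)."""
    return float(
        np.sum(
            1.0
            - np.exp(
                -community.detection_rates * observer.rate_multiplier * duration_minutes
            )
        )
    )


def simulate_checklist(
    community: CommunityModel,
    observer: ObserverModel,
    duration_minutes: float,
    seed: Optional[int] = None,
    event_id: str = "EV0001",
    date: dt.date = dt.date(2014, 5, 15),
    start_time: dt.time = dt.time(6, 0),
    latitude: float = 23.5,
    longitude: float = 121.0,
    protocol: str = "stationary",
    distance_km: float = 0.0,
    location_name: str = "synthetic locality",
    group_id: Optional[str] = None,
    count_intensity: float = 3.0,
) -> Checklist:
    """Simulate one semi-structured checklist with full effort metadata."""
    rng = np.random.default_rng(seed)
    observations = detect_species(
        community, observer, duration_minutes, rng, count_intensity
    )
    return Checklist(
        event_id=event_id,
        protocol=protocol,
        date=date,
        start_time=start_time,
        duration_minutes=duration_minutes,
        distance_km=distance_km,
        latitude=latitude,
        longitude=longitude,
        location_name=location_name,
        group_id=group_id,
        complete_flag=True,
        approved_flag=True,
        observations=list(observations),
    )


def simulate_bbs_site(
    community: CommunityModel,
    years: Sequence[int] = tuple(range(2010, 2018)),
    visits_per_year: int = 2,
    points_per_visit: int = 10,
    minutes_per_point: int = 6,
    seed: Optional[int] = None,
    site_id: str = "S001",
    centroid_lat: float = 23.5,
    centroid_lon: float = 121.0,
    habitat_class: str = "forest",
    coastal_flag: bool = False,
    observer: Optional[ObserverModel] = None,
    count_intensity: float = 3.0,
    band_probs: Tuple[float, float, float] = (0.25, 0.5, 0.25),
) -> Tuple[BBSSite, List[BBSVisit]]:
    """Simulate one structured site: repeated point-count visits over years.

    Each visit surveys every point for ``minutes_per_point`` minutes
    (defaults give the standard 60-minute visit) and each detection is
    assigned a distance band so band filtering is exercisable.
    """
    if visits_per_year < 1 or points_per_visit < 1 or minutes_per_point <= 0:
        raise ValueError("design parameters must be positive")
    rng = np.random.default_rng(seed)
    observer = observer or ObserverModel(skill=0.9)
    bands = ["0-25", "25-100", ">100"]
    visits: List[BBSVisit] = []
    for year in years:
        for visit_number in range(1, visits_per_year + 1):
            records: List[BBSObservation] = []
            for point in range(1, points_per_visit + 1):
                for species, count in detect_species(
                    community, observer, minutes_per_point, rng, count_intensity
                ):
                    band = bands[rng.choice(3, p=band_probs)]
                    records.append(
                        BBSObservation(
                            point_id=f"{site_id}-P{point:02d}",
                            species_id=species,
                            distance_band=band,
                            count=count,
                        )
                    )
            visits.append(
                BBSVisit(
                    site_id=site_id,
                    year=int(year),
                    visit_number=visit_number,
                    records=tuple(records),
                )
            )
    site = BBSSite(
        site_id=site_id,
        centroid_lat=centroid_lat,
        centroid_lon=centroid_lon,
        n_points=points_per_visit,
        coastal_flag=coastal_flag,
        habitat_class=habitat_class,
    )
    return site, visits


# ---------------------------------------------------------------------------
# full-dataset generation


@dataclass
class SimulationConfig:
    """Knobs for a full paired-dataset simulation (YAML-loadable)."""

    species_count_true: int = 135
    lognormal_sigma: float = 1.0
    rate_min: float = 0.005
    rate_max: float = 0.08
    n_sites: int = 10
    n_checklists: int = 300
    duration_range: Tuple[float, float] = (6.0, 200.0)
    skill_range: Tuple[float, float] = (0.5, 1.0)
    weather_range: Tuple[float, float] = (0.9, 1.0)
    count_intensity: float = 3.0
    years: Tuple[int, ...] = tuple(range(2010, 2018))
    visits_per_year: int = 2
    points_per_visit: int = 10
    minutes_per_point: int = 6
    # injection rates for the culling rules
    x_count_rate: float = 0.05
    missing_count_rate: float = 0.05
    group_share_rate: float = 0.05
    bbs_name_rate: float = 0.02
    outside_buffer_rate: float = 0.03
    # site-selection fodder: sites with < 10 points or on the coastline
    short_site_rate: float = 0.1
    coastal_site_rate: float = 0.1
    # contaminant species flagged ineligible in the metadata table
    n_ineligible_species: int = 3
    # study-region geometry
    lat_range: Tuple[float, float] = (22.0, 25.0)
    lon_range: Tuple[float, float] = (120.0, 122.0)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        kwargs = {}
        for f in cls.__dataclass_fields__:
            if f in raw:
                v = raw[f]
                kwargs[f] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)


@dataclass
class DatasetBundle:
    """Everything one simulation produced, plus the generating truth."""

    community: CommunityModel
    checklists: List[Checklist]
    sites: List[BBSSite]
    visits: List[BBSVisit]
    species_table: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_checklists(self.checklists, outdir / "checklists.tsv")
        write_bbs_sites(self.sites, outdir / "sites.csv")
        write_bbs_visits(self.visits, outdir / "visits.csv")
        write_species_table(self.species_table, outdir / "species.csv")
        self.truth.to_csv(outdir / "truth.csv", index=False)


def simulate_dataset(config: SimulationConfig) -> DatasetBundle:
    """Generate a paired structured + semi-structured dataset with truth.

    The community holds ``species_count_true`` eligible species plus
    ``n_ineligible_species`` contaminants (flagged nocturnal or winter
    visitor in the species metadata) so the species filter has work to do.
    Checklist metadata is generated inside the alignment windows — sunrise
    to four hours after, breeding-season months of the study years — with
    the configured rates of culling-rule violations injected on top.
    """
    rng = np.random.default_rng(config.seed)
    total_species = config.species_count_true + config.n_ineligible_species
    community = simulate_community(
        total_species,
        sigma=config.lognormal_sigma,
        rate_min=config.rate_min,
        rate_max=config.rate_max,
        seed=int(rng.integers(2**31 - 1)),
    )
    ids = community.species_ids
    ineligible = set(
        rng.choice(ids, size=config.n_ineligible_species, replace=False)
        if config.n_ineligible_species
        else []
    )
    species_table = pd.DataFrame(
        {
            "species": ids,
            "diurnal": [sp not in ineligible for sp in ids],
            "status": ["resident" if sp not in ineligible else "winter_visitor" for sp in ids],
        }
    )

    # structured sites, spaced on a jittered grid inside the study region
    sites: List[BBSSite] = []
    visits: List[BBSVisit] = []
    habitats = ["forest", "agriculture", "developed", "grassland", "wetland"]
    for i in range(config.n_sites):
        lat = float(rng.uniform(*config.lat_range))
        lon = float(rng.uniform(*config.lon_range))
        n_points = config.points_per_visit
        if rng.random() < config.short_site_rate:
            n_points = int(rng.integers(6, 10))
        coastal = bool(rng.random() < config.coastal_site_rate)
        site, site_visits = simulate_bbs_site(
            community,
            years=config.years,
            visits_per_year=config.visits_per_year,
            points_per_visit=n_points,
            minutes_per_point=config.minutes_per_point,
            seed=int(rng.integers(2**31 - 1)),
            site_id=f"S{i:03d}",
            centroid_lat=lat,
            centroid_lon=lon,
            habitat_class=habitats[i % len(habitats)],
            coastal_flag=coastal,
            count_intensity=config.count_intensity,
        )
        sites.append(site)
        visits.extend(site_visits)

    sunrise = NoaaSunriseProvider()
    checklists: List[Checklist] = []
    truth_rows: List[dict] = []
    group_counter = 0
    for j in range(config.n_checklists):
        site = sites[int(rng.integers(len(sites)))]
        if rng.random() < config.outside_buffer_rate:
            offset_km = rng.uniform(1.5, 3.0, size=2) * rng.choice([-1, 1], size=2)
        else:
            offset_km = rng.uniform(-0.8, 0.8, size=2)
        lat = site.centroid_lat + offset_km[0] / 111.32
        lon = site.centroid_lon + offset_km[1] / (
            111.32 * math.cos(math.radians(site.centroid_lat))
        )
        year = int(rng.choice(config.years))
        month = int(rng.choice([3, 4, 5, 6, 7]))
        day = int(rng.integers(1, 29))
        date = dt.date(year, month, day)
        rise = sunrise(date, lat, lon)
        start_min = rise.hour * 60 + rise.minute + float(rng.uniform(2, 230))
        start = dt.time(int(start_min // 60) % 24, int(start_min % 60))
        lo, hi = config.duration_range
        duration = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        protocol = "stationary" if rng.random() < 0.8 else "traveling"
        distance = 0.0 if protocol == "stationary" else float(rng.uniform(0.1, 4.0))
        skill = float(rng.uniform(*config.skill_range))
        weather = float(rng.uniform(*config.weather_range))
        observer = ObserverModel(skill=skill, weather_penalty=weather)
        if rng.random() < config.bbs_name_rate:
            locality = f"BBS-{site.site_id}-{int(rng.integers(1, 20))}"
        else:
            locality = f"locality {j:04d}"
        group_id = None
        if rng.random() < config.group_share_rate:
            group_counter += 1
            group_id = f"G{group_counter:04d}"
        cl = simulate_checklist(
            community,
            observer,
            duration,
            seed=int(rng.integers(2**31 - 1)),
            event_id=f"EV{j:05d}",
            date=date,
            start_time=start,
            latitude=lat,
            longitude=lon,
            protocol=protocol,
            distance_km=distance,
            location_name=locality,
            group_id=group_id,
            count_intensity=config.count_intensity,
        )
        # inject culling-rule violations
        if cl.observations and rng.random() < config.x_count_rate:
            k = int(rng.integers(len(cl.observations)))
            cl.observations[k] = (cl.observations[k][0], "X")
        if cl.observations and rng.random() < config.missing_count_rate:
            k = int(rng.integers(len(cl.observations)))
            cl.observations[k] = (cl.observations[k][0], None)
        checklists.append(cl)
        truth_rows.append(
            {
                "event_id": cl.event_id,
                "site_id": site.site_id,
                "duration_minutes": duration,
                "skill": skill,
                "weather_penalty": weather,
                "expected_richness": expected_observed_richness(
                    community, observer, duration
                ),
            }
        )
        # group sharing: duplicate the checklist under a new event id
        if group_id is not None:
            dup = cl.replace(event_id=f"EV{j:05d}D", observations=list(cl.observations))
            checklists.append(dup)
            truth_rows.append({**truth_rows[-1], "event_id": dup.event_id})

    truth = pd.DataFrame(truth_rows)
    truth.insert(0, "species_count_true", config.species_count_true)
    return DatasetBundle(
        community=community,
        checklists=checklists,
        sites=sites,
        visits=visits,
        species_table=species_table,
        truth=truth,
        config=config,
    )
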