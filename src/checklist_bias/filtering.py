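"""Checklist alignment, data culling, site selection and buffer assignment.

Semi-structured checklists are only comparable with structured point
counts after aligning their protocols: daybreak timing (sunrise to four
hours after), breeding season and study years, a travel-distance cap that
keeps the checklist inside the site's habitat buffer, and a minimum
duration equal to one point count.  Culling then removes count tokens the
richness estimator cannot use, and group-shared duplicates.  Every filter
returns the kept records together with a :class:`FilterReport`; each
removed record is attributed to exactly the first rule that rejected it,
so the attrition ledger always reconciles: input = kept + sum(removed).

Rule order is fixed: protocol/flags -> sunrise window -> season/year ->
distance -> duration; then culling, group dedup, structured-survey
duplicate exclusion, and the species filter.
"""

from __future__ import annotations

import datetime as dt
import math
import re
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .ingest import BBSSite, BBSVisit, Checklist

KM_PER_DEG = 111.32  # metres per degree latitude at Earth's mean radius / 1000

SunriseProvider = Callable[[dt.date, float, float], dt.time]


@dataclass
class FilterReport:
    """Attrition ledger: per-rule identifiers of removed records, in rule order."""

    removed: Dict[str, List[str]] = field(default_factory=dict)

    def add(self, rule: str, identifier: str) -> None:
        self.removed.setdefault(rule, []).append(identifier)

    @property
    def counts(self) -> Dict[str, int]:
        return {rule: len(ids) for rule, ids in self.removed.items()}

    @property
    def total_removed(self) -> int:
        return sum(len(ids) for ids in self.removed.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"rule": rule, "record_id": rid}
            for rule, ids in self.removed.items()
            for rid in ids
        ]
        return pd.DataFrame(rows, columns=["rule", "record_id"])


@dataclass(frozen=True)
class FilterConfig:
    """Alignment thresholds; defaults are the standard breeding-season setup."""

    year_min: int = 2010
    year_max: int = 2017
    months: Tuple[int, ...] = (3, 4, 5, 6, 7)
    sunrise_window_hours: float = 4.0
    max_distance_km: float = 4.0
    min_duration_minutes: float = 6.0
    allowed_protocols: Tuple[str, ...] = ("stationary", "traveling", "historical")


def _minutes(t: dt.time) -> float:
    return t.hour * 60.0 + t.minute + t.second / 60.0


def filter_checklists(
    checklists: Sequence[Checklist],
    sunrise_provider: SunriseProvider,
    config: FilterConfig = FilterConfig(),
) -> Tuple[List[Checklist], FilterReport]:
    """Apply the alignment criteria; failing records are reported, not raised.

    Boundaries are inclusive as stated: a 4.0 km travel and a 6-minute
    duration are both kept, as is a start exactly at sunrise or exactly
    four hours after.
    """
    kept: List[Checklist] = []
    report = FilterReport()
    for cl in checklists:
        if cl.protocol not in config.allowed_protocols:
            report.add("protocol", cl.event_id)
            continue
        if not (cl.complete_flag and cl.approved_flag):
            report.add("flags", cl.event_id)
            continue
        sunrise = sunrise_provider(cl.date, cl.latitude, cl.longitude)
        start = _minutes(cl.start_time)
        rise = _minutes(sunrise)
        if not (rise <= start <= rise + config.sunrise_window_hours * 60.0):
            report.add("sunrise_window", cl.event_id)
            continue
        if cl.date.month not in config.months or not (
            config.year_min <= cl.date.year <= config.year_max
        ):
            report.add("season_year", cl.event_id)
            continue
        if cl.distance_km > config.max_distance_km:
            report.add("distance", cl.event_id)
            continue
        if cl.duration_minutes < config.min_duration_minutes:
            report.add("duration", cl.event_id)
            continue
        kept.append(cl)
    return kept, report


def cull_observations(
    checklists: Sequence[Checklist],
) -> Tuple[List[Checklist], FilterReport]:
    """Remove unusable counts and group-shared duplicates.

    (1) any "X" count drops the whole checklist; (2) a missing count drops
    only that species row; (3) checklists sharing a group identifier keep a
    single deterministic representative, the lexicographically smallest
    event id.
    """
    report = FilterReport()
    survivors: List[Checklist] = []
    for cl in checklists:
        if any(c == "X" for _, c in cl.observations):
            report.add("x_count", cl.event_id)
            continue
        complete = [(sp, c) for sp, c in cl.observations if c is not None]
        if len(complete) < len(cl.observations):
            cl = cl.replace(observations=complete)
        survivors.append(cl)

    group_best: Dict[str, str] = {}
    for cl in survivors:
        if cl.group_id:
            best = group_best.get(cl.group_id)
            if best is None or cl.event_id < best:
                group_best[cl.group_id] = cl.event_id
    kept: List[Checklist] = []
    for cl in survivors:
        if cl.group_id and group_best[cl.group_id] != cl.event_id:
            report.add("group_duplicate", cl.event_id)
        else:
            kept.append(cl)
    return kept, report


def select_bbs_sites(
    sites: Sequence[BBSSite],
) -> Tuple[List[BBSSite], FilterReport]:
    """Keep full 10-point, non-coastal sites (so every visit is 60 minutes)."""
    kept: List[BBSSite] = []
    report = FilterReport()
    for site in sites:
        if site.n_points != 10:
            report.add("n_points", site.site_id)
        elif site.coastal_flag:
            report.add("coastal", site.site_id)
        else:
            kept.append(site)
    return kept, report


def filter_bbs_bands(
    visits: Sequence[BBSVisit], drop_band: str = ">100"
) -> List[BBSVisit]:
    """Drop the far distance band (>100 m) from every point record."""
    return [
        BBSVisit(
            site_id=v.site_id,
            year=v.year,
            visit_number=v.visit_number,
            records=tuple(r for r in v.records if r.distance_band != drop_band),
        )
        for v in visits
    ]


def assign_checklists_to_sites(
    checklists: Sequence[Checklist],
    sites: Sequence[BBSSite],
    half_side_km: float = 1.0,
) -> Tuple[List[Tuple[str, Checklist]], FilterReport]:
    """Assign each checklist to every site whose square buffer contains it.

    Buffers are axis-aligned squares of side ``2*half_side_km`` centred on
    the site centroid, evaluated in a local equirectangular projection
    (longitude scaled by cos latitude); at the 2 km scale the planar error
    is negligible relative to the buffer.  A checklist inside k overlapping
    buffers yields k pairs; one outside all buffers is dropped and
    reported.
    """
    pairs: List[Tuple[str, Checklist]] = []
    report = FilterReport()
    for cl in checklists:
        hits = []
        for site in sites:
            dy = (cl.latitude - site.centroid_lat) * KM_PER_DEG
            dx = (
                (cl.longitude - site.centroid_lon)
                * KM_PER_DEG
                * math.cos(math.radians(site.centroid_lat))
            )
            if abs(dx) <= half_side_km and abs(dy) <= half_side_km:
                hits.append(site.site_id)
        if hits:
            pairs.extend((sid, cl) for sid in hits)
        else:
            report.add("outside_buffers", cl.event_id)
    return pairs, report


def exclude_bbs_duplicates(
    checklists: Sequence[Checklist],
    bbs_points: Sequence[Tuple[float, float]],
    name_pattern: str = r"(?i)\bBBS[-_ ]",
    coordinate_decimals: int = 6,
) -> Tuple[List[Checklist], FilterReport]:
    """Drop checklists that are re-submissions of structured-survey counts.

    A checklist is removed if its location name matches the configurable
    survey-name pattern (e.g. "BBS-A35-19"), or its coordinates equal a
    survey point's coordinates after rounding to ``coordinate_decimals``
    places.
    """
    pattern = re.compile(name_pattern)
    point_set: Set[Tuple[float, float]] = {
        (round(lat, coordinate_decimals), round(lon, coordinate_decimals))
        for lat, lon in bbs_points
    }
    kept: List[Checklist] = []
    report = FilterReport()
    for cl in checklists:
        if pattern.search(cl.location_name):
            report.add("bbs_location_name", cl.event_id)
        elif (
            round(cl.latitude, coordinate_decimals),
            round(cl.longitude, coordinate_decimals),
        ) in point_set:
            report.add("bbs_point_coordinates", cl.event_id)
        else:
            kept.append(cl)
    return kept, report


def _eligible_species(species_table: pd.DataFrame) -> Set[str]:
    ok = species_table["diurnal"] & species_table["status"].isin(
        ["resident", "summer_visitor"]
    )
    return set(species_table.loc[ok, "species"])


def filter_species_checklists(
    checklists: Sequence[Checklist], species_table: pd.DataFrame
) -> List[Checklist]:
    """Keep only diurnal residents and summer visitors on each checklist."""
    eligible = _eligible_species(species_table)
    return [
        cl.replace(observations=[(sp, c) for sp, c in cl.observations if sp in eligible])
        for cl in checklists
    ]


def filter_species_visits(
    visits: Sequence[BBSVisit], species_table: pd.DataFrame
) -> List[BBSVisit]:
    """Keep only diurnal residents and summer visitors in each visit."""
    eligible = _eligible_species(species_table)
    return [
        BBSVisit(
            site_id=v.site_id,
            year=v.year,
            visit_number=v.visit_number,
            records=tuple(r for r in v.records if r.species_id in eligible),
        )
        for v in visits
    ]
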