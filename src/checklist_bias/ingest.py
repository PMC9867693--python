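"""Domain records and file I/O for the two survey dialects.

Semi-structured checklists travel as an EBD-dialect TSV (one row per
species observation, event metadata repeated on every row); structured
point-count surveys travel as three CSVs (sites, visits, species
metadata).  Readers reconstruct one record per sampling event; writers
are exact inverses so the synthetic generator round-trips through the
same code path real extracts would use.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd

Count = Union[int, str, None]  # positive integer, the token "X", or missing

PROTOCOLS = ("stationary", "traveling", "historical", "other")

#: canonical name -> EBD-dialect column header (matched case-insensitively)
EBD_COLUMNS: Dict[str, str] = {
    "event_id": "SAMPLING EVENT IDENTIFIER",
    "group_id": "GROUP IDENTIFIER",
    "protocol": "PROTOCOL TYPE",
    "date": "OBSERVATION DATE",
    "start_time": "TIME OBSERVATIONS STARTED",
    "duration_minutes": "DURATION MINUTES",
    "distance_km": "EFFORT DISTANCE KM",
    "latitude": "LATITUDE",
    "longitude": "LONGITUDE",
    "location_name": "LOCALITY",
    "complete_flag": "ALL SPECIES REPORTED",
    "approved_flag": "APPROVED",
    "species_id": "SCIENTIFIC NAME",
    "count": "OBSERVATION COUNT",
}

DISTANCE_BANDS = ("0-25", "25-100", ">100")


@dataclass
class Checklist:
    """One semi-structured survey event with effort metadata and species counts."""

    event_id: str
    protocol: str
    date: dt.date
    start_time: dt.time
    duration_minutes: float
    distance_km: float
    latitude: float
    longitude: float
    location_name: str = ""
    group_id: Optional[str] = None
    complete_flag: bool = True
    approved_flag: bool = True
    observations: List[Tuple[str, Count]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.duration_minutes <= 0:
            raise ValueError(f"checklist {self.event_id}: duration must be positive")
        if self.distance_km < 0:
            raise ValueError(f"checklist {self.event_id}: distance must be non-negative")

    def replace(self, **kwargs) -> "Checklist":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class BBSSite:
    """One structured-survey site: point-count station cluster with metadata."""

    site_id: str
    centroid_lat: float
    centroid_lon: float
    n_points: int
    coastal_flag: bool
    habitat_class: str


@dataclass(frozen=True)
class BBSObservation:
    """One per-point detection inside a visit."""

    point_id: str
    species_id: str
    distance_band: str
    count: int


@dataclass(frozen=True)
class BBSVisit:
    """One visit to a site: every point surveyed once for a fixed duration."""

    site_id: str
    year: int
    visit_number: int
    records: Tuple[BBSObservation, ...]


def _normalise_header(columns: Sequence[str]) -> Dict[str, str]:
    return {c.strip().upper(): c for c in columns}


def _parse_count(raw) -> Count:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None
    s = str(raw).strip()
    if s == "" or s.upper() == "NA":
        return None
    if s.upper() == "X":
        return "X"
    return int(float(s))


def read_checklists(
    path: Union[str, Path], column_map: Optional[Dict[str, str]] = None
) -> List[Checklist]:
    """Read an EBD-dialect TSV into one :class:`Checklist` per sampling event.

    ``column_map`` overrides the default canonical-name -> header mapping.
    Missing required columns and unparseable date/time cells raise with the
    offending column or line named.
    """
    colmap = dict(EBD_COLUMNS)
    if column_map:
        colmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[])
    header = _normalise_header(df.columns)
    missing = [v for v in colmap.values() if v.upper() not in header]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(sorted(missing))}")
    actual = {k: header[v.upper()] for k, v in colmap.items()}

    checklists: Dict[str, Checklist] = {}
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        event_id = row[actual["event_id"]].strip()
        if event_id not in checklists:
            try:
                date = dt.date.fromisoformat(row[actual["date"]].strip())
                start_time = dt.time.fromisoformat(row[actual["start_time"]].strip())
            except ValueError as err:
                raise ValueError(f"line {line_no}: unparseable date/time ({err})") from err
            group_raw = row[actual["group_id"]].strip()
            checklists[event_id] = Checklist(
                event_id=event_id,
                protocol=row[actual["protocol"]].strip().lower(),
                date=date,
                start_time=start_time,
                duration_minutes=float(row[actual["duration_minutes"]]),
                distance_km=float(row[actual["distance_km"]] or 0.0),
                latitude=float(row[actual["latitude"]]),
                longitude=float(row[actual["longitude"]]),
                location_name=row[actual["location_name"]].strip(),
                group_id=group_raw or None,
                complete_flag=_parse_bool(row[actual["complete_flag"]]),
                approved_flag=_parse_bool(row[actual["approved_flag"]]),
            )
        species = row[actual["species_id"]].strip()
        if species:
            checklists[event_id].observations.append(
                (species, _parse_count(row[actual["count"]]))
            )
    return list(checklists.values())


def _parse_bool(raw) -> bool:
    return str(raw).strip().lower() in {"1", "true", "t", "yes"}


def write_checklists(
    checklists: Sequence[Checklist], path: Union[str, Path]
) -> None:
    """Write checklists as the EBD-dialect TSV ``read_checklists`` expects."""
    rows = []
    for cl in checklists:
        base = {
            EBD_COLUMNS["event_id"]: cl.event_id,
            EBD_COLUMNS["group_id"]: cl.group_id or "",
            EBD_COLUMNS["protocol"]: cl.protocol,
            EBD_COLUMNS["date"]: cl.date.isoformat(),
            EBD_COLUMNS["start_time"]: cl.start_time.isoformat(),
            EBD_COLUMNS["duration_minutes"]: cl.duration_minutes,
            EBD_COLUMNS["distance_km"]: cl.distance_km,
            EBD_COLUMNS["latitude"]: cl.latitude,
            EBD_COLUMNS["longitude"]: cl.longitude,
            EBD_COLUMNS["location_name"]: cl.location_name,
            EBD_COLUMNS["complete_flag"]: int(cl.complete_flag),
            EBD_COLUMNS["approved_flag"]: int(cl.approved_flag),
        }
        obs = cl.observations or [("", None)]
        for species, count in obs:
            row = dict(base)
            row[EBD_COLUMNS["species_id"]] = species
            row[EBD_COLUMNS["count"]] = "" if count is None else count
            rows.append(row)
    pd.DataFrame(rows, columns=list(EBD_COLUMNS.values())).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# structured-survey CSVs


def read_bbs_sites(path: Union[str, Path]) -> List[BBSSite]:
    df = pd.read_csv(path)
    return [
        BBSSite(
            site_id=str(r.site_id),
            centroid_lat=float(r.lat),
            centroid_lon=float(r.lon),
            n_points=int(r.n_points),
            coastal_flag=bool(r.coastal_flag),
            habitat_class=str(r.habitat),
        )
        for r in df.itertuples()
    ]


def write_bbs_sites(sites: Sequence[BBSSite], path: Union[str, Path]) -> None:
    pd.DataFrame(
        [
            {
                "site_id": s.site_id,
                "lat": s.centroid_lat,
                "lon": s.centroid_lon,
                "n_points": s.n_points,
                "coastal_flag": int(s.coastal_flag),
                "habitat": s.habitat_class,
            }
            for s in sites
        ]
    ).to_csv(path, index=False)


def read_bbs_visits(path: Union[str, Path]) -> List[BBSVisit]:
    df = pd.read_csv(path)
    visits: Dict[Tuple[str, int, int], List[BBSObservation]] = {}
    for r in df.itertuples():
        key = (str(r.site_id), int(r.year), int(r.visit))
        visits.setdefault(key, []).append(
            BBSObservation(
                point_id=str(r.point_id),
                species_id=str(r.species),
                distance_band=str(r.band),
                count=int(r.count),
            )
        )
    return [
        BBSVisit(site_id=k[0], year=k[1], visit_number=k[2], records=tuple(v))
        for k, v in visits.items()
    ]


def write_bbs_visits(visits: Sequence[BBSVisit], path: Union[str, Path]) -> None:
    rows = [
        {
            "site_id": v.site_id,
            "year": v.year,
            "visit": v.visit_number,
            "point_id": rec.point_id,
            "species": rec.species_id,
            "band": rec.distance_band,
            "count": rec.count,
        }
        for v in visits
        for rec in v.records
    ]
    pd.DataFrame(
        rows, columns=["site_id", "year", "visit", "point_id", "species", "band", "count"]
    ).to_csv(path, index=False)


def read_species_table(path: Union[str, Path]) -> pd.DataFrame:
    """Species metadata: columns species, diurnal (0/1), status."""
    df = pd.read_csv(path, dtype={"species": str, "status": str})
    df["diurnal"] = df["diurnal"].astype(bool)
    return df


def write_species_table(df: pd.DataFrame, path: Union[str, Path]) -> None:
    out = df.copy()
    out["diurnal"] = out["diurnal"].astype(int)
    out.to_csv(path, index=False)
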