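"""Alignment, culling, site selection, buffer assignment and the attrition
ledger: every rule removes exactly its intended records, boundaries are
inclusive, and input = kept + removed always reconciles."""

import datetime as dt
import random

import pandas as pd
import pytest

from checklist_bias.filtering import (
    FilterConfig,
    assign_checklists_to_sites,
    cull_observations,
    exclude_bbs_duplicates,
    filter_bbs_bands,
    filter_checklists,
    filter_species_checklists,
    select_bbs_sites,
)
from checklist_bias.ingest import BBSObservation, BBSSite, BBSVisit
from checklist_bias.sunrise import NoaaSunriseProvider

from conftest import fixed_sunrise, make_checklist


def site(site_id="S1", lat=23.5, lon=121.0, n_points=10, coastal=False):
    return BBSSite(site_id, lat, lon, n_points, coastal, "forest")


class TestAlignmentRules:
    @pytest.mark.parametrize(
        "overrides,rule",
        [
            ({"protocol": "incidental"}, "protocol"),
            ({"complete_flag": False}, "flags"),
            ({"approved_flag": False}, "flags"),
            ({"start_time": dt.time(5, 0)}, "sunrise_window"),  # before sunrise
            ({"start_time": dt.time(10, 0)}, "sunrise_window"),  # > 4 h after
            ({"date": dt.date(2014, 8, 15)}, "season_year"),  # August
            ({"date": dt.date(2009, 5, 15)}, "season_year"),  # pre-study year
            ({"date": dt.date(2018, 5, 15)}, "season_year"),
            ({"distance_km": 4.5, "protocol": "traveling"}, "distance"),
            ({"duration_minutes": 5.0}, "duration"),
        ],
    )
    def test_each_rule_removes_its_violator(self, overrides, rule):
        cl = make_checklist("BAD", **overrides)
        kept, report = filter_checklists([cl], fixed_sunrise)
        assert kept == []
        assert report.removed == {rule: ["BAD"]}

    @pytest.mark.parametrize(
        "overrides",
        [
            {"distance_km": 4.0, "protocol": "traveling"},  # <= 4 km inclusive
            {"duration_minutes": 6.0},  # >= 6 min inclusive
            {"start_time": dt.time(5, 30)},  # exactly at sunrise
            {"start_time": dt.time(9, 30)},  # exactly sunrise + 4 h
            {"date": dt.date(2010, 3, 1)},  # window start
            {"date": dt.date(2017, 7, 31)},  # window end
            {"protocol": "historical"},
        ],
    )
    def test_boundaries_are_inclusive(self, overrides):
        kept, report = filter_checklists([make_checklist(**overrides)], fixed_sunrise)
        assert len(kept) == 1 and report.total_removed == 0

    def test_first_failing_rule_attribution_and_reconciliation(self):
        cls = [make_checklist(f"EV{i}") for i in range(7)]
        cls += [
            make_checklist("V1", duration_minutes=5.0),
            make_checklist("V2", distance_km=9.0, protocol="traveling"),
            make_checklist("V3", date=dt.date(2014, 12, 1)),
        ]
        kept, report = filter_checklists(cls, fixed_sunrise)
        assert len(kept) == 7
        assert report.total_removed == 3
        assert len(cls) == len(kept) + report.total_removed
        # a record violating several rules is charged to the first in order
        both = make_checklist("V4", protocol="incidental", duration_minutes=1.0)
        _, rep = filter_checklists([both], fixed_sunrise)
        assert rep.removed == {"protocol": ["V4"]}

    def test_kept_set_order_insensitive_and_idempotent(self):
        cls = [make_checklist(f"EV{i}") for i in range(5)] + [
            make_checklist("BAD", duration_minutes=2)
        ]
        kept1, _ = filter_checklists(cls, fixed_sunrise)
        shuffled = cls[:]
        random.Random(0).shuffle(shuffled)
        kept2, _ = filter_checklists(shuffled, fixed_sunrise)
        assert {c.event_id for c in kept1} == {c.event_id for c in kept2}
        kept3, rep3 = filter_checklists(kept1, fixed_sunrise)
        assert [c.event_id for c in kept3] == [c.event_id for c in kept1]
        assert rep3.total_removed == 0

    def test_configurable_window(self):
        config = FilterConfig(year_min=2015, year_max=2016)
        kept, _ = filter_checklists(
            [make_checklist(date=dt.date(2014, 5, 15))], fixed_sunrise, config
        )
        assert kept == []

    def test_noaa_sunrise_plausible_for_subtropics(self):
        """Late-spring sunrise near 23.5N, 121E is a little after 05:00 local."""
        rise = NoaaSunriseProvider(8.0)(dt.date(2014, 5, 15), 23.5, 121.0)
        assert dt.time(5, 0) <= rise <= dt.time(5, 40)


class TestCulling:
    def test_x_count_drops_whole_checklist(self):
        cl = make_checklist(
            observations=[("a", 1), ("b", 2), ("c", "X"), ("d", 1), ("e", 3)]
        )
        kept, report = cull_observations([cl])
        assert kept == [] and report.removed == {"x_count": [cl.event_id]}

    def test_missing_count_drops_only_that_species(self):
        cl = make_checklist(observations=[("a", 1), ("b", None), ("c", 3), ("d", 2)])
        kept, _ = cull_observations([cl])
        assert len(kept) == 1
        assert [sp for sp, _ in kept[0].observations] == ["a", "c", "d"]

    def test_group_duplicates_keep_smallest_event_id(self):
        a = make_checklist("EV2", group_id="G1")
        b = make_checklist("EV1", group_id="G1")
        c = make_checklist("EV3", group_id=None)
        kept, report = cull_observations([a, b, c])
        assert {cl.event_id for cl in kept} == {"EV1", "EV3"}
        assert report.removed == {"group_duplicate": ["EV2"]}

    def test_idempotent(self):
        cls = [
            make_checklist("EV1", group_id="G1"),
            make_checklist("EV2", group_id="G1"),
            make_checklist("EV3", observations=[("a", None), ("b", 1)]),
        ]
        kept1, _ = cull_observations(cls)
        kept2, rep2 = cull_observations(kept1)
        assert [c.event_id for c in kept2] == [c.event_id for c in kept1]
        assert rep2.total_removed == 0


class TestSiteSelectionAndBands:
    def test_site_selection(self):
        sites = [
            site("S1"),
            site("S2", n_points=8),
            site("S3", coastal=True),
            site("S4"),
            site("S5"),
        ]
        kept, report = select_bbs_sites(sites)
        assert [s.site_id for s in kept] == ["S1", "S4", "S5"]
        assert report.counts == {"n_points": 1, "coastal": 1}
        assert len(sites) == len(kept) + report.total_removed

    def test_far_band_removed_species_absent_when_only_far(self):
        visit = BBSVisit(
            "S1", 2014, 1,
            (
                BBSObservation("P1", "far_only", ">100", 3),
                BBSObservation("P1", "both", "0-25", 2),
                BBSObservation("P2", "both", ">100", 5),
            ),
        )
        (filtered,) = filter_bbs_bands([visit])
        species = {r.species_id for r in filtered.records}
        assert species == {"both"}
        assert sum(r.count for r in filtered.records if r.species_id == "both") == 2

    def test_empty_visit_stays_empty(self):
        (filtered,) = filter_bbs_bands([BBSVisit("S1", 2014, 1, ())])
        assert filtered.records == ()


class TestAssignment:
    def test_checklist_at_centroid_assigned(self):
        cl = make_checklist(latitude=23.5, longitude=121.0)
        pairs, report = assign_checklists_to_sites([cl], [site()])
        assert pairs == [("S1", cl)] and report.total_removed == 0

    def test_overlapping_buffers_yield_two_pairs(self):
        # centroids 1 km apart: both 2x2 km buffers contain the midpoint
        s1 = site("S1", lat=23.5)
        s2 = site("S2", lat=23.5 + 1.0 / 111.32)
        cl = make_checklist(latitude=23.5 + 0.5 / 111.32, longitude=121.0)
        pairs, _ = assign_checklists_to_sites([cl], [s1, s2])
        assert sorted(sid for sid, _ in pairs) == ["S1", "S2"]

    def test_outside_all_buffers_dropped(self):
        # 1.5 km due east under the equirectangular projection
        import math

        dlon = 1.5 / (111.32 * math.cos(math.radians(23.5)))
        cl = make_checklist(latitude=23.5, longitude=121.0 + dlon)
        pairs, report = assign_checklists_to_sites([cl], [site()])
        assert pairs == [] and report.removed == {"outside_buffers": [cl.event_id]}


class TestBBSDuplicateExclusion:
    def test_bbs_style_location_name_removed(self):
        cl = make_checklist(location_name="BBS-A35-19")
        kept, report = exclude_bbs_duplicates([cl], [])
        assert kept == [] and report.removed == {"bbs_location_name": [cl.event_id]}

    def test_coordinates_matching_bbs_point_removed(self):
        cl = make_checklist(latitude=23.123456, longitude=121.654321)
        kept, report = exclude_bbs_duplicates([cl], [(23.123456, 121.654321)])
        assert kept == []
        assert report.removed == {"bbs_point_coordinates": [cl.event_id]}
        # beyond the configured precision the match no longer fires
        kept2, _ = exclude_bbs_duplicates(
            [cl], [(23.1234565, 121.654321)], coordinate_decimals=7
        )
        assert len(kept2) == 1

    def test_ordinary_locality_kept(self):
        cl = make_checklist(location_name="Riverside park")
        kept, report = exclude_bbs_duplicates([cl], [(24.0, 120.0)])
        assert len(kept) == 1 and report.total_removed == 0


class TestSpeciesFilter:
    def test_only_diurnal_breeders_survive(self):
        table = pd.DataFrame(
            {
                "species": ["owl", "winter", "res", "summer"],
                "diurnal": [False, True, True, True],
                "status": ["resident", "winter_visitor", "resident", "summer_visitor"],
            }
        )
        cl = make_checklist(
            observations=[("owl", 1), ("winter", 2), ("res", 3), ("summer", 1)]
        )
        (filtered,) = filter_species_checklists([cl], table)
        assert [sp for sp, _ in filtered.observations] == ["res", "summer"]
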