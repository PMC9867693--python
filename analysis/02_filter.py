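"""Align, cull and select: make the two datasets comparable.

Applies the full attrition chain — site selection (10 points, non-coastal),
far distance band removal, checklist alignment (protocol, flags, sunrise
window, season/years, distance, duration), culling ("X" lists, missing
counts, group duplicates), survey-duplicate exclusion and the species
filter — and reports how many records each rule removed.
"""

import argparse
from pathlib import Path

import pandas as pd

from checklist_bias import filtering, ingest
from checklist_bias.sunrise import NoaaSunriseProvider


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--results-dir", type=Path, default=Path("results/analysis"))
    args = parser.parse_args()

    data = args.results_dir / "data"
    outdir = args.results_dir / "filtered"
    outdir.mkdir(parents=True, exist_ok=True)

    checklists = ingest.read_checklists(data / "checklists.tsv")
    sites = ingest.read_bbs_sites(data / "sites.csv")
    visits = ingest.read_bbs_visits(data / "visits.csv")
    species = ingest.read_species_table(data / "species.csv")

    kept_sites, site_report = filtering.select_bbs_sites(sites)
    visits = [v for v in visits if v.site_id in {s.site_id for s in kept_sites}]
    visits = filtering.filter_bbs_bands(visits)
    visits = filtering.filter_species_visits(visits, species)

    kept, align_report = filtering.filter_checklists(checklists, NoaaSunriseProvider())
    kept, cull_report = filtering.cull_observations(kept)
    kept, dup_report = filtering.exclude_bbs_duplicates(
        kept, [(s.centroid_lat, s.centroid_lon) for s in sites]
    )
    kept = filtering.filter_species_checklists(kept, species)

    ingest.write_checklists(kept, outdir / "checklists.tsv")
    ingest.write_bbs_sites(kept_sites, outdir / "sites.csv")
    ingest.write_bbs_visits(visits, outdir / "visits.csv")
    reports = (site_report, align_report, cull_report, dup_report)
    pd.concat([r.to_frame() for r in reports], ignore_index=True).to_csv(
        outdir / "attrition.csv", index=False
    )

    print(f"sites: {len(sites)} -> {len(kept_sites)} (removed {site_report.counts})")
    print(f"checklists: {len(checklists)} -> {len(kept)}")
    for rep in (align_report, cull_report, dup_report):
        for rule, n in rep.counts.items():
            print(f"  removed {n:3d} by {rule}")
    print(f"wrote filtered data and attrition ledger under {outdir}")


if __name__ == "__main__":
    main()
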