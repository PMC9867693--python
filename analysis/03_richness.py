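"""Estimate richness per survey unit: checklists and pooled visits.

Computes observed richness, singleton/doubleton counts, the
small-sample-corrected Chao1 estimate and the singleton percentage for
every filtered checklist and every structured visit (pooled over its 10
points after band filtering).
"""

import argparse
from pathlib import Path

from checklist_bias import ingest, richness
from checklist_bias.bias import pool_visit


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--results-dir", type=Path, default=Path("results/analysis"))
    args = parser.parse_args()

    filtered = args.results_dir / "filtered"
    checklists = ingest.read_checklists(filtered / "checklists.tsv")
    visits = ingest.read_bbs_visits(filtered / "visits.csv")

    checklist_table = richness.richness_table(
        {cl.event_id: richness.make_sample(cl.observations) for cl in checklists}
    )
    visit_table = richness.richness_table(
        {f"{v.site_id}-{v.year}-{v.visit_number}": pool_visit(v) for v in visits}
    )
    checklist_table.to_csv(args.results_dir / "richness_checklists.csv", index=False)
    visit_table.to_csv(args.results_dir / "richness_visits.csv", index=False)

    print(
        f"checklists (n={len(checklist_table)}): mean S_obs "
        f"{checklist_table.S_obs.mean():.1f}, mean Chao1 {checklist_table.chao1.mean():.1f}, "
        f"mean singleton share {checklist_table.singleton_pct.mean():.0f}%"
    )
    print(
        f"visits (n={len(visit_table)}): mean S_obs {visit_table.S_obs.mean():.1f}, "
        f"mean Chao1 {visit_table.chao1.mean():.1f}"
    )


if __name__ == "__main__":
    main()
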