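"""End-to-end orchestration: data -> filters -> richness -> bias -> effort fits.

One :class:`RunConfig` (YAML-loadable) governs a full run, whether the
inputs are simulated or read from files, so every threshold of the
alignment protocol is data rather than code.  The run persists every
intermediate table as CSV under the output directory and returns a
:class:`RunReport` whose numbers are all recomputable from those
artifacts.  Identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import effort, filtering, ingest, richness
from .bias import (
    BIAS_TYPES,
    bias_table,
    pool_visit,
    singleton_bias_relation,
    site_reference,
    site_reference_table,
)
from .sunrise import NoaaSunriseProvider
from .synthetic import SimulationConfig, simulate_dataset

STAGES = ("input", "filter", "estimate", "bias", "fit")


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything a full run needs; exactly one of simulation/input paths."""

    simulation: Optional[SimulationConfig] = None
    input_dir: Optional[str] = None
    filter: filtering.FilterConfig = field(default_factory=filtering.FilterConfig)
    chao1_variant: str = "small_sample_corrected"
    standardized_duration: float = 60.0
    n_sims: int = 10_000
    buffer_half_side_km: float = 1.0
    utc_offset_hours: float = 8.0
    min_fit_points: int = 3
    seed: int = 0
    outdir: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.input_dir is None):
            raise ValueError("exactly one of simulation block or input_dir must be set")
        if self.standardized_duration <= 0 or self.n_sims < 1:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.get("simulation")
        filt = raw.get("filter", {})
        if "months" in filt:
            filt["months"] = tuple(filt["months"])
        if "allowed_protocols" in filt:
            filt["allowed_protocols"] = tuple(filt["allowed_protocols"])
        return cls(
            simulation=SimulationConfig.from_dict(sim) if sim is not None else None,
            input_dir=raw.get("input_dir"),
            filter=filtering.FilterConfig(**filt),
            chao1_variant=raw.get("chao1_variant", "small_sample_corrected"),
            standardized_duration=raw.get("standardized_duration", 60.0),
            n_sims=raw.get("n_sims", 10_000),
            buffer_half_side_km=raw.get("buffer_half_side_km", 1.0),
            utc_offset_hours=raw.get("utc_offset_hours", 8.0),
            seed=raw.get("seed", 0),
            outdir=raw.get("outdir"),
        )


@dataclass
class RunReport:
    """Headline numbers of one run; every figure is also in a persisted CSV."""

    n_checklists_in: int
    n_checklists_kept: int
    n_sites_in: int
    n_sites_kept: int
    n_assignments: int
    attrition: Dict[str, int]
    fits: Dict[str, effort.PowerFitResult]
    standardized_bias: Dict[str, float]
    standardized_completeness: Dict[str, float]
    crossing_durations: Dict[str, Optional[float]]
    nonnegative_bias_counts: Dict[str, int]
    singleton_relation: Dict[str, float]

    def to_dict(self) -> dict:
        fits = {
            k: {
                f.name: (None if isinstance(v := getattr(fit, f.name), np.ndarray) else v)
                for f in dataclasses.fields(fit)
            }
            for k, fit in self.fits.items()
        }
        return {
            "n_checklists_in": self.n_checklists_in,
            "n_checklists_kept": self.n_checklists_kept,
            "n_sites_in": self.n_sites_in,
            "n_sites_kept": self.n_sites_kept,
            "n_assignments": self.n_assignments,
            "attrition": self.attrition,
            "fits": fits,
            "standardized_bias": self.standardized_bias,
            "standardized_completeness": self.standardized_completeness,
            "crossing_durations": self.crossing_durations,
            "nonnegative_bias_counts": self.nonnegative_bias_counts,
            "singleton_relation": self.singleton_relation,
        }


def count_nonnegative_bias(bias_records: pd.DataFrame, bias_type: str) -> int:
    """Checklists of one comparison recording at least the reference (bias >= 0)."""
    sub = bias_records[bias_records["bias_type"] == bias_type]
    return int((sub["bias"] >= 0).sum())


def _fit_table(fits: Dict[str, effort.PowerFitResult]) -> pd.DataFrame:
    rows = []
    for bias_type, fit in fits.items():
        for pname, est, se, t, p in (
            ("coef", fit.coef, fit.se_coef, fit.t_coef, fit.p_coef),
            ("exp", fit.exp, fit.se_exp, fit.t_exp, fit.p_exp),
        ):
            rows.append(
                {
                    "bias_type": bias_type,
                    "parameter": pname,
                    "estimate": est,
                    "std_error": se,
                    "t_value": t,
                    "p_value": p,
                    "residual_se": fit.residual_se,
                    "dof": fit.dof,
                    "converged": fit.converged,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full comparison and persist artifacts; see module docstring."""
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    # --- input -----------------------------------------------------------
    try:
        if config.simulation is not None:
            bundle = simulate_dataset(config.simulation)
            checklists = bundle.checklists
            sites, visits = bundle.sites, bundle.visits
            species_table = bundle.species_table
            if outdir:
                bundle.write(outdir / "input")
        else:
            indir = Path(config.input_dir)
            checklists = ingest.read_checklists(indir / "checklists.tsv")
            sites = ingest.read_bbs_sites(indir / "sites.csv")
            visits = ingest.read_bbs_visits(indir / "visits.csv")
            species_table = ingest.read_species_table(indir / "species.csv")
    except (OSError, ValueError) as err:
        raise PipelineError("input", str(err)) from err

    n_checklists_in, n_sites_in = len(checklists), len(sites)

    # --- filter ----------------------------------------------------------
    try:
        kept_sites, site_report = filtering.select_bbs_sites(sites)
        visits = [v for v in visits if v.site_id in {s.site_id for s in kept_sites}]
        visits = filtering.filter_bbs_bands(visits)
        visits = filtering.filter_species_visits(visits, species_table)

        sunrise = NoaaSunriseProvider(config.utc_offset_hours)
        kept, align_report = filtering.filter_checklists(checklists, sunrise, config.filter)
        kept, cull_report = filtering.cull_observations(kept)
        bbs_points = [(s.centroid_lat, s.centroid_lon) for s in sites]
        kept, dup_report = filtering.exclude_bbs_duplicates(kept, bbs_points)
        kept = filtering.filter_species_checklists(kept, species_table)
        assignments, assign_report = filtering.assign_checklists_to_sites(
            kept, kept_sites, config.buffer_half_side_km
        )
    except ValueError as err:
        raise PipelineError("filter", str(err)) from err

    attrition: Dict[str, int] = {}
    for rep in (site_report, align_report, cull_report, dup_report, assign_report):
        attrition.update(rep.counts)
    if outdir:
        pd.concat(
            [r.to_frame() for r in (site_report, align_report, cull_report, dup_report, assign_report)],
            ignore_index=True,
        ).to_csv(outdir / "attrition.csv", index=False)

    # --- estimate --------------------------------------------------------
    try:
        checklist_samples = {
            cl.event_id: richness.make_sample(cl.observations) for cl in kept
        }
        checklist_table = richness.richness_table(checklist_samples, config.chao1_variant)
        visit_samples: Dict[str, List[richness.AbundanceSample]] = {}
        for v in visits:
            visit_samples.setdefault(v.site_id, []).append(pool_visit(v))
        visit_table = richness.richness_table(
            {
                f"{v.site_id}-{v.year}-{v.visit_number}": pool_visit(v)
                for v in visits
            },
            config.chao1_variant,
        )
    except ValueError as err:
        raise PipelineError("estimate", str(err)) from err
    if outdir:
        checklist_table.to_csv(outdir / "richness_checklists.csv", index=False)
        visit_table.to_csv(outdir / "richness_visits.csv", index=False)

    # --- bias ------------------------------------------------------------
    try:
        references = {
            site_id: site_reference(site_id, samples, config.chao1_variant)
            for site_id, samples in visit_samples.items()
        }
        assignments = [(sid, cl) for sid, cl in assignments if sid in references]
        if not assignments:
            raise ValueError(
                "no checklist survived filtering and assignment; nothing to compare"
            )
        checklist_richness = {
            row.unit_id: (float(row.S_obs), float(row.chao1))
            for row in checklist_table.itertuples()
        }
        records = bias_table(assignments, references, checklist_richness)
    except ValueError as err:
        raise PipelineError("bias", str(err)) from err
    if outdir:
        site_reference_table(references).to_csv(
            outdir / "site_references.csv", index=False
        )
        records.to_csv(outdir / "bias_records.csv", index=False)

    # --- fit -------------------------------------------------------------
    try:
        fits: Dict[str, effort.PowerFitResult] = {}
        std_bias: Dict[str, float] = {}
        std_completeness: Dict[str, float] = {}
        crossings: Dict[str, Optional[float]] = {}
        counts: Dict[str, int] = {}
        rng = np.random.default_rng(config.seed)
        x_grid = np.linspace(6.0, 200.0, 98)
        bands = []
        for bias_type in BIAS_TYPES:
            sub = records[records["bias_type"] == bias_type]
            if len(sub) < config.min_fit_points:
                raise ValueError(
                    f"only {len(sub)} bias records for {bias_type}; cannot fit"
                )
            fit = effort.fit_power(sub["duration"].to_numpy(), sub["bias"].to_numpy())
            fits[bias_type] = fit
            std_bias[bias_type] = float(
                effort.predict_bias(fit, config.standardized_duration)
            )
            std_completeness[bias_type] = float(
                effort.completeness_percent(fit, config.standardized_duration)
            )
            crossings[bias_type] = effort.crossing_duration(fit)
            counts[bias_type] = count_nonnegative_bias(records, bias_type)
            band = effort.mc_confidence_band(
                fit, x_grid, n_sims=config.n_sims, seed=int(rng.integers(2**31 - 1))
            )
            bands.append(
                pd.DataFrame(
                    {
                        "bias_type": bias_type,
                        "x": band.x,
                        "fit": band.fitted,
                        "lo95": band.lower95,
                        "hi95": band.upper95,
                    }
                )
            )
        est_obs = records[records["bias_type"] == "est_vs_obs"].merge(
            checklist_table[["unit_id", "singleton_pct"]],
            left_on="event_id",
            right_on="unit_id",
        )
        relation = singleton_bias_relation(
            est_obs["bias"].to_list(), est_obs["singleton_pct"].to_list()
        )
    except ValueError as err:
        raise PipelineError("fit", str(err)) from err

    report = RunReport(
        n_checklists_in=n_checklists_in,
        n_checklists_kept=len(kept),
        n_sites_in=n_sites_in,
        n_sites_kept=len(kept_sites),
        n_assignments=len(assignments),
        attrition=attrition,
        fits=fits,
        standardized_bias=std_bias,
        standardized_completeness=std_completeness,
        crossing_durations=crossings,
        nonnegative_bias_counts=counts,
        singleton_relation=relation,
    )
    if outdir:
        _fit_table(fits).to_csv(outdir / "fits.csv", index=False)
        pd.concat(bands, ignore_index=True).to_csv(outdir / "bands.csv", index=False)
        with open(outdir / "run_summary.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True, default=float)
    return report
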