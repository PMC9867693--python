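"""Relative-bias statistics between checklists and their site references.

For a checklist assigned to a structured-survey site, bias is the relative
difference between the checklist's richness and the site's reference
richness:

    bias = (numerator - reference) / reference

Four comparisons arise from crossing observed versus Chao1-estimated
richness on each side.  The site reference is A_i (mean over visits of
per-visit observed richness) or B_i (mean over visits of per-visit Chao1
estimates); the checklist numerator is O_ij (observed) or E_ij (Chao1).
A bias of 0 means parity with the reference; -1 means nothing recorded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .ingest import BBSVisit, Checklist
from .richness import AbundanceSample, chao1, make_sample

BIAS_TYPES = ("obs_vs_obs", "est_vs_obs", "obs_vs_est", "est_vs_est")


@dataclass(frozen=True)
class SiteReference:
    """Per-site reference richness: visit means of observed (A_i) and Chao1 (B_i)."""

    site_id: str
    a_i: float
    b_i: float
    n_visits: int


def pool_visit(visit: BBSVisit) -> AbundanceSample:
    """Pool a visit's per-point records into one abundance sample."""
    return make_sample((r.species_id, r.count) for r in visit.records)


def site_reference(
    site_id: str,
    visit_samples: Sequence[AbundanceSample],
    variant: str = "small_sample_corrected",
    include_empty_visits: bool = True,
) -> SiteReference:
    """Average per-visit observed and estimated richness for one site.

    Visits with zero detections contribute richness 0 by default; dropping
    them (``include_empty_visits=False``) would silently inflate the
    reference.
    """
    if not include_empty_visits:
        visit_samples = [s for s in visit_samples if s.s_obs > 0]
    if not visit_samples:
        raise ValueError(f"site {site_id}: no visits to average")
    obs = [float(s.s_obs) for s in visit_samples]
    est = [chao1(s, variant).estimate for s in visit_samples]
    return SiteReference(
        site_id=site_id,
        a_i=float(np.mean(obs)),
        b_i=float(np.mean(est)),
        n_visits=len(visit_samples),
    )


def bias(numerator_richness: float, reference: float) -> float:
    """Relative bias (numerator - reference)/reference; reference must be > 0."""
    if reference <= 0:
        raise ValueError(f"reference richness must be positive, got {reference}")
    return (numerator_richness - reference) / reference


def bias_table(
    assignments: Sequence[Tuple[str, Checklist]],
    site_references: Mapping[str, SiteReference],
    checklist_richness: Mapping[str, Tuple[float, float]],
) -> pd.DataFrame:
    """All four bias records for every (site, checklist) assignment.

    ``checklist_richness`` maps event_id -> (observed, estimated).  A
    checklist assigned to k sites yields 4k rows.
    """
    rows: List[dict] = []
    for site_id, cl in assignments:
        ref = site_references[site_id]
        o_ij, e_ij = checklist_richness[cl.event_id]
        for bias_type in BIAS_TYPES:
            numerator = o_ij if bias_type.startswith("obs") else e_ij
            reference = ref.a_i if bias_type.endswith("obs") else ref.b_i
            rows.append(
                {
                    "site_id": site_id,
                    "event_id": cl.event_id,
                    "duration": cl.duration_minutes,
                    "bias_type": bias_type,
                    "numerator": numerator,
                    "reference": reference,
                    "bias": bias(numerator, reference),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["site_id", "event_id", "duration", "bias_type", "numerator", "reference", "bias"],
    )


def site_reference_table(references: Mapping[str, SiteReference]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"site_id": r.site_id, "A_i": r.a_i, "B_i": r.b_i, "n_visits": r.n_visits}
            for r in references.values()
        ],
        columns=["site_id", "A_i", "B_i", "n_visits"],
    )


def singleton_bias_relation(
    bias_values: Sequence[float], singleton_pcts: Sequence[float]
) -> Dict[str, float]:
    """Rank correlation and OLS trend of bias on singleton percentage.

    The headline output is the sign of the relationship: Chao1 bias is
    expected to rise with the share of singletons in a sample.  Returns
    Spearman rho and p, and the OLS slope of bias on singleton % with its
    p value; a constant predictor yields slope 0 and missing correlation.
    """
    import statsmodels.api as sm

    y = np.asarray(bias_values, dtype=float)
    x = np.asarray(singleton_pcts, dtype=float)
    keep = np.isfinite(y) & np.isfinite(x)
    y, x = y[keep], x[keep]
    if y.size < 3:
        raise ValueError("need at least 3 finite (bias, singleton %) pairs")
    if np.ptp(x) == 0:
        return {
            "spearman_rho": np.nan,
            "spearman_p": np.nan,
            "ols_slope": 0.0,
            "ols_slope_p": np.nan,
            "n": int(y.size),
        }
    rho, rho_p = stats.spearmanr(x, y)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return {
        "spearman_rho": float(rho),
        "spearman_p": float(rho_p),
        "ols_slope": float(model.params[1]),
        "ols_slope_p": float(model.pvalues[1]),
        "n": int(y.size),
    }
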