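# checklist-bias

Tools for asking how well semi-structured citizen-science checklists
(eBird-style) recover the species richness that structured point-count
surveys (BBS-style) record at the same places — and how much a
nonparametric richness estimator closes the gap once survey effort is
standardized.

The package is aimed at ecologists and biodiversity-informatics
practitioners who want to reuse the workflow on their own extracts, and it
ships a synthetic-data generator with known true richness so the whole
pipeline is testable end to end without any data downloads.

## The statistics at the core

**Chao1.** For an abundance sample with `S_obs` observed species, `f1`
singletons, `f2` doubletons and `n` individuals, the Chao1 lower bound on
true richness is

    S_chao1 = S_obs + f1^2 / (2 f2)            (f2 > 0)
    S_chao1 = S_obs + f1 (f1 - 1) / 2          (f2 = 0)

with the small-sample correction multiplying the added term by
`(n - 1)/n` (the default here, matching the iNEXT/SpadeR convention).

**Relative bias.** Each checklist `j` assigned to survey site `i` is
scored against the site's reference richness:

    bias = (O_ij - A_i) / A_i

where `O_ij` is the checklist's observed richness and `A_i` the mean
per-visit observed richness of the site; substituting the checklist's
Chao1 estimate `E_ij` and/or the mean per-visit Chao1 reference `B_i`
gives four comparisons (`obs_vs_obs`, `est_vs_obs`, `obs_vs_est`,
`est_vs_est`). Bias 0 means parity; -1 means nothing recorded.

**Effort model.** Bias is regressed on checklist duration `x` (minutes)
with the shifted power function

    y = a x^b - 1

fitted by least squares (Levenberg–Marquardt, analytic Jacobian).
Completeness at a standardized duration — by convention 60 min, one full
structured visit of 10 × 6-min points — is `100 · a · 60^b` percent.
Uncertainty bands come from Monte-Carlo simulation of the parameter
covariance (10,000 draws), with first-/second-order Taylor propagation
available for comparison.

Before any of that, checklists are aligned with the structured protocol:
stationary/traveling/historical protocols only, complete and approved
lists, started between local sunrise (NOAA solar approximation) and four
hours after, March–July of the study years, ≤ 4 km traveled, ≥ 6 min
duration; lists with "X" counts are dropped, missing-count species rows
removed, group-shared duplicates reduced to one representative, and
lists that look like re-submitted survey counts excluded. Every removal
is attributed to exactly one rule in an attrition ledger that always
reconciles.

## Worked example

The analysis is organised as numbered drivers over the library:

```sh
python analysis/01_simulate.py --seed 0     # paired datasets + truth file
python analysis/02_filter.py                # alignment, culling, site selection
python analysis/03_richness.py              # Chao1 per checklist and per visit
python analysis/04_bias.py                  # site references + bias records
python analysis/05_fit_effort.py --seed 0   # power fits, bands, figures
python analysis/06_standardized_comparison.py
```

With the default configuration (a 135-species community, 10 sites, ~300
checklists) the chain prints, among other things:

```
checklists (n=272): mean S_obs 77.0, mean Chao1 162.8, mean singleton share 62%
visits (n=128): mean S_obs 98.7, mean Chao1 126.6
obs_vs_obs: y = 0.1600 x^0.4237 - 1  (SEs 0.0080/0.0114, residual SE 0.1181 on 202 dof, n=204)
at 60 min:
  obs_vs_obs: bias -0.09, completeness 91%, parity within 6-200 min: 75.6, ...
  est_vs_obs: bias +0.64, completeness 164%, parity within 6-200 min: not reached, ...
singleton share vs Chao1 bias: OLS slope 0.0071 (p=0.00054), Spearman rho 0.15
```

Read: raw 60-min checklists recover about 91% of the average observed
visit richness in this synthetic world, and the fitted curve reaches
parity at ~76 min; applying Chao1 to the checklists overshoots the
observed reference (bias +0.64 at 60 min), driven by singleton-rich short
lists — the positive slope between singleton share and bias quantifies
exactly that overestimation risk. All numbers land in
`results/analysis/` as CSV/JSON, with one figure per comparison.

The same workflow is scriptable through the `checklist-bias` CLI
(`simulate`, `filter`, `estimate`, `bias`, `fit`, `run`) or the library
API (`checklist_bias.run_pipeline` with a `RunConfig`).

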