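# Methods

This note records the models, numerical choices and limitations behind
the package, in the order the pipeline applies them.

## Study design being compared

Two survey modes over the same bird community:

* **Structured point counts** ("BBS-style"): fixed sites of 10 points
  inside a 2 × 2 km square, each point surveyed 6 min per visit (60 min
  total), two visits a year across the 2010–2017 breeding seasons
  (March–July), detections recorded in distance bands 0–25 m, 25–100 m
  and > 100 m. Sites with fewer than 10 points or intersecting the
  coastline are excluded; the far band is discarded so a visit's species
  pool reflects the local 100-m-scale habitat.
* **Semi-structured checklists** ("eBird-style"): events of 6–200 min by
  observers of mixed skill, with effort metadata (protocol, start time,
  duration, distance traveled, coordinates), aligned to the structured
  protocol by the filter chain before comparison.

The comparison statistic is the relative bias `(O - A)/A` of a
checklist's richness against its site's mean per-visit richness, in four
variants crossing observed vs Chao1-estimated richness on either side,
followed by a least-squares fit of `y = a x^b - 1` to (duration, bias)
and evaluation at the 60-minute standardized duration. Completeness is
`100 (1 + bias)` percent.

## Chao1

Implemented over the sufficient statistics `(S_obs, f1, f2, n)`. Default
variant is the small-sample-corrected form — `S_obs + ((n-1)/n)
f1^2/(2 f2)`, falling back to `S_obs + ((n-1)/n) f1(f1-1)/2` when
`f2 = 0` — the convention of the iNEXT/SpadeR software family; the
classic textbook form is retained as an option for sensitivity analysis.
Consequences worth noting: with no singletons the estimate equals
`S_obs`; a single singleton with no doubletons adds nothing; an empty
sample returns 0 flagged `empty` rather than raising. Estimates are
never rounded internally.

## Filtering protocol

Rule order is fixed and each removed record is charged to the **first**
failing rule, so the attrition ledger reconciles exactly
(`input = kept + removed`): protocol/flags → sunrise window →
season/year → distance → duration → culling ("X" lists dropped whole,
missing-count rows dropped individually, group duplicates reduced to the
lexicographically smallest event id) → survey-duplicate exclusion
(location-name pattern, default `BBS[-_ ]`, and coordinate equality at 6
decimal places, both configurable) → species filter (diurnal residents
and summer visitors only). Printed boundaries are inclusive: 4.0 km and
6 min survive, as do starts exactly at sunrise or sunrise + 4 h.

Sunrise uses the NOAA solar-position approximation (fractional-year
Fourier terms for declination and the equation of time, zenith 90.833°),
accurate to about ±2 min at subtropical latitudes — negligible against
the 4-hour window it gates. A fixed UTC offset (+8 by default) converts
to local clock time; a precomputed-sunrise column can override the
provider. Buffer assignment evaluates the 2 × 2 km squares in a local
equirectangular projection (longitude scaled by cos latitude); at this
scale the planar error is far below the buffer size, and the choice is
documented so results are bit-reproducible. A checklist inside k
overlapping buffers is counted once per site, mirroring the overlap
convention of the source protocol.

## Power-function fit and uncertainty

`fit_power` minimizes `Σ (y_i - (a x_i^b - 1))^2` with MINPACK
Levenberg–Marquardt and the analytic Jacobian `(x^b, a x^b ln x)`;
relative tolerances 1e-10, at most 1000 function evaluations.
Initialization regresses `log(y + 1)` on `log x` over points with
`y + 1 > 0` (exact for noiseless data), falling back to `(0.2, 0.3)`
when fewer than three points qualify. Standard errors come from
`s^2 (J'J)^{-1}` at the optimum with `s^2 = RSS/(n-2)`; t statistics are
estimate/SE and p values two-sided from the t distribution on `n - 2`
degrees of freedom (the standard convention; asserted in tests).
Non-convergence is flagged on the result, never silently returned.

The primary uncertainty output for the fitted curve is a Monte-Carlo
band: 10,000 draws from the bivariate normal on (a, b) with the fit
covariance, pointwise 2.5/97.5 percentiles, seeded. First- and
second-order Taylor (delta-method) bands are produced for parity with
error-propagation software and labeled as such; the simulation band is
wider than the first-order band where the curve is most nonlinear in
the exponent, which is expected, not an error. Non-positive-definite
covariances are repaired by clipping negative eigenvalues at zero, with
a warning. The parity-crossing duration solves `a x^b - 1 = y*`
analytically and reports "not reached" beyond the 200-min range or for
non-increasing curves (`b ≤ 0`).

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
not any particular landscape:

* **Community**: `S` species (default 135 eligible, plus 3 contaminants
  flagged nocturnal/winter-visitor to exercise the species filter) with
  log-normal rank abundances (σ = 1), weights sorted descending and
  normalized.
* **Detection**: independent per-species Poisson encounter processes;
  species s is detected in t minutes with probability
  `1 - exp(-r_s · skill · weather · t)`. Encounter rates interpolate
  from 0.08/min (most abundant) to 0.005/min (rarest) by rank, so
  common species are also easiest to detect. Chosen because it has
  closed-form expectations (`E[S_obs] = Σ (1 - e^{-r t})`, tested
  against simulation) and reproduces the two qualitative phenomena the
  analysis rests on: observed richness rising monotonically toward truth
  with effort, and singleton inflation at short durations.
* **Counts**: detected species receive a zero-truncated Poisson count
  with mean `κ · w_s · t` (abundance × duration). The intensity
  κ = 3 individuals per unit abundance weight per minute was chosen so a
  60-min list carries a realistic load (~180 individuals, ~50%
  singletons, rising to ~85% at 6 min) **and** sits in the regime where
  singleton-driven Chao1 inflation, not the duration trend, dominates
  the bias–singleton relationship — the structure the generator exists
  to emulate. At much higher κ counts saturate, singletons vanish and
  that relationship flips sign.
* **Observers**: checklist skill ~ U(0.5, 1.0), weather multiplier
  ~ U(0.9, 1.0); structured visits use a fixed trained-observer skill of
  0.9. Skill acts multiplicatively on encounter rates.
* **Dirty data**: "X" counts (5% of lists), missing counts (5%),
  group-shared duplicate lists (5%), survey-style locality names (2%),
  lists placed outside all buffers (3%), short/coastal sites (10% each)
  are injected so every filter rule has real work in end-to-end runs.
  All other checklist metadata is generated inside the alignment windows.

Everything is seeded: identical configuration and seed give
byte-identical output files.

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: spatial habitat structure and species
turnover between sites (every site samples the same community), within-
season phenology, observer-specific species preferences, count
overdispersion beyond Poisson, flocking, and misidentification. The
generator supports the claim that the *pipeline computes the intended
quantities correctly*, not that any particular bias value generalizes.

## Problem sizes

Default analysis runs use 10 sites × 16 visits and ~300 checklists; the
repeated-run property checks use 4 sites and 80 checklists per seed over
20 seeds, and the fit-calibration study uses 200 replicates at n = 564
points with residual noise 0.27 — the scale of the motivating dataset.
These sizes were chosen as the smallest at which the Monte-Carlo checks
are decisively signed.

## Known limitations

* The coastline test is a per-site boolean attribute, not a GIS
  intersection; shapefile support is out of scope.
* Coordinate-equality precision (6 decimals), filter order, and the
  group-duplicate representative are conventions of this implementation;
  the motivating protocol does not pin them down.
* No per-sample Chao1 variance, no Chao2/ACE/jackknife, no
  rarefaction/extrapolation curves, and no alternative effort models
  (Michaelis–Menten, Weibull): the analysis uses the Chao1 point
  estimate and the shifted power function only.
* The supplementary-style singleton analyses are a Spearman rank
  correlation plus an OLS slope; only the sign and significance are
  meaningful outputs there.
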