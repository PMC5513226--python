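# Methods

## Coordinate and time conventions

All coordinates are planar meters in a projected system; every quantity the
pipeline reports is a Euclidean distance (m) or area (ha), so no geodesy is
performed. Phase logic runs at daily resolution with half-open windows
`[start, end)`; segments and distances use full timestamps. A fix stamped
00:00 is the roost location for the night that is ending and is attributed
to the preceding calendar day — this is load-bearing for laying detection,
where the diagnostic signature is a daytime nest visit with the midnight
roost *elsewhere*. A consequence is that a midnight fix stamped with the
laying date belongs to the last prenesting day.

## Phase delineation

* **Incubation onset** — the earliest day on which every fix lies within
  `incubation_radius_m` (default 50 m) of the nest. By default the day must
  open a run of ≥ 2 consecutive such days (`incubation_run_days`); a run
  length of 1 reproduces the literal single-day rule. The run guard
  protects against one-off low-movement days, but it is the more fragile
  rule under GPS error: with hourly sampling (16 fixes/day) and isotropic
  error σ = 15 m, a single > 50 m outlier occurs on ~6% of on-nest days,
  so the two-day rule misses ±1-day recovery for ~6% of females while the
  single-day rule stays above 99%. Synthetic recovery checks therefore
  exercise the single-day rule; the default remains 2 for field data where
  single quiet days are a real failure mode.
* **Laying onset** — the first day of the run of consecutive
  visit-signature days (≥ 1 non-midnight fix within the visit radius,
  midnight fix outside it) ending the day before incubation begins. When
  no such run exists the laying onset collapses onto the incubation onset
  and is logged; the visit radius defaults to the incubation radius, which
  the source material does not specify separately.
* **Prenesting** — the `prenesting_days` (45) days before laying;
  days-before-laying indexes 1..45 counting back from the first laying day.

## Range estimation

The prenesting UD is a dynamic Brownian bridge: per segment the position
density is the bivariate normal along the straight line between fixes with
variance `σ²m·t(T−t)/T + ((1−t/T)² + (t/T)²)·δ²`, where δ is the GPS
location error (default 10 m, the GPS-accuracy scale that also motivates
the exclusion threshold below). The motion variance σ²m (m²/s) is estimated
by leave-one-out maximum likelihood — odd-indexed fixes predicted from
their even-indexed neighbours — in sliding windows of 31 fixes with an
11-fix margin, the estimator's published defaults; each window's estimate
is assigned to its core segments and overlapping assignments averaged, so
behavioural change points at window margins show up as variance steps
without an explicit changepoint test. Tracks shorter than one window fall
back to a single global estimate (logged). Time integration uses midpoint
quadrature with the step chosen so consecutive bridge means are spaced
well below the narrowest bridge SD (≥ δ/√2) and below the grid cell.

Incubation ranges use a fixed isotropic Gaussian kernel; the default
bandwidth is the per-axis normal-scale rule `σ̂_j · n^(−1/6)` averaged to
one isotropic h (no bandwidth is stated in the source material, which used
an external GIS tool). Degenerate point sets (zero spread) raise an error
asking for an explicit minimum bandwidth.

Grids auto-scale: cell size `max(5 m, extent/400)` with padding of several
bandwidths/bridge SDs, because the per-bird range areas span two orders of
magnitude (tens of hectares to > 20,000 ha) and no fixed resolution serves
both ends.

**Isopleths** are probability-mass contours: cells are ranked by density
and the smallest prefix holding ≥ the level defines the isopleth set
(contained mass is within one cell mass of the level), whose outline is
traced by marching squares; rings are assembled into shells and holes by
containment parity, and areas are summed over parts. Ties in density (a
flat UD) are resolved by the stable cell ordering, which keeps the
uniform-distribution case well defined (area ≈ level × support area).
Points on a polygon boundary count as inside.

## Nest-distance metrics

Per-bird prenesting summaries use **all** prenesting fixes: mean, sample SD
(ddof = 1), minimum, and the days-before-laying at which the minimum occurs
(ties resolve to the day nearer laying; a mean-of-daily-means variant is
available via `mean_distance_mode`). The 10-m GPS-error exclusion (strict
`<`) applies only to incubation-period summaries, where sub-10-m scatter
around a stationary female is measurement noise: the published per-bird
prenesting minima go below 10 m (6.47, 2.51, "<1" m), so a global
exclusion would contradict the published tables. Censored "<1" entries are
parsed as the bound with a censored flag and excluded from recomputed
means (with a footnote count).

Recomputation note: the published Eastern-population table is internally
inconsistent in two places. Its 99%-isopleth footer implies 13% of nests
outside while the printed membership column contains 4 of 23 "Out" (17.4%),
and its minimum-distance footer (235.01 m) is not recoverable from the
printed column under any treatment of the censored cell (excluding it
gives 247.04 m, including it as 1 m gives 236.3 m). The recomputed
column-based values are reported; the footers are not reconciled. The
published dispersion columns are labelled SD and treated as SD throughout.

## Buffers and segment classification

The equivalent radius of an area is `r = √(A/π)`. The five regions and the
population mean incubation distances (70.82 m Rio Grande, 55.24 m Eastern)
are configurable. "Intersects" defaults to the closed-region semantics —
any point of the closed segment inside or on the region, so a segment
wholly inside a nest buffer counts as an interaction; boundary-crossing
semantics is available via `intersection_semantics`. Segments join
consecutive fixes whose days are both prenesting (phase-spanning segments
are dropped rather than split, which would invent a fix) and take the
days-before-laying of their starting fix. Zero-length segments are
classified by point containment.

## Inference

The unit of analysis is the segment, pooled across females within a
population, mirroring the original analysis; per-bird clustering is
deliberately unmodeled in the default fit. This matters: segment flags are
autocorrelated within a bird (movement persistence within and across
days), so the naive Wald interval for the day slope is anticonservative —
in no-sampling simulations its 95% CI covers zero in only ~79% of
replicates, while with cluster-robust (by bird) standard errors and a
t(G−1) critical value coverage returns to ~93%. `LogisticFit.slope_ci`
therefore uses t(G−1) whenever the fit is cluster-robust, and the
synthetic specificity checks use the cluster-robust interval; under a
genuinely independent flat null the naive Wald test's type-I rate is
nominal (~5%), which the calibration check verifies separately.

Odds ratios come from 2×2 windowed counts, `OR = (a/b)/(c/d)` with the
Woolf log-interval `exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d))` and a 0.5
Haldane–Anscombe addition to all cells iff any cell is zero (flagged).
Windows default to days 1–5 / 6–15 / 16–45 before laying, and the odds
ratios are computed on the population-mean incubation circle (the smallest
routinely available region), both configurable. Counts are segments by
default (`contingency_unit`). The Welch statistic uses the Satterthwaite
df via `scipy.stats.ttest_ind(equal_var=False)`.

## Synthetic data

One female is a biased correlated random walk: gamma step lengths
(shape 2, scale 90 m → mean 180 m per hourly step), wrapped-Cauchy turning
(ρ = 0.4), and a linear pull (0.08 per step) toward a range centre, burned
in for 150 steps so tracks start in the walk's stationary regime. Roost
sites (3, scattered ~400 m around the centre, ≥ 150 m from the nest)
absorb the midnight fix. The nest sits at a lognormal distance from the
centre (median 700 m, shape 0.5) in a uniform direction — far enough that
under no sampling the closest-approach day is uniform over the window,
while typically inside the 95% range but outside the 50% core, matching
the published membership pattern. Laying lasts ~12 days (one at-nest visit
per day); incubation ~27 days of fixes at the nest plus GPS noise, with a
daily failure hazard of 0.08 (≈ 88% of nests fail, the published failure
rate's order). GPS error is isotropic Gaussian, σ = 10 m. Under
`habitat_sampling="sampling"` the female additionally visits the nest area
(15 m spread) with per-day probability ramping linearly from ~0.01 at day
45 to ~0.39 at day 1 (mean 0.2/day).

What the simulator does **not** emulate: habitat covariates and
landscapes, predation processes (failure is a coin flip), heavy-tailed GPS
error, renesting, and incubation recesses (incubating females emit fixes
at the nest only). Passing recovery checks therefore demonstrates that the
pipeline's logic is correct under the stated movement model, not that the
detectors are robust to every field pathology.

## Problem sizes used in validation

Synthetic checks run at the study's design scale chosen for the package's
test suite: 60–100 females for onset recovery, 100 replicates of 20 birds
for the power/specificity of the day-slope test, 500 replicates of 2,000
independent segments for Wald calibration, and 1,000 random
segment-region instances for the geometric oracle.

## Known limitations

* Pooled logistic inference without random effects is kept deliberately
  (it mirrors the original analysis) and its anticonservatism is
  documented above rather than corrected by default.
* dBBMM window estimates use averaged sliding windows, not BIC-selected
  changepoints; variance transitions are smoothed over the margin width.
* Isopleth areas inherit marching-squares discretisation error (~1 cell
  along the boundary); the Gaussian closed-form check bounds this at 3%
  for cells ≤ σ/10.
* The laying detector assumes the visit signature is observable; sparse
  schedules or nest-adjacent roosts degrade it to the incubation onset
  (flagged in logs).
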