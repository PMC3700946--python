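# Methods

This note documents the models, the numerical choices, and what the
synthetic data can and cannot establish.

## Geodesy and areas

Distances are great circles on a sphere of radius 6371.0088 km; the
published distances carry 0.1 km precision, far above the <0.5% error of
the spherical approximation, and whether the original GIS distances were
geodesic or planar is unrecorded, so a sphere is used throughout. Areas and
planar constructions (KDE grids, hulls, occupancy cells) live in a local
Lambert azimuthal equal-area frame centred on the point set's centroid;
areas in that frame are true spherical areas, so no projection-choice error
enters the km² quantities. Bathymetry lookups are nearest-cell, no
interpolation, at 1 arc-minute resolution by default; a point on an exact
cell boundary resolves to the north-east cell. Land is `value ≥ 0`.

## Filtering

The cleaning chain is: reject class-Z fixes; a forward-sweep speed filter
(a fix is dropped when the great-circle speed from the last *retained* fix
exceeds 5 km/h — the simplest deterministic rule consistent with a bare
speed limit, in preference to the Douglas/Freitas family); mask fixes on
land or deeper than the neritic cutoff (−200 m, closed bound: exactly
−200 m is kept). The chain is idempotent. Mean daily locations are
arithmetic means of each UTC date's fixes (the study area spans no
antimeridian; an assertion guards this). Day-granularity quantities
truncate timestamps to UTC dates. KDE eligibility is ≥ 20 mean daily
locations.

## Switching CRW state-space model

Process and observation equations are as in the README. Fixed constants
and priors:

* Per-class t error table (df, scale km): 3 → (8, 0.25); 2 → (6, 0.45);
  1 → (5, 0.90); 0 → (3, 2.5); A → (3, 3.5); B → (2.5, 5.0). These follow
  the shape of published Argos error calibrations — heavier tails and
  larger scales for the unvalidated A/B classes — and are shipped in
  `RunConfig` so they are auditable. Scales are applied per coordinate in
  degrees (km / 111.195 on both axes); at the study latitudes this ignores
  a cos-latitude factor of ~0.87 on longitude, absorbed by ψ.
* Priors: γ_b uniform on (0,1) with the identifiability constraint
  γ₁ > γ₂ enforced by relabelling; θ_b uniform on (−π, π]; α conjugate
  Beta(1,1); σ² conjugate inverse-gamma(0.001, 0.001) per axis; log ψ
  standard normal.
* Sampler: per iteration — stride-3 coloured random-walk updates of the
  latent positions (nodes three apart are conditionally independent given
  the second-order process); exact forward-filter backward-sample of the
  state chain; five sweeps of per-state (γ, θ) Metropolis updates, 10% of
  them independence draws from the prior so chains can hop between
  persistence/turn-angle modes; conjugate α and σ draws; a log-scale ψ
  step. Proposal scales adapt toward 0.3 acceptance during burn-in only
  (Robbins–Monro), so the post-burn-in kernel is fixed. Two chains from a
  common interpolation-based initialisation; convergence is monitored by
  the two-chain R-hat per parameter, and a fit with any R-hat above 1.1 is
  returned flagged and routed to the non-SSM summary path rather than
  raising.
* Defaults mirror the study: 8-h interval anchored at the first fix's hour,
  2 chains, 10,000 iterations after 7,000 burn-in, thinned by 5. The
  recovery experiments in the tests and the acceptance script use 3,000
  iterations with 2,000 burn-in — enough for the 120-day problem size — so
  a fit takes ~30 s on one CPU.
* Mode cutoffs on the posterior mean state index are 1.25/1.75, the
  convention of the model's originating literature (the study states
  none); both are in `RunConfig`.

The inter-nesting period runs from the tagging date to the date of the
last inter-nesting-classified step, inclusive, regardless of interleaved
migration steps; a turtle that never leaves migration mode has none.

## Home ranges

KDE uses a Gaussian product kernel. The LSCV score is minimised over 50
log-spaced candidates in [0.05σ, 2σ]; when the axis standard deviations
differ by more than 10% the coordinates are rescaled to unit variance, one
h is selected, and it is back-scaled per axis. The density is evaluated on
a grid padded 3h beyond the point extent at resolution ≤ h/3 (coarsened
only past 512 cells per axis), exploiting kernel separability (one matrix
product). Contours are marching-squares isolines at the smallest density
threshold whose superlevel set holds the requested probability mass;
nested rings become holes by even-odd depth. In-water areas subtract the
union of land cells (shapely difference in the equal-area frame). MCP is
the convex hull of all points; fewer than three non-collinear points
degenerate to zero area with the centroid at the point mean, flagged. The
centroid of a multi-centre 50% contour is that of the largest-area
polygon; exact ties break to the westernmost centroid.

## Site-fidelity test

The dispersal statistic is the mean squared displacement from the first
point, computed in the local equal-area km frame. Projecting into that
frame is what puts the unequal latitude/longitude spreads on a common
scale; calibration experiments showed that additionally self-standardising
each axis to unit variance makes the test anticonservative (null
random-walk tracks "pass" ~14% of the time instead of the nominal ~5%) and
removes its power against ballistic tracks, so no further scaling is
applied. Null replicates keep the observed step-length sequence — the
minimal randomisation consistent with a random-walk null — draw headings
uniformly, start at the observed start, and redraw any step leaving the
0 to −200 m water domain (100 attempts, then the heading is reversed). A
track shows fidelity when its MSD is below at least 95 of 100 null MSDs;
the reported `prop_null_exceeding` is the fraction of nulls more dispersed.

Nest-site fidelity on the beach is the 5 km rule on successive emergence
distances, boundary inclusive. Pooled emergence-distance summaries weight
per-turtle means by their distance counts. Summary statistics use the
sample SD (n−1) and half-up rounding to the printed precision.

## Occupancy grid, GLM, threats

Grid cells are 10 × 10 km, axis-aligned in the equal-area frame, kept only
where the centre depth is strictly inside (−200, 0) m. A turtle-day is a
distinct (turtle, date, cell) triple — a turtle visiting two cells on one
day contributes one day to each. The turtle-days model is a Poisson
log-link GLM (IRLS, tolerance 1e-8, ≤ 100 iterations) — the study names
only "GLM with log-transformation" and reports a chi-square, and Poisson/
log is the canonical count choice — with Wald chi-squares per covariate at
α = 0.05, and distance measured from the cell centre to the mean tagging
location. Platform counts use a 10 km haversine buffer, boundary
inclusive, after removing platforms with a removal date. Trawl scoring
reports the effort-days of the zone containing a centroid and the
published band label (4; 5–1500; 1501–3000; 3001–7000 days, closed
intervals). The packaged trawl zones are synthetic polygons with assigned
efforts: the real effort data were never public.

## Synthetic data

The generator is the model's generative twin: states from the two-state
Markov chain, positions from the switching CRW, fixes at Poisson-scheduled
irregular times linearly interpolated between bracketing states with
per-class t noise from the same error table, plus configurable class-Z
junk and beach-side outliers for filter testing. Defaults: γ = (0.8, 0.2),
θ = (0°, 180°), α = (0.95, 0.10), σ = 0.05° per 8-h step (≈ 28 km/day of
directed migration), 120-day deployments, 6 fixes/day with a class mixture
weighted toward A/B (0.05/0.08/0.12/0.15/0.25/0.35 for 3/2/1/0/A/B). The
environment is a straight east-west coast with a linear shelf reaching
−200 m at 110 km offshore — the simplest geometry exposing every
land/depth behaviour; no attempt is made to mimic a real shoreline.
Emergences occur at ~14-day re-nesting intervals during inter-nesting
phases, capped by a per-season clutch count drawn uniformly from 1–5; the
faithful scenario keeps nests within 5 km of one beach, the swap scenario
alternates between beaches 250 km apart.

Two deliberate departures from the pure process: (i) the track is kept at
sea by redrawing process noise that would beach it, which slightly distorts
dynamics near the coast — parameter-recovery experiments therefore place
the coast out of reach so the fitted model is the exact twin, and the
recovery experiment's track is itself fixed (one 120-day simulation) with
only the sampler reseeded; (ii) an optional attraction term pulls the
quiescent state toward a fixed centre (`attraction`, default 0), because
the pure quiescent CRW is diffusive and cannot represent a turtle holding a
stationary inter-nesting site — the scenario the end-to-end fidelity/KDE
checks need. With attraction enabled the fitted model is deliberately
misspecified, as it would be for real data.

What passing tests show — and don't: recovery and calibration hold under
the model's own assumptions (t-distributed errors of known per-class scale,
Markov switching, linear interpolation between 8-h states). Real Argos
tracks add serial error correlation, location-class misassignment, haul-out
and surfacing schedules, and tides/currents, none of which are emulated;
results on real data depend on those assumptions approximately holding.

## Known limitations

* γ₂ and θ₂ are weakly identified when inter-nesting dwells are short;
  chains flagged by R-hat > 1.1 should be treated as the study treated its
  "SSM not possible" animals.
* The LSCV criterion can undersmooth clustered data (a known property);
  bandwidths are reported in km with the rescaling flag so this is
  auditable.
* Scale-mixture (per-fix latent variance) sampling of the t observation
  model would mix faster than the coloured Metropolis used here; the
  current sampler is adequate at the problem sizes used (≤ 360 steps).
* Day-count conventions (periods inclusive of both end dates; per-day
  rates divide by the period length in whole days) follow the printed
  tables and can differ by one day from calendar intuition.
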