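# Methods

## Scope and data model

The package analyses ARGOS-style satellite telemetry of individually
tracked migratory shorebirds: one row per Doppler fix (animal, UTC
timestamp, latitude, longitude, location class), grouped into per-animal
tracks with transmitter duty-cycle metadata. All geometry is spherical:
great-circle (haversine) distances on the IUGG mean radius 6371.0088 km,
coordinates in unprojected WGS84 decimal degrees with longitudes normalized
to (−180, 180]. Tests compare the haversine against an independent WGS84
Vincenty solver; the spherical approximation is within 0.6% for any pair of
points, far below every threshold that consumes a distance.

Only location classes 1–3 (error < 1 km) inform any analysis step; classes
0/A/B/Z are dropped at ingest and never used downstream. A speed-spike
filter (drop a fix implying an implausible speed to both neighbours)
exists but is off by default.

## Season segmentation

Territories (breeding, winter) are summarized by a **territory model**:
centroid = arithmetic mean latitude and circularly unwrapped mean
longitude of residency fixes, plus the mean and SD of great-circle
displacements of those fixes from the centroid. The model is fitted on the
first 14 days of residency (configurable) so departure movement cannot
contaminate it.

**Departure** is the first fix whose displacement exceeds mean + 2 SD,
confirmed before it is accepted: either the fix is already a net
displacement above 100 km, or the first fix at least 2 h later exceeds the
threshold by a further 5 km. The confirmation margin matters: with
realistic positional error and within-territory wander, two *consecutive*
threshold exceedances occur by chance over a months-long residency, whereas
a genuine migrant flying near 53 km/h is far beyond threshold + 5 km within
2 h. **Arrival** is the mirror image: the first fix settling inside the
destination model's threshold (floored at 30 km so a tight model still
captures an error-perturbed arrival fix), confirmed by the following fix.

**Event-time interpolation.** When a transition happens during a
transmitter off-period, the observed event fix lags (departure) or leads
(arrival) the true instant. Following the flight-speed rule, the apparent
speed across the gap between the event fix and its neighbour (last
territory fix for departures, last in-flight fix for arrivals) is compared
with the mean flight speed 14.7 m/s minus two SDs. The printed ±0.3 m/s
with n = 45 is a standard error, so the individual-level SD is
0.3·√45 ≈ 2.01 m/s and the threshold 10.68 m/s. Below threshold, part of
the gap was spent stationary and the event time is set from the
great-circle distance flown at the mean speed (clamped into the gap);
otherwise the observed fix time stands. On noise-free, always-on synthetic
tracks detected events land within one sampling interval of truth; with a
48 h off / 10 h on duty cycle the median absolute event-time error is a few
hours (criterion: < 24 h).

The four seasons partition each tracked year: autumn migration = [breeding
departure, winter arrival), winter, spring migration, breeding (closed by
the next year's departure where tracked). Initiation date = UTC calendar
date of the event time.

**Stationary periods** along migration are maximal runs of fixes whose
segment displacement stays under 5 km/h · Δt plus a 3 km error allowance
(so near-simultaneous fixes scattered by measurement error do not split a
residency) and which stay within 25 km of the running centroid, lasting at
least 6 h. These defaults sit well below sustained flight speed and above
the scale of roost–forage commutes; all are configurable.

## Path interpolation (CTCRW)

Duty-cycle gaps are filled with the continuous-time correlated random
walk: per planar axis the velocity is an Ornstein–Uhlenbeck process
(dv = −β v dt + σ dW) and position integrates it. β (1/h) sets how fast
velocity decorrelates (exp(−β·lag)); σ (km·h^−3/2) sets stochasticity; the
stationary speed scale is σ/√(2β). Exact discrete transitions at irregular
intervals make the Kalman filter the exact likelihood, verified in tests
against a brute-force joint-Gaussian density to 1e−6 relative on small
instances. Observation error is fixed per location class (LC3 100 m,
LC2 250 m, LC1 700 m), not estimated, which matches the ARGOS class
definitions and keeps the likelihood well conditioned.

Each flight segment (between consecutive stationary periods, anchored by
the adjacent stationary-edge fixes) is projected with an
azimuthal-equidistant projection centred on its midpoint fix, fitted by
L-BFGS-B on log(β), log(σ) from a fixed documented start (β = 1/h,
σ = 10), smoothed with the Rauch–Tung–Striebel pass onto a 15-minute grid,
and inverse-projected before geodesic measurement. Standard errors come
from the numerical Hessian at the optimum; over 20 seeded 500-fix
replicates the median relative parameter error is under 15% and the 2-SE
intervals cover at their nominal rate. Segments with fewer than 8 usable
fixes fall back to the piecewise great-circle polyline of their fixes;
degenerate fits (parameter at its bound) are flagged and fall back the
same way.

**Migration distance** is the summed length of the interpolated flight
segments — local movements within staging/stopover visits are excluded,
per the pathway definition. Duration runs departure event to arrival
event *including* stops; speed is the ratio in km/d. A known limitation:
when a fast direct flight yields almost no usable in-flight fixes (sparse
duty cycle × class subsampling), the measured segment collapses toward the
chord between its anchors and under-measures any route curvature. This is
an information limit of duty-cycled telemetry, not of the estimator; it is
visible in the synthetic Hudson-Bay spring leg.

## Sites, classification, fidelity

Stationary periods within migration seasons are clustered into sites by
single-linkage agglomeration over great-circle distance, cut at 250 km —
regional scale, since named staging areas span whole coastlines. Input
order cannot affect the result (visits are canonically sorted first).

Classification follows the staging/stopover distinction used in the
shorebird literature: **staging** requires median stay ≥ 7 d, an onward
leg > 1,000 km to the next *major* destination (the next long-stay site or
the terminal territory — short en-route stops never count as a
destination), and population-level use (≥ 2 years of reuse or ≥ 20% of
the tracked population); otherwise a site with median stay ≤ 7 d is a
**stopover**; anything else is unclassified. The resource-density part of
the field definition is unobservable from telemetry and intentionally not
a criterion. The 7-day floor is the largest value that still admits the
shortest published staging mean (7.6 d). Each stopover is associated with
the staging site most recently departed by its visitors (majority vote,
ties to the earliest site); stopovers with no upstream staging are flagged
as origin-associated.

**Fidelity** counts, over all (animal, staging site, year, season) events
where the animal was also tracked through that season the following year,
the fraction in which the site was reused. A tracked-but-absent year is an
overflight and counts against fidelity; by default coverage is inferred
from observed staging visits, so overflights are only chargeable when
coverage is supplied explicitly. With no multi-year animals the quantity
is reported as undefined rather than zero.

## Statistics

Group summaries are mean ± SE with sample sizes n (x) = individuals
(total seasons); repeated seasons of one animal are treated as independent
samples, matching the source convention (a per-animal averaging mode
exists for sensitivity analysis). Comparisons are two-tailed t-tests,
pooled-variance Student's t by default — the printed df subscripts
(e.g. t₅₃ for 25 + 30 seasons) identify the pooled form — with Welch
available. From summaries, SDs are back-computed as SE·√n. Bonferroni
correction uses the number of tests in the same output table as the
family. Calendar-date statistics operate on day-of-year with circular
unwrapping within a 180-day window; wider windows are rejected as
ambiguous rather than silently averaged.

## Synthetic telemetry

The generator emulates the study conditions so every stage has a
recoverable target:

* **Schedules**: per-population presets encode the published mean
  initiation dates (day-of-year) with their printed SEs and season counts;
  between-individual SDs are SE·√n (the ± values are read as standard
  errors throughout, as the one labelled table confirms). Staging
  itineraries carry the published per-site stays (mean ± SE, n) and
  post-staging stopover rates.
* **Movement**: great-circle legs flown at a per-animal speed drawn from
  N(14.7, 2.01²) m/s; per-leg shaping waypoints calibrated so each
  season's itinerary length matches the published migration distances
  within ~1% (Mackenzie 11,348 / 11,421 km, Hudson Bay 8,996 / 8,547 km);
  unplanned stopovers as Poisson counts per leg placed on the route with
  exponential stays; within-territory wander as an AR(1) offset process
  (correlation time ~6 h, stationary SD = radius/2, reflective at the
  5 km territory radius).
* **Observation**: duty cycles 48 h off/10 h on (default) or 24/5;
  1–34 fixes per on-period with mean 5.48; location classes drawn from a
  configurable mix; circular Gaussian error with per-class scales
  (100/250/700/1500/3000/5000 m). Zero-error, always-on configurations
  reproduce the true path exactly.
* **Truth logs** record true transition instants, per-leg path lengths and
  site visits; all randomness flows from one seeded generator, so runs are
  byte-reproducible.

What the generator does *not* emulate — and hence what passing tests do
not demonstrate about field data: between-individual route variation
(routes are deterministic per population), wind and storm displacement,
landfall-then-drift behaviour on the winter coast, partial-year
deployments, transmitter failure, and the published tables' own internal
tensions. Two of those tensions forced choices: the Hudson-Bay stopover
durations (9.5/12.4 d) plus staging stays cannot fit inside that
population's autumn span, so stopover stay means are capped near 1.5 d
while stays and counts keep their published values; and the spring
itinerary stays are too short to fill the published spring span, so the
simulated breeding arrival runs ~2 weeks earlier than the printed mean.
Season spans and migration durations are emergent, not imposed.

## Numerical conventions

Problem sizes used by the shipped drivers and checks — cohorts of 6–10
animals per population for event-recovery and distance checks, 30 per
population for the between-population departure contrast, 20 replicates of
500 fixes for CTCRW recovery, 15-minute prediction grids — keep full runs
in the minutes range on a single core while leaving sampling error well
inside the tolerances being checked. Ties in duplicate timestamps resolve
to the best location class then first occurrence; cluster numbering is by
centroid latitude; optimizer bounds are log β ∈ [ln 1e−3, ln 50],
log σ ∈ [ln 1e−3, ln 500], and a fit ending on a bound is flagged
degenerate rather than trusted.
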