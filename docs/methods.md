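# Methods

This note documents the conventions, models and numerical choices behind
`reeftrack`, in the order data flows through the pipeline.

## Data model and time

Detections are stored tz-aware UTC at second precision. All day-level
statistics use *local* calendar days, obtained by adding a configurable
offset (default +10 h: Queensland, which observes no daylight saving)
before truncating to the date. The choice of day boundary is a convention,
not a fact of the data; it is exposed as `utc_offset_hours` everywhere a
day is formed.

Receiver deployments are date-granular intervals; a detection joins the
deployment whose `[active_from, active_to]` contains its UTC date.
Detections at unknown receivers, outside any active interval, or from
unknown transmitters are routed to a rejects table with a reason column —
they are data (often other projects' animals), not errors. Reads enforce:
≤ 1 % unparseable timestamps (configurable), exact-duplicate collapse
(keep first; duplicates are the signature of overlapping receiver
downloads), depth within the transmitter's 68 m pressure rating (values
outside are sensor glitches and are blanked), no overlapping deployments
per receiver, one environment record per station-day.

## Presence and residency

An animal is present in an array on a day iff some pair of detections on
that day, pooled across all that array's receivers, lies within a rolling
3600 s window. The window is evaluated within the day only: a pair
spanning local midnight confers presence on neither day, since the rule
anchors the pair to one calendar day. Pooling at array level (not per
receiver) reflects that presence is defined for the array as a whole. For
sparse satellite arrays, where a pair within an hour is unlikely even when
the animal is genuinely there, a 1-detection threshold is used
(`min_detections=1`); this is the default for non-home arrays in the
pipeline and is configurable.

Days monitored run from the tagging date through the study's last day,
both endpoints inclusive (`DM = (end − tagging).days + 1`); the packaged
reference table's `STUDY_LAST_DAY` is 2014-10-14, and this convention
reproduces every printed DM value exactly. `RI = DD/DM ∈ [0, 1]`.
Maximum consecutive days is the longest run of strictly consecutive
presence dates (0 for no presence).

Residency groups use fixed cutpoints {0.09, 0.20, 0.50}: I above 0.50, II
in [0.20, 0.50], III in [0.09, 0.20), IV below 0.09. The band (0.40,
0.50], which published group ranges leave unspecified, is assigned to II —
group I strictly requires RI > 0.50. A generic single-linkage 1-D
clustering (scipy linkage + maxclust cut, clusters relabelled by
descending mean RI) is provided for dendrogram-style grouping. The two
approaches agree when the RI distribution has its widest gaps at the
cutpoints; on real data with a stretched-out middle band they can differ
— single linkage cuts at the largest gaps wherever they fall — which is
why the banded rule, not the clustering, defines the reported groups.

Animals detected on fewer than 2 days in the home array (default
`min_detection_days=2`) are excluded from population residency statistics
as tagging-day transients but retained for migration analysis. Population
summaries report mean, SD (n−1 denominator; NaN for a single animal),
min, max, overall and by sex; report-table rounding is half-up at the
printed precision, computed on the decimal representation so that entered
ties round as they read.

Monthly residency rows prorate days at liberty in the tagging and final
months, giving the binomial (detected, at-liberty) response for
mixed-model fitting outside the package.

## Space use

Hourly centres of activity are detection-count-weighted means of receiver
positions over clock-aligned local hours, computed in projected
coordinates and inverted back to geographic ones — so every COA lies in
the convex hull of its contributing receivers. The projection is WGS84 /
UTM zone 55 south, implemented as the Krüger series in the third
flattening truncated at n⁴ (round-trip error < 1 µm in-zone, verified in
tests against an independently integrated meridian arc). `pyproj` is not
required. Dispersal between consecutive COAs is planar on the UTM grid by
default; a haversine great-circle alternative (`geodesic=True`) is
available for multi-hundred-km spans where projection distortion
accumulates.

Roaming counts a reef as visited on *any* detection — the day-level
two-detection rule does not apply, otherwise low-residency animals'
printed reefs-visited counts would be unreachable.

Movement matrices derive from each animal's time-ordered site sequence;
each change of site is a directed transition. The default counts distinct
individuals per ordered pair over the whole period (the connectivity-plot
convention); `mode="moves"` counts raw transitions and feeds the
inner/outer shelf frequency table, whose percentages sum to 100 over all
counted moves. Self-transitions are excluded unless requested, and the
choice is recorded in the matrix metadata.

Acoustic coverage is `min(1, Σ πr²/area)` with no overlap correction —
an upper bound, capped at 100 %.

## Broad-scale migration

An away-episode opens at the first detection in a non-home array after a
home detection (or after tagging, for animals never detected at home) and
closes at the next home detection (`returned = True`). The episode records
the first away array as destination plus the full itinerary. Travel times
are computed per transition leg — last detection at the previous array to
first at the next — and summaries *from home* only include legs departing
the home array: an arrival staged through intermediate arrays has no
meaningful home travel time and raises `NoEventsError` rather than a
misleading number. This minimum-travel-time definition is the only one
consistent with detections alone; the animal may have left later or
arrived earlier than it was heard.

Population classification: an animal moved if it has ≥ 1 episode, stayed
otherwise, returned if every episode it opened also closed. Proportions
over moved/stayed sum to 1; returned is a subset of moved.

## Synthetic data

The generator's defaults are the reference study design: 17 focal reefs
in two shelf rows (inner/outer) spaced 5–15 km apart, 4 receivers per
reef ≈ 600 m apart, nine satellite arrays at 78–1,400 km along the coast,
receivers with a 250 m nominal detection radius, 33 animals (25:8 F:M,
fork length ~ N(201.8, 25.2) cm) tagged over the first 480 days of a
734-day window starting 2012-10-08, transmitters pinging at uniform
50–100 s intervals with a 68 m depth rating.

Movement is a daily-resolution Markov process — the simplest model that
exercises every day-level metric. Each animal draws a target focal-array
occupancy π from Beta(0.8, 3.4) (mean 0.19, heavy right skew: strong
individual heterogeneity, a few near-resident animals) realised by a
two-state leave/return chain with leave probability uniform in
[0.05, 0.40] and return probability π·p_leave/(1−π); within the array it
switches reefs with probability 0.3/day. With probability 0.55 (F) / 0.45
(M) an animal schedules one migration excursion departing in an austral
summer month (Dec–Feb), travelling at 40 km/day plus exponential slack to
a random satellite array, dwelling 1 + Poisson(3) days, and returning
with probability 0.94 — matching a female-heavy migrant pool in which all
but one migrant returns.

Within a day the animal sits at one receiver of its current site per hour
and is acoustically available for one contiguous block of hours (default
6 of 24); ping times advance by uniform 50–100 s draws and each ping is
logged with probability 0.8 (step detection model: in range or not). The
6 h availability block keeps detection volumes tractable while leaving
day-level presence detection essentially certain, which is the regime the
day-level metrics assume. What the simulator deliberately omits —
continuous-space swimming, range-dependent detection decay, wind-driven
detection loss, tide/diel behaviour — means passing recovery tests
validate the *metric pipeline*, not detection-range ecology: with real
data, detection efficiency itself becomes a confounder the package does
not model.

All randomness flows from one `numpy` Generator seeded from
`SimulationConfig.seed`; identical seeds give byte-identical CSV output.

## Problem sizes in the test suite

Unit tests run the simulator at 4–10 animals over 90–200 days; the
parameter-recovery experiment uses 30 animals over 500 days with
detection probability 0.5 and all animals tagged on day one (a clean
truth window), recovering per-animal residency to ≤ 0.05 mean absolute
error and ≥ 95 % of scheduled excursions with ≥ 2 away days. The whole
suite completes in well under a minute.

## Known limitations

- Presence, residency and occupancy are conditional on detection: the
  package reports apparent residency, and no detection-efficiency
  correction is applied.
- The away-array 1-detection threshold trades false positives for
  sensitivity on sparse arrays; flip `min_detections_away` to 2 to
  tighten it.
- Coverage ignores receiver-circle overlap and reef geometry.
- Planar UTM distances inflate slightly for inter-array spans far from
  the central meridian; use the geodesic flag for those.
- Travel times are minimum estimates bounded by detection gaps, not
  measured transit durations.
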