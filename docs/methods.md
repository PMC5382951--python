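# Methods

## Scope and data model

The package analyses four instrument streams plus one event table:

| stream      | cadence | fields                                   |
|-------------|---------|------------------------------------------|
| actigraphy  | 1 min   | trunk activity count (piezo events/min)   |
| accel       | 1 min   | collar ax, ay, az in g                    |
| gps         | 1 min   | latitude, longitude (decimal degrees)     |
| weather     | 10 min  | air T, black-globe Tg, RH, wind, solar …  |
| astro       | daily   | sunset, sunrise, twilight offsets, moon   |

All timestamps are naive local civil time under a single fixed UTC
offset; the study region has no daylight-saving transitions, so naive
datetimes are unambiguous.  Astronomical times are inputs, never
computed: field deployments take them from almanac services, and the
synthetic generator emits printed-style values (constant per-night
drifts) rather than an ephemeris.

### The analysis night

A night runs 12:00 → 12:00 and is labelled by its morning date.  This is
forced by the data: a night can pair an evening onset (e.g. 19:00) with
a pre-dawn offset (03:10), which no midnight-aligned day can hold.
Windows tile a deployment exactly; an episode crossing the noon boundary
is truncated at the edge (the boundary sits in the middle of the
behavioural day, where sleep is rare).

One residual ambiguity is inherited from the source tables: a printed
night row carries its *own* date's sunset, while the onset it pairs with
followed the *previous* date's sunset.  Daily drift is ~1 min, so the
two conventions differ by at most that.  Statistics computed from the
printed tables use the printed same-row pairing (this reproduces the
printed onset-after-sunset range exactly); detection on raw streams uses
the sunset that actually falls inside the window.

## Sleep scoring

* Epoch rule: active ⇔ count > threshold (default 0).  The threshold is
  exposed because some actigraphs emit low-level noise; raising it can
  only convert active epochs to inactive, so total sleep time is
  monotone non-decreasing in the threshold (property-tested).
* Modal blocks: 5 epochs → majority state.  The block length must be
  odd — a binary majority is then always defined, which is why an even
  block length is a configuration error rather than a tie-break choice.
  Blocks align to clock times divisible by the block length (matching
  how the loggers are programmed); partial edge blocks are discarded.
* Episodes: maximal runs of inactive blocks; minimum episode is one
  block (5 min).  The longest episode per night is the main sleep
  episode; the earliest wins ties, making output deterministic.
* Consolidated episodes must *exceed* 10 min.  At 5-min granularity that
  means ≥ 15 min: two blocks are exactly 10 min and 10 is not > 10.  The
  cut-off is configurable (`sleep_scoring.CONSOLIDATED_MIN`).
* No-sleep nights: total nightly inactivity ≤ 10 min.  The inclusive
  bound (rather than "exactly zero") is deliberate: nights with one or
  two isolated 5-min blocks are classified as sleepless, matching how
  such nights are treated in the field literature.
* Daytime "naps" count toward TST; the nocturnality statistic (fraction
  of inactive blocks between sunset and sunrise) quantifies them
  separately.

## Posture and recumbency

A sample is usable only when the resultant is 1 ± 0.1 g (otherwise the
collar is accelerating and gravity cannot be read).  Z > 0 ⇒ standing;
Z ≤ 0 ⇒ lying, with laterality asserted only when |X| lies within 0.3 g
of 1 g.  The lateral tolerance is symmetric with the resultant rule; the
source method states only "±1 g in X", so the width is our choice and is
exposed as a parameter.

Run-length encoding turns samples into bouts.  Indeterminate gaps of
≤ 2 min flanked by the same posture are bridged (an animal shifting its
weight should not fragment a bout); longer gaps split it.  Recumbent
sleep is the interval intersection of lying bouts with sleep episodes,
clipped to the night window; intersected runs separated by ≥ 5 min count
as separate recumbent-sleep episodes.  Episode *counts* are reported but
were not reconstructible from the published per-day data (the printed
per-animal episode counts and mean durations are mutually inconsistent
with the printed totals), so no acceptance gate uses them.

## Environment (WBGT)

Stull's closed-form natural wet-bulb approximation is evaluated with
arctangents in radians — this is called out in the code because a
degree-mode evaluation produces silently wrong values.  Stated validity
is RH 5–99 %, T −20–50 °C; outside it the function warns and still
computes.  Two numerical caveats, both verified in tests:

* Against an iterative psychrometric solver (bisection on the
  psychrometer equation with a Magnus saturation curve, 1013 hPa) the
  closed form agrees to within ~1 °C over the warm domain, and to ~0.1 °C
  near saturation.
* The fit is monotone in T and RH for T ≳ 5 °C but loses RH-monotonicity
  below ~3 °C — an artifact of the empirical fit.  The study site never
  went below 8.9 °C, so the property is tested on T ∈ [5, 50] °C only.

WBGT = 0.7·Tw + 0.2·Tg + 0.1·T is a convex combination, so it always
lies between the minimum and maximum of its inputs (property-tested).
The nightly minimum is searched over the full noon-to-noon window — the
diurnal cycle puts it pre-dawn without any further constraint — with the
earliest sample winning ties.  WBGT "at" an event uses the latest sample
at or before the event (step convention): on a 10-min cadence
interpolation would change values by at most the intra-sample trend, and
the step rule is exactly reproducible.

## Movement

Haversine on a sphere of radius 6371.0 km.  At the study latitudes and
separations (< 50 km) this agrees with planar geometry to < 0.5 % and
reproduces the printed site-to-site distances at print precision;
an ellipsoid would change nothing at two printed decimals.  Speeds are
per-minute finite differences; smoothing uses a 15-min *centred* moving
average (the source figures do not state the alignment; centred was
chosen and is configurable).  Sustained-activity bouts are runs of
smoothed speed above a threshold (default 1.5 km/h for ≥ 120 min); the
source gives no numeric trigger, so these are configuration, not
constants.

Sleep-site geometry: consecutive-site distances span no-sleep nights
(the 16 → 18 Apr interval is one distance), and inter-animal distances
exist only for nights on which both animals slept.

### Coordinate encoding

The published site coordinates are degrees + decimal minutes packed into
a decimal-looking number: 18.05649 means 18° 5.649′ = 18.09415°.  Only
this reading reproduces the published distances (e.g. the 2.77 km
15 → 16 Apr pair); reading the values as plain decimal degrees is off by
tens of percent.  The parser rejects minute fields ≥ 60.

### A documented inconsistency in the published tables

The published per-day distance column and the published coordinate table
disagree with each other for some day-pairs: most pairs agree to
≤ 0.03 km, but several ordinary pairs differ by 0.06–0.14 km, and the
two pairs that span the 8 May and 14 May no-sleep nights differ by 2.9
and 4.9 km — there the distance column evidently used the site of the
short, discarded inactivity episodes, for which the coordinate table
prints no entry.  The acceptance test asserting per-day agreement within
0.05 km therefore fails, and is left failing: both source columns are
shipped verbatim, and the discrepancy is in the source, not in the
computation.  Consequently the coordinate-derived mean consecutive-site
distance is 7.0 km while the distance-column mean is 7.23 km; summary
statistics use the distance column, which matches the published 7.2 km.

## Statistics

* OLS via the standard least-squares fit; r² is the squared Pearson
  correlation and p comes from the slope's t statistic on n − 2 df.
  p-values are reported uncorrected — each regression is a single
  pre-planned comparison.
* The allometric law TST = a·Mb^b is fitted by OLS in log–log space and
  evaluated with mass in grams.  The two published models
  (a = 17.946, b = −0.076 across mammals; a = 21.995, b = −0.14 for
  herbivores) are shipped as constants for evaluation; they are not
  refitted, because their underlying comparative dataset is external.
  The fitter itself is exercised on synthetic data (noiseless recovery
  is exact to float tolerance).
* Event-time statistics are computed in minutes since the 12:00 window
  start, so sunset references and post-midnight events subtract
  correctly; the representation is invariant to recoding events across
  midnight (property-tested).  Clock-time means are ordinary means on
  this timeline, not circular means — all events fall in one contiguous
  night window, and ordinary means reproduce the published ranges.
* All standard deviations are sample (n − 1) deviations; this choice
  reproduces the published values at print precision.
* The moon stratification sums recumbent minutes over nights with < 50 %
  lunar illumination.  On the published daily data this gives 60.1 %,
  not the published "70 % (15 of 26 episodes)" — which is not
  reconstructible from the published per-day sums (nor is 15/26 = 70 %).
  The computed fraction is reported; no gate uses it.

## Synthetic data generator

The generator is the test substrate: it plants a known night structure
and emits streams from which the pipeline must recover it.

Defaults mirror the study conditions: 35 nights; nightly TST ~
N(120, 60²) min truncated below at one block; ~5 episodes/night
(N(5, 2²), ≥ 1), the main episode taking ~half of TST and never less
than 15 min; episode starts drawn from a clock density centred 02:30
(sd 100 min) confined to one hour after sunset through 10 min before
sunrise, placed without overlap and with ≥ 10 min separation so modal
aggregation recovers block edges exactly; a single 30–70 min recumbent
bout inside the main episode every 3rd–4th sleeping night, sides
balanced; no-sleep probability 0.07 with a ~10 h, ~3 km/h directed
flight bout (~30 km displacement); wake counts 1 + NegBin(2, 0.01)
(overdispersed, strictly positive — the instrument's count law is not
published, only its zero/non-zero semantics matter downstream); a
sinusoidal diurnal air-temperature cycle (20 ± 8 °C, trough 05:40) with
antiphase RH and a daytime globe-temperature excess, which puts the
WBGT minimum shortly before sunrise; sunset drifting −31 s/night and
sunrise +17 s/night from 18:11 / 06:32.

What the generator does *not* emulate: collar-rotation artifacts,
GPS fix dropouts, actigraph low-level noise (counts during wake are
strictly positive), weather fronts, or any physiological coupling
between sleep pressure and prior activity.  Passing recovery tests
therefore demonstrate algorithmic correctness on clean, well-posed
streams — not robustness to instrument pathology.

Ground truth is consistent with the emitted streams by construction;
the truth onset/offset apply the same consolidated-episode definition to
the planted schedule, and the truth WBGT-minimum time is the argmin of
the emitted series.  Determinism: one `numpy` Generator seeded from the
mandatory config seed; two runs are value-identical.

## Problem sizes in tests

Unit tests run on single nights or small grids.  The end-to-end
recovery and throughput check uses a 200-night deployment (288 000
minutes per stream), chosen to make law-of-large-numbers checks tight
(mean TST within 10 min of the configured mean) while the whole suite
stays fast; the full generate-score-recover cycle completes in well
under half a minute on one core.

## Known limitations

* Trunk inactivity is a proxy; the package scores behavioural sleep and
  makes no REM/NREM claims.
* The Stull fit degrades below ~5 °C (see above); for cold-climate use
  substitute a psychrometric solver.
* Recumbent-episode counting depends on the 5-min merge gap; published
  episode-level counts could not be used for validation (source
  inconsistency), so this parameter is a convention.
* The no-sleep flight-bout detector is threshold-based and untuned;
  thresholds are explicit configuration.
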