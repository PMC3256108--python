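# Methods

`timeact` classifies interval-logged GPS fixes into four time-activity
categories (indoor, outdoor static, outdoor walking, in-vehicle travel)
with a deterministic rule cascade and a shallow random forest. This note
records the models, the parameters that matter, the numerical choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate.

## Data model and preprocessing

A track is a time-ordered sequence of fixes `(t, x, y, v)` for one subject:
epoch-second timestamps, planar coordinates in metres, and speed in km/h.
Geodetic input is projected to UTM (NAD83 / GRS80; zone 11N default for the
Southern California study region) by an in-package Krüger-series transverse
Mercator with sub-millimetre round-trip error; synthetic fixtures are
generated directly in planar metres and bypass projection, which keeps
projection variance out of algorithm tests.

Cleaning drops fixes without a timestamp (they cannot be ordered), keeps
the first of duplicate timestamps, and corrects speeds above a 200 km/h
plausibility ceiling to zero while retaining the fix in place — such
readings are device glitches that teleport the reported position, and the
position is deliberately *not* edited because no relocation rule can be
validated without reference data. Cleaning is idempotent. A subject whose
inter-fix gaps are in the majority (> 50%) at 1 s is flagged for exclusion:
that device was not logging at the nominal 15 s interval and duration-based
rules would be distorted. Recording dropouts longer than 30 min
(configurable) act as track boundaries so signal loss cannot fabricate
movement. If device speed is absent, speed is derived from consecutive
displacement over elapsed time and flagged as derived.

## Rule-based classifier

All thresholds live in `RuleConfig` and are overridable; defaults, with
units:

| parameter | default | role |
|---|---|---|
| `static_speed_max` | 3 km/h | cluster membership (strict `<`) |
| `static_min_duration` | 60 s | minimum stop time span |
| `line_tolerance` | 1 m | collinearity detour bound |
| `moving_speed_high` | 15 km/h | moving criterion 1 (strict `>`) |
| `bounded_gap_max_points` | 5 | criterion 2 gap length |
| `run_min_points` / `run_speed_min` | 6 / 2.5 km/h | criterion 3 |
| `road_buffer` / `cluster_center_buffer` | 10 m / 25 m | criterion 4 |
| `residual_moving_speed` | 10 km/h | criterion 5, residual split |
| `vehicle_second_highest_speed` / `vehicle_median_speed` | 10 / 5 km/h | mode split |
| `outdoor_max_duration` | 2 h | cascade R1 |
| `home_indoor_radius` / `apartment_radius` | 10 m / 50 m | R2 / R3 |
| `short_cluster_duration` | 5 min | R3 |
| `indoor_second_lowest_speed` | 0.1 km/h | R4 |
| `scatter_factor` | 2 | R5 |
| `home_min_duration` | 24 h | home detection |
| `tz_offset_s` | 0 | local midnight for the home rule |

Inequalities are strict on the side the rule wording implies ("above",
"lower than"): boundary values do not qualify. A cluster's time span is
measured as last-minus-first timestamp, not a point count, so interval
jitter does not change which stops qualify.

Design choices that were genuinely open:

* **Line refinement mechanics.** Scans run forward from the first member
  and backward from the last; each triple of consecutive remaining members
  with detour ≤ 1 m is excluded wholesale and the scan continues with the
  next three points (excluded points are not reused); each scan stops at
  its first non-line triple. A perfectly stationary repeated coordinate has
  detour 0 for every triple, so both scans consume it; if the survivors
  span under one minute the cluster dissolves and its members return to the
  untagged pool. This edge case is exercised by a dedicated test.
* **Cascade order.** The indoor/outdoor evidence rules are ordered from
  strongest to weakest: duration (R1), home proximity (R2/R3), member
  speed (R4), scatter (R5), default outdoor (R6). Each terminal label
  carries the name of the rule that fired, so alternative orderings can be
  audited from the output alone.
* **Scatter rule (R5).** The geographic range (maximum pairwise member
  distance, convex-hull accelerated) is compared to `scatter_factor` times
  the cluster's own median member distance from its centroid. The
  threshold is a reconstruction — no quantitative bound is established for
  this criterion — and is deliberately config-visible. Note that for a
  compact jitter cloud the diameter generically exceeds twice the median
  radius, so R5 classifies most clusters that reach it as indoor; in
  practice R1–R3 decide the common cases first and R5 mirrors the known
  weakness of scatter-based indoor/outdoor separation.
* **Consolidation** is a single left-to-right pass (not iterated to a
  fixpoint); a gap is only absorbed if it contains no cluster members and
  no track boundary. Moving runs that end with fewer than 2 points are
  residual, not periods.
* **Residuals.** Points left untagged (dissolved clusters, unmerged
  1-point runs) become outdoor static when slower than 10 km/h, otherwise
  they inherit the label of the temporally nearest labeled fix.
* **Home.** Home is the member-weighted centroid of all clusters whose
  local-time span contains midnight or exceeds 24 h; an explicit hint
  overrides detection; with neither, the home-distance rules R2/R3 are
  skipped (logged).

The module contains no randomness: identical input and config give
identical labels.

## Windowed features and the forest

Features are computed per fix over time windows of ±w/2 centered on its
timestamp (window grid 2–60 min). Speed and detour get min/median/max
(detour also SD, n−1 denominator); each window gets a distance ratio (net
displacement over path length, 1 for straight motion and for a zero-length
path); acceleration is the speed change from the previous fix. Detour
values are stamped at the middle fix of their triple. Edge windows use the
available fixes and are flagged truncated rather than dropped — every fix
must be classifiable. The default feature set is the five predictors the
selection procedure retains on realistic data (max speed 4/60 min, median
speed 30 min, max detour 6/30 min).

The forest is scikit-learn's `RandomForestClassifier` behind the package's
own protocol: indoor subsampling (cap 30,000 by default, 5,000 for small
datasets; all points of rarer classes kept; deterministic under seed),
two-stage selection, and deterministic prediction (probability ties broken
indoor > outdoor static > walking > in-vehicle). Stage 1 ranks by mean
decrease in impurity and greedily keeps top-ranked features whose pairwise
|Pearson r| with everything kept is below 0.75, up to 20. Stage 2 refits
`n_refits = 25` times under bootstrap row-resampling with fresh seeds and
keeps features with importance z = mean/SD exceeding the one-sided normal
p < 0.001 bound; a feature with zero importance in every refit gets p = 1.
The z-score construction is one of several defensible definitions (the
importance index of legacy workbenches is not fully specified) and is
recorded in the trained-model metadata as pluggable. Depth is capped at 3
with 10 trees by default: unrestricted depth wins in-sample
cross-validation but transfers poorly across devices and populations.

## Evaluation

Confusion matrices are 4×4 with rows = manually-coded truth and columns =
model output. Per class: sensitivity = diagonal / row sum, precision =
diagonal / column sum, specificity = TN/(TN+FP) with FP the off-diagonal
column mass; zero denominators are flagged undefined rather than silently
zeroed. Transposing a matrix swaps sensitivity and precision — this
arithmetic identity is how the orientation of a printed table can be
verified, and `ConfusionMatrix` carries a `transposed_source` flag so both
printed conventions normalize to the same canonical layout (one embedded
reference panel requires it; the check is in the test suite).
Cross-validation pools fold counts and computes metrics once
(micro-average); repeats are supported but default to 1. Cross-dataset
transfer applies a trained model to a second labeled dataset without
refitting.

## Synthetic data: what it emulates and what it does not

The simulator generates labeled person-days: a 15 s recording interval
with occasional ±1 s jitter; indoor dwells as a fixed anchor plus Gaussian
jitter (5 m default) with a heavy multipath tail up to 300 m and signal
dropouts; outdoor stops with tight jitter; walks at 3–6 km/h with short
random stops; drives along an orthogonal road grid (500 m spacing over
3 km) at 30–70 km/h with configurable idling; device speed is the true
kinematic speed with ±10% multiplicative noise and rare > 200 km/h spikes.
Days start at 21:00 local the previous evening so local midnight falls
strictly inside the overnight home dwell, as it does in multi-day field
recordings. The default commuter schedule spends ~84% of time indoors,
with drives departing from dwells or short boarding pauses the way real
commutes do. A dedicated scenario inserts a 4-minute mid-route car idle:
the rule model labels it outdoor static — the documented failure mode of
time/speed/location rules, since a parked occupied car is observationally
identical to an outdoor stop.

Not emulated: physically realistic GNSS error correlation (multipath is
i.i.d. heavy-tailed here, not building-geometry-driven), urban-canyon
signal loss, real road topology, bus/train/bicycle travel, or coding error
in the reference labels. Passing recovery tests on this generator
therefore demonstrates that the algorithms implement their stated rules
and separate the intended speed/location regimes — not that any particular
accuracy will be achieved on field data, where label noise and
device-specific error dominate.

## Problem sizes and tolerances

Tests run on single simulated days (~5,800 fixes) and small constructed
fixtures; brute-force oracle comparisons use tracks of ≤ 500 points where
exhaustive recomputation is exact. Geometry comparisons use absolute
tolerances ≤ 1e-6 m except the projection check (2e-3 relative against an
ellipsoidal meridian-arc oracle, reflecting in-zone UTM scale distortion).
Published-table metric checks are exact to the printed precision (±0.05
points). Forest and cross-validation checks fix every seed.

## Known limitations

* Outdoor static precision is intrinsically poor: the scatter rule cannot
  separate a quiet outdoor stop from a wood-frame indoor dwell, and short
  stops at trip ends are frequently absorbed into moving periods. This
  mirrors the behavior of the approach on field data and is asserted, not
  hidden, by the tests.
* The rule cascade assumes a single home per subject; multi-residence
  subjects need an explicit home hint.
* Criterion 2's gap fill and the consolidation pass are single-pass;
  iterating to a fixpoint would absorb slightly more, and is left as a
  sensitivity knob for future work.
* Multi-zone UTM stitching and map-matching are out of scope; tracks are
  assumed to stay within one UTM zone.
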