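# Methods

This note documents the models, conventions and numerical choices behind
`trackanim`, in the order data flows through the package.

## Ingestion and record classification

Input CSVs are RFC 4180, UTF-8, comma-separated, first row header; no
delimiter sniffing. The four required roles (identifier, longitude,
latitude, timestamp) resolve to columns in this order: Movebank default
header names when all four are present; an explicit user mapping, which is
persisted to the YAML config store keyed by *file name + SHA-256 of
content* (so a renamed copy still resolves); a previously stored mapping.
Otherwise a mapping-required error lists the unresolved roles.

Timestamps use the letter-pattern vocabulary (`yyyy`, `MM`, `dd`, `HH`,
`mm`, `ss`), translated token-wise to `strptime` directives. Before
failing, the loader auto-tries `yyyy-MM-dd HH:mm:ss` and ISO-8601 with a
`T` separator and optional fractional seconds. Timestamps are
timezone-naive and interpreted as UTC throughout; no DST logic.

Classification is a total function over raw rows; the first matching rule
wins:

1. `visible` ∈ {`0`, `false` (any case)} → marked invisible (blank means
   visible);
2. longitude/latitude non-numeric or outside [−180, 180] / [−90, 90] →
   corrupt coordinates;
3. missing identifier or missing/unparseable timestamp → corrupt required
   field;
4. year < 1800 → ignored; 1800 ≤ year ≤ 1980 → kept but reported as its
   own category; timestamp more than 20 calendar years after the
   reference instant → ignored; within (now, now + 20 y] → kept; else
   valid.

Boundaries are inclusive on the keep side wherever the rule wording is
ambiguous (year 1800 kept, year 1980 in the historical bucket, exactly
+20 years kept): where a convention had to be chosen, we keep data rather
than drop it. The 20-year horizon uses calendar years (`year + 20`, Feb 29
clamped to Feb 28), not 20 × 365 days. The reference instant is always an
explicit argument (defaulting to the run's start time) so classification
is reproducible; the classifier never reads the wall clock.

Kept rows are grouped into tracks by identifier (ordered by first
appearance) and time-sorted. Non-required columns become numeric
attributes; a column with any non-numeric, non-blank kept value is
categorical, which the attribute model does not support, and is dropped
with a warning. Blank numeric cells become NaN (missing).

## Attribute registry

Each attribute records its observed min/max over **all** kept
individuals, enabled or not, so toggling tracks never rescales symbology
mid-animation. Aliases and units come from a small editable TSV snapshot
of known environmental variable names (NDVI, tail/cross wind, thermal
uplift, ocean NPP, 10 m V-wind, 2 m temperature, wind direction, and the
derived movement parameters); unknown names alias to themselves with an
empty unit. Units in the snapshot are conventional placeholders and are
meant to be edited. `round_range` rounds a range outward to two
significant digits (floor the min, ceil the max), guaranteeing the
rounded interval contains the observed one; subnormal magnitudes are left
untouched.

## Movement parameters

Geometry is spherical with R = 6 371 000 m — visualization-grade accuracy
without an ellipsoidal dependency. Speed at point *i* is the haversine
distance from point *i−1* divided by the elapsed seconds; duplicate
timestamps yield a missing value (logged), as does the first point of a
track. Move azimuth is the initial great-circle bearing
`atan2(sin Δλ cos φ₂, cos φ₁ sin φ₂ − sin φ₁ cos φ₂ cos Δλ)`, normalized
to [0, 360); zero displacement yields missing. Derived columns
(`computed_speed` m/s, `move_azimuth` deg) are added only when the input
lacks them — user columns are never overwritten.

## Projection and viewport

Spherical Web Mercator in the slippy-map convention: 256-px tiles, zoom
doubling, y south-positive. Latitude is clamped to ±85.05113°; longitude
is deliberately *not* clamped, so unwrapped longitudes project onto
horizontally repeated world copies. Unwrapping sets each value to its
congruent-mod-360 representative nearest the previous one, which bounds
every consecutive step by 180°; at rendering time each track is unwrapped
independently and shifted to the world copy nearest the viewport center.
This mirrors the extended-basemap strategy for data near the 180th
meridian: the basemap repeats, the polyline never splits.

`fit_viewport` centers on the bounding-box centroid (bbox computed from
unwrapped longitudes) and picks the largest integer zoom at which the
projected bbox occupies at most 95% of the window in both axes — the 5%
margin is a padding convention. A degenerate single-point bbox gets zoom
10. Fractional zoom is not used; integer zoom keeps tile math exact.

## Styling

Color ramps interpolate piecewise-linearly per channel in sRGB (simple,
reproducible, and monotone per channel between stops), with half-up
rounding to integer channels; values are clamped to the attribute range,
missing values produce no glyph, and a degenerate range maps to the ramp
midpoint. Size/width/length scales are affine on the clamped normalized
value; a degenerate range yields the output midpoint. Identifier coloring
uses a 12-color maximally-distinct palette indexed by first appearance,
cycling beyond 12. Vector directions are compass bearings (0 = north,
clockwise), normalized mod 360. Two ramps ship by default: a blue→white→
red diverging ramp (tailwind/headwind style) and a compact viridis-like
sequential ramp.

The legend model always exposes exactly seven block kinds — title, line
color, point color, vector color, line width, point size, vector length —
with per-block pixel positions and font size; only blocks whose binding
is enabled are drawn. Layouts serialize to the config store for reuse.

## Animation clock and fade

Animation speed is data-time per frame (`time_step`), decoupled from
playback fps, so frames are deterministic regardless of playback rate.
The schedule runs from start to end inclusive, appending the end instant
when it is off-grid. The fade window assigns opacity
`max(0, 1 − age/duration)` — a linear falloff, the simplest
monotone interpretation of gradual fading — with a 24 h default duration.
Besides cognition, the fade bounds the number of glyphs drawn per frame,
which is the mechanism that keeps long datasets rendering at a constant
per-frame cost.

## Rendering

`render_frame` is a pure function of its context. Layer order bottom→top:
basemap; underlay history polylines (defaults white, 1 px, 40% opacity —
a faint frame of reference); track segments (color/width per styling,
alpha multiplied by the fade value at the segment's end time; faded-out
gaps are not bridged); point markers; vector glyphs; legend blocks;
title/time/scale annotations. Within a layer, glyphs draw in
chronological order, newest on top. Each layer is drawn on its own
transparent overlay and alpha-composited, so per-glyph transparency
interacts correctly with the basemap. Text uses Pillow's bundled default
font at fixed sizes; no wall-clock reads occur anywhere in the path, so
identical contexts give byte-identical rasters.

The default basemap is `offline-graticule`: a neutral canvas with a 10°
graticule and an attribution line, requiring no network. Named web
providers (Esri, Google, Microsoft lineups) go through a pluggable
tile-fetcher adapter with an on-disk cache; the map-scale annotation
reports ground meters per 100 px at the viewport center latitude.
Selecting an identifier thickens that track's stroke by 2 px
(highlighting) without touching others. The timeline strip draws one bar
per enabled track (categorical color, spanning the track's own extent
proportionally) and a red playhead at the current instant.

## Export

Frames are watermarked (semi-transparent text, 8 px inset, upper-right)
and written as zero-padded PNGs under `<out_dir>/temp`; videos are named
`<title>_<n>.mp4` with an auto-incremented recording number, duration =
frame count / fps. Encoding is delegated to a narrow adapter (PNG paths +
fps → file); the default adapter uses imageio's ffmpeg backend, and when
that backend is absent the PNG sequence survives and an explicit error
names the missing dependency. MP4/H.264 is the chosen container/codec for
portability. Stored frames are exactly `watermark(render_frame(ctx))`, so
re-exports are byte-identical.

## Synthetic data generator

The generator emulates a multi-individual GPS study with context
annotations; its defaults are the conditions of a seabird foraging
campaign: 9 individuals, 90-minute sampling, starting 2008-06-01, 1952
fixes per track (≈122 days). Movement is a correlated random walk:
per-step turning angles are Normal(0, σ²) with σ = √(−2 ln ρ), so the
heading-persistence parameter ρ = 0.8 is the turn distribution's mean
resultant length; a weak homeward bias (0.1 of the wrapped angular error
per step) keeps tracks looping through a region, as foraging tracks do,
instead of diffusing away. Step speed is `max(0, base + β·w + ε)` with
base 10 m/s, tailwind `w ~ N(0, 1)` m/s, β = 2 (m/s per m/s) and noise
`ε ~ N(0, 0.5)` m/s; with these values the floor at zero is essentially
never active, so the analytic speed–wind correlation
`βσ_w / √(β²σ_w² + σ_ε²)` ≈ 0.970 holds and parameter recovery is exact
to sampling error. NDVI is a smooth deterministic sinusoidal field of
position scaled to [0, 1] with a seed-derived phase. Each individual gets
its own RNG stream derived from (seed, index), so adding individuals
never perturbs existing tracks, and numeric formatting is fixed-precision
so identical specs are byte-identical.

What the generator does *not* emulate: behavioral state switching, GPS
measurement error, irregular sampling, heteroscedastic covariate error,
or real environmental rasters. Tests passing on this data therefore
demonstrate pipeline correctness (classification, conservation,
projection, styling, determinism), not ecological realism.

Invalid rows are injected in exact per-category counts after the valid
rows. Future-dated categories are constructed relative to an explicit
`reference_now` carried in the spec (default 2026-01-01); loaders should
be given the same instant for the counts to classify as intended. An
antimeridian preset starts tracks at 175° E heading east to exercise the
unwrap/render path.

## Problem sizes and tolerances

The test suite and acceptance script use desk-scale sizes chosen to make
the statistics decisive: 10 000 random points for projection round-trip
(tolerance 1e−9 deg), 1 000 random pairs against an independent
tangent-vector/arctan² geodesic oracle (1e−6 relative), 300–1 000 random
fixture files for conservation (exact), 1 000 draws for ramp/scale
properties (exact endpoints; 1e−12 affinity), and n = 10 000 fixes for
correlation recovery (±0.05 of the closed form). Distances are also
cross-checked against R's `geosphere::distHaversine`; geosphere's
`bearing` is ellipsoidal, so azimuths are checked against the in-suite
spherical oracle instead.

## Known limitations

- Spherical geometry only; no ellipsoidal geodesics or alternative CRS.
- Categorical attributes are dropped rather than encoded.
- Byte-identical rendering is guaranteed within one environment (same
  Pillow build/font), not across library versions.
- Web basemap fetching is a thin adapter without retry/backoff and is
  untested against live providers.
- No outlier filtering beyond the record categories: rows are either kept
  or ignored, never corrected.
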