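# trackanim

Headless multivariate visualization and animation of animal tracking data.

Movement ecologists increasingly work with GPS trajectories annotated with
internal and external context — wind support, thermal uplift, NDVI, ocean
productivity, derived movement parameters — and communicating how movement
relates to that context is easiest through maps and animations. `trackanim`
turns tracking CSVs into deterministic static maps and animated frame
sequences: each fix's attributes are mapped onto cartographic visual
variables (line color and width, point color and size, vector direction,
length and color), drawn over a Web-Mercator basemap with a temporal fade
window, a full-history underlay, a seven-block legend, and a timeline
strip. Everything runs without a display or network, so the same code
serves scripted figure generation, batch video export, and reproducible
pipelines.

## The model in brief

- **Input.** CSV with four required columns — individual identifier,
  longitude and latitude (WGS84 degrees), timestamp — plus any number of
  numeric attribute columns. Movebank's default headers
  (`individual-local-identifier`, `location-long`, `location-lat`,
  `study-local-timestamp`) resolve automatically; custom headers are
  remembered per file (name + content hash) after being supplied once.
- **Validation.** Every row is classified into exactly one category:
  marked invisible (`visible` = 0/false), corrupt coordinates, corrupt
  required field, dated before 1800, dated 1800–1980 (kept but reported
  separately), within 20 years in the future (kept), beyond 20 years
  (ignored), or valid. Category counts always sum to the rows read.
- **Movement parameters.** Per-fix speed `v_i = d(p_{i-1}, p_i) / Δt_i`
  (great-circle distance on a sphere of radius 6 371 000 m, in m/s) and
  move azimuth (initial bearing, degrees clockwise from north in
  [0, 360)) are derived when absent from the input.
- **Projection.** Spherical Web Mercator in the slippy-map convention
  (x = (λ+180)/360, y = (1 − ln tan(π/4 + φ/2)/π)/2, 256-px tiles,
  integer zoom). Tracks crossing the 180th meridian are kept contiguous
  by longitude unwrapping (each fix placed on the world copy nearest its
  predecessor, |Δλ| ≤ 180°).
- **Styling.** Continuous attributes map through piecewise-linear sRGB
  color ramps and affine size scales over the attribute's registered
  range; the identifier maps to stable categorical colors. A fade window
  of *h* hours gives each drawn glyph opacity `max(0, 1 − age/h)`.
- **Rendering.** A frame is a pure function of its context (dataset,
  style, viewport, instant): identical inputs produce byte-identical
  PNGs.

## Worked example

```python
from datetime import datetime
from trackanim import (FixtureSpec, generate_tracks, load_tracks,
                       add_movement_attributes, register_attributes)

spec = FixtureSpec(n_individuals=3, n_points_per_track=100, seed=42)
path = generate_tracks(spec, "tracks.csv")
dataset, report = load_tracks(path, reference_now=datetime(2026, 1, 1))
add_movement_attributes(dataset)
register_attributes(dataset)
for line in report.summary_lines():
    print(line)
```

prints (with four invisible, two corrupt-coordinate and one pre-1800 row
injected, as in `examples/01_load_and_validate.py`):

```
Marked invisible: 4 (Ignored)
Corrupt coordinates: 2 (Ignored)
Corrupt required field: 0 (Ignored)
Date before 1800: 1 (Ignored)
Date between 1800 and 1980: 0 (Kept)
Date within 20 years in the future: 0 (Kept)
Date beyond 20 years in the future: 0 (Ignored)
Valid: 300 (Kept)
Total data points available for visualization: 300
```

i.e. the seven broken rows were ignored and the 300 simulated fixes were
kept, grouped into three time-sorted tracks. Continuing
(`examples/02_derive_and_style.py`) the derived speed registers an
observed range of 3.94–16.89 m/s, and a fix at 9.04 m/s resolves to line
color `(198, 207, 240, 255)` (just blue of the diverging ramp's white
midpoint) and a 2.97 px line width on a 1–6 px scale.

The `examples/` directory holds one short script per capability: loading
and validation, deriving and styling, rendering a frame and the timeline,
exporting an animation, and antimeridian-crossing tracks. A thin CLI
mirrors the batch workflow:

```
trackanim fixtures --out demo.csv --individuals 3 --points 200
trackanim load demo.csv
trackanim frame demo.csv --at 2008-06-15T00:00:00 --out frame.png
trackanim animate demo.csv --out vids --time-step 12 --store-frames
```

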