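"""Derive movement parameters and resolve them into visual variables.

Computes per-fix speed (m/s, great-circle distance over elapsed time) and
move azimuth (degrees clockwise from north), then shows how a value is
mapped to a ramp color and a line width over the attribute's registered
range.
"""

import tempfile
from datetime import datetime
from pathlib import Path

from trackanim import (
    FixtureSpec,
    add_movement_attributes,
    generate_tracks,
    interpolate_ramp,
    load_tracks,
    named_ramp,
    register_attributes,
    scale_size,
)

with tempfile.TemporaryDirectory() as tmp:
    path = generate_tracks(FixtureSpec(n_individuals=1, n_points_per_track=50, seed=3), Path(tmp) / "t.csv")
    dataset, _ = load_tracks(path, reference_now=datetime(2026, 1, 1))

added = add_movement_attributes(dataset)
register_attributes(dataset)
print("derived attributes:", added)

speed = dataset.attribute("computed_speed")
print(f"{speed.alias}: observed range {speed.min:.2f}–{speed.max:.2f} {speed.unit}")

point = dataset.tracks[0].points[10]
value = point.attributes["computed_speed"]
color = interpolate_ramp(value, speed.min, speed.max, named_ramp("blue_red"))
width = scale_size(value, speed.min, speed.max, 1.0, 6.0)
print(f"speed {value:.2f} m/s -> line color {color}, line width {width:.2f} px")
# A mid-range speed lands mid-ramp (near white on the blue->red diverging
# ramp) and mid-way between the 1 px and 6 px width bounds.
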