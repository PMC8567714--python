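"""Render one deterministic animation frame to PNG.

Fits a Web-Mercator viewport to the data extent, binds speed to line
width and the wind covariate to line color, enables a 24 h fade window
and the history underlay, and composites a single frame.
"""

import tempfile
from datetime import datetime, timedelta
from pathlib import Path

from trackanim import (
    FadeSettings,
    FixtureSpec,
    FrameContext,
    UnderlaySettings,
    VisualStyle,
    add_movement_attributes,
    fit_viewport,
    generate_tracks,
    load_tracks,
    named_ramp,
    register_attributes,
    render_frame,
    render_timeline,
)
from trackanim.styling import TrackLayer

with tempfile.TemporaryDirectory() as tmp:
    path = generate_tracks(FixtureSpec(n_individuals=4, n_points_per_track=120, seed=11), Path(tmp) / "t.csv")
    dataset, _ = load_tracks(path, reference_now=datetime(2026, 1, 1))
add_movement_attributes(dataset)
register_attributes(dataset)

style = VisualStyle(
    track=TrackLayer(color_attr="tail_wind", ramp=named_ramp("blue_red"), width_attr="computed_speed"),
    underlay=UnderlaySettings(enabled=True),
    fade=FadeSettings(enabled=True, duration_hours=24.0),
)
viewport = fit_viewport(dataset.bbox, 800, 600)
now = dataset.time_extent[0] + timedelta(days=3)

frame = render_frame(FrameContext(dataset=dataset, style=style, viewport=viewport, now=now))
frame.save("frame.png")
timeline = render_timeline(dataset, now)
timeline.save("timeline.png")
print(f"frame.png: {frame.size[0]}x{frame.size[1]} px, viewport zoom {viewport.zoom}")
print(f"timeline.png: one bar per track, playhead at {now}")
# Rendering the same context twice yields byte-identical PNGs; the fade
# window means only the last 24 h of each track carry full ink.
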