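"""Render tracks that cross the 180th meridian without splitting.

Raw longitudes jump from +180 to -180 mid-track; unwrapping places each
fix on the world copy nearest its predecessor so the projected polyline
stays contiguous and the fitted viewport centers on the crossing.
"""

import tempfile
from datetime import datetime
from pathlib import Path

from trackanim import (
    FixtureSpec,
    FrameContext,
    VisualStyle,
    fit_viewport,
    generate_tracks,
    load_tracks,
    register_attributes,
    render_frame,
    unwrap_longitudes,
)

with tempfile.TemporaryDirectory() as tmp:
    path = generate_tracks(FixtureSpec.antimeridian_preset(seed=8), Path(tmp) / "t.csv")
    dataset, _ = load_tracks(path, reference_now=datetime(2026, 1, 1))
register_attributes(dataset)

raw = [p.lon for p in dataset.tracks[0].points]
unwrapped = unwrap_longitudes(raw)
jumps = sum(1 for a, b in zip(raw, raw[1:]) if abs(b - a) > 180)
print(f"raw longitudes jump across +-180 {jumps} times")
print(f"unwrapped range: {min(unwrapped):.1f} to {max(unwrapped):.1f} deg (contiguous)")

lons = [lon for t in dataset.tracks for lon in unwrap_longitudes([p.lon for p in t.points])]
lats = [p.lat for p in dataset.iter_points()]
viewport = fit_viewport((min(lons), min(lats), max(lons), max(lats)), 800, 600)
print(f"viewport centered at lon {viewport.center_lon:.1f} (on the antimeridian side)")

frame = render_frame(
    FrameContext(dataset=dataset, style=VisualStyle(), viewport=viewport, now=dataset.time_extent[1])
)
frame.save("antimeridian.png")
print("wrote antimeridian.png — the track renders as one unbroken polyline")
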