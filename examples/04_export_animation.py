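"""Export an animation as a watermarked PNG frame sequence (plus video
where an H.264 encoder is installed).

The frame schedule steps data time in fixed increments; playback fps is
independent, so the video duration is frame_count / fps regardless of the
chosen data step.
"""

import tempfile
from datetime import datetime, timedelta
from pathlib import Path

from trackanim import (
    AnimationSpec,
    EncoderUnavailableError,
    FixtureSpec,
    FrameContext,
    VisualStyle,
    export_animation,
    fit_viewport,
    frame_schedule,
    generate_tracks,
    load_tracks,
    register_attributes,
)

with tempfile.TemporaryDirectory() as tmp:
    path = generate_tracks(FixtureSpec(n_individuals=3, n_points_per_track=60, seed=5), Path(tmp) / "t.csv")
    dataset, _ = load_tracks(path, reference_now=datetime(2026, 1, 1))
register_attributes(dataset)

t0, t1 = dataset.time_extent
spec = AnimationSpec(t_start=t0, t_end=t1, time_step=timedelta(hours=12), fps=10)
viewport = fit_viewport(dataset.bbox, 640, 480)
contexts = [
    FrameContext(dataset=dataset, style=VisualStyle(), viewport=viewport, now=now)
    for now in frame_schedule(spec)
]
print(f"{len(contexts)} frames -> video duration {len(contexts) / spec.fps:.1f} s at {spec.fps} fps")

try:
    video, frames = export_animation(contexts, spec.fps, "export", dataset.title, store_frames=True)
    print(f"wrote {video} and {len(frames)} frames under export/temp/")
except EncoderUnavailableError as error:
    # no ffmpeg on this machine: the PNG sequence is still complete
    print(error)
    print("first frame:", error.frame_paths[0])
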