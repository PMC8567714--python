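"""Animation clock: frame scheduling and the fade window.

Animation speed is expressed as data-time per frame (``time_step``),
decoupled from the playback frame rate, so a frame's content depends only
on its data timestamp — never on how fast it is played back. The *fade*
window keeps only the last ``duration`` hours of each track visible,
with opacity falling off linearly with age; besides focusing attention on
recent movement it bounds the number of glyphs drawn per frame, which is
what keeps long recordings rendering at a steady pace.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta

__all__ = ["FadeSettings", "AnimationSpec", "fade_alpha", "frame_schedule"]

DEFAULT_FADE_HOURS = 24.0


@dataclass(frozen=True)
class FadeSettings:
    """Whether and how fast old points fade out (duration in hours)."""

    enabled: bool = False
    duration_hours: float = DEFAULT_FADE_HOURS

    def __post_init__(self) -> None:
        if self.enabled and self.duration_hours <= 0:
            raise ValueError("fade duration must be positive when enabled")


@dataclass(frozen=True)
class AnimationSpec:
    """Time range, data-time step per frame, playback rate, frame size."""

    t_start: datetime
    t_end: datetime
    time_step: timedelta
    fps: float = 24.0
    frame_size: tuple[int, int] = (800, 600)

    def __post_init__(self) -> None:
        if self.t_start >= self.t_end:
            raise ValueError("t_start must precede t_end")
        if self.time_step <= timedelta(0):
            raise ValueError("time_step must be positive")
        if self.fps <= 0:
            raise ValueError("fps must be positive")


def fade_alpha(point_time: datetime, now: datetime, fade: FadeSettings) -> float:
    """Opacity multiplier in [0, 1] for a point of the given age.

    With fade disabled every past point is fully opaque. Enabled, opacity
    falls linearly from 1 at age zero to 0 at the fade duration:
    ``max(0, 1 - age / duration)``. Future points are never drawn, so
    *point_time* must not exceed *now*.
    """
    if point_time > now:
        raise ValueError("fade_alpha called for a future point")
    if not fade.enabled:
        return 1.0
    age_h = (now - point_time).total_seconds() / 3600.0
    return max(0.0, 1.0 - age_h / fade.duration_hours)


def frame_schedule(spec: AnimationSpec) -> list[datetime]:
    """Frame instants: t_start, t_start+step, ... with t_end always included."""
    frames = []
    t = spec.t_start
    while t <= spec.t_end:
        frames.append(t)
        t = t + spec.time_step
    if frames[-1] != spec.t_end:
        frames.append(spec.t_end)
    return frames
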