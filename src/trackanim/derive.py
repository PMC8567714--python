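"""Movement parameters computed from consecutive fixes.

Speed and move azimuth are the two path characteristics mapped most often
onto visual variables (line width for speed, point size or vector length
for bearing), so they are derived automatically when the input data does
not already carry them. Geometry is spherical (great circle on a sphere of
radius 6,371,000 m) — visualization-grade accuracy without an ellipsoidal
geodesy dependency.
"""

from __future__ import annotations

import logging
import math

from .trackstore import Dataset, Track

log = logging.getLogger(__name__)

__all__ = [
    "EARTH_RADIUS_M",
    "haversine_distance",
    "computed_speed",
    "move_azimuth",
    "add_movement_attributes",
]

EARTH_RADIUS_M = 6_371_000.0

SPEED_ATTRIBUTE = "computed_speed"
AZIMUTH_ATTRIBUTE = "move_azimuth"


def haversine_distance(p1: tuple[float, float], p2: tuple[float, float]) -> float:
    """Great-circle distance in meters between two (lon, lat) degree pairs."""
    lon1, lat1 = map(math.radians, p1)
    lon2, lat2 = map(math.radians, p2)
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = math.sin(dlat / 2) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2) ** 2
    return 2.0 * EARTH_RADIUS_M * math.asin(min(1.0, math.sqrt(a)))


def computed_speed(track: Track) -> list[float]:
    """Per-point speed in m/s over the step ending at each point.

    ``speed[i] = haversine(p[i-1], p[i]) / (t[i] - t[i-1])``. The first
    point, and any point sharing its predecessor's timestamp, gets NaN.
    """
    out = [math.nan] * len(track.points)
    for i in range(1, len(track.points)):
        a, b = track.points[i - 1], track.points[i]
        dt = (b.time - a.time).total_seconds()
        if dt <= 0:
            log.warning(
                "track %r: duplicate timestamp at %s; speed undefined",
                track.identifier,
                b.time,
            )
            continue
        out[i] = haversine_distance((a.lon, a.lat), (b.lon, b.lat)) / dt
    return out


def move_azimuth(track: Track) -> list[float]:
    """Per-point bearing of the step ending at each point.

    Initial great-circle bearing from the previous fix, degrees clockwise
    from geographic north in [0, 360). First point and zero-displacement
    steps get NaN.
    """
    out = [math.nan] * len(track.points)
    for i in range(1, len(track.points)):
        a, b = track.points[i - 1], track.points[i]
        if a.lon == b.lon and a.lat == b.lat:
            continue
        lat1, lat2 = math.radians(a.lat), math.radians(b.lat)
        dlon = math.radians(b.lon - a.lon)
        y = math.sin(dlon) * math.cos(lat2)
        x = math.cos(lat1) * math.sin(lat2) - math.sin(lat1) * math.cos(lat2) * math.cos(dlon)
        out[i] = math.degrees(math.atan2(y, x)) % 360.0
    return out


def add_movement_attributes(dataset: Dataset) -> list[str]:
    """Attach ``computed_speed`` / ``move_azimuth`` attributes where absent.

    Existing user columns with those names are never overwritten. Returns
    the names actually added. Re-registering attributes afterwards is the
    caller's job (``register_attributes``) if legend ranges are needed.
    """
    added = []
    existing = {
        name for p in dataset.iter_points() for name in p.attributes
    }
    for name, fn in ((SPEED_ATTRIBUTE, computed_speed), (AZIMUTH_ATTRIBUTE, move_azimuth)):
        if name in existing:
            continue
        for track in dataset.tracks:
            for point, value in zip(track.points, fn(track)):
                point.attributes[name] = value
        added.append(name)
    return added
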