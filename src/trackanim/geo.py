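"""Web-Mercator projection, antimeridian-safe longitudes, viewport fitting.

The slippy-map convention is used throughout: 256-pixel tiles, zoom level
doubling the world width, y increasing southward. Longitudes are allowed
outside [-180, 180] so that tracks crossing the 180th meridian stay
contiguous after :func:`unwrap_longitudes`; the rendered basemap simply
repeats horizontally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "MAX_MERCATOR_LAT",
    "TILE_SIZE",
    "Viewport",
    "project_mercator",
    "unproject_mercator",
    "unwrap_longitudes",
    "fit_viewport",
]

MAX_MERCATOR_LAT = 85.05113
TILE_SIZE = 256
MAX_ZOOM = 22
SINGLE_POINT_ZOOM = 10
FIT_MARGIN = 0.95  # bbox may occupy at most this fraction of the window


def project_mercator(lon: float, lat: float) -> tuple[float, float]:
    """Forward spherical Mercator to normalized world coordinates.

    ``x = (lon + 180) / 360``; ``y = (1 - ln(tan(pi/4 + phi/2)) / pi) / 2``.
    (0.5, 0.5) is lon 0 / lat 0; y grows southward. Latitude is clamped to
    +/-85.05113 deg; longitude is deliberately unclamped so unwrapped values
    map onto horizontally repeated world copies.
    """
    lat = max(-MAX_MERCATOR_LAT, min(MAX_MERCATOR_LAT, lat))
    phi = math.radians(lat)
    x = (lon + 180.0) / 360.0
    y = (1.0 - math.log(math.tan(math.pi / 4.0 + phi / 2.0)) / math.pi) / 2.0
    return x, y


def unproject_mercator(x: float, y: float) -> tuple[float, float]:
    """Inverse of :func:`project_mercator` (lon unbounded, lat in Mercator range)."""
    lon = x * 360.0 - 180.0
    phi = 2.0 * math.atan(math.exp((1.0 - 2.0 * y) * math.pi)) - math.pi / 2.0
    return lon, math.degrees(phi)


def unwrap_longitudes(lons: Sequence[float]) -> list[float]:
    """Shift each longitude by a multiple of 360 so no step exceeds 180 deg.

    The first value is returned unchanged; every subsequent value keeps its
    value mod 360 but is placed on the world copy nearest its predecessor,
    so a track crossing the antimeridian stays contiguous.
    """
    if not lons:
        return []
    out = [float(lons[0])]
    for lon in lons[1:]:
        prev = out[-1]
        shifted = float(lon) + 360.0 * round((prev - lon) / 360.0)
        out.append(shifted)
    return out


@dataclass(frozen=True)
class Viewport:
    """A Web-Mercator camera: center, integer zoom, and pixel size."""

    center_lon: float
    center_lat: float
    zoom: int
    width_px: int
    height_px: int

    def __post_init__(self) -> None:
        if abs(self.center_lat) > MAX_MERCATOR_LAT:
            raise ValueError("center latitude outside Mercator range")
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("viewport size must be positive")
        if self.zoom < 0:
            raise ValueError("zoom must be >= 0")

    @property
    def world_px(self) -> float:
        """Width of one world copy in pixels at this zoom."""
        return TILE_SIZE * 2.0**self.zoom

    def to_pixel(self, lon: float, lat: float) -> tuple[float, float]:
        """Project a coordinate to window pixels (origin top-left)."""
        x, y = project_mercator(lon, lat)
        cx, cy = project_mercator(self.center_lon, self.center_lat)
        px = (x - cx) * self.world_px + self.width_px / 2.0
        py = (y - cy) * self.world_px + self.height_px / 2.0
        return px, py

    def from_pixel(self, px: float, py: float) -> tuple[float, float]:
        cx, cy = project_mercator(self.center_lon, self.center_lat)
        x = cx + (px - self.width_px / 2.0) / self.world_px
        y = cy + (py - self.height_px / 2.0) / self.world_px
        return unproject_mercator(x, y)

    def meters_per_pixel(self) -> float:
        """Ground resolution at the viewport center latitude."""
        lat = max(-MAX_MERCATOR_LAT, min(MAX_MERCATOR_LAT, self.center_lat))
        circumference = 2.0 * math.pi * 6_371_000.0
        return math.cos(math.radians(lat)) * circumference / self.world_px


def fit_viewport(
    bbox: tuple[float, float, float, float],
    width_px: int,
    height_px: int,
) -> Viewport:
    """Camera centered on the bbox centroid, zoomed to its full extent.

    *bbox* is (lon_min, lat_min, lon_max, lat_max) with longitudes already
    unwrapped, so an antimeridian-spanning extent is contiguous. The zoom
    is the largest integer at which the projected bbox occupies at most
    95% of the window in both axes. A degenerate (single-point) bbox gets
    zoom 10.
    """
    lon_min, lat_min, lon_max, lat_max = bbox
    if lon_min > lon_max or lat_min > lat_max:
        raise ValueError("malformed bbox")
    center_lon = (lon_min + lon_max) / 2.0
    center_lat = (lat_min + lat_max) / 2.0
    center_lat = max(-MAX_MERCATOR_LAT, min(MAX_MERCATOR_LAT, center_lat))

    x0, y1 = project_mercator(lon_min, lat_min)  # south edge has larger y
    x1, y0 = project_mercator(lon_max, lat_max)
    span_x = abs(x1 - x0)
    span_y = abs(y1 - y0)
    if span_x == 0.0 and span_y == 0.0:
        return Viewport(center_lon, center_lat, SINGLE_POINT_ZOOM, width_px, height_px)

    zoom = 0
    for z in range(MAX_ZOOM + 1):
        world = TILE_SIZE * 2.0**z
        if span_x * world <= FIT_MARGIN * width_px and span_y * world <= FIT_MARGIN * height_px:
            zoom = z
        else:
            break
    return Viewport(center_lon, center_lat, zoom, width_px, height_px)
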