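"""Deterministic frame composition.

One animation frame is a pure function of a :class:`FrameContext`: basemap,
underlay history, fading track segments, point markers, vector glyphs,
legend blocks, and text annotations (title, current time, map scale) are
composited bottom-to-top onto an RGBA raster. Identical contexts produce
byte-identical images — there are no wall-clock reads and the single
bundled bitmap font is used for all text.

The default basemap, ``offline-graticule``, is a neutral canvas with a 10
degree graticule and needs no network. The named web providers are served
through a pluggable tile-fetcher adapter with an on-disk cache; they are
never required for rendering to work.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime
from functools import lru_cache
from pathlib import Path
from typing import Protocol

from PIL import Image, ImageDraw, ImageFont

from .animate import fade_alpha
from .geo import Viewport, unwrap_longitudes
from .styling import (
    IDENTIFIER_ATTRIBUTE,
    LegendLayout,
    VisualStyle,
    categorical_color,
    interpolate_ramp,
    resolve_vector,
    scale_size,
)
from .trackstore import Dataset, Track

__all__ = [
    "FrameContext",
    "ConfigurationError",
    "render_frame",
    "render_timeline",
    "BASEMAP_PROVIDERS",
    "OFFLINE_BASEMAP",
    "TileFetcher",
]

OFFLINE_BASEMAP = "offline-graticule"

#: Named tile providers selectable as basemaps (slippy z/x/y URL templates).
BASEMAP_PROVIDERS: dict[str, str] = {
    "esri-natgeo": "https://server.arcgisonline.com/ArcGIS/rest/services/NatGeo_World_Map/MapServer/tile/{z}/{y}/{x}",
    "esri-ocean": "https://server.arcgisonline.com/ArcGIS/rest/services/Ocean/World_Ocean_Base/MapServer/tile/{z}/{y}/{x}",
    "esri-world-gray-canvas": "https://server.arcgisonline.com/ArcGIS/rest/services/Canvas/World_Light_Gray_Base/MapServer/tile/{z}/{y}/{x}",
    "esri-world-shaded-relief": "https://server.arcgisonline.com/ArcGIS/rest/services/World_Shaded_Relief/MapServer/tile/{z}/{y}/{x}",
    "esri-world-terrain": "https://server.arcgisonline.com/ArcGIS/rest/services/World_Terrain_Base/MapServer/tile/{z}/{y}/{x}",
    "esri-world-topo": "https://server.arcgisonline.com/ArcGIS/rest/services/World_Topo_Map/MapServer/tile/{z}/{y}/{x}",
    "google-maps": "https://mt1.google.com/vt/lyrs=m&x={x}&y={y}&z={z}",
    "google-maps-simple": "https://mt1.google.com/vt/lyrs=m&x={x}&y={y}&z={z}",
    "google-terrain": "https://mt1.google.com/vt/lyrs=p&x={x}&y={y}&z={z}",
    "microsoft-aerial": "https://ecn.t3.tiles.virtualearth.net/tiles/a{q}.jpeg?g=1",
}

_CANVAS_COLOR = (242, 242, 238, 255)
_GRATICULE_COLOR = (205, 205, 210, 255)
_GRATICULE_STEP_DEG = 10.0


class ConfigurationError(ValueError):
    """A style references an attribute missing from the dataset registry."""


@lru_cache(maxsize=8)
def _font(size: int = 12) -> ImageFont.ImageFont:
    try:
        return ImageFont.load_default(size=size)
    except TypeError:  # older Pillow: fixed-size bitmap font only
        return ImageFont.load_default()


@dataclass(frozen=True)
class FrameContext:
    """Everything needed to render one frame, and nothing else."""

    dataset: Dataset
    style: VisualStyle
    viewport: Viewport
    now: datetime
    legend: LegendLayout = field(default_factory=LegendLayout)
    basemap: str = OFFLINE_BASEMAP
    title: str | None = None
    highlight_identifier: str | None = None

    @property
    def frame_title(self) -> str:
        return self.title if self.title is not None else self.dataset.title


# ---------------------------------------------------------------------------
# basemap


class TileProvider(Protocol):
    def get_tile(self, z: int, x: int, y: int) -> Image.Image: ...


class TileFetcher:
    """Fetch slippy-map tiles over HTTP with an on-disk cache.

    Only used when a named web basemap is requested; the test-facing
    rendering path never touches it.
    """

    def __init__(self, url_template: str, cache_dir: str | Path):
        self.url_template = url_template
        self.cache_dir = Path(cache_dir)

    def get_tile(self, z: int, x: int, y: int) -> Image.Image:
        x = x % (1 << z)  # repeated world copies share tiles
        cached = self.cache_dir / f"{z}_{x}_{y}.png"
        if cached.exists():
            return Image.open(cached).convert("RGBA")
        from urllib.request import urlopen

        url = self.url_template.format(z=z, x=x, y=y, q=_quadkey(z, x, y))
        with urlopen(url, timeout=30) as response:
            data = response.read()
        self.cache_dir.mkdir(parents=True, exist_ok=True)
        cached.write_bytes(data)
        return Image.open(cached).convert("RGBA")


def _quadkey(z: int, x: int, y: int) -> str:
    key = []
    for i in range(z, 0, -1):
        digit = 0
        mask = 1 << (i - 1)
        if x & mask:
            digit += 1
        if y & mask:
            digit += 2
        key.append(str(digit))
    return "".join(key)


def _draw_graticule(image: Image.Image, viewport: Viewport) -> None:
    draw = ImageDraw.Draw(image)
    w, h = viewport.width_px, viewport.height_px
    lon_left, _ = viewport.from_pixel(0, h / 2)
    lon_right, _ = viewport.from_pixel(w, h / 2)
    _, lat_top = viewport.from_pixel(w / 2, 0)
    _, lat_bottom = viewport.from_pixel(w / 2, h)

    lon = math.floor(lon_left / _GRATICULE_STEP_DEG) * _GRATICULE_STEP_DEG
    while lon <= lon_right:
        px, _ = viewport.to_pixel(lon, 0.0)
        draw.line([(px, 0), (px, h)], fill=_GRATICULE_COLOR, width=1)
        lon += _GRATICULE_STEP_DEG

    lat = math.floor(lat_bottom / _GRATICULE_STEP_DEG) * _GRATICULE_STEP_DEG
    while lat <= min(lat_top, 80.0):
        if lat >= -80.0:
            _, py = viewport.to_pixel(viewport.center_lon, lat)
            draw.line([(0, py), (w, py)], fill=_GRATICULE_COLOR, width=1)
        lat += _GRATICULE_STEP_DEG


def _render_basemap(
    viewport: Viewport, basemap: str, tile_provider: TileProvider | None
) -> Image.Image:
    image = Image.new("RGBA", (viewport.width_px, viewport.height_px), _CANVAS_COLOR)
    if basemap == OFFLINE_BASEMAP:
        _draw_graticule(image, viewport)
        return image
    if basemap not in BASEMAP_PROVIDERS:
        raise ConfigurationError(
            f"unknown basemap {basemap!r}; choose one of "
            f"{[OFFLINE_BASEMAP, *BASEMAP_PROVIDERS]}"
        )
    provider = tile_provider or TileFetcher(
        BASEMAP_PROVIDERS[basemap], Path.home() / ".cache" / "trackanim" / basemap
    )
    z = viewport.zoom
    n = 1 << z
    from .geo import TILE_SIZE, project_mercator

    wx, wy = project_mercator(viewport.center_lon, viewport.center_lat)
    origin_x = wx * n * TILE_SIZE - viewport.width_px / 2.0
    origin_y = wy * n * TILE_SIZE - viewport.height_px / 2.0
    tx0 = math.floor(origin_x / TILE_SIZE)
    ty0 = math.floor(origin_y / TILE_SIZE)
    tx1 = math.floor((origin_x + viewport.width_px) / TILE_SIZE)
    ty1 = math.floor((origin_y + viewport.height_px) / TILE_SIZE)
    for ty in range(ty0, ty1 + 1):
        if ty < 0 or ty >= n:
            continue
        for tx in range(tx0, tx1 + 1):
            tile = provider.get_tile(z, tx, ty)
            image.paste(tile, (round(tx * TILE_SIZE - origin_x), round(ty * TILE_SIZE - origin_y)))
    return image


# ---------------------------------------------------------------------------
# data layers


def _track_pixels(track: Track, viewport: Viewport) -> list[tuple[float, float]]:
    """Project a track with per-track longitude unwrapping, placed on the
    world copy nearest the viewport center."""
    lons = unwrap_longitudes([p.lon for p in track.points])
    if lons:
        shift = 360.0 * round((viewport.center_lon - lons[0]) / 360.0)
        lons = [lon + shift for lon in lons]
    return [viewport.to_pixel(lon, p.lat) for lon, p in zip(lons, track.points)]


def _with_alpha(color: tuple[int, int, int, int], alpha: float) -> tuple[int, int, int, int]:
    return (color[0], color[1], color[2], math.floor(color[3] * alpha + 0.5))


def _visible_indices(track: Track, now: datetime, style: VisualStyle) -> list[int]:
    idx = []
    for i, p in enumerate(track.points):
        if p.time > now:
            break
        if style.fade.enabled and fade_alpha(p.time, now, style.fade) <= 0.0:
            continue
        idx.append(i)
    return idx


def _ranges(dataset: Dataset) -> dict[str, tuple[float, float]]:
    return {a.name: (a.min, a.max) for a in dataset.attributes}


def _check_style(ctx: FrameContext) -> None:
    registered = set(ctx.dataset.attribute_names)
    missing = ctx.style.referenced_attributes() - registered
    if missing:
        raise ConfigurationError(f"style references unregistered attributes: {sorted(missing)}")


def _draw_underlay(layer: Image.Image, ctx: FrameContext) -> None:
    settings = ctx.style.underlay
    draw = ImageDraw.Draw(layer)
    color = _with_alpha(settings.color, settings.opacity)
    for track in ctx.dataset.tracks:
        if not track.enabled:
            continue
        pixels = [
            xy
            for xy, p in zip(_track_pixels(track, ctx.viewport), track.points)
            if p.time <= ctx.now
        ]
        if len(pixels) >= 2:
            draw.line(pixels, fill=color, width=max(1, round(settings.weight_px)))


def _segment_color(ctx: FrameContext, track: Track, value_point, ranges) -> tuple | None:
    layer = ctx.style.track
    if layer.color_attr == IDENTIFIER_ATTRIBUTE:
        return categorical_color(track.identifier, ctx.dataset.identifiers)
    vmin, vmax = ranges[layer.color_attr]
    return interpolate_ramp(value_point.attributes.get(layer.color_attr), vmin, vmax, layer.ramp)


def _draw_tracks(layer_img: Image.Image, ctx: FrameContext, ranges) -> None:
    layer = ctx.style.track
    draw = ImageDraw.Draw(layer_img)
    for track in ctx.dataset.tracks:
        if not track.enabled:
            continue
        pixels = _track_pixels(track, ctx.viewport)
        bonus = 2.0 if track.identifier == ctx.highlight_identifier else 0.0
        visible = _visible_indices(track, ctx.now, ctx.style)
        for j, i in enumerate(visible[1:], start=1):
            prev = visible[j - 1]
            if i - prev != 1:
                continue  # faded-out gap: do not bridge
            end = track.points[i]
            color = _segment_color(ctx, track, end, ranges)
            if color is None:
                continue
            if layer.width_attr is None:
                width = layer.width_min_px
            else:
                wmin, wmax = ranges[layer.width_attr]
                width = scale_size(
                    end.attributes.get(layer.width_attr),
                    wmin,
                    wmax,
                    layer.width_min_px,
                    layer.width_max_px,
                )
                if width is None:
                    continue
            alpha = fade_alpha(end.time, ctx.now, ctx.style.fade)
            draw.line(
                [pixels[prev], pixels[i]],
                fill=_with_alpha(color, alpha),
                width=max(1, round(width + bonus)),
            )


def _draw_points(layer_img: Image.Image, ctx: FrameContext, ranges) -> None:
    layer = ctx.style.point
    draw = ImageDraw.Draw(layer_img)
    for track in ctx.dataset.tracks:
        if not track.enabled:
            continue
        pixels = _track_pixels(track, ctx.viewport)
        for i in _visible_indices(track, ctx.now, ctx.style):
            p = track.points[i]
            if layer.color_attr is None:
                color = categorical_color(track.identifier, ctx.dataset.identifiers)
            else:
                vmin, vmax = ranges[layer.color_attr]
                color = interpolate_ramp(p.attributes.get(layer.color_attr), vmin, vmax, layer.ramp)
                if color is None:
                    continue
            if layer.size_attr is None:
                size = layer.size_min_px
            else:
                smin, smax = ranges[layer.size_attr]
                size = scale_size(
                    p.attributes.get(layer.size_attr), smin, smax, layer.size_min_px, layer.size_max_px
                )
                if size is None:
                    continue
            alpha = fade_alpha(p.time, ctx.now, ctx.style.fade)
            x, y = pixels[i]
            r = size / 2.0
            draw.ellipse([x - r, y - r, x + r, y + r], fill=_with_alpha(color, alpha))


def _draw_vectors(layer_img: Image.Image, ctx: FrameContext, ranges) -> None:
    draw = ImageDraw.Draw(layer_img)
    for track in ctx.dataset.tracks:
        if not track.enabled:
            continue
        pixels = _track_pixels(track, ctx.viewport)
        for i in _visible_indices(track, ctx.now, ctx.style):
            p = track.points[i]
            glyph = resolve_vector(p, ctx.style, ranges)
            if glyph is None:
                continue
            alpha = fade_alpha(p.time, ctx.now, ctx.style.fade)
            x, y = pixels[i]
            theta = math.radians(glyph.angle_deg)
            dx = glyph.length_px * math.sin(theta)
            dy = -glyph.length_px * math.cos(theta)
            draw.line([(x, y), (x + dx, y + dy)], fill=_with_alpha(glyph.color, alpha), width=2)


# ---------------------------------------------------------------------------
# legend and annotations

_LEGEND_PANEL = (255, 255, 255, 185)
_LEGEND_BORDER = (90, 90, 90, 255)
_TEXT_COLOR = (30, 30, 30, 255)
_BLOCK_SIZE = (150, 42)
_RAMP_BAR = (120, 8)


def _attr_label(ctx: FrameContext, name: str) -> str:
    try:
        info = ctx.dataset.attribute(name)
    except KeyError:
        return name
    return f"{info.alias} ({info.unit})" if info.unit else info.alias


def _draw_legend(layer_img: Image.Image, ctx: FrameContext, ranges) -> None:
    draw = ImageDraw.Draw(layer_img)
    font = _font(ctx.legend.font_size)
    style = ctx.style

    def panel(xy: tuple[int, int]) -> tuple[int, int]:
        x, y = xy
        draw.rectangle(
            [x, y, x + _BLOCK_SIZE[0], y + _BLOCK_SIZE[1]],
            fill=_LEGEND_PANEL,
            outline=_LEGEND_BORDER,
        )
        return x + 6, y + 4

    def ramp_bar(x: int, y: int, ramp, vmin: float, vmax: float) -> None:
        for i in range(_RAMP_BAR[0]):
            t = vmin + (vmax - vmin) * (i / (_RAMP_BAR[0] - 1))
            draw.line(
                [(x + i, y), (x + i, y + _RAMP_BAR[1])],
                fill=interpolate_ramp(t, vmin, vmax, ramp),
            )

    for kind in ctx.legend.enabled_blocks(style):
        x, y = panel(ctx.legend.positions[kind])
        if kind == "title":
            draw.text((x, y), ctx.frame_title, font=font, fill=_TEXT_COLOR)
            draw.text((x, y + 16), ctx.now.strftime("%Y-%m-%d %H:%M"), font=font, fill=_TEXT_COLOR)
        elif kind == "line_color":
            if style.track.color_attr == IDENTIFIER_ATTRIBUTE:
                draw.text((x, y), "Track: one color per individual", font=font, fill=_TEXT_COLOR)
                for i, ident in enumerate(ctx.dataset.identifiers[:8]):
                    draw.rectangle(
                        [x + i * 14, y + 18, x + i * 14 + 10, y + 28],
                        fill=categorical_color(ident, ctx.dataset.identifiers),
                    )
            else:
                name = style.track.color_attr
                draw.text((x, y), f"Line color: {_attr_label(ctx, name)}", font=font, fill=_TEXT_COLOR)
                ramp_bar(x, y + 20, style.track.ramp, *ranges[name])
        elif kind == "point_color":
            name = style.point.color_attr
            draw.text((x, y), f"Point color: {_attr_label(ctx, name)}", font=font, fill=_TEXT_COLOR)
            ramp_bar(x, y + 20, style.point.ramp, *ranges[name])
        elif kind == "vector_color":
            name = style.vector.color_attr
            draw.text((x, y), f"Vector color: {_attr_label(ctx, name)}", font=font, fill=_TEXT_COLOR)
            ramp_bar(x, y + 20, style.vector.ramp, *ranges[name])
        elif kind == "line_width":
            draw.text(
                (x, y),
                f"Line width: {_attr_label(ctx, style.track.width_attr)}",
                font=font,
                fill=_TEXT_COLOR,
            )
            draw.text(
                (x, y + 16),
                f"{style.track.width_min_px:g}-{style.track.width_max_px:g} px",
                font=font,
                fill=_TEXT_COLOR,
            )
        elif kind == "point_size":
            draw.text(
                (x, y),
                f"Point size: {_attr_label(ctx, style.point.size_attr)}",
                font=font,
                fill=_TEXT_COLOR,
            )
            draw.text(
                (x, y + 16),
                f"{style.point.size_min_px:g}-{style.point.size_max_px:g} px",
                font=font,
                fill=_TEXT_COLOR,
            )
        elif kind == "vector_length":
            draw.text(
                (x, y),
                f"Vector length: {_attr_label(ctx, style.vector.length_attr)}",
                font=font,
                fill=_TEXT_COLOR,
            )
            draw.text(
                (x, y + 16),
                f"{style.vector.length_min_px:g}-{style.vector.length_max_px:g} px",
                font=font,
                fill=_TEXT_COLOR,
            )


def _draw_annotations(layer_img: Image.Image, ctx: FrameContext) -> None:
    draw = ImageDraw.Draw(layer_img)
    font = _font(12)
    w, h = ctx.viewport.width_px, ctx.viewport.height_px
    scale_m = ctx.viewport.meters_per_pixel() * 100.0
    scale_text = (
        f"{scale_m / 1000.0:.1f} km / 100 px" if scale_m >= 1000 else f"{scale_m:.0f} m / 100 px"
    )
    draw.text((8, h - 18), scale_text, font=font, fill=_TEXT_COLOR)
    time_text = ctx.now.strftime("%Y-%m-%d %H:%M:%S")
    draw.text((w - 8 - draw.textlength(time_text, font=font), h - 18), time_text, font=font, fill=_TEXT_COLOR)
    if ctx.basemap == OFFLINE_BASEMAP:
        draw.text((8, h - 34), "offline graticule basemap", font=font, fill=(150, 150, 150, 255))


# ---------------------------------------------------------------------------
# entry points


def render_frame(ctx: FrameContext, tile_provider: TileProvider | None = None) -> Image.Image:
    """Compose one animation frame; a pure function of its context.

    Layer order, bottom to top: basemap, underlay history polylines,
    fading track segments, point markers, vector glyphs, legend blocks for
    the enabled bindings, then title/time/scale annotations. Tracks whose
    ``enabled`` flag is off leave no trace. Raises
    :class:`ConfigurationError` when the style references an attribute the
    dataset has not registered.
    """
    _check_style(ctx)
    ranges = _ranges(ctx.dataset)
    frame = _render_basemap(ctx.viewport, ctx.basemap, tile_provider)
    size = frame.size

    def composite(draw_fn, *args) -> None:
        nonlocal frame
        overlay = Image.new("RGBA", size, (0, 0, 0, 0))
        draw_fn(overlay, ctx, *args)
        frame = Image.alpha_composite(frame, overlay)

    if ctx.style.underlay.enabled:
        composite(_draw_underlay)
    if ctx.style.track.enabled:
        composite(_draw_tracks, ranges)
    if ctx.style.point.enabled:
        composite(_draw_points, ranges)
    if ctx.style.vector.enabled:
        composite(_draw_vectors, ranges)
    composite(_draw_legend, ranges)
    composite(lambda img, c: _draw_annotations(img, c))
    return frame


_TIMELINE_BG = (252, 252, 252, 255)
_PLAYHEAD_COLOR = (220, 20, 20, 255)


def render_timeline(
    dataset: Dataset, now: datetime, size: tuple[int, int] = (800, 160)
) -> Image.Image:
    """Render the timeline strip: one bar per enabled track, red playhead.

    Each bar spans the track's own time extent, positioned proportionally
    within the dataset's overall extent and filled with the track's
    categorical color; the red vertical line marks *now*.
    """
    w, h = size
    image = Image.new("RGBA", size, _TIMELINE_BG)
    draw = ImageDraw.Draw(image)
    font = _font(12)
    t0, t1 = dataset.time_extent
    total = max(1.0, (t1 - t0).total_seconds())
    label_w = 90
    x0, x1 = label_w, w - 10

    def time_to_x(t: datetime) -> float:
        return x0 + (x1 - x0) * (t - t0).total_seconds() / total

    enabled = [t for t in dataset.tracks if t.enabled]
    row_h = (h - 20) / max(1, len(enabled))
    for row, track in enumerate(enabled):
        ta, tb = track.time_extent
        y = 10 + row * row_h
        draw.text((6, y + row_h / 2 - 7), track.identifier, font=font, fill=_TEXT_COLOR)
        draw.rectangle(
            [time_to_x(ta), y + 2, max(time_to_x(tb), time_to_x(ta) + 1), y + row_h - 2],
            fill=categorical_color(track.identifier, dataset.identifiers),
        )
    px = min(max(time_to_x(now), x0), x1)
    draw.line([(px, 4), (px, h - 4)], fill=_PLAYHEAD_COLOR, width=2)
    return image
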