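"""Map attribute values onto visual variables.

Seven channels are available, mirroring a classical multivariate
cartography toolbox: line color, line width, point color, point size,
vector direction, vector color and vector length. Continuous attributes go
through a :class:`ColorRamp` or an affine size scale over the attribute's
registered range; the individual identifier gets stable categorical colors
instead of a gradient. A :class:`LegendLayout` models the seven legend
blocks (title plus one per channel) that overlay the rendered frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .animate import FadeSettings
from .trackstore import TrackPoint

__all__ = [
    "RGBA",
    "ColorRamp",
    "TrackLayer",
    "PointLayer",
    "VectorLayer",
    "UnderlaySettings",
    "VisualStyle",
    "VectorGlyph",
    "LegendLayout",
    "LEGEND_BLOCK_KINDS",
    "DEFAULT_CATEGORICAL_PALETTE",
    "interpolate_ramp",
    "scale_size",
    "categorical_color",
    "resolve_vector",
    "named_ramp",
]

RGBA = tuple[int, int, int, int]

#: Attribute name standing for "color by individual" rather than a gradient.
IDENTIFIER_ATTRIBUTE = "identifier"


@dataclass(frozen=True)
class ColorRamp:
    """A piecewise-linear color gradient with at least two RGBA stops."""

    stops: tuple[RGBA, ...]

    def __post_init__(self) -> None:
        if len(self.stops) < 2:
            raise ValueError("a color ramp needs at least two stops")


_NAMED_RAMPS: dict[str, ColorRamp] = {
    # diverging blue -> white -> red (tailwind/headwind style)
    "blue_red": ColorRamp(((24, 64, 220, 255), (245, 245, 245, 255), (215, 35, 25, 255))),
    # compact viridis-like sequential ramp
    "viridis": ColorRamp(
        (
            (68, 1, 84, 255),
            (59, 82, 139, 255),
            (33, 145, 140, 255),
            (94, 201, 98, 255),
            (253, 231, 37, 255),
        )
    ),
    "grayscale": ColorRamp(((0, 0, 0, 255), (255, 255, 255, 255))),
}


def named_ramp(name: str) -> ColorRamp:
    """Look up one of the shipped ramps: blue_red, viridis, grayscale."""
    try:
        return _NAMED_RAMPS[name]
    except KeyError:
        raise KeyError(f"unknown ramp {name!r}; available: {sorted(_NAMED_RAMPS)}") from None


#: 12 well-separated categorical colors, assigned by order of first appearance.
DEFAULT_CATEGORICAL_PALETTE: tuple[RGBA, ...] = (
    (230, 25, 75, 255),
    (60, 180, 75, 255),
    (255, 225, 25, 255),
    (0, 130, 200, 255),
    (245, 130, 48, 255),
    (145, 30, 180, 255),
    (70, 240, 240, 255),
    (240, 50, 230, 255),
    (210, 245, 60, 255),
    (250, 190, 190, 255),
    (0, 128, 128, 255),
    (170, 110, 40, 255),
)


# ---------------------------------------------------------------------------
# layer bindings


@dataclass(frozen=True)
class TrackLayer:
    """Line layer: color by attribute (or identifier) and width by attribute."""

    enabled: bool = True
    color_attr: str = IDENTIFIER_ATTRIBUTE
    ramp: ColorRamp = _NAMED_RAMPS["blue_red"]
    width_attr: str | None = None
    width_min_px: float = 1.0
    width_max_px: float = 6.0

    def __post_init__(self) -> None:
        if self.width_min_px > self.width_max_px:
            raise ValueError("width_min_px > width_max_px")


@dataclass(frozen=True)
class PointLayer:
    """Point-marker layer: color and size bound to attributes."""

    enabled: bool = False
    color_attr: str | None = None
    ramp: ColorRamp = _NAMED_RAMPS["viridis"]
    size_attr: str | None = None
    size_min_px: float = 2.0
    size_max_px: float = 10.0

    def __post_init__(self) -> None:
        if self.size_min_px > self.size_max_px:
            raise ValueError("size_min_px > size_max_px")


@dataclass(frozen=True)
class VectorLayer:
    """Vector glyphs: direction, length and color each bound to an attribute."""

    enabled: bool = False
    direction_attr: str | None = None
    length_attr: str | None = None
    length_min_px: float = 5.0
    length_max_px: float = 40.0
    color_attr: str | None = None
    ramp: ColorRamp = _NAMED_RAMPS["blue_red"]

    def __post_init__(self) -> None:
        if self.length_min_px > self.length_max_px:
            raise ValueError("length_min_px > length_max_px")


@dataclass(frozen=True)
class UnderlaySettings:
    """Faint full-history polyline drawn beneath the animated layers."""

    enabled: bool = False
    color: RGBA = (255, 255, 255, 255)
    weight_px: float = 1.0
    opacity: float = 0.4


@dataclass(frozen=True)
class VisualStyle:
    """Complete binding of data attributes to the visual variables."""

    track: TrackLayer = field(default_factory=TrackLayer)
    point: PointLayer = field(default_factory=PointLayer)
    vector: VectorLayer = field(default_factory=VectorLayer)
    underlay: UnderlaySettings = field(default_factory=UnderlaySettings)
    fade: FadeSettings = field(default_factory=FadeSettings)

    def referenced_attributes(self) -> set[str]:
        """Attribute names an enabled layer binds (identifier excluded)."""
        names: set[str] = set()
        if self.track.enabled:
            names.update({self.track.color_attr, self.track.width_attr})
        if self.point.enabled:
            names.update({self.point.color_attr, self.point.size_attr})
        if self.vector.enabled:
            names.update(
                {self.vector.direction_attr, self.vector.length_attr, self.vector.color_attr}
            )
        names.discard(None)
        names.discard(IDENTIFIER_ATTRIBUTE)
        return names


@dataclass(frozen=True)
class VectorGlyph:
    """A resolved vector: compass angle, pixel length, color."""

    angle_deg: float
    length_px: float
    color: RGBA

    def __post_init__(self) -> None:
        if self.length_px < 0:
            raise ValueError("vector length must be >= 0")


# ---------------------------------------------------------------------------
# scaling primitives


def _is_missing(value: float | None) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def interpolate_ramp(
    value: float | None, vmin: float, vmax: float, ramp: ColorRamp
) -> RGBA | None:
    """Resolve a value to a ramp color; None for missing values.

    The value is normalized over [vmin, vmax] with clamping, then
    interpolated piecewise-linearly per sRGB channel across the stops,
    rounding half-up to integer channels. A degenerate range (vmin ==
    vmax) maps everything to the ramp midpoint.
    """
    if _is_missing(value):
        return None
    if vmax > vmin:
        t = (value - vmin) / (vmax - vmin)
    else:
        t = 0.5
    t = min(1.0, max(0.0, t))

    stops = ramp.stops
    if t >= 1.0:
        return stops[-1]
    scaled = t * (len(stops) - 1)
    i = int(scaled)
    frac = scaled - i
    a, b = stops[i], stops[i + 1]
    return tuple(math.floor(a[c] + (b[c] - a[c]) * frac + 0.5) for c in range(4))  # type: ignore[return-value]


def scale_size(
    value: float | None,
    vmin: float,
    vmax: float,
    out_min: float,
    out_max: float,
) -> float | None:
    """Affine map of a clamped normalized value onto [out_min, out_max].

    Missing values yield None; a degenerate input range yields the output
    midpoint.
    """
    if out_min > out_max:
        raise ValueError("out_min > out_max")
    if _is_missing(value):
        return None
    if vmax <= vmin:
        return (out_min + out_max) / 2.0
    t = min(1.0, max(0.0, (value - vmin) / (vmax - vmin)))
    return out_min + t * (out_max - out_min)


def categorical_color(
    identifier: str,
    order: Sequence[str],
    palette: Sequence[RGBA] = DEFAULT_CATEGORICAL_PALETTE,
) -> RGBA:
    """Stable per-individual color: palette indexed by first-appearance order,
    cycling when there are more individuals than palette entries."""
    try:
        index = list(order).index(identifier)
    except ValueError:
        raise KeyError(f"unknown identifier {identifier!r}") from None
    return palette[index % len(palette)]


def resolve_vector(
    point: TrackPoint,
    style: VisualStyle,
    ranges: Mapping[str, tuple[float, float]],
) -> VectorGlyph | None:
    """Build the vector glyph for one point, or None when undrawable.

    The direction attribute is read as a compass bearing (degrees clockwise
    from north, normalized mod 360), length goes through the size scale on
    the layer's pixel range, and color through the layer's ramp. Missing
    direction or length suppresses the glyph.
    """
    layer = style.vector
    if not layer.enabled:
        raise ValueError("vector layer is not enabled")
    if layer.direction_attr is None or layer.length_attr is None:
        raise ValueError("vector layer needs direction and length attributes")

    direction = point.attributes.get(layer.direction_attr)
    length_value = point.attributes.get(layer.length_attr)
    if _is_missing(direction) or _is_missing(length_value):
        return None

    lmin, lmax = ranges[layer.length_attr]
    length_px = scale_size(length_value, lmin, lmax, layer.length_min_px, layer.length_max_px)

    color: RGBA = (0, 0, 0, 255)
    if layer.color_attr is not None:
        cmin, cmax = ranges[layer.color_attr]
        resolved = interpolate_ramp(point.attributes.get(layer.color_attr), cmin, cmax, layer.ramp)
        if resolved is not None:
            color = resolved
    return VectorGlyph(angle_deg=direction % 360.0, length_px=length_px, color=color)


# ---------------------------------------------------------------------------
# legend model

#: The seven legend block kinds, exactly.
LEGEND_BLOCK_KINDS: tuple[str, ...] = (
    "title",
    "line_color",
    "point_color",
    "vector_color",
    "line_width",
    "point_size",
    "vector_length",
)


@dataclass(frozen=True)
class LegendLayout:
    """Pixel positions and font size for the seven legend blocks.

    The model always knows all seven kinds; at render time only the blocks
    whose binding is enabled are drawn. Layouts serialize to plain dicts so
    they can be stored in the config file and reused across animations.
    """

    positions: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {
            kind: (10, 10 + 48 * i) for i, kind in enumerate(LEGEND_BLOCK_KINDS)
        }
    )
    font_size: int = 12

    def __post_init__(self) -> None:
        unknown = set(self.positions) - set(LEGEND_BLOCK_KINDS)
        if unknown:
            raise ValueError(f"unknown legend block kinds: {sorted(unknown)}")
        missing = set(LEGEND_BLOCK_KINDS) - set(self.positions)
        if missing:
            raise ValueError(f"legend layout missing blocks: {sorted(missing)}")

    @property
    def block_kinds(self) -> tuple[str, ...]:
        return LEGEND_BLOCK_KINDS

    def moved(self, kind: str, xy: tuple[int, int]) -> "LegendLayout":
        if kind not in LEGEND_BLOCK_KINDS:
            raise KeyError(kind)
        positions = dict(self.positions)
        positions[kind] = xy
        return replace(self, positions=positions)

    def enabled_blocks(self, style: VisualStyle) -> list[str]:
        """Blocks to draw, in model order, given the current bindings."""
        shown = {"title"}
        if style.track.enabled:
            shown.add("line_color")
            if style.track.width_attr is not None:
                shown.add("line_width")
        if style.point.enabled:
            if style.point.color_attr is not None:
                shown.add("point_color")
            if style.point.size_attr is not None:
                shown.add("point_size")
        if style.vector.enabled:
            if style.vector.color_attr is not None:
                shown.add("vector_color")
            if style.vector.length_attr is not None:
                shown.add("vector_length")
        return [k for k in LEGEND_BLOCK_KINDS if k in shown]

    def to_dict(self) -> dict:
        return {
            "positions": {k: list(v) for k, v in self.positions.items()},
            "font_size": self.font_size,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LegendLayout":
        return cls(
            positions={k: (int(v[0]), int(v[1])) for k, v in d["positions"].items()},
            font_size=int(d.get("font_size", 12)),
        )
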