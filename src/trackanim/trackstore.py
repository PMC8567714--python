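"""Core trajectory containers and the attribute registry.

A :class:`Dataset` holds one :class:`Track` per individual, each an ordered
sequence of :class:`TrackPoint` fixes carrying an open-ended map of numeric
attributes (movement parameters, Env-DATA annotations, bio-logger channels).
The registry side (:func:`register_attributes`) records, per attribute, the
observed value range plus a display alias and unit looked up in a small
bundled snapshot of known environmental variable names, so legends can be
labelled without any network service.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import datetime
from importlib import resources
from typing import Iterable, Mapping

log = logging.getLogger(__name__)

__all__ = [
    "TrackPoint",
    "Track",
    "Dataset",
    "AttributeInfo",
    "register_attributes",
    "round_range",
    "load_alias_snapshot",
]


@dataclass
class TrackPoint:
    """One GPS fix: position, instant, and ancillary numeric attributes.

    Coordinates are WGS84 degrees; ``attributes`` maps attribute name to a
    float, with ``math.nan`` marking a missing value.
    """

    identifier: str
    lon: float
    lat: float
    time: datetime
    attributes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} outside [-180, 180]")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")


@dataclass
class Track:
    """All fixes of one individual, sorted non-decreasing by time."""

    identifier: str
    points: list[TrackPoint]
    enabled: bool = True

    def __post_init__(self) -> None:
        for a, b in zip(self.points, self.points[1:]):
            if b.time < a.time:
                raise ValueError(f"track {self.identifier!r} not time-sorted")
        for p in self.points:
            if p.identifier != self.identifier:
                raise ValueError("point identifier does not match track")

    @property
    def time_extent(self) -> tuple[datetime, datetime]:
        return self.points[0].time, self.points[-1].time


@dataclass
class AttributeInfo:
    """Registry entry for one numeric attribute column."""

    name: str
    alias: str
    unit: str
    min: float
    max: float
    rounded: bool = False
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.min > self.max:
            raise ValueError(f"attribute {self.name!r}: min > max")

    @property
    def range(self) -> tuple[float, float]:
        return self.min, self.max


@dataclass
class Dataset:
    """A titled collection of tracks with their attribute registry."""

    title: str
    tracks: list[Track]
    attributes: list[AttributeInfo] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.tracks:
            raise ValueError("dataset has no tracks")

    # -- derived geometry -------------------------------------------------

    def iter_points(self, enabled_only: bool = False) -> Iterable[TrackPoint]:
        for track in self.tracks:
            if enabled_only and not track.enabled:
                continue
            yield from track.points

    @property
    def time_extent(self) -> tuple[datetime, datetime]:
        times = [p.time for p in self.iter_points()]
        return min(times), max(times)

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        """(lon_min, lat_min, lon_max, lat_max) over every point."""
        lons = [p.lon for p in self.iter_points()]
        lats = [p.lat for p in self.iter_points()]
        return min(lons), min(lats), max(lons), max(lats)

    @property
    def identifiers(self) -> list[str]:
        return [t.identifier for t in self.tracks]

    def track(self, identifier: str) -> Track:
        for t in self.tracks:
            if t.identifier == identifier:
                return t
        raise KeyError(identifier)

    def attribute(self, name: str) -> AttributeInfo:
        for a in self.attributes:
            if a.name == name:
                return a
        raise KeyError(name)

    @property
    def attribute_names(self) -> list[str]:
        return [a.name for a in self.attributes]


# ---------------------------------------------------------------------------
# alias snapshot


def load_alias_snapshot() -> dict[str, tuple[str, str]]:
    """Load the bundled name -> (alias, unit) table for known variables.

    The table is a tab-separated text file shipped with the package; users
    can point :func:`register_attributes` at their own mapping instead.
    Lookup is case-insensitive on the raw column name.
    """
    table: dict[str, tuple[str, str]] = {}
    text = resources.files("trackanim.data").joinpath("env_aliases.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        name = parts[0].strip().lower()
        alias = parts[1].strip() if len(parts) > 1 else name
        unit = parts[2].strip() if len(parts) > 2 else ""
        table[name] = (alias, unit)
    return table


def register_attributes(
    dataset: Dataset,
    alias_table: Mapping[str, tuple[str, str]] | None = None,
) -> list[AttributeInfo]:
    """Build the attribute registry for every numeric column in *dataset*.

    Ranges (min/max of non-missing values) are computed over all kept
    individuals regardless of their enabled flag, so toggling tracks never
    rescales the symbology mid-animation. Names found in the alias snapshot
    get its alias and unit; unknown names fall back to ``alias = name``,
    empty unit. Attributes with no non-missing value at all are dropped
    with a warning.

    The registry is also assigned to ``dataset.attributes`` and returned.
    """
    if alias_table is None:
        alias_table = load_alias_snapshot()
    lookup = {str(k).lower(): v for k, v in alias_table.items()}

    names: list[str] = []
    for p in dataset.iter_points():
        for name in p.attributes:
            if name not in names:
                names.append(name)

    infos: list[AttributeInfo] = []
    for name in names:
        values = [
            v
            for p in dataset.iter_points()
            if (v := p.attributes.get(name)) is not None and not math.isnan(v)
        ]
        if not values:
            log.warning("attribute %r has no non-missing values; excluded", name)
            continue
        alias, unit = lookup.get(name.lower(), (name, ""))
        infos.append(AttributeInfo(name=name, alias=alias, unit=unit, min=min(values), max=max(values)))
    dataset.attributes = infos
    return infos


# ---------------------------------------------------------------------------
# range rounding


def _round_sig(x: float, up: bool, digits: int = 2) -> float:
    if x == 0.0:
        return 0.0
    exp = math.floor(math.log10(abs(x)))
    quantum = 10.0 ** (exp - (digits - 1))
    if quantum == 0.0 or not math.isfinite(quantum):
        return x  # subnormal or overflowing scale: leave untouched
    rounded = (math.ceil if up else math.floor)(x / quantum) * quantum
    # guard the containment guarantee against float rounding in the product
    if up and rounded < x:
        rounded += quantum
    elif not up and rounded > x:
        rounded -= quantum
    return rounded


def round_range(vmin: float, vmax: float) -> tuple[float, float]:
    """Round a value range outward to two significant digits.

    The minimum is floored, the maximum is ceiled, so the result always
    contains the input interval — legends get tidy bounds without ever
    clipping observed values.
    """
    if vmin > vmax:
        raise ValueError("vmin > vmax")
    return _round_sig(vmin, up=False), _round_sig(vmax, up=True)
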