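"""Read tracking CSVs, classify every record, and build a clean Dataset.

Input is conventional GPS/telemetry tracking data as CSV with at least four
required columns — individual identifier, longitude, latitude, timestamp —
plus any number of numeric attribute columns. Movebank's default header
names are recognised automatically; any other dialect is handled through an
explicit column mapping which is remembered (keyed by file name + content
hash) so it only has to be supplied once per data file.

Every row is classified into exactly one :class:`RecordCategory`; rows
flagged invisible, with corrupt coordinates or required fields, dated
before 1800, or dated more than 20 years into the future are ignored, and
the per-category tally is returned as a :class:`ValidationReport` whose
``summary_lines`` mirror the status summary a user sees on load.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import datetime
from enum import Enum
from pathlib import Path

import pandas as pd

from .config import ConfigStore, source_key
from .trackstore import Dataset, Track, TrackPoint, register_attributes

__all__ = [
    "MOVEBANK_DEFAULTS",
    "REQUIRED_ROLES",
    "DEFAULT_DATETIME_FORMAT",
    "HeaderMapping",
    "RecordCategory",
    "ValidationReport",
    "RawRecord",
    "MappingRequiredError",
    "TimestampParseError",
    "map_headers",
    "parse_timestamp",
    "classify_record",
    "load_tracks",
]

#: Required roles and their Movebank default header names.
MOVEBANK_DEFAULTS: dict[str, str] = {
    "identifier": "individual-local-identifier",
    "longitude": "location-long",
    "latitude": "location-lat",
    "timestamp": "study-local-timestamp",
}
REQUIRED_ROLES: tuple[str, ...] = tuple(MOVEBANK_DEFAULTS)

DEFAULT_DATETIME_FORMAT = "yyyy-MM-dd HH:mm:ss"
#: Formats tried automatically before asking for a custom pattern. "iso8601"
#: accepts 2008-06-01T12:30:00 with optional fractional seconds.
AUTO_DATETIME_FORMATS: tuple[str, ...] = (DEFAULT_DATETIME_FORMAT, "iso8601")

OPTIONAL_TITLE_COLUMN = "study-name"
OPTIONAL_VISIBLE_COLUMN = "visible"


class MappingRequiredError(ValueError):
    """Required columns could not be resolved; lists the missing roles."""

    def __init__(self, missing: list[str]):
        self.missing = list(missing)
        super().__init__(
            "cannot resolve required columns for roles: " + ", ".join(missing)
        )


class TimestampParseError(ValueError):
    """A timestamp string did not match the expected format."""

    def __init__(self, value: str, fmt: str):
        self.value = value
        self.format = fmt
        super().__init__(f"timestamp {value!r} does not match format {fmt!r}")


@dataclass(frozen=True)
class HeaderMapping:
    """Resolved column roles plus per-file parsing settings."""

    identifier_column: str
    longitude_column: str
    latitude_column: str
    timestamp_column: str
    datetime_format: str = DEFAULT_DATETIME_FORMAT
    discarded_columns: tuple[str, ...] = ()
    source_key: str = ""

    def __post_init__(self) -> None:
        required = (
            self.identifier_column,
            self.longitude_column,
            self.latitude_column,
            self.timestamp_column,
        )
        if any(not c for c in required):
            raise ValueError("required column names must be non-empty")
        if len(set(required)) != 4:
            raise ValueError("required column names must be pairwise distinct")
        if not self.datetime_format:
            raise ValueError("datetime_format must be non-empty")
        clash = set(self.discarded_columns) & set(required)
        if clash:
            raise ValueError(f"discarded_columns contains required columns: {clash}")

    def to_dict(self) -> dict:
        return {
            "identifier_column": self.identifier_column,
            "longitude_column": self.longitude_column,
            "latitude_column": self.latitude_column,
            "timestamp_column": self.timestamp_column,
            "datetime_format": self.datetime_format,
            "discarded_columns": list(self.discarded_columns),
            "source_key": self.source_key,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HeaderMapping":
        d = dict(d)
        d["discarded_columns"] = tuple(d.get("discarded_columns", ()))
        return cls(**d)


class RecordCategory(Enum):
    """Exhaustive, mutually exclusive classification of an input row."""

    MARKED_INVISIBLE = "marked invisible"
    CORRUPT_COORDINATES = "corrupt coordinates"
    CORRUPT_REQUIRED_FIELD = "corrupt required field"
    DATE_BEFORE_1800 = "date before 1800"
    DATE_1800_TO_1980 = "date between 1800 and 1980"
    DATE_FUTURE_WITHIN_20Y = "date within 20 years in the future"
    DATE_FUTURE_BEYOND_20Y = "date beyond 20 years in the future"
    VALID = "valid"


#: Categories whose rows are kept for visualization.
KEPT_CATEGORIES = frozenset(
    {
        RecordCategory.VALID,
        RecordCategory.DATE_1800_TO_1980,
        RecordCategory.DATE_FUTURE_WITHIN_20Y,
    }
)


@dataclass(frozen=True)
class RawRecord:
    """One CSV row before any interpretation: index plus raw text values."""

    row_index: int
    values: dict[str, str]


@dataclass
class ValidationReport:
    """Per-category row counts from one load."""

    counts: dict[RecordCategory, int] = field(
        default_factory=lambda: {c: 0 for c in RecordCategory}
    )

    @property
    def total_rows(self) -> int:
        return sum(self.counts.values())

    @property
    def kept_rows(self) -> int:
        return sum(self.counts[c] for c in KEPT_CATEGORIES)

    def summary_lines(self) -> list[str]:
        """Human-readable load summary, one line per category."""
        status = lambda c: "Kept" if c in KEPT_CATEGORIES else "Ignored"
        lines = [
            f"{c.value.capitalize()}: {self.counts[c]} ({status(c)})"
            for c in RecordCategory
        ]
        lines.append(f"Total data points available for visualization: {self.kept_rows}")
        return lines


# ---------------------------------------------------------------------------
# header mapping


def map_headers(
    header_row: list[str],
    config: ConfigStore | None = None,
    *,
    key: str = "",
    explicit: dict[str, str] | None = None,
    datetime_format: str | None = None,
    discarded_columns: tuple[str, ...] = (),
) -> HeaderMapping:
    """Resolve which columns play the four required roles.

    Resolution order: Movebank default header names if all four are present;
    otherwise an ``explicit`` role -> column-name mapping (persisted to
    *config* under *key* so it is only needed once per data file); otherwise
    a mapping previously stored in *config*. Raises
    :class:`MappingRequiredError` naming the unresolved roles when none
    applies.
    """
    if not header_row:
        raise ValueError("header_row is empty")
    header_set = set(header_row)

    if explicit is not None:
        mapping = HeaderMapping(
            identifier_column=explicit["identifier"],
            longitude_column=explicit["longitude"],
            latitude_column=explicit["latitude"],
            timestamp_column=explicit["timestamp"],
            datetime_format=datetime_format or DEFAULT_DATETIME_FORMAT,
            discarded_columns=tuple(discarded_columns),
            source_key=key,
        )
        missing = [r for r in REQUIRED_ROLES if explicit[r] not in header_set]
        if missing:
            raise MappingRequiredError(missing)
        if config is not None and key:
            config.store_header_mapping(key, mapping.to_dict())
        return mapping

    if all(col in header_set for col in MOVEBANK_DEFAULTS.values()):
        return HeaderMapping(
            identifier_column=MOVEBANK_DEFAULTS["identifier"],
            longitude_column=MOVEBANK_DEFAULTS["longitude"],
            latitude_column=MOVEBANK_DEFAULTS["latitude"],
            timestamp_column=MOVEBANK_DEFAULTS["timestamp"],
            datetime_format=datetime_format or DEFAULT_DATETIME_FORMAT,
            discarded_columns=tuple(discarded_columns),
            source_key=key,
        )

    if config is not None and key:
        stored = config.get_header_mapping(key)
        if stored is not None:
            return HeaderMapping.from_dict(stored)

    missing = [
        role for role, col in MOVEBANK_DEFAULTS.items() if col not in header_set
    ]
    raise MappingRequiredError(missing)


# ---------------------------------------------------------------------------
# timestamp parsing

_PATTERN_TOKENS = [
    ("yyyy", "%Y"),
    ("MM", "%m"),
    ("dd", "%d"),
    ("HH", "%H"),
    ("mm", "%M"),
    ("ss", "%S"),
]


def _pattern_to_strptime(fmt: str) -> str:
    out = fmt.replace("%", "%%")
    for token, directive in _PATTERN_TOKENS:
        out = out.replace(token, directive)
    return out


def parse_timestamp(value: str, fmt: str = DEFAULT_DATETIME_FORMAT) -> datetime:
    """Parse a timestamp using a ``yyyy-MM-dd HH:mm:ss``-style pattern.

    Patterns use the familiar letter vocabulary (``yyyy`` year, ``MM``
    month, ``dd`` day, ``HH`` hour, ``mm`` minute, ``ss`` second). The
    special format name ``"iso8601"`` accepts ISO strings with a ``T``
    separator and optional fractional seconds. Returned instants are
    timezone-naive and interpreted as UTC. Raises
    :class:`TimestampParseError` carrying the offending value on mismatch.
    """
    value = value.strip()
    try:
        if fmt == "iso8601":
            parsed = datetime.fromisoformat(value)
            if parsed.tzinfo is not None:
                parsed = parsed.replace(tzinfo=None)
            return parsed
        return datetime.strptime(value, _pattern_to_strptime(fmt))
    except ValueError:
        raise TimestampParseError(value, fmt) from None


def _try_parse(value: str, mapping: HeaderMapping) -> datetime:
    formats = [mapping.datetime_format]
    formats += [f for f in AUTO_DATETIME_FORMATS if f not in formats]
    for fmt in formats[:-1]:
        try:
            return parse_timestamp(value, fmt)
        except TimestampParseError:
            continue
    return parse_timestamp(value, formats[-1])


# ---------------------------------------------------------------------------
# record classification

_INVISIBLE_VALUES = {"0", "false"}
_NUMBER_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def _shift_years(t: datetime, years: int) -> datetime:
    try:
        return t.replace(year=t.year + years)
    except ValueError:  # Feb 29 in a non-leap target year
        return t.replace(year=t.year + years, day=28)


def classify_record(
    record: RawRecord,
    mapping: HeaderMapping,
    reference_now: datetime,
) -> RecordCategory:
    """Assign a raw row to exactly one category; first matching rule wins.

    Rule order: visible flag false/0; corrupt coordinates (non-numeric or
    outside WGS84 ranges); missing/unparseable required field; year before
    1800; year 1800–1980 inclusive (kept, reported separately); more than
    20 calendar years after *reference_now* (ignored) vs. at most 20 years
    ahead (kept); otherwise valid. *reference_now* is always an explicit
    argument — the classifier never reads the wall clock.
    """
    values = record.values

    visible = values.get(OPTIONAL_VISIBLE_COLUMN, "").strip().lower()
    if visible in _INVISIBLE_VALUES:
        return RecordCategory.MARKED_INVISIBLE

    lon_text = values.get(mapping.longitude_column, "").strip()
    lat_text = values.get(mapping.latitude_column, "").strip()
    if not (_NUMBER_RE.match(lon_text) and _NUMBER_RE.match(lat_text)):
        return RecordCategory.CORRUPT_COORDINATES
    lon, lat = float(lon_text), float(lat_text)
    if not (-180.0 <= lon <= 180.0 and -90.0 <= lat <= 90.0):
        return RecordCategory.CORRUPT_COORDINATES

    if not values.get(mapping.identifier_column, "").strip():
        return RecordCategory.CORRUPT_REQUIRED_FIELD
    ts_text = values.get(mapping.timestamp_column, "").strip()
    if not ts_text:
        return RecordCategory.CORRUPT_REQUIRED_FIELD
    try:
        ts = _try_parse(ts_text, mapping)
    except TimestampParseError:
        return RecordCategory.CORRUPT_REQUIRED_FIELD

    if ts.year < 1800:
        return RecordCategory.DATE_BEFORE_1800
    if ts.year <= 1980:
        return RecordCategory.DATE_1800_TO_1980
    horizon = _shift_years(reference_now, 20)
    if ts > horizon:
        return RecordCategory.DATE_FUTURE_BEYOND_20Y
    if ts > reference_now:
        return RecordCategory.DATE_FUTURE_WITHIN_20Y
    return RecordCategory.VALID


# ---------------------------------------------------------------------------
# loading


def _is_number(text: str) -> bool:
    return bool(_NUMBER_RE.match(text.strip()))


def load_tracks(
    path: str | Path,
    mapping: HeaderMapping | None = None,
    reference_now: datetime | None = None,
    *,
    config: ConfigStore | None = None,
    explicit: dict[str, str] | None = None,
    title: str | None = None,
) -> tuple[Dataset, ValidationReport]:
    """Load a tracking CSV into a :class:`Dataset` plus its load report.

    Rows in ignored categories are excluded; kept rows are grouped into
    tracks by identifier (ordered by first appearance) and time-sorted.
    Columns listed in ``mapping.discarded_columns`` are dropped; remaining
    non-required columns become attributes. Text-valued (categorical)
    columns are not supported as attributes and are skipped with a notice
    in the report. When *mapping* is omitted it is resolved via
    :func:`map_headers` (Movebank defaults, then the config store).

    *reference_now* anchors the future-date rules; it defaults to the
    current run's start so tests can pin it explicitly.
    """
    path = Path(path)
    if reference_now is None:
        reference_now = datetime.now()

    frame = pd.read_csv(path, dtype=str, keep_default_na=False, engine="python")
    header = list(frame.columns)
    if mapping is None:
        key = source_key(path) if (config is not None or explicit is not None) else ""
        mapping = map_headers(header, config, key=key, explicit=explicit)
    required = {
        mapping.identifier_column,
        mapping.longitude_column,
        mapping.latitude_column,
        mapping.timestamp_column,
    }
    missing_cols = required - set(header)
    if missing_cols:
        raise MappingRequiredError(sorted(missing_cols))

    attr_columns = [
        c
        for c in header
        if c not in required
        and c not in mapping.discarded_columns
        and c not in (OPTIONAL_TITLE_COLUMN, OPTIONAL_VISIBLE_COLUMN)
    ]

    report = ValidationReport()
    kept: list[tuple[str, float, float, datetime, dict[str, str]]] = []
    for row_index, row in enumerate(frame.itertuples(index=False)):
        values = dict(zip(header, row))
        category = classify_record(RawRecord(row_index, values), mapping, reference_now)
        report.counts[category] += 1
        if category in KEPT_CATEGORIES:
            kept.append(
                (
                    values[mapping.identifier_column].strip(),
                    float(values[mapping.longitude_column]),
                    float(values[mapping.latitude_column]),
                    _try_parse(values[mapping.timestamp_column], mapping),
                    {c: values.get(c, "") for c in attr_columns},
                )
            )

    # categorical columns cannot be mapped to visual variables; drop them
    numeric_columns = [
        c
        for c in attr_columns
        if all(_is_number(r[4][c]) or not r[4][c].strip() for r in kept)
    ]

    by_id: dict[str, list[TrackPoint]] = {}
    for identifier, lon, lat, ts, raw_attrs in kept:
        attrs = {
            c: float(raw_attrs[c]) if raw_attrs[c].strip() else float("nan")
            for c in numeric_columns
        }
        by_id.setdefault(identifier, []).append(
            TrackPoint(identifier=identifier, lon=lon, lat=lat, time=ts, attributes=attrs)
        )

    if title is None:
        if OPTIONAL_TITLE_COLUMN in header:
            names = [v for v in frame[OPTIONAL_TITLE_COLUMN] if v.strip()]
            title = names[0].strip() if names else path.stem
        else:
            title = path.stem

    tracks = [
        Track(identifier=i, points=sorted(pts, key=lambda p: p.time))
        for i, pts in by_id.items()
    ]
    if not tracks:
        raise ValueError(f"{path}: no rows kept for visualization")
    dataset = Dataset(title=title, tracks=tracks)
    register_attributes(dataset)
    return dataset, report
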