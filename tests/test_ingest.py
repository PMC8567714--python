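"""Header mapping, timestamp parsing, record classification, loading."""

import csv
from datetime import datetime

import pytest

from trackanim import ConfigStore, classify_record, load_tracks, map_headers, parse_timestamp
from trackanim.config import source_key
from trackanim.ingest import (
    HeaderMapping,
    MappingRequiredError,
    RawRecord,
    RecordCategory,
    TimestampParseError,
)

NOW = datetime(2026, 1, 1)

MOVEBANK_HEADER = [
    "individual-local-identifier",
    "location-long",
    "location-lat",
    "study-local-timestamp",
    "visible",
]


def make_mapping(**overrides):
    defaults = dict(
        identifier_column="individual-local-identifier",
        longitude_column="location-long",
        latitude_column="location-lat",
        timestamp_column="study-local-timestamp",
    )
    defaults.update(overrides)
    return HeaderMapping(**defaults)


def record(lon="10.0", lat="50.0", ts="2008-06-01 12:30:00", ident="a", visible=""):
    values = {
        "individual-local-identifier": ident,
        "location-long": lon,
        "location-lat": lat,
        "study-local-timestamp": ts,
    }
    if visible != "":
        values["visible"] = visible
    return RawRecord(0, values)


class TestMapHeaders:
    def test_movebank_defaults_resolve_automatically(self):
        mapping = map_headers(MOVEBANK_HEADER)
        assert mapping.identifier_column == "individual-local-identifier"
        assert mapping.longitude_column == "location-long"
        assert mapping.latitude_column == "location-lat"
        assert mapping.timestamp_column == "study-local-timestamp"

    def test_custom_mapping_is_remembered_per_file(self, tmp_path):
        config = ConfigStore(tmp_path / "config.yaml")
        header = ["id", "lon", "lat", "time"]
        explicit = {"identifier": "id", "longitude": "lon", "latitude": "lat", "timestamp": "time"}
        first = map_headers(header, config, key="file:abc", explicit=explicit)
        # second call for the same file resolves without user input
        second = map_headers(header, config, key="file:abc")
        assert second == first

    def test_missing_required_column_raises_with_roles(self):
        with pytest.raises(MappingRequiredError) as excinfo:
            map_headers(["id", "lon", "time"])
        assert "latitude" in excinfo.value.missing

    def test_required_columns_must_be_distinct(self):
        with pytest.raises(ValueError):
            make_mapping(longitude_column="location-lat")

    def test_discarded_cannot_contain_required(self):
        with pytest.raises(ValueError):
            make_mapping(discarded_columns=("location-lat",))

    def test_stored_mapping_round_trips(self, tmp_path):
        config = ConfigStore(tmp_path / "c.yaml")
        mapping = make_mapping(discarded_columns=("battery",), source_key="k")
        config.store_header_mapping("k", mapping.to_dict())
        reloaded = ConfigStore(tmp_path / "c.yaml")
        assert HeaderMapping.from_dict(reloaded.get_header_mapping("k")) == mapping

    def test_source_key_tracks_content(self, tmp_path):
        a = tmp_path / "a.csv"
        a.write_text("x\n1\n")
        key1 = source_key(a)
        a.write_text("x\n2\n")
        assert source_key(a) != key1


class TestParseTimestamp:
    @pytest.mark.parametrize(
        "value, fmt, expected",
        [
            ("2008-06-01 12:30:00", "yyyy-MM-dd HH:mm:ss", datetime(2008, 6, 1, 12, 30)),
            ("01/06/2008 12:30", "dd/MM/yyyy HH:mm", datetime(2008, 6, 1, 12, 30)),
            ("2008-06-01T12:30:00.250", "iso8601", datetime(2008, 6, 1, 12, 30, 0, 250000)),
        ],
    )
    def test_pattern_vocabulary(self, value, fmt, expected):
        assert parse_timestamp(value, fmt) == expected

    def test_parse_error_carries_value(self):
        with pytest.raises(TimestampParseError) as excinfo:
            parse_timestamp("not-a-date", "yyyy-MM-dd")
        assert excinfo.value.value == "not-a-date"


class TestClassifyRecord:
    MAPPING = None

    @pytest.mark.parametrize(
        "rec, expected",
        [
            (record(visible="0"), RecordCategory.MARKED_INVISIBLE),
            (record(visible="false"), RecordCategory.MARKED_INVISIBLE),
            (record(visible="1"), RecordCategory.VALID),
            (record(lat="95.0"), RecordCategory.CORRUPT_COORDINATES),
            (record(lon="181.0"), RecordCategory.CORRUPT_COORDINATES),
            (record(lon="abc"), RecordCategory.CORRUPT_COORDINATES),
            (record(ident=""), RecordCategory.CORRUPT_REQUIRED_FIELD),
            (record(ts=""), RecordCategory.CORRUPT_REQUIRED_FIELD),
            (record(ts="garbage"), RecordCategory.CORRUPT_REQUIRED_FIELD),
            (record(ts="1799-12-31 23:59:59"), RecordCategory.DATE_BEFORE_1800),
            (record(ts="1800-01-01 00:00:00"), RecordCategory.DATE_1800_TO_1980),
            (record(ts="1900-01-01 00:00:00"), RecordCategory.DATE_1800_TO_1980),
            (record(ts="1980-12-31 23:59:59"), RecordCategory.DATE_1800_TO_1980),
            (record(ts="1981-01-01 00:00:00"), RecordCategory.VALID),
            (record(ts="2008-06-01 12:30:00"), RecordCategory.VALID),
            (record(ts="2036-01-01 00:00:00"), RecordCategory.DATE_FUTURE_WITHIN_20Y),
            # inclusive horizon: exactly +20 years is kept, one second beyond ignored
            (record(ts="2046-01-01 00:00:00"), RecordCategory.DATE_FUTURE_WITHIN_20Y),
            (record(ts="2046-01-01 00:00:01"), RecordCategory.DATE_FUTURE_BEYOND_20Y),
            (record(ts="2051-01-01 00:00:00"), RecordCategory.DATE_FUTURE_BEYOND_20Y),
        ],
    )
    def test_rule_order_and_boundaries(self, rec, expected):
        assert classify_record(rec, make_mapping(), NOW) == expected

    def test_invisible_wins_over_corrupt_coordinates(self):
        rec = record(lat="95.0", visible="0")
        assert classify_record(rec, make_mapping(), NOW) == RecordCategory.MARKED_INVISIBLE

    def test_total_function_over_random_rows(self):
        # any raw row lands in exactly one category without raising
        import random

        rng = random.Random(0)
        fields = ["", "abc", "10.0", "95.0", "-200", "2008-06-01 12:30:00", "1700-01-01 00:00:00"]
        for _ in range(300):
            rec = record(
                lon=rng.choice(fields),
                lat=rng.choice(fields),
                ts=rng.choice(fields),
                ident=rng.choice(["", "a"]),
                visible=rng.choice(["", "0", "1", "false"]),
            )
            assert classify_record(rec, make_mapping(), NOW) in RecordCategory


class TestLoadTracks:
    def test_fixture_counts_and_grouping(self, small_csv, small_spec):
        dataset, report = load_tracks(small_csv, reference_now=NOW)
        expected_rows = small_spec.n_individuals * small_spec.n_points_per_track
        assert report.kept_rows == expected_rows
        assert report.total_rows == expected_rows
        assert len(dataset.tracks) == small_spec.n_individuals
        for track in dataset.tracks:
            times = [p.time for p in track.points]
            assert times == sorted(times)

    def test_idempotent_loading(self, small_csv):
        first = load_tracks(small_csv, reference_now=NOW)
        second = load_tracks(small_csv, reference_now=NOW)
        assert first[1].counts == second[1].counts
        for t1, t2 in zip(first[0].tracks, second[0].tracks):
            assert [(p.lon, p.lat, p.time) for p in t1.points] == [
                (p.lon, p.lat, p.time) for p in t2.points
            ]

    def test_title_from_study_name_column(self, small_csv, small_spec):
        dataset, _ = load_tracks(small_csv, reference_now=NOW)
        assert dataset.title == small_spec.title

    def test_discarded_columns_dropped(self, small_csv):
        mapping = make_mapping(discarded_columns=("ndvi",))
        dataset, _ = load_tracks(small_csv, mapping, reference_now=NOW)
        assert "ndvi" not in dataset.attribute_names
        assert "tail_wind" in dataset.attribute_names

    def test_categorical_column_not_an_attribute(self, tmp_path):
        path = tmp_path / "cat.csv"
        with path.open("w", newline="") as handle:
            writer = csv.writer(handle)
            writer.writerow(MOVEBANK_HEADER[:4] + ["label", "value"])
            writer.writerow(["a", "10", "50", "2008-06-01 00:00:00", "resting", "1.5"])
            writer.writerow(["a", "10.1", "50", "2008-06-01 01:00:00", "flying", "2.5"])
        dataset, _ = load_tracks(path, reference_now=NOW)
        assert dataset.attribute_names == ["value"]

    def test_summary_mirrors_category_table(self, small_csv):
        _, report = load_tracks(small_csv, reference_now=NOW)
        lines = report.summary_lines()
        assert len(lines) == len(RecordCategory) + 1  # one per category + total
        assert any("available for visualization" in line for line in lines)
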