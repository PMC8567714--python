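"""Great-circle movement parameters vs. independent geodesic oracles."""

import math
import subprocess
from datetime import datetime, timedelta

import numpy as np
import pytest

from trackanim import Track, TrackPoint, computed_speed, haversine_distance, move_azimuth
from trackanim.derive import EARTH_RADIUS_M, add_movement_attributes

T0 = datetime(2008, 6, 1)


def make_track(coords, hours_apart=1.0):
    points = [
        TrackPoint("a", lon, lat, T0 + timedelta(hours=i * hours_apart))
        for i, (lon, lat) in enumerate(coords)
    ]
    return Track("a", points)


# -- independent oracle: tangent-vector bearing + Vincenty-style arc ---------


def oracle_distance(lon1, lat1, lon2, lat2):
    """Arc length via the arctan2 (Vincenty sphere) formula."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dlon = math.radians(lon2 - lon1)
    num = math.hypot(
        math.cos(phi2) * math.sin(dlon),
        math.cos(phi1) * math.sin(phi2) - math.sin(phi1) * math.cos(phi2) * math.cos(dlon),
    )
    den = math.sin(phi1) * math.sin(phi2) + math.cos(phi1) * math.cos(phi2) * math.cos(dlon)
    return EARTH_RADIUS_M * math.atan2(num, den)


def oracle_bearing(lon1, lat1, lon2, lat2):
    """Initial bearing via 3-D unit vectors and the local east/north frame."""

    def unit(lon, lat):
        lam, phi = math.radians(lon), math.radians(lat)
        return np.array(
            [math.cos(phi) * math.cos(lam), math.cos(phi) * math.sin(lam), math.sin(phi)]
        )

    p1, p2 = unit(lon1, lat1), unit(lon2, lat2)
    tangent = p2 - np.dot(p1, p2) * p1
    east = np.cross([0.0, 0.0, 1.0], p1)
    east = east / np.linalg.norm(east)
    north = np.cross(p1, east)
    return math.degrees(math.atan2(np.dot(tangent, east), np.dot(tangent, north))) % 360.0


class TestHaversine:
    @pytest.mark.parametrize(
        "p1, p2, expected, tol",
        [
            ((0, 0), (0, 0), 0.0, 0.0),
            ((0, 0), (1, 0), 111194.93, 0.01),  # 2*pi*R/360 along the equator
            ((0, 0), (0, 90), 10007543.4, 0.1),  # quarter meridian pi*R/2
        ],
    )
    def test_reference_distances(self, p1, p2, expected, tol):
        assert haversine_distance(p1, p2) == pytest.approx(expected, abs=max(tol, 1e-9))

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            p1 = (rng.uniform(-180, 180), rng.uniform(-89, 89))
            p2 = (rng.uniform(-180, 180), rng.uniform(-89, 89))
            d = haversine_distance(p1, p2)
            assert d >= 0
            assert d == pytest.approx(haversine_distance(p2, p1), rel=1e-12)

    def test_agrees_with_independent_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            lon1, lon2 = rng.uniform(-180, 180, 2)
            lat1, lat2 = rng.uniform(-85, 85, 2)
            ours = haversine_distance((lon1, lat1), (lon2, lat2))
            ref = oracle_distance(lon1, lat1, lon2, lat2)
            assert ours == pytest.approx(ref, rel=1e-6, abs=1e-6)


class TestComputedSpeed:
    def test_speed_from_distance_and_interval(self):
        track = make_track([(0, 0), (1, 0)], hours_apart=1.0)
        speeds = computed_speed(track)
        assert math.isnan(speeds[0])
        assert speeds[1] == pytest.approx(111194.93 / 3600.0, abs=1e-3)

    def test_stationary_fix_is_zero(self):
        speeds = computed_speed(make_track([(5, 5), (5, 5)]))
        assert speeds[1] == 0.0

    def test_duplicate_timestamp_gives_missing(self):
        track = make_track([(0, 0), (1, 0)], hours_apart=0.0)
        assert math.isnan(computed_speed(track)[1])


class TestMoveAzimuth:
    @pytest.mark.parametrize(
        "coords, expected",
        [
            ([(0, 0), (0, 1)], 0.0),  # due north
            ([(0, 0), (1, 0)], 90.0),  # due east on the equator
            ([(0, 0), (1, 1)], 44.996),
        ],
    )
    def test_reference_bearings(self, coords, expected):
        assert move_azimuth(make_track(coords))[1] == pytest.approx(expected, abs=1e-3)

    def test_zero_displacement_missing(self):
        assert math.isnan(move_azimuth(make_track([(3, 3), (3, 3)]))[1])

    def test_range_and_oracle_agreement(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            lon1, lon2 = rng.uniform(-180, 180, 2)
            lat1, lat2 = rng.uniform(-85, 85, 2)
            az = move_azimuth(make_track([(lon1, lat1), (lon2, lat2)]))[1]
            assert 0.0 <= az < 360.0
            ref = oracle_bearing(lon1, lat1, lon2, lat2)
            delta = abs(az - ref) % 360.0
            assert min(delta, 360.0 - delta) < 1e-6

    def test_reversed_infinitesimal_step_flips_180(self):
        step = 1e-7
        forward = move_azimuth(make_track([(10, 0), (10 + step, step)]))[1]
        backward = move_azimuth(make_track([(10 + step, step), (10, 0)]))[1]
        assert abs((backward - forward) % 360.0 - 180.0) < 1e-6


class TestAddMovementAttributes:
    def test_adds_only_missing_attributes(self, small_dataset):
        # conftest dataset already ran add_movement_attributes once
        before = [
            p.attributes["computed_speed"] for p in small_dataset.iter_points()
        ]
        assert add_movement_attributes(small_dataset) == []
        after = [p.attributes["computed_speed"] for p in small_dataset.iter_points()]
        assert before == after

    def test_speed_nonnegative_azimuth_in_range(self, small_dataset):
        for p in small_dataset.iter_points():
            speed = p.attributes["computed_speed"]
            azimuth = p.attributes["move_azimuth"]
            assert math.isnan(speed) or speed >= 0
            assert math.isnan(azimuth) or 0 <= azimuth < 360


def test_distance_agrees_with_r_geosphere():
    """Cross-check great-circle distances against R's geosphere.

    (geosphere's ``bearing`` is ellipsoidal, so azimuths are checked
    against the in-suite spherical tangent-vector oracle instead.)
    """
    pairs = [
        (-91.0, -0.7, -80.0, -5.0),
        (0.0, 0.0, 1.0, 1.0),
        (179.5, 10.0, -179.5, 11.0),
        (-120.0, 34.0, -118.0, 36.0),
        (30.0, -60.0, 35.0, -55.0),
    ]
    lines = "\n".join(f"{a} {b} {c} {d}" for a, b, c, d in pairs)
    script = f"""
    suppressMessages(library(geosphere))
    pairs <- read.table(text="{lines}")
    for (i in seq_len(nrow(pairs))) {{
      p1 <- c(pairs[i,1], pairs[i,2]); p2 <- c(pairs[i,3], pairs[i,4])
      cat(sprintf("%.6f\\n", distHaversine(p1, p2, r=6371000)))
    }}
    """
    out = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, check=True
    ).stdout.split()
    for i, (lon1, lat1, lon2, lat2) in enumerate(pairs):
        r_dist = float(out[i])
        assert haversine_distance((lon1, lat1), (lon2, lat2)) == pytest.approx(r_dist, rel=1e-6)
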