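"""Visual-variable resolution: ramps, size scales, categorical colors, legend."""

import math
from datetime import datetime

import pytest
from hypothesis import given, settings, strategies as st

from trackanim import (
    ColorRamp,
    LegendLayout,
    TrackPoint,
    VisualStyle,
    categorical_color,
    interpolate_ramp,
    named_ramp,
    resolve_vector,
    scale_size,
)
from trackanim.styling import (
    DEFAULT_CATEGORICAL_PALETTE,
    LEGEND_BLOCK_KINDS,
    PointLayer,
    TrackLayer,
    VectorLayer,
)

BW = ColorRamp(((0, 0, 0, 255), (255, 255, 255, 255)))


class TestInterpolateRamp:
    def test_endpoints_exact(self):
        for ramp in (BW, named_ramp("blue_red"), named_ramp("viridis")):
            assert interpolate_ramp(0.0, 0.0, 1.0, ramp) == ramp.stops[0]
            assert interpolate_ramp(1.0, 0.0, 1.0, ramp) == ramp.stops[-1]

    def test_midpoint_of_black_white(self):
        assert interpolate_ramp(0.5, 0.0, 1.0, BW) == (128, 128, 128, 255)

    def test_clamps_out_of_range(self):
        assert interpolate_ramp(-5.0, 0.0, 1.0, BW) == BW.stops[0]
        assert interpolate_ramp(99.0, 0.0, 1.0, BW) == BW.stops[-1]

    def test_missing_value_has_no_color(self):
        assert interpolate_ramp(math.nan, 0.0, 1.0, BW) is None
        assert interpolate_ramp(None, 0.0, 1.0, BW) is None

    def test_degenerate_range_maps_to_midpoint(self):
        assert interpolate_ramp(7.0, 7.0, 7.0, BW) == (128, 128, 128, 255)

    @settings(max_examples=1000, derandomize=True)
    @given(
        a=st.floats(0, 1, allow_nan=False),
        b=st.floats(0, 1, allow_nan=False),
        stops=st.tuples(
            st.tuples(*[st.integers(0, 255)] * 4), st.tuples(*[st.integers(0, 255)] * 4)
        ),
    )
    def test_monotone_per_channel_for_two_stop_ramps(self, a, b, stops):
        ramp = ColorRamp(stops)
        lo, hi = min(a, b), max(a, b)
        c_lo = interpolate_ramp(lo, 0.0, 1.0, ramp)
        c_hi = interpolate_ramp(hi, 0.0, 1.0, ramp)
        for channel in range(4):
            increasing = ramp.stops[1][channel] >= ramp.stops[0][channel]
            if increasing:
                assert c_lo[channel] <= c_hi[channel]
            else:
                assert c_lo[channel] >= c_hi[channel]

    def test_requires_two_stops(self):
        with pytest.raises(ValueError):
            ColorRamp(((0, 0, 0, 255),))


class TestScaleSize:
    def test_endpoints_and_midpoint(self):
        assert scale_size(0.0, 0.0, 1.0, 2.0, 10.0) == 2.0
        assert scale_size(1.0, 0.0, 1.0, 2.0, 10.0) == 10.0
        assert scale_size(0.5, 0.0, 1.0, 2.0, 10.0) == 6.0

    def test_clamping(self):
        assert scale_size(5.0, 0.0, 1.0, 2.0, 10.0) == 10.0
        assert scale_size(-5.0, 0.0, 1.0, 2.0, 10.0) == 2.0

    def test_degenerate_range_gives_midpoint(self):
        assert scale_size(3.0, 3.0, 3.0, 2.0, 10.0) == 6.0

    def test_missing_value(self):
        assert scale_size(math.nan, 0.0, 1.0, 2.0, 10.0) is None

    @settings(max_examples=300, derandomize=True)
    @given(
        a=st.floats(0, 1),
        b=st.floats(0, 1),
        alpha=st.floats(0, 1),
    )
    def test_affinity_between_clamps(self, a, b, alpha):
        mix = alpha * a + (1 - alpha) * b
        left = scale_size(mix, 0.0, 1.0, 3.0, 9.0)
        right = alpha * scale_size(a, 0.0, 1.0, 3.0, 9.0) + (1 - alpha) * scale_size(
            b, 0.0, 1.0, 3.0, 9.0
        )
        assert left == pytest.approx(right, abs=1e-12)


class TestCategoricalColor:
    ORDER = [f"id{i}" for i in range(13)]

    def test_first_appearance_indexing(self):
        assert categorical_color("id0", self.ORDER) == DEFAULT_CATEGORICAL_PALETTE[0]
        assert categorical_color("id3", self.ORDER) == DEFAULT_CATEGORICAL_PALETTE[3]

    def test_stable_across_calls(self):
        assert categorical_color("id5", self.ORDER) == categorical_color("id5", self.ORDER)

    def test_palette_cycles(self):
        assert categorical_color("id12", self.ORDER) == DEFAULT_CATEGORICAL_PALETTE[0]

    def test_unknown_identifier_raises(self):
        with pytest.raises(KeyError):
            categorical_color("ghost", self.ORDER)


class TestResolveVector:
    STYLE = VisualStyle(
        vector=VectorLayer(
            enabled=True,
            direction_attr="wind_direction",
            length_attr="speed",
            length_min_px=5.0,
            length_max_px=40.0,
            color_attr="tail_wind",
            ramp=BW,
        )
    )
    RANGES = {"speed": (0.0, 20.0), "tail_wind": (-2.0, 2.0)}

    def point(self, **attrs):
        return TrackPoint("a", 0, 0, datetime(2008, 6, 1), attrs)

    def test_full_glyph_at_attribute_max(self):
        p = self.point(wind_direction=90.0, speed=20.0, tail_wind=2.0)
        glyph = resolve_vector(p, self.STYLE, self.RANGES)
        assert glyph.angle_deg == 90.0
        assert glyph.length_px == 40.0
        assert glyph.color == BW.stops[-1]

    def test_missing_direction_suppresses_glyph(self):
        p = self.point(speed=10.0, tail_wind=0.0)
        assert resolve_vector(p, self.STYLE, self.RANGES) is None

    def test_direction_normalized_mod_360(self):
        p = self.point(wind_direction=450.0, speed=10.0, tail_wind=0.0)
        assert resolve_vector(p, self.STYLE, self.RANGES).angle_deg == 90.0


class TestLegendLayout:
    def test_exactly_seven_block_kinds(self):
        layout = LegendLayout()
        assert len(layout.block_kinds) == 7
        assert set(layout.positions) == set(LEGEND_BLOCK_KINDS)

    def test_rendered_blocks_subset_of_enabled_bindings(self):
        layout = LegendLayout()
        style = VisualStyle(
            track=TrackLayer(enabled=True, width_attr="speed"),
            point=PointLayer(enabled=False),
        )
        blocks = layout.enabled_blocks(style)
        assert "line_color" in blocks and "line_width" in blocks
        assert "point_color" not in blocks and "vector_length" not in blocks
        assert set(blocks) <= set(LEGEND_BLOCK_KINDS)

    def test_layout_round_trips_through_dict(self):
        layout = LegendLayout().moved("title", (200, 300))
        assert LegendLayout.from_dict(layout.to_dict()) == layout

    def test_rejects_incomplete_positions(self):
        with pytest.raises(ValueError):
            LegendLayout(positions={"title": (0, 0)})
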