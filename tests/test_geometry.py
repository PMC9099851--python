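"""Geometry construction, strut placement and the inlet-velocity conversion."""

import json

import numpy as np
import pytest
import shapely
from hypothesis import given, settings, strategies as st

from bifurcbench.geometry import (
    BifurcationParams,
    GeometryError,
    build_bifurcation,
    inlet_velocity_from_flow,
    largest_remainder,
    make_channel,
    place_struts,
)


@pytest.fixture(scope="module")
def geom():
    return build_bifurcation()


class TestBuildBifurcation:
    def test_channel_widths_match_printed_dimensions(self, geom):
        # inlet face spans the proximal diameter; each outlet face spans its
        # branch diameter (faces are normal to the local axis)
        inlet = geom.tagged_segments("inlet")[0]
        assert np.linalg.norm(inlet[1] - inlet[0]) == pytest.approx(5.5, abs=1e-9)
        for tag, width in (("outlet_mb", 3.5), ("outlet_sb", 3.5)):
            seg = geom.tagged_segments(tag)[0]
            assert np.linalg.norm(seg[1] - seg[0]) == pytest.approx(width, abs=1e-9)

    def test_proximal_walls_are_parallel_at_half_width(self, geom):
        # horizontal wall edges are the proximal walls at y = +-D_prox/2
        ys = set()
        for i, j, t in geom.edges:
            if t != "wall":
                continue
            a, b = geom.vertices[i], geom.vertices[j]
            if abs(a[1] - b[1]) < 1e-12:
                ys.add(round(a[1], 9))
        assert ys == {2.75, -2.75}

    def test_mirror_symmetry_for_equal_branches(self, geom):
        v = geom.vertices
        mirrored = np.sort(np.round(np.column_stack([v[:, 0], -v[:, 1]]), 9), axis=0)
        assert np.allclose(np.sort(np.round(v, 9), axis=0), mirrored)

    def test_polygon_is_simple_with_one_inlet_two_outlets(self, geom):
        geom.validate()
        tags = [t for _, _, t in geom.edges]
        assert tags.count("inlet") == 1
        assert tags.count("outlet_mb") == 1
        assert tags.count("outlet_sb") == 1

    def test_ostium_endpoints_lie_on_boundary(self, geom):
        boundary = geom.polygon().exterior
        for p in geom.ostium_segment:
            assert boundary.distance(shapely.points(*p)) < 1e-9

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(angle_mb_sb=0.0),
            dict(angle_mb_sb=180.0),
            dict(D_prox=-1.0),
            dict(D_mb=0.0),
            dict(L_prox=0.0),
            dict(D_prox=3.0),  # proximal narrower than branches
        ],
    )
    def test_degenerate_parameters_rejected(self, kwargs):
        with pytest.raises(GeometryError):
            build_bifurcation(BifurcationParams(**kwargs))

    def test_area_matches_monte_carlo_estimate(self, geom):
        poly = geom.polygon()
        rng = np.random.default_rng(42)
        v = geom.vertices
        lo, hi = v.min(axis=0), v.max(axis=0)
        pts = lo + rng.random((2_000_000, 2)) * (hi - lo)
        frac = shapely.contains_xy(poly, pts[:, 0], pts[:, 1]).mean()
        mc_area = frac * np.prod(hi - lo)
        assert abs(mc_area - poly.area) / poly.area < 0.005

    def test_serialization_round_trip(self, geom):
        from bifurcbench.geometry import BifurcationGeometry2D

        back = BifurcationGeometry2D.from_dict(json.loads(geom.to_json()))
        assert np.allclose(back.vertices, geom.vertices)
        assert back.edges == geom.edges
        assert geom.to_wkt().startswith("POLYGON")


class TestPlaceStruts:
    def test_largest_remainder_counting_example(self, geom):
        layout = place_struts(geom, "KIO", mix=(0.80, 0.05, 0.15), seed=1,
                              n_struts=40)
        assert layout.counts() == (32, 2, 6)

    def test_bd_des_has_exactly_two_connector_struts(self, geom):
        layout = place_struts(geom, "BD-DES", mix=(0.97, 0.03, 0.0), seed=2,
                              n_struts=40)
        assert sum(s.is_connector for s in layout.struts) == 2
        assert len(layout.struts) == 40

    def test_same_seed_reproduces_layout_exactly(self, geom):
        a = place_struts(geom, "KIO", mix=(0.79, 0.05, 0.16), seed=7)
        b = place_struts(geom, "KIO", mix=(0.79, 0.05, 0.16), seed=7)
        assert a.to_json() == b.to_json()
        c = place_struts(geom, "KIO", mix=(0.79, 0.05, 0.16), seed=8)
        assert a.to_json() != c.to_json()

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(
        fl=st.floats(0.0, 0.3),
        ma=st.floats(0.0, 0.15),
        seed=st.integers(0, 10_000),
    )
    def test_apposition_labels_satisfy_rule(self, fl, ma, seed):
        geom = build_bifurcation()
        mix = (1.0 - fl - ma, ma, fl)
        layout = place_struts(geom, "KIO", mix=mix, seed=seed, n_struts=40)
        for s in layout.struts:
            assert s.apposition == s.expected_apposition()
            if s.apposition == "MA":
                assert s.wall_gap_um > s.thickness_um

    def test_infeasible_mix_rejected(self, geom):
        with pytest.raises(GeometryError):
            place_struts(geom, "KIO", mix=(1.0, 0.0, 0.0), seed=0, n_struts=500)
        with pytest.raises(GeometryError):
            place_struts(geom, "BD-DES", mix=(0.8, 0.1, 0.1), seed=0, n_struts=40)

    def test_floating_requires_an_ostium(self):
        channel = make_channel(5.5, 15.0)
        with pytest.raises(GeometryError):
            place_struts(channel, "KIO", mix=(0.8, 0.05, 0.15), seed=0)

    def test_mix_validation(self, geom):
        with pytest.raises(GeometryError):
            place_struts(geom, "KIO", mix=(0.5, 0.1, 0.1), seed=0)  # sum != 1


class TestLargestRemainder:
    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        w=st.lists(st.floats(0.01, 1.0), min_size=2, max_size=5),
        total=st.integers(1, 200),
    )
    def test_counts_sum_and_bound(self, w, total):
        fr = np.asarray(w) / np.sum(w)
        counts = largest_remainder(fr, total)
        assert sum(counts) == total
        for f, c in zip(fr, counts):
            assert np.floor(f * total) <= c <= np.ceil(f * total)


class TestInletVelocity:
    def test_bench_flow_rate_maps_to_printed_speed(self):
        v = inlet_velocity_from_flow(200.0, 5.5)
        assert v == pytest.approx(0.1403, abs=5e-4)
        assert round(v, 2) == 0.14

    def test_linearity_in_flow_rate(self):
        assert inlet_velocity_from_flow(400.0, 5.5) == pytest.approx(0.2807, abs=5e-4)

    def test_vanishing_flow_limit(self):
        assert inlet_velocity_from_flow(1e-9, 5.5) < 1e-12

    @pytest.mark.parametrize("q,d", [(0.0, 5.5), (-1.0, 5.5), (200.0, 0.0)])
    def test_nonpositive_inputs_rejected(self, q, d):
        with pytest.raises(GeometryError):
            inlet_velocity_from_flow(q, d)
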