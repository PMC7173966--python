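"""Fold morphometry: envelopes, detachment counting, depth and gyrus area."""

import math

import numpy as np
import pytest
from shapely.geometry import Polygon

from conftest import circle
from gyrify import (
    FoldLandmarks,
    GeometryError,
    SectionContour,
    UndefinedRatioError,
    compute_outer_contour,
    detect_landmarks,
    fold_metrics,
    local_gn,
    local_gs,
    local_sd,
    side_ratio,
)
from gyrify._util import point_line_distance
from gyrify.synthetic import SyntheticConfig, generate_contour_pair


def notched_circle(depth=600.0, width=800.0, radius=4000.0, n=1440, center_angle=np.pi / 2):
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    r = np.full_like(theta, radius)
    w_ang = width / radius
    u = (theta - center_angle + np.pi) % (2 * np.pi) - np.pi
    inside = np.abs(u) < w_ang / 2
    r[inside] -= depth * 0.5 * (1 + np.cos(2 * np.pi * u[inside] / w_ang))
    return SectionContour(np.column_stack([r * np.cos(theta), r * np.sin(theta)]))


class TestOuterContour:
    def test_convex_contour_is_its_own_envelope(self):
        c = SectionContour(circle(n=64))
        o = compute_outer_contour(c, 1000.0)
        assert abs(o.polygon.area - c.polygon.area) / c.polygon.area < 1e-3
        assert o.polygon.buffer(1.0).contains(c.polygon)

    def test_infinite_radius_gives_convex_hull(self):
        c = notched_circle()
        o = compute_outer_contour(c, float("inf"))
        assert abs(o.polygon.area - c.polygon.convex_hull.area) < 1e-6

    def test_envelope_encloses_input(self):
        # 2 µm tolerance covers the arc discretisation of the disc buffer
        c = notched_circle()
        o = compute_outer_contour(c, 1000.0)
        assert o.polygon.buffer(2.0).contains(c.polygon)

    def test_notch_bridged_matches_raster_closing_oracle(self):
        """Disc closing agrees with pixelised morphological closing at 5 µm/px.

        The raster oracle closes via Euclidean distance transforms
        (dilation = within r of the shape; erosion = deeper than r inside),
        which is exact morphological closing up to pixelisation.
        """
        import shapely
        from scipy.ndimage import distance_transform_edt

        c = notched_circle()
        radius = 1000.0
        o = compute_outer_contour(c, radius)

        px = 5.0
        pad = 1.2 * radius
        minx, miny, maxx, maxy = c.polygon.bounds
        nx = int((maxx - minx + 2 * pad) / px)
        ny = int((maxy - miny + 2 * pad) / px)
        xs = minx - pad + (np.arange(nx) + 0.5) * px
        ys = miny - pad + (np.arange(ny) + 0.5) * px
        xx, yy = np.meshgrid(xs, ys)
        mask = shapely.contains_xy(c.polygon, xx.ravel(), yy.ravel()).reshape(ny, nx)
        r_px = radius / px
        dilated = distance_transform_edt(~mask) <= r_px
        closed = distance_transform_edt(dilated) >= r_px
        raster_area = closed.sum() * px**2
        assert abs(o.polygon.area - raster_area) / raster_area < 0.01

    def test_rejects_positive_radius_violation(self):
        c = SectionContour(circle(n=32))
        with pytest.raises(ValueError):
            compute_outer_contour(c, -5.0)


class TestLocalGN:
    def test_convex_contour_has_zero(self):
        c = SectionContour(circle(n=128))
        o = compute_outer_contour(c)
        assert local_gn(c, o) == 0

    def test_three_notches_counted(self, folded_pair):
        c = folded_pair.ep
        o = compute_outer_contour(c)
        assert local_gn(c, o) == 3

    def test_shallow_notch_below_threshold_not_counted(self):
        c = notched_circle(depth=30.0, width=800.0)
        o = compute_outer_contour(c)
        assert local_gn(c, o, gap_threshold=50.0) == 0

    def test_rejects_nonpositive_threshold(self):
        c = SectionContour(circle(n=32))
        o = compute_outer_contour(c)
        with pytest.raises(ValueError):
            local_gn(c, o, gap_threshold=0.0)

    @pytest.mark.parametrize("angle,scale", [(0.7, 2.5), (-1.2, 0.4)])
    def test_invariant_under_rigid_motion_and_scaling(self, angle, scale):
        c = notched_circle()
        rot = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
        moved = SectionContour(scale * (c.vertices @ rot.T) + np.array([123.0, -456.0]))
        o1 = compute_outer_contour(c, 1000.0)
        o2 = compute_outer_contour(moved, scale * 1000.0)
        assert local_gn(c, o1, 50.0) == local_gn(moved, o2, scale * 50.0) == 1


class TestLandmarks:
    def test_convex_contour_has_no_bottoms(self):
        c = SectionContour(circle(n=128))
        lm = detect_landmarks(c, compute_outer_contour(c))
        assert lm.n_sulci == 0

    def test_bottoms_match_generator_truth_within_vertex_spacing(self, folded_pair):
        c, truth = folded_pair.ep, folded_pair.truth_ep
        lm = detect_landmarks(c, compute_outer_contour(c))
        assert lm.n_sulci == len(truth.sulcus_bottoms)
        for b in truth.sulcus_bottoms:
            d = np.min(np.hypot(*(lm.sulcus_bottoms - b).T))
            assert d <= c.vertex_spacing

    def test_depth_recovered_on_clean_sulci(self):
        """Hull-envelope depth of narrow clean sulci within 2 % of configured."""
        cfg = SyntheticConfig(seed=5, sulcus_width_um=500.0)
        pair = generate_contour_pair(cfg)
        lm = detect_landmarks(pair.ep, compute_outer_contour(pair.ep, float("inf")))
        assert np.all(np.abs(lm.depths - cfg.sulcus_depth_um) / cfg.sulcus_depth_um < 0.02)

    def test_noise_below_min_depth_not_reported(self):
        cfg = SyntheticConfig(seed=3, n_sulci_ep=0, n_sulci_nonep=0, noise_amplitude_um=20.0)
        pair = generate_contour_pair(cfg)
        lm = detect_landmarks(pair.ep, compute_outer_contour(pair.ep), min_depth=50.0)
        assert lm.n_sulci == 0


def _lm(tops, bottoms, n_vertices=8):
    tops = np.atleast_2d(tops)
    bottoms = np.atleast_2d(bottoms)
    return FoldLandmarks(
        gyrus_tops=tops,
        sulcus_bottoms=bottoms,
        top_indices=np.array([0, n_vertices // 2])[: len(tops)],
        bottom_indices=np.array([n_vertices // 4])[: len(bottoms)],
        depths=np.array([np.hypot(*b) for b in bottoms]),
    )


class TestLocalSD:
    contour = SectionContour(circle(radius=4000.0, n=8))

    def test_horizontal_chord_example(self):
        lm = _lm([(0.0, 0.0), (4000.0, 0.0)], (1000.0, -750.0))
        assert local_sd(self.contour, lm) == pytest.approx(750.0)

    def test_apex_below_line(self):
        lm = _lm([(-2000.0, 0.0), (2000.0, 0.0)], (0.0, -500.0))
        assert local_sd(self.contour, lm) == pytest.approx(500.0)

    def test_matches_analytic_point_line_distance(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            a, b, p = rng.uniform(-5000, 5000, size=(3, 2))
            if np.allclose(a, b):
                continue
            # implicit-form oracle: |ax+by+c|/sqrt(a^2+b^2)
            A = b[1] - a[1]
            B = a[0] - b[0]
            C = -(A * a[0] + B * a[1])
            expected = abs(A * p[0] + B * p[1] + C) / math.hypot(A, B)
            lm = _lm([a, b], p)
            assert local_sd(self.contour, lm) == pytest.approx(expected, rel=1e-9)

    def test_requires_two_tops(self):
        lm = FoldLandmarks(
            gyrus_tops=np.array([[0.0, 0.0]]),
            sulcus_bottoms=np.array([[1.0, -1.0]]),
            top_indices=np.array([0]),
            bottom_indices=np.array([2]),
            depths=np.array([1.0]),
        )
        with pytest.raises(GeometryError):
            local_sd(self.contour, lm)


class TestLocalGS:
    def test_semicircular_bump_area(self):
        r = 1000.0
        theta = np.linspace(0, np.pi, 721)
        arc = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        base = np.array([[-r, -2000.0], [r, -2000.0]])  # close the test contour below
        c = SectionContour(np.vstack([arc, base]))
        lm = FoldLandmarks(
            gyrus_tops=np.array([[0.0, r]]),
            sulcus_bottoms=np.array([[r, 0.0], [-r, 0.0]]),
            top_indices=np.array([360]),
            bottom_indices=np.array([0, 720]),
            depths=np.array([1.0, 1.0]),
        )
        assert local_gs(c, lm) == pytest.approx(math.pi * r**2 / 2, rel=1e-4)

    def test_matches_shoelace_oracle(self, folded_pair):
        c = folded_pair.ep
        lm = detect_landmarks(c, compute_outer_contour(c))
        area = local_gs(c, lm)
        order = np.argsort(lm.depths)[::-1]
        i, j = sorted(int(lm.bottom_indices[k]) for k in order[:2])
        arc = c.vertices[i : j + 1]
        x, y = arc[:, 0], arc[:, 1]
        shoelace = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        assert area == pytest.approx(shoelace, rel=1e-9)

    def test_single_sulcus_degenerates_to_zero(self):
        c = SectionContour(circle(n=16))
        lm = FoldLandmarks(
            gyrus_tops=np.empty((0, 2)), sulcus_bottoms=np.array([[1.0, 1.0]]),
            top_indices=np.empty(0, dtype=int), bottom_indices=np.array([3]),
            depths=np.array([5.0]),
        )
        with pytest.warns(UserWarning):
            assert local_gs(c, lm) == 0.0

    def test_scales_quadratically(self, folded_pair):
        c = folded_pair.ep
        lm = detect_landmarks(c, compute_outer_contour(c))
        a1 = local_gs(c, lm)
        s = 3.0
        c2 = SectionContour(s * c.vertices)
        lm2 = detect_landmarks(c2, compute_outer_contour(c2, s * 1000.0), min_depth=s * 50.0)
        assert local_gs(c2, lm2) == pytest.approx(s**2 * a1, rel=1e-6)


class TestSideRatio:
    @pytest.mark.parametrize(
        "ep,nonep,expected", [(5.0, 5.0, 1.0), (2, 4, 0.5), (450.0, 1000.0, 0.45)]
    )
    def test_examples(self, ep, nonep, expected):
        assert side_ratio(ep, nonep) == pytest.approx(expected)

    def test_zero_denominator_names_section(self):
        with pytest.raises(UndefinedRatioError, match="s99"):
            side_ratio(1.0, 0.0, section_id="s99")


class TestFoldMetrics:
    def test_congruent_sides_give_unit_ratios(self, folded_pair):
        m = fold_metrics(folded_pair.ep, folded_pair.nonep)
        assert m.local_gn_ratio == pytest.approx(1.0)
        assert m.local_sd_ratio == pytest.approx(1.0, abs=1e-9)
        assert m.local_gs_ratio == pytest.approx(1.0, abs=1e-9)

    def test_fewer_ep_sulci_reduce_gn_ratio(self):
        cfg = SyntheticConfig(seed=9, n_sulci_ep=2, n_sulci_nonep=4)
        pair = generate_contour_pair(cfg)
        m = fold_metrics(pair.ep, pair.nonep)
        assert m.local_gn_ep == 2 and m.local_gn_nonep == 4
        assert m.local_gn_ratio == pytest.approx(0.5)

    def test_rejects_self_intersecting_contour(self):
        bowtie = np.array([[0, 0], [10, 10], [10, 0], [0, 10]], dtype=float)
        with pytest.raises(GeometryError):
            SectionContour(bowtie)
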