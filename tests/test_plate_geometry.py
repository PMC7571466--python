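"""Contour length, Pratt circle fitting, plate alignment/averaging and statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats

from conftest import grid_search_circle
from kinetosim import scene
from kinetosim.plate_geometry import (
    PlateContour,
    align_plate,
    average_plates,
    contour_length,
    fit_circle_pratt,
    student_t_test,
    summarize_population,
)
from kinetosim.scene import ContourSpec, generate_em_contour


def _circle_points(radius, center=(0.0, 0.0), n=100, span=(0, 2 * math.pi)):
    t = np.linspace(*span, n, endpoint=False)
    return np.column_stack(
        [center[0] + radius * np.cos(t), center[1] + radius * np.sin(t)]
    )


class TestContourLength:
    def test_straight_trace_length_is_spacing_times_segments(self):
        pts = np.column_stack([np.arange(161) * 1.88, np.zeros(161)])
        assert contour_length(PlateContour(pts)) == pytest.approx(160 * 1.88)

    def test_arc_length_matches_analytic_value(self):
        c = generate_em_contour(ContourSpec(radius=287.0, arc_length=301.0))
        # polyline length of n chords of a circle underestimates 2*alpha*R
        # by O((spacing/R)^2); spacing error bound
        assert contour_length(c) == pytest.approx(301.0, abs=1.88)

    def test_population_mean_within_confidence_interval(self):
        rng = np.random.default_rng(123)
        lengths = rng.normal(301.0, 70.0, 117)
        rep = summarize_population(lengths=lengths)["length"]
        half_ci = 1.96 * 70.0 / math.sqrt(117)
        assert abs(rep["mean"] - 301.0) < half_ci + 1e-9

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        angle=st.floats(0.0, 2 * math.pi),
        tx=st.floats(-1e4, 1e4),
        ty=st.floats(-1e4, 1e4),
    )
    def test_length_invariant_under_rigid_motion_and_reversal(self, angle, tx, ty):
        c = generate_em_contour(ContourSpec(radius=239.0, arc_length=418.0))
        rot = np.array(
            [[math.cos(angle), -math.sin(angle)], [math.sin(angle), math.cos(angle)]]
        )
        moved = PlateContour(c.points_nm @ rot.T + [tx, ty])
        reversed_ = PlateContour(c.points_nm[::-1])
        ref = contour_length(c)
        assert contour_length(moved) == pytest.approx(ref, rel=1e-9)
        assert contour_length(reversed_) == pytest.approx(ref, rel=1e-9)

    def test_too_short_contour_rejected(self):
        with pytest.raises(ValueError):
            contour_length(PlateContour(np.array([[0.0, 0.0]])))


class TestPrattFit:
    @pytest.mark.parametrize("radius", [287.0, 239.0])
    def test_exact_circle_recovered_to_machine_precision(self, radius):
        fit = fit_circle_pratt(_circle_points(radius, center=(37.0, -11.0)))
        assert fit.radius == pytest.approx(radius, abs=1e-9)
        assert fit.center == pytest.approx((37.0, -11.0), abs=1e-9)
        assert fit.rms_residual < 1e-9

    def test_partial_arc_recovered(self):
        pts = _circle_points(287.0, n=161, span=(1.0, 2.0))
        assert fit_circle_pratt(pts).radius == pytest.approx(287.0, abs=1e-6)

    def test_collinear_points_give_infinite_radius_sentinel(self):
        pts = np.column_stack([np.arange(10.0), 2.0 * np.arange(10.0)])
        fit = fit_circle_pratt(pts)
        assert fit.is_degenerate and math.isinf(fit.radius)

    def test_noisy_arc_within_2nm_of_grid_search_oracle(self):
        c = generate_em_contour(
            ContourSpec(radius=239.0, arc_length=418.0, noise_sd=5.0, seed=9)
        )
        fit = fit_circle_pratt(c)
        _, _, oracle_r = grid_search_circle(c.points_nm, fit.center, fit.radius)
        assert abs(fit.radius - oracle_r) < 2.0

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        angle=st.floats(0.0, 2 * math.pi),
        tx=st.floats(-1e3, 1e3),
        ty=st.floats(-1e3, 1e3),
    )
    def test_equivariance_under_rigid_motion(self, angle, tx, ty):
        c = generate_em_contour(
            ContourSpec(radius=287.0, arc_length=301.0, noise_sd=3.0, seed=5)
        )
        rot = np.array(
            [[math.cos(angle), -math.sin(angle)], [math.sin(angle), math.cos(angle)]]
        )
        base = fit_circle_pratt(c)
        moved = fit_circle_pratt(c.points_nm @ rot.T + [tx, ty])
        assert moved.radius == pytest.approx(base.radius, rel=1e-6)
        expected_center = rot @ np.asarray(base.center) + [tx, ty]
        assert np.allclose(moved.center, expected_center, atol=1e-6 * base.radius)


class TestAlignment:
    def test_aligned_arc_returned_unchanged(self):
        c = generate_em_contour(ContourSpec(radius=287.0, arc_length=301.0))
        a1, rot1, tr1 = align_plate(c)
        a2, rot2, tr2 = align_plate(a1)
        assert abs(rot2) < 1e-9 and np.allclose(tr2, 0.0, atol=1e-9)
        assert np.allclose(a1.points_nm, a2.points_nm, atol=1e-9)

    def test_rotated_arc_termini_back_on_horizontal_line(self):
        c = generate_em_contour(ContourSpec(radius=239.0, arc_length=418.0))
        ang = math.radians(30.0)
        rot = np.array(
            [[math.cos(ang), -math.sin(ang)], [math.sin(ang), math.cos(ang)]]
        )
        tilted = PlateContour(c.points_nm @ rot.T)
        aligned, _, _ = align_plate(tilted)
        dy = abs(aligned.points_nm[0, 1] - aligned.points_nm[-1, 1])
        assert dy < 0.5 * 1.88  # within half a trace pixel

    def test_apex_matches_brute_force_max_distance_point(self):
        c = generate_em_contour(
            ContourSpec(radius=287.0, arc_length=301.0, noise_sd=0.0)
        )
        aligned, _, _ = align_plate(c)
        pts = aligned.points_nm
        p0, p1 = pts[0], pts[-1]
        chord = (p1 - p0) / np.linalg.norm(p1 - p0)
        perp = np.abs(np.cross(np.append(chord, 0.0), np.column_stack(
            [pts - p0, np.zeros(len(pts))]))[:, 2])
        brute = pts[np.argmax(perp)]
        assert np.allclose(brute, [0.0, 0.0], atol=1.0)

    def test_coincident_termini_rejected(self):
        loop = PlateContour(_circle_points(100.0, n=30))
        closed = PlateContour(np.vstack([loop.points_nm, loop.points_nm[:1] + 1e-12]))
        with pytest.raises(ValueError, match="termini"):
            align_plate(closed)


class TestAveraging:
    def test_identical_arcs_average_to_input_radius(self):
        cs = [
            generate_em_contour(ContourSpec(radius=287.0, arc_length=301.0))
            for _ in range(5)
        ]
        avg = average_plates(cs)
        assert avg.n_plates == 5
        assert avg.image.dtype == np.float32
        assert avg.fit.radius == pytest.approx(287.0, abs=2.0)

    def test_untreated_and_taxol_populations_recover_mean_geometry(self):
        # populations at the study scale: 117 / 113 plates, 2 nm trace noise
        for true_r, arc, n, seed0 in ((287.0, 301.0, 117, 0), (239.0, 418.0, 113, 500)):
            cs = [
                generate_em_contour(
                    ContourSpec(radius=true_r, arc_length=arc, noise_sd=2.0, seed=seed0 + i)
                )
                for i in range(n)
            ]
            avg = average_plates(cs)
            assert abs(avg.fit.radius - true_r) < 12.0

    def test_mixed_radii_match_direct_image_average_oracle(self):
        mix = [
            generate_em_contour(ContourSpec(radius=r, arc_length=300.0))
            for r in (250.0, 350.0)
        ]
        avg = average_plates(mix)
        # oracle: average the two rasterized images by hand on the same grid
        from kinetosim.plate_geometry import _extract_chord, align_plate, rasterize_contour

        aligned = [align_plate(c)[0] for c in mix]
        allpts = np.vstack([a.points_nm for a in aligned])
        lo = allpts.min(axis=0) - 4 * 1.88
        hi = allpts.max(axis=0) + 4 * 1.88
        shape = (
            int(np.ceil((hi[1] - lo[1]) / 1.88)) + 1,
            int(np.ceil((hi[0] - lo[0]) / 1.88)) + 1,
        )
        manual = sum(rasterize_contour(a, 1.88, tuple(lo), shape) for a in aligned) / 2.0
        oracle = fit_circle_pratt(_extract_chord(manual, 1.88, tuple(lo)))
        assert avg.fit.radius == pytest.approx(oracle.radius, rel=0.02)

    def test_averaging_order_invariant_and_idempotent(self):
        cs = [
            generate_em_contour(ContourSpec(radius=287.0, arc_length=301.0, noise_sd=3.0, seed=i))
            for i in range(4)
        ]
        a = average_plates(cs)
        b = average_plates(cs[::-1])
        assert a.fit.radius == pytest.approx(b.fit.radius, rel=1e-6)
        twice = average_plates([cs[0], cs[0]])
        once = average_plates([cs[0]])
        assert twice.fit.radius == pytest.approx(once.fit.radius, rel=1e-6)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            average_plates([])


class TestPopulationStats:
    def test_identical_groups_give_t_zero_p_one(self):
        res = student_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == pytest.approx(1.0)

    def test_textbook_example_matches_closed_form_and_scipy(self):
        a, b = [1.0, 2, 3, 4, 5], [2.0, 3, 4, 5, 6]
        res = student_t_test(a, b)
        # pooled variance 2.5 -> t = -1 / sqrt(2.5 * 2/5) = -1, df = 8
        assert res.t == pytest.approx(-1.0)
        assert res.df == 8
        ref = sstats.ttest_ind(a, b, equal_var=True)
        assert res.t == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    def test_median_reported_for_skewed_distributions(self):
        rng = np.random.default_rng(11)
        radii = np.exp(rng.normal(math.log(275.0), 0.5, 200))
        rep = summarize_population(radii=radii)["radius"]
        assert rep["median"] < rep["mean"]  # right-skewed
        assert rep["n"] == 200 and sum(rep["hist_counts"]) == 200

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            student_t_test([1.0], [1.0, 2.0])
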