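"""Profile extraction, Gaussian peak fitting, pairwise delta and skew behaviour."""

import math

import numpy as np
import pytest
from scipy import special

from kinetosim import geometry_effect, linescan, optics, scene
from kinetosim._fitting import MultiPeakError, SinglePeakError, fit_gaussian_peaks
from kinetosim.linescan import (
    LineProfile,
    PeakFitResult,
    extract_profile,
    fit_two_peaks,
    measure_layer_fwhm,
    pair_delta,
    skew_sweep,
)


def _gauss(x, a, c, s):
    return a * np.exp(-0.5 * ((x - c) / s) ** 2)


def make_profile(x, y):
    return LineProfile(x, {"green": y}, np.zeros(3), np.array([x[-1], 0, 0]))


class TestExtractProfile:
    def test_profile_matches_continuous_voxel_average_oracle(self, psf):
        # the bilinear profile must track the exact box-integrated intensity
        # field (erf products) evaluated continuously along the line
        cloud = scene.build_point_source((10.0, 5.0, 0.0))
        vol = optics.render(cloud, psf, margin_sigma=6.0, subvoxel=(0.0, 0.0, 0.0))
        line_y = 5.0
        prof = extract_profile(vol, (-300, line_y, 0), (300, line_y, 0), channels="green")
        vx, vy, _ = vol.voxel_size
        sigma = psf.sigma_lateral("green")

        def box_avg(u, mu, width, s):
            a = (u - width / 2 - mu) / (s * math.sqrt(2))
            b = (u + width / 2 - mu) / (s * math.sqrt(2))
            return 0.5 * (special.erf(b) - special.erf(a))

        grid = vol.grid
        iz = prof.z_index
        z_edges = grid.axis_edges(2)
        zfac = 0.5 * (
            special.erf((z_edges[iz + 1] - 0.0) / (psf.sigma_axial("green") * math.sqrt(2)))
            - special.erf((z_edges[iz] - 0.0) / (psf.sigma_axial("green") * math.sqrt(2)))
        )
        # nearest row of voxel centres to the scan line
        yc = grid.axis_centers(1)
        y_row = yc[np.argmin(np.abs(yc - line_y))]
        xs = -300.0 + prof.positions  # world x of the samples
        oracle = box_avg(xs, 10.0, vx, sigma) * box_avg(y_row, 5.0, vy, sigma) * zfac
        dev = np.abs(prof.channel() - oracle)
        assert dev.max() / oracle.max() < 0.02

    def test_profile_maximum_at_source_position(self, psf):
        cloud = scene.build_point_source((37.0, 0.0, 0.0))
        vol = optics.render(cloud, psf, margin_sigma=6.0, subvoxel=(0.0, 0.0, 0.0))
        prof = extract_profile(vol, (-300, 0, 0), (300, 0, 0), channels="green")
        step = np.diff(prof.positions)[0]
        x_peak = prof.positions[np.argmax(prof.channel())] - 300.0
        assert abs(x_peak - 37.0) <= step / 2 + 1e-9

    def test_out_of_plane_line_rejected(self, psf, im_pair):
        _, vol, _ = im_pair
        with pytest.raises(ValueError, match="Z plane"):
            extract_profile(vol, (0, 0, 0), (100, 0, 200.0))


class TestPeakFitting:
    def test_noiseless_two_gaussian_profile_recovered_exactly(self):
        x = np.arange(-900.0, 900.0, 21.5)
        sigma = 200.0 / 2.35482
        y = _gauss(x, 1.0, -500, sigma) + _gauss(x, 0.8, 500, sigma) + 0.05
        p1, p2 = fit_two_peaks(make_profile(x, y))
        assert p1.center == pytest.approx(-500.0, abs=0.1)
        assert p2.center == pytest.approx(500.0, abs=0.1)
        assert p1.fwhm == pytest.approx(200.0, abs=0.5)
        assert p1.relative_fit_error < 1e-6

    def test_overlapping_peaks_match_grid_search_oracle(self):
        # separation 250 nm, FWHM 220 nm, slight noise: compare against a
        # brute-force least-squares oracle over the two centre positions
        rng = np.random.default_rng(42)
        x = np.arange(-800.0, 800.0, 21.5)
        sigma = 220.0 / 2.35482
        y = _gauss(x, 1.0, -125, sigma) + _gauss(x, 1.0, 125, sigma)
        y = y + rng.normal(0.0, 0.005, len(x))

        def sse_for_centers(c1, c2):
            design = np.column_stack(
                [_gauss(x, 1.0, c1, sigma), _gauss(x, 1.0, c2, sigma), np.ones_like(x)]
            )
            coef, *_ = np.linalg.lstsq(design, y, rcond=None)
            return float(np.sum((design @ coef - y) ** 2))

        best = None
        for c1 in np.arange(-140, -110, 0.5):
            for c2 in np.arange(110, 140, 0.5):
                s = sse_for_centers(c1, c2)
                if best is None or s < best[0]:
                    best = (s, c1, c2)
        p1, p2 = fit_two_peaks(make_profile(x, y))
        assert p1.center == pytest.approx(best[1], abs=2.0)
        assert p2.center == pytest.approx(best[2], abs=2.0)

    def test_single_peak_profile_raises_distinct_error(self):
        x = np.arange(-500.0, 500.0, 21.5)
        y = _gauss(x, 1.0, 0.0, 90.0)
        with pytest.raises(SinglePeakError):
            fit_two_peaks(make_profile(x, y))
        # while a two-peak profile is rejected by the single-layer fit
        y2 = _gauss(x, 1.0, -250, 80.0) + _gauss(x, 1.0, 250, 80.0)
        with pytest.raises(MultiPeakError):
            measure_layer_fwhm(make_profile(x, y2))


class TestPairDelta:
    def _peak(self, center, err=0.0):
        return PeakFitResult(center, 200.0, 1.0, 0.0, err)

    def test_delta_is_half_the_ikd_difference(self):
        m = pair_delta(
            (self._peak(-500), self._peak(500)), (self._peak(-600), self._peak(600))
        )
        assert (m.ikd_green, m.ikd_red, m.delta) == (1000.0, 1200.0, 100.0)
        assert m.qc_pass

    def test_uniform_red_shift_cancels_in_pairwise_delta(self):
        base = pair_delta(
            (self._peak(-500), self._peak(500)), (self._peak(-600), self._peak(600))
        )
        shifted = pair_delta(
            (self._peak(-500), self._peak(500)),
            (self._peak(-600 + 50), self._peak(600 + 50)),
        )
        assert shifted.delta == base.delta

    def test_reported_im_delta_convention(self):
        # IKDr 1190, IKDg 1000 -> delta 95 nm
        m = pair_delta(
            (self._peak(-500), self._peak(500)), (self._peak(-595), self._peak(595))
        )
        assert m.delta == pytest.approx(95.0)

    def test_fit_error_gate_at_three_percent(self):
        bad = pair_delta(
            (self._peak(-500), self._peak(500, err=0.04)),
            (self._peak(-600), self._peak(600)),
        )
        assert not bad.qc_pass
        good = pair_delta(
            (self._peak(-500), self._peak(500, err=0.029)),
            (self._peak(-600), self._peak(600)),
        )
        assert good.qc_pass


class TestLayerFWHM:
    def _dense_line_cloud(self, width):
        # dense deterministic points along x: the x-profile of the rendered
        # image is exactly (uniform slab) convolved (Gaussian) x (pixel box)
        if width == 0:
            return scene.build_point_source((0, 0, 0), channels=("red",))
        xs = np.linspace(-width / 2, width / 2, 2001)
        pts = np.column_stack([xs, np.zeros_like(xs), np.zeros_like(xs)])
        return scene.MoleculeCloud(pts, np.array(["red"] * len(xs), dtype=object))

    def _measured_fwhm(self, psf, width):
        grid = optics.GridSpec((7, 11, 40), (43.0, 43.0, 200.0), (-860.0, -236.5, -700.0))
        vol = optics.render(self._dense_line_cloud(width), psf, grid)
        prof = extract_profile(vol, (-650, 0, 0), (650, 0, 0), channels="red")
        return measure_layer_fwhm(prof).fwhm

    def test_zero_width_layer_is_diffraction_limited(self, psf):
        assert self._measured_fwhm(psf, 0.0) == pytest.approx(172.0, rel=0.05)

    def test_slab_fwhm_matches_numeric_convolution_oracle(self, psf):
        # 160 nm slab x Gaussian (FWHM 172) x 43 nm pixel box, fitted with the
        # same single-Gaussian estimator on an independent 1D numeric route
        width, vx = 160.0, 43.0
        t = np.arange(-800.0, 800.0, 0.5)
        slab = ((np.abs(t) <= width / 2)).astype(float)
        sigma = 172.0 / 2.35482
        kern = np.exp(-0.5 * (t / sigma) ** 2)
        box = (np.abs(t) <= vx / 2).astype(float)
        y = np.convolve(np.convolve(slab, kern, mode="same"), box, mode="same")
        peaks, *_ = fit_gaussian_peaks(t, y / y.max(), 1)
        oracle_fwhm = peaks[0][2] * 2.35482
        assert self._measured_fwhm(psf, width) == pytest.approx(oracle_fwhm, abs=2.0)

    def test_fwhm_monotone_in_true_layer_width(self, psf):
        widths = [0.0, 80.0, 160.0, 240.0]
        fwhms = [self._measured_fwhm(psf, w) for w in widths]
        assert all(b > a for a, b in zip(fwhms, fwhms[1:]))


class TestSkewSweep:
    def test_zero_angle_only_has_zero_fluctuation(self, im_pair):
        _, vol, base = im_pair
        assert skew_sweep(vol, base, [0.0]).fluctuation == 0.0

    def test_ten_degree_skew_fluctuation_below_five_percent(self, im_pair):
        _, vol, base = im_pair
        sweep = skew_sweep(vol, base, [-10.0, 0.0, 10.0])
        assert sweep.fluctuation < 0.05
        assert all(m.qc_pass for m in sweep.measurements.values())

    def test_twenty_degree_error_matches_foreshortening_model(self, im_pair):
        # measured relative error within 1 percentage point of the analytic
        # cosine model
        _, vol, base = im_pair
        sweep = skew_sweep(vol, base, [0.0, 20.0])
        measured = abs(sweep.measurements[20.0].delta - sweep.delta_reference) / abs(
            sweep.delta_reference
        )
        assert abs(measured - geometry_effect.skew_error(20.0)) < 0.01

    def test_delta_independent_of_plate_length_for_flat_plates(self, psf):
        deltas = {}
        for length in (300.0, 1000.0):
            vals = []
            for rep in range(12):
                plate = scene.vary_plate(scene.im_plate(), plate_length=length)
                spec = scene.SisterPairSpec(plates=(plate, plate),
                                            inter_kinetochore_distance=1000.0)
                cloud = scene.build_sister_pair(spec, seed=3000 + rep)
                vol = optics.render(cloud, psf, seed=4000 + rep)
                base = linescan.pair_scan_line(cloud.ground_truth, psf)
                vals.append(linescan.measure_pair(vol, *base).delta)
            deltas[length] = np.mean(vals)
        assert abs(deltas[300.0] - deltas[1000.0]) < 2.0
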