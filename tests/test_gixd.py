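"""GIXD reduction and 2D unit-cell indexing."""

import numpy as np
import pytest

from monofilm.gixd import (
    BraggPeak,
    BraggPeakSet,
    GIXDImage,
    IndexingError,
    NoPeaksError,
    excess_area,
    chain_areas_and_tilt,
    reduce_to_bragg_peaks,
    solve_unit_cell,
)
from monofilm.synth import gen_gixd, peak_positions_from_cell, reciprocal_vectors


def _nn_azimuth(a, b, gamma_deg):
    g = np.radians(gamma_deg)
    nn = np.array([a + b * np.cos(g), b * np.sin(g)])
    return float(np.degrees(np.arctan2(nn[1], nn[0])))


def _forward_peaks(a, b, gamma_deg, tilt_deg, azimuth_deg):
    G = reciprocal_vectors(a, b, gamma_deg)
    pos = peak_positions_from_cell(G, tilt_deg, azimuth_deg)
    A_true = (2 * np.pi) ** 2 / abs(G["10"][0] * G["01"][1] - G["10"][1] * G["01"][0])
    return pos, A_true


class TestSolveUnitCell:
    def test_single_peak_hexagonal_area_formula(self):
        cell = solve_unit_cell(BraggPeakSet([BraggPeak(1.50, 0.0, 0.02, 100.0)]))
        assert cell.cell_class == "hexagonal"
        assert cell.tilt == 0.0
        assert cell.A_chain == pytest.approx(2 * (2 * np.pi / 1.5) ** 2 / np.sqrt(3), rel=1e-12)
        assert cell.A_chain == pytest.approx(20.26, abs=0.01)

    def test_three_equal_inplane_peaks_degenerate_hexagonal(self):
        peaks = BraggPeakSet([BraggPeak(1.50, 0.0, 0.02, 50.0) for _ in range(3)])
        cell = solve_unit_cell(peaks)
        assert cell.cell_class == "hexagonal"
        assert cell.tilt == 0.0

    def test_tilted_single_peak_rejected(self):
        with pytest.raises(IndexingError):
            solve_unit_cell(BraggPeakSet([BraggPeak(1.50, 0.3, 0.02, 100.0)]))

    def test_inconsistent_two_peak_set_rejected(self):
        # |G_1-1| cannot exceed 2|G_10|
        with pytest.raises(IndexingError):
            solve_unit_cell(BraggPeakSet([BraggPeak(0.7, 0.3, 0.02, 10.0),
                                          BraggPeak(1.5, 0.0, 0.02, 10.0)]))

    @pytest.mark.parametrize("a,gamma,tilt", [(4.9, 118.0, 12.0), (4.7, 121.5, 5.0), (5.2, 116.0, 24.0)])
    def test_nn_tilt_round_trip_exact(self, a, gamma, tilt):
        pos, A_true = _forward_peaks(a, a, gamma, tilt, _nn_azimuth(a, a, gamma))
        peaks = BraggPeakSet([BraggPeak(*pos["10"], 0.02, 100.0), BraggPeak(*pos["1-1"], 0.02, 100.0)])
        cell = solve_unit_cell(peaks)
        assert cell.cell_class == "nn-tilt"
        assert cell.A_chain == pytest.approx(A_true, rel=1e-9)
        assert cell.tilt == pytest.approx(tilt, rel=1e-9)

    def test_oblique_round_trip_exact(self):
        pos, A_true = _forward_peaks(4.8, 5.0, 117.0, 15.0, 20.0)
        peaks = BraggPeakSet([BraggPeak(*p, 0.02, 100.0) for p in pos.values()])
        cell = solve_unit_cell(peaks)
        assert cell.cell_class == "oblique"
        assert cell.A_chain == pytest.approx(A_true, rel=1e-6)
        assert cell.tilt == pytest.approx(15.0, rel=1e-6)

    def test_indexing_round_trip_50_random_cells(self, rng):
        """Hexagonal / NN-tilt / oblique cells all invert to <= 1e-6 relative."""
        for i in range(50):
            kind = i % 3
            if kind == 0:  # hexagonal
                a = rng.uniform(4.6, 5.2)
                pos, A_true = _forward_peaks(a, a, 120.0, 0.0, 0.0)
                peaks = BraggPeakSet([BraggPeak(*pos["10"], 0.02, 1.0)])
                t_true = 0.0
            elif kind == 1:  # NN tilt
                a = rng.uniform(4.6, 5.2)
                g = rng.uniform(114.0, 126.0)
                t_true = rng.uniform(3.0, 28.0)
                pos, A_true = _forward_peaks(a, a, g, t_true, _nn_azimuth(a, a, g))
                peaks = BraggPeakSet([BraggPeak(*pos["10"], 0.02, 1.0), BraggPeak(*pos["1-1"], 0.02, 1.0)])
            else:  # oblique
                a, b = rng.uniform(4.5, 5.3, size=2)
                g = rng.uniform(112.0, 128.0)
                t_true = rng.uniform(4.0, 28.0)
                az = rng.uniform(0.0, 180.0)
                pos, A_true = _forward_peaks(a, b, g, t_true, az)
                peaks = BraggPeakSet([BraggPeak(max(p[0], 1e-9), p[1], 0.02, 1.0) for p in pos.values()])
            cell = solve_unit_cell(peaks)
            assert cell.A_chain == pytest.approx(A_true, rel=1e-6)
            assert cell.tilt == pytest.approx(t_true, abs=max(1e-6, 1e-6 * t_true))

    def test_increasing_tilt_at_fixed_cross_section_increases_area(self):
        """A_chain = A_xs / cos(t): the in-plane footprint grows with tilt."""
        A_xs = 20.0
        areas = []
        for t in (0.0, 10.0, 20.0, 30.0):
            A_chain = A_xs / np.cos(np.radians(t))
            q = 2 * np.pi / np.sqrt(A_chain * np.sqrt(3) / 2)
            cell = solve_unit_cell(BraggPeakSet([BraggPeak(q, 0.0, 0.02, 1.0)]))
            areas.append(cell.A_chain)
        assert np.all(np.diff(areas) > 0)


class TestChainAreas:
    def test_untilted_cross_section_equals_chain_area(self):
        cell = solve_unit_cell(BraggPeakSet([BraggPeak(1.50, 0.0, 0.02, 1.0)]))
        A_chain, A_pair, A_xs, t = chain_areas_and_tilt(cell)
        assert t == 0.0 and A_xs == A_chain
        assert A_pair == pytest.approx(40.52, abs=0.01)

    def test_cross_section_cosine_arithmetic(self):
        from monofilm.gixd import UnitCell2D

        cell = UnitCell2D(cell_class="nn-tilt", d_spacings={}, A_chain=23.4, tilt=30.0)
        assert cell.A_xs == pytest.approx(23.4 * np.cos(np.radians(30.0)), rel=1e-12)
        assert cell.A_xs == pytest.approx(20.26, abs=0.01)


class TestExcessArea:
    def test_pure_component_has_zero_excess(self):
        assert excess_area(41.0, [41.0, 40.0], [1.0, 0.0]) == 0.0

    def test_weighted_mean_has_zero_excess(self):
        assert excess_area(0.3 * 41.0 + 0.7 * 40.0, [41.0, 40.0], [0.3, 0.7]) == pytest.approx(0.0)

    def test_chain_fraction_conversion_for_cardiolipin(self):
        """25 mol% CL is 40% of the chains: 4*0.25/(4*0.25 + 2*0.75)."""
        a_pg, a_cl = 41.0, 40.0
        ex = excess_area(40.5, [a_pg, a_cl], [0.75, 0.25], n_chains=[2, 4], basis="chains")
        assert ex == pytest.approx(40.5 - (0.6 * a_pg + 0.4 * a_cl), rel=1e-12)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            excess_area(40.0, [41.0, 40.0], [0.5, 0.4])


class TestReduceToBraggPeaks:
    def test_single_peak_recovery(self):
        img, truth = gen_gixd(a=4.84, b=4.84, gamma_deg=120.0, tilt_deg=0.0,
                              poisson_noise=True, seed=11)
        peaks = reduce_to_bragg_peaks(img)
        assert len(peaks) == 1
        p = peaks.peaks[0]
        assert p.q_xy == pytest.approx(truth["peaks"]["10"][0], abs=0.002)
        assert p.q_z <= 0.05  # consistent with zero

    def test_flat_background_raises_nopeaks(self):
        img = GIXDImage(q_xy=np.linspace(1.2, 1.8, 300), q_z=np.linspace(0.0, 0.7, 120),
                        intensity=np.full((120, 300), 7.0))
        with pytest.raises(NoPeaksError):
            reduce_to_bragg_peaks(img)

    def test_two_overlapping_peaks_resolved(self):
        """Centres 1.42 / 1.47 with fwhm 0.03 are separated to within 0.005."""
        qxy = np.linspace(1.2, 1.8, 600)
        qz = np.linspace(0.0, 0.72, 150)
        X, Z = np.meshgrid(qxy, qz)
        s = 0.03 / 2.3548
        img = 20.0 + 0.0 * X
        for c, zc in ((1.42, 0.25), (1.47, 0.0)):
            img = img + 2000.0 * np.exp(-((X - c) ** 2) / (2 * s**2)) * (
                np.exp(-((Z - zc) ** 2) / (2 * 0.1**2)) + np.exp(-((Z + zc) ** 2) / (2 * 0.1**2))
            )
        rng = np.random.default_rng(3)
        image = GIXDImage(q_xy=qxy, q_z=qz, intensity=rng.poisson(img).astype(float))
        peaks = reduce_to_bragg_peaks(image, n_peaks=2)
        centers = sorted(p.q_xy for p in peaks)
        assert centers[0] == pytest.approx(1.42, abs=0.005)
        assert centers[1] == pytest.approx(1.47, abs=0.005)

    def test_peak_centers_invariant_to_intensity_scale(self):
        img1, _ = gen_gixd(tilt_deg=10.0, poisson_noise=False, seed=0)
        img2, _ = gen_gixd(tilt_deg=10.0, poisson_noise=False, seed=0,
                           intensities={"10": 3000.0, "01": 3000.0, "1-1": 3000.0})
        c1 = sorted(p.q_xy for p in reduce_to_bragg_peaks(img1))
        c2 = sorted(p.q_xy for p in reduce_to_bragg_peaks(img2))
        assert np.allclose(c1, c2, atol=1e-3)

    def test_center_estimate_unbiased_over_noise(self):
        """Mean centre error over seeded noisy single-peak images < 10% of fwhm."""
        errs = []
        for seed in range(25):
            img, truth = gen_gixd(a=4.9, b=4.9, gamma_deg=120.0, tilt_deg=0.0,
                                  poisson_noise=True, seed=seed)
            p = reduce_to_bragg_peaks(img).peaks[0]
            errs.append(p.q_xy - truth["peaks"]["10"][0])
        assert abs(np.mean(errs)) < 0.1 * 0.02


class TestImagePipeline:
    @pytest.mark.parametrize("kw", [
        dict(a=4.9, b=4.9, gamma_deg=118.0, tilt_deg=12.0),
        dict(a=4.8, b=5.0, gamma_deg=117.0, tilt_deg=15.0, azimuth_deg=20.0),
        dict(a=4.88, b=4.88, gamma_deg=120.0, tilt_deg=0.0),
    ])
    def test_noisy_image_recovery(self, kw):
        """Full reduce+solve pipeline on Poisson-noisy maps recovers the
        chain area within 0.1 A^2 and the tilt within 0.5 degrees."""
        img, truth = gen_gixd(poisson_noise=True, seed=5, **kw)
        cell = solve_unit_cell(reduce_to_bragg_peaks(img))
        assert cell.A_chain == pytest.approx(truth["A_chain"], abs=0.1)
        assert cell.tilt == pytest.approx(truth["tilt_deg"], abs=0.5)
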