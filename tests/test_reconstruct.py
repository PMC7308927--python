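import math

import numpy as np
import pytest

from psm3d import (
    NoMatchError,
    PSMModel,
    Reconstruction,
    RingPhantom,
    SimConfig,
    compensate_frame,
    detect_target_depth,
    error_report,
    eval_plane,
    psm_reconstruct,
    simulate_acquisition,
    target_curve,
)
from psm3d.phantom import default_surface_curve, default_tmc_curve

from conftest import CONTACT_RADIUS


class TestDetectTargetDepth:
    def test_single_bright_pixel(self):
        img = np.zeros((1, 10))
        img[0, 7] = 1.0
        d = detect_target_depth(img, 0.5, 0.25)
        assert d[0] == pytest.approx(7 * 0.25)

    def test_dark_scanline_gives_nan(self):
        d = detect_target_depth(np.zeros((2, 5)), 0.5, 1.0)
        assert np.all(np.isnan(d))

    def test_first_crossing_wins(self):
        img = np.zeros((1, 10))
        img[0, 3] = 0.9
        img[0, 8] = 1.0
        d = detect_target_depth(img, 0.5, 1.0)
        assert d[0] == 3.0

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            detect_target_depth(np.zeros((1, 4)), 1.5, 1.0)


class TestCompensateFrame:
    def test_reference_conditions_are_identity(self, noiseless_frames8,
                                               calibration, echo_model):
        f = noiseless_frames8[0]  # D = 4, TMC = 1, force = baseline
        raw, _ = compensate_frame(f, calibration, echo_model, enabled=False)
        corr, fb = compensate_frame(f, calibration, echo_model, enabled=True)
        assert np.allclose(corr[~np.isnan(corr)], raw[~np.isnan(raw)])
        assert fb.correction_mm == pytest.approx(0.0, abs=1e-12)

    def test_disabled_is_exact_identity(self, phantom, calibration, echo_model):
        cfg = SimConfig(delta_v=8, seed=3, surface_curve=default_surface_curve())
        f = simulate_acquisition(phantom, cfg, calibration, echo_model)[2]
        raw, fb = compensate_frame(f, calibration, echo_model, enabled=False)
        d = detect_target_depth(f.image, 0.5, f.depth_spacing_mm)
        assert np.array_equal(np.nan_to_num(raw), np.nan_to_num(d))
        assert fb.correction_mm == 0.0

    def test_surface_distortion_restored_to_reference(self, phantom,
                                                      calibration, echo_model):
        """A frame imaged at the 7 mm control returns to the 4 mm stand-off
        after pressure compensation (within one depth sample)."""
        curve = default_surface_curve()
        cfg = SimConfig(delta_v=8, seed=3, pose_sd=0, angle_sd=0,
                        pressure_sd=0, surface_curve=curve)
        frames = simulate_acquisition(phantom, cfg, calibration, echo_model)
        k7 = list(curve.control_values).index(7.0)
        f = frames[k7]
        corr, fb = compensate_frame(f, calibration, echo_model, enabled=True)
        center = corr[63]
        assert center == pytest.approx(4.0, abs=2 * f.depth_spacing_mm)
        assert fb.correction_mm == pytest.approx(3.0, abs=0.01)

    def test_tmc_distortion_rescaled(self, phantom, calibration, echo_model):
        curve = default_tmc_curve()
        cfg = SimConfig(delta_v=8, seed=3, pose_sd=0, angle_sd=0,
                        pressure_sd=0, tmc_curve=curve)
        frames = simulate_acquisition(phantom, cfg, calibration, echo_model)
        k = list(curve.control_values).index(2.77)
        f = frames[k]
        corr, _ = compensate_frame(f, calibration, echo_model, enabled=True)
        assert corr[63] == pytest.approx(4.0, abs=2 * f.depth_spacing_mm)


class TestPsmReconstruct:
    def test_noiseless_frames_match_their_sectors(self, noiseless_frames8,
                                                  db8, phantom):
        recon = psm_reconstruct(noiseless_frames8, db8,
                                contact_radius=CONTACT_RADIUS)
        assert recon.n_skipped == 0
        assert sorted(s for _, s in recon.matched_sectors) == list(range(8))
        rep = error_report(recon, phantom)
        assert rep.radial_rmse < 0.1

    def test_placement_invariant(self, noiseless_frames8, db8):
        recon = psm_reconstruct(noiseless_frames8, db8,
                                contact_radius=CONTACT_RADIUS)
        by_sector = dict(recon.matched_sectors)
        assert recon.n_points > 0
        # every placed point lies on SOME database sector plane to < 1e-6
        for p, az in zip(recon.points, recon.point_azimuths):
            sector = min(db8.sectors, key=lambda s: abs(s.azimuth - az))
            assert abs(eval_plane(p, sector.plane)) < 1e-6

    def test_uncompensated_error_follows_surface_curve(self, phantom, db8,
                                                       calibration, echo_model):
        """Without compensation the per-frame radial error equals
        |D(azimuth) - 4| (within a couple of depth samples)."""
        curve = default_surface_curve()
        cfg = SimConfig(delta_v=8, seed=3, pose_sd=0, angle_sd=0,
                        pressure_sd=0, surface_curve=curve)
        frames = simulate_acquisition(phantom, cfg, calibration, echo_model)
        recon = psm_reconstruct(frames, db8, calibration, echo_model,
                                compensate=False,
                                contact_radius=CONTACT_RADIUS)
        u, z = phantom.local_coords(recon.points)
        err = u - phantom.front_radius(z)
        spacing = frames[0].depth_spacing_mm
        for (i, sid), frame in zip(recon.matched_sectors, frames):
            mask = np.abs(recon.point_azimuths - frame.true_azimuth) < 1e-9
            expected = 4.0 - frame.true_distance
            assert np.all(np.abs(err[mask] - expected) <= 2 * spacing)

    def test_empty_frame_list_gives_empty_reconstruction(self, db8):
        recon = psm_reconstruct([], db8)
        assert recon.n_points == 0
        assert recon.n_skipped == 0

    def test_all_unmatched_raises_with_advice(self, noiseless_frames8):
        # database around a displaced target: no frame plane contains it
        from psm3d import build_sector_database

        off_db = build_sector_database((5.0, 3.0, 0.0), None, 20.0, 8, 0.3)
        with pytest.raises(NoMatchError, match="delta_v"):
            psm_reconstruct(noiseless_frames8, off_db,
                            contact_radius=CONTACT_RADIUS)


class TestTargetCurve:
    def test_empty_reconstruction(self):
        tc = target_curve(Reconstruction(points=np.empty((0, 3)),
                                         intensities=np.empty(0)))
        assert tc.radians.size == 0

    def test_cumulative_sums_in_azimuth_order(self):
        pts = np.array([[1.0, 0.0, 0.0], [0.0, 2.0, 0.0], [-3.0, 0.0, 0.0]])
        recon = Reconstruction(points=pts, intensities=np.ones(3),
                               point_azimuths=np.array([0.0, math.pi / 2,
                                                        math.pi]))
        tc = target_curve(recon)
        assert tc.cum_x == pytest.approx([1.0, 1.0, -2.0])
        assert tc.cum_y == pytest.approx([0.0, 2.0, 2.0])

    def test_compensated_curve_close_to_ideal(self, phantom, db8,
                                              calibration, echo_model):
        """The compensated target curve tracks the undistorted one to within
        a few percent of its range."""
        ideal_cfg = SimConfig(delta_v=8, seed=3, pose_sd=0, angle_sd=0,
                              pressure_sd=0)
        ideal = psm_reconstruct(
            simulate_acquisition(phantom, ideal_cfg, calibration, echo_model),
            db8, calibration, echo_model, contact_radius=CONTACT_RADIUS)
        cfg = ideal_cfg.with_(surface_curve=default_surface_curve())
        comp = psm_reconstruct(
            simulate_acquisition(phantom, cfg, calibration, echo_model),
            db8, calibration, echo_model, compensate=True,
            contact_radius=CONTACT_RADIUS)
        tci, tcc = target_curve(ideal), target_curve(comp)
        assert tci.cum_x.size == tcc.cum_x.size
        rng_x = tci.cum_x.max() - tci.cum_x.min()
        rng_y = tci.cum_y.max() - tci.cum_y.min()
        assert np.max(np.abs(tcc.cum_x - tci.cum_x)) <= 0.05 * rng_x
        assert np.max(np.abs(tcc.cum_y - tci.cum_y)) <= 0.05 * rng_y


class TestErrorReport:
    def test_points_on_front_face_score_zero(self, phantom):
        az = np.linspace(0, 2 * math.pi, 40, endpoint=False)
        pts = np.column_stack([22.0 * np.cos(az), 22.0 * np.sin(az),
                               np.zeros_like(az)])
        rep = error_report(Reconstruction(points=pts,
                                          intensities=np.ones(az.size)),
                           phantom)
        assert rep.radial_rmse == pytest.approx(0.0, abs=1e-12)

    def test_single_point_one_mm_outside(self, phantom):
        rep = error_report(Reconstruction(points=np.array([[23.0, 0.0, 0.0]]),
                                          intensities=np.ones(1)), phantom)
        assert rep.radial_rmse == pytest.approx(1.0)
        assert rep.max_radial_error == pytest.approx(1.0)

    def test_rmse_matches_perturbation_sd(self, phantom):
        rng = np.random.default_rng(8)
        n = 1000
        az = rng.uniform(0, 2 * math.pi, n)
        sigma = 0.7
        r = 22.0 + rng.normal(0, sigma, n)
        pts = np.column_stack([r * np.cos(az), r * np.sin(az), np.zeros(n)])
        rep = error_report(Reconstruction(points=pts, intensities=np.ones(n)),
                           phantom)
        assert rep.radial_rmse == pytest.approx(sigma, rel=0.2)
        assert rep.radial_rmse <= rep.max_radial_error

    def test_empty_reconstruction_flagged(self, phantom):
        rep = error_report(Reconstruction(points=np.empty((0, 3)),
                                          intensities=np.empty(0)), phantom)
        assert rep.n_points == 0
        assert math.isnan(rep.radial_rmse)


class TestModelInterface:
    def test_fit_returns_results_with_summary(self, phantom, db8,
                                              noiseless_frames8):
        model = PSMModel(noiseless_frames8, db8, contact_radius=CONTACT_RADIUS)
        res = model.fit()
        assert res.n_matched == 8
        text = res.summary(phantom)
        assert "matched:           8" in text
        assert "radial RMSE" in text
        fb = res.feedback_frame()
        assert list(fb.columns) == ["frame_index", "azimuth_rad",
                                    "correction_mm"]
        assert len(fb) == 8

    def test_from_simulation_convenience(self, phantom):
        cfg = SimConfig(delta_v=8, seed=11, pose_sd=0, angle_sd=0,
                        pressure_sd=0)
        model = PSMModel.from_simulation(phantom, cfg)
        assert model.contact_radius == pytest.approx(26.0)
        res = model.fit()
        assert res.n_matched == 8
        assert res.error_report(phantom).radial_rmse < 0.1

    def test_compensation_improves_distorted_run(self, phantom):
        cfg = SimConfig(delta_v=8, seed=11,
                        surface_curve=default_surface_curve())
        model = PSMModel.from_simulation(phantom, cfg, match_tol=0.5)
        on = model.fit(compensate=True).error_report(phantom)
        off = model.fit(compensate=False).error_report(phantom)
        assert on.radial_rmse < off.radial_rmse
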