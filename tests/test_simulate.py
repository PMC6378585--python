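"""Simulator: blinking statistics, rendering physics, reproducibility."""

import numpy as np
import pytest

from parastorm.errors import ConfigError
from parastorm.calibrate import default_calibration
from parastorm.io_formats import CameraModel
from parastorm.simulate import (
    GroundTruth,
    SimulationConfig,
    expected_photon_image,
    fit_decay_rate,
    generate_ground_truth,
    render_movie,
)


class TestGroundTruth:
    def test_no_bleaching_keeps_event_rate_constant(self):
        cfg = SimulationConfig(n_frames=400, n_emitters=500, p_on=0.05,
                               p_bleach=0.0, structure="uniform", seed=1)
        truth = generate_ground_truth(cfg)
        counts = truth.events_per_frame(cfg.n_frames)
        first, second = counts[:200].mean(), counts[200:].mean()
        expected = cfg.n_emitters * cfg.p_on
        assert abs(first - expected) / expected < 0.1
        assert abs(second - expected) / expected < 0.1

    def test_bleaching_gives_configured_decay_rate(self):
        cfg = SimulationConfig(n_frames=1200, n_emitters=4000, p_on=0.02,
                               p_bleach=0.25, structure="uniform", seed=2)
        truth = generate_ground_truth(cfg)
        rate = fit_decay_rate(truth.events_per_frame(cfg.n_frames))
        assert abs(rate - cfg.p_on * cfg.p_bleach) / (cfg.p_on * cfg.p_bleach) < 0.15

    def test_no_events_after_bleach(self):
        cfg = SimulationConfig(n_frames=500, n_emitters=200, p_on=0.05,
                               p_bleach=1.0, structure="uniform", seed=3)
        truth = generate_ground_truth(cfg)
        # p_bleach = 1: every emitter blinks at most once
        assert len(np.unique(truth.event_emitters)) == len(truth.event_emitters)

    def test_same_seed_is_identical(self):
        cfg = SimulationConfig(n_frames=50, n_emitters=100, seed=11)
        a, b = generate_ground_truth(cfg), generate_ground_truth(cfg)
        np.testing.assert_array_equal(a.emitters, b.emitters)
        np.testing.assert_array_equal(a.event_frames, b.event_frames)
        np.testing.assert_array_equal(a.event_photons, b.event_photons)

    def test_zero_emitters_is_empty_not_error(self):
        cfg = SimulationConfig(n_frames=10, n_emitters=0, seed=0)
        truth = generate_ground_truth(cfg)
        assert truth.n_events == 0

    def test_mean_photons_matches_config(self):
        cfg = SimulationConfig(n_frames=300, n_emitters=1000, p_on=0.05,
                               p_bleach=0.0, structure="uniform", seed=4)
        truth = generate_ground_truth(cfg)
        assert abs(truth.event_photons.mean() - cfg.photons_mean) < 0.03 * cfg.photons_mean


class TestRendering:
    def test_no_signal_no_noise_gives_baseline(self, tmp_path):
        cfg = SimulationConfig(n_frames=3, n_emitters=0,
                               background_photons=0.0, read_noise_e=0.0,
                               seed=0)
        truth = generate_ground_truth(cfg)
        movie, _, _ = render_movie(truth, cfg, tmp_path / "flat.ome.tif")
        import tifffile
        stack = tifffile.imread(movie)
        assert np.all(stack == cfg.camera.baseline_adu)

    def test_photon_conservation(self):
        cfg = SimulationConfig(n_frames=1, n_emitters=0, seed=0)
        truth = GroundTruth(
            emitters=np.array([[3200.0, 3200.0, 0.0]]),
            event_frames=np.array([1]), event_emitters=np.array([0]),
            event_photons=np.array([1e6]),
            drift=np.zeros((1, 2)))
        img = expected_photon_image(truth, cfg, 1)
        assert abs(img.sum() - 1e6) / 1e6 < 0.01   # edge truncation < 1%

    def test_drift_shifts_positions_linearly(self):
        cfg = SimulationConfig(n_frames=5, n_emitters=10, p_on=1.0,
                               p_bleach=0.0, structure="uniform",
                               drift_nm_per_frame=(2.0, -1.0), seed=5)
        truth = generate_ground_truth(cfg)
        for k in range(5):
            np.testing.assert_allclose(truth.drift[k],
                                       [2.0 * k, -1.0 * k])
        pos = truth.event_positions_nm()
        at1 = pos[truth.event_frames == 1]
        at4 = pos[truth.event_frames == 4]
        np.testing.assert_allclose(at4 - at1, [[6.0, -3.0]] * len(at1),
                                   atol=1e-9)

    def test_symmetric_spot_at_focus_in_3d(self):
        cal = default_calibration()
        cfg = SimulationConfig(n_frames=1, n_emitters=0, astig=cal,
                               z_range_nm=400.0, background_photons=0.0,
                               read_noise_e=0.0, seed=0)
        truth = GroundTruth(
            emitters=np.array([[3200.0, 3200.0, 0.0]]),
            event_frames=np.array([1]), event_emitters=np.array([0]),
            event_photons=np.array([1e5]), drift=np.zeros((1, 2)))
        img = expected_photon_image(truth, cfg, 1)
        ii, jj = np.indices(img.shape)
        m = img.sum()
        ci, cj = (img * ii).sum() / m, (img * jj).sum() / m
        var_r = (img * (ii - ci) ** 2).sum() / m
        var_c = (img * (jj - cj) ** 2).sum() / m
        assert abs(var_r - var_c) / var_r < 1e-6   # sigma_x == sigma_y at z=0

    def test_movie_bytes_reproducible(self, tmp_path, small_movie):
        cfg, truth, movie = small_movie
        again, _, _ = render_movie(truth, cfg, tmp_path / "again.ome.tif")
        assert open(movie, "rb").read() == open(again, "rb").read()

    def test_3d_without_calibration_is_config_error(self):
        with pytest.raises(ConfigError):
            SimulationConfig(z_range_nm=400.0)

    def test_truth_csv_and_calibration_written(self, tmp_path):
        cfg = SimulationConfig(n_frames=5, n_emitters=20, seed=6,
                               astig=default_calibration(), z_range_nm=300.0)
        truth = generate_ground_truth(cfg)
        movie, truth_csv, cal = render_movie(truth, cfg, tmp_path / "m.ome.tif")
        assert truth_csv.exists() and cal is not None and cal.exists()
        header = truth_csv.read_text().splitlines()[0]
        assert header == "frame,emitter,x [nm],y [nm],z [nm],photons"


def test_uniform_grid_filament_structures_stay_in_field():
    for structure in ("uniform", "grid", "filaments"):
        cfg = SimulationConfig(n_frames=1, n_emitters=200,
                               structure=structure, seed=9)
        truth = generate_ground_truth(cfg)
        w_nm = cfg.width * cfg.camera.pixel_size_nm
        assert np.all(truth.emitters[:, :2] >= 0)
        assert np.all(truth.emitters[:, :2] <= w_nm)
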