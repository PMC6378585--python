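"""Localization engines: recovery on noiseless spots, agreement, precision."""

import math

import numpy as np
import pytest

from conftest import make_spot
from parastorm.errors import DegenerateInputError, DomainError
from parastorm.io_formats import CameraModel, open_movie
from parastorm.localize import (
    estimate_initial,
    fit_gaussian,
    fit_phasor,
    localization_uncertainty,
    localize_frames,
    thompson_uncertainty,
)
from parastorm.simulate import SimulationConfig, generate_ground_truth, render_movie

CAM = CameraModel(pixel_size_nm=100.0, photons_per_adu=0.5, baseline_adu=100.0)


class TestEstimateInitial:
    def test_symmetric_spot_gives_geometric_centre(self):
        roi = make_spot(7, 3.5, 3.5, 1.3, 1.3, 1000, 5)
        x, y, s, n, b = estimate_initial(roi)
        assert abs(x - 3.5) < 1e-9 and abs(y - 3.5) < 1e-9

    def test_constant_patch_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            estimate_initial(np.full((7, 7), 4.2))

    def test_offset_spot_centroid_close(self):
        roi = make_spot(7, 3.9, 3.5, 1.3, 1.3, 1000, 0)
        x, _, _, _, _ = estimate_initial(roi)
        assert abs(x - 3.9) < 0.2


class TestFitGaussian:
    @pytest.mark.parametrize("engine", ["nwls", "mle"])
    def test_noiseless_recovery(self, engine):
        roi = make_spot(7, 3.2, 3.6, 1.3, 1.3, 1000, 5)
        fit = fit_gaussian(roi, estimate_initial(roi), engine)
        assert fit.converged
        assert abs(fit.x_px - 3.2) < 1e-3
        assert abs(fit.y_px - 3.6) < 1e-3
        assert abs(fit.sigma_x_px - 1.3) / 1.3 < 5e-3
        assert abs(fit.n_photons - 1000) / 1000 < 5e-3
        assert abs(fit.b_photons - 5) < 0.1

    @pytest.mark.parametrize("engine", ["nwls", "mle"])
    def test_pure_background_does_not_converge_to_a_spot(self, engine):
        rng = np.random.default_rng(0)
        roi = rng.poisson(10.0, (7, 7)).astype(float)
        try:
            fit = fit_gaussian(roi, estimate_initial(roi), engine)
        except DegenerateInputError:
            return
        # either flagged, or the "spot" it found is nothing like a PSF
        # (these are what the width/intensity filters remove downstream)
        if fit.converged:
            assert fit.n_photons < 100 or not (0.5 < fit.sigma_x_px < 2.5)

    def test_elliptical_ratio_recovered(self):
        roi = make_spot(9, 4.3, 4.6, 1.1, 1.7, 1500, 3)
        fit = fit_gaussian(roi, estimate_initial(roi), "mle", elliptical=True)
        assert fit.converged
        assert abs(fit.sigma_x_px / fit.sigma_y_px - 1.1 / 1.7) / (1.1 / 1.7) < 0.02

    def test_engines_agree_on_noiseless_spot(self):
        roi = make_spot(7, 3.37, 3.81, 1.3, 1.3, 2000, 8)
        nwls = fit_gaussian(roi, estimate_initial(roi), "nwls")
        mle = fit_gaussian(roi, estimate_initial(roi), "mle")
        phasor = fit_phasor(roi)
        assert abs(nwls.x_px - mle.x_px) < 1e-3
        assert abs(phasor.x_px - mle.x_px) < 0.05
        assert abs(phasor.y_px - mle.y_px) < 0.05

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        roi = rng.poisson(make_spot(7, 3.4, 3.4, 1.3, 1.3, 800, 10)).astype(float)
        a = fit_gaussian(roi, estimate_initial(roi), "mle")
        b = fit_gaussian(roi, estimate_initial(roi), "mle")
        assert a == b


class TestFitPhasor:
    def test_delta_pixel_localizes_exactly(self):
        patch = np.zeros((7, 7))
        patch[3, 3] = 10.0
        fit = fit_phasor(patch)
        assert fit.x_px - 0.5 == pytest.approx(3.0, abs=1e-12)
        assert fit.y_px - 0.5 == pytest.approx(3.0, abs=1e-12)

    def test_noiseless_gaussian_within_5_centipixels(self):
        roi = make_spot(7, 3.2, 3.7, 1.3, 1.3, 1000, 0)
        fit = fit_phasor(roi)
        assert abs(fit.x_px - 3.2) < 0.05
        assert abs(fit.y_px - 3.7) < 0.05

    def test_width_proxy_tracks_sigma(self):
        roi = make_spot(9, 4.5, 4.5, 1.5, 1.5, 5000, 0)
        fit = fit_phasor(roi)
        assert abs(fit.sigma_x_px - 1.5) / 1.5 < 0.1

    def test_repeat_calls_identical_no_iterations(self):
        roi = make_spot(7, 3.3, 3.3, 1.3, 1.3, 900, 2)
        a, b = fit_phasor(roi), fit_phasor(roi)
        assert a == b
        assert a.n_iter == 0 and a.converged

    def test_flat_patch_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            fit_phasor(np.full((7, 7), 3.0))


class TestThompson:
    def test_reference_value(self):
        # sigma 130 nm, pixel 100 nm, 1000 photons, background std 10
        assert thompson_uncertainty(130, 100, 1000, 10) == pytest.approx(
            9.461, abs=5e-3)

    def test_zero_background_small_pixel_limit(self):
        val = thompson_uncertainty(130, 1e-3, 1000, 0)
        assert val == pytest.approx(130 / math.sqrt(1000), rel=1e-6)

    def test_doubling_photons_scales_root_two(self):
        a = thompson_uncertainty(130, 100, 1000, 0)
        b = thompson_uncertainty(130, 100, 2000, 0)
        assert a / b == pytest.approx(math.sqrt(2), rel=1e-9)

    def test_nonpositive_photons_is_domain_error(self):
        with pytest.raises(DomainError):
            thompson_uncertainty(130, 100, 0, 5)

    def test_phasor_fits_have_no_uncertainty(self):
        roi = make_spot(7, 3.3, 3.3, 1.3, 1.3, 900, 2)
        assert localization_uncertainty(fit_phasor(roi), CAM) is None


class TestLocalizeFrames:
    def test_empty_movie_gives_empty_table(self, tmp_path):
        cfg = SimulationConfig(n_frames=5, n_emitters=0, seed=0,
                               background_photons=0.0, read_noise_e=0.0)
        truth = generate_ground_truth(cfg)
        movie, _, _ = render_movie(truth, cfg, tmp_path / "empty.ome.tif")
        table = localize_frames(open_movie(movie), engine="mle")
        assert len(table) == 0
        assert table.dim == 2

    def test_most_events_recovered_within_50_nm(self, sparse_movie):
        from scipy.spatial import cKDTree
        cfg, truth, movie = sparse_movie
        table = localize_frames(open_movie(movie), engine="mle")
        pos = truth.event_positions_nm()
        frames = truth.event_frames
        loc = table.df[["x_nm", "y_nm"]].to_numpy()
        fr = table.df["frame"].to_numpy().astype(int)
        # isolated events only: nearest same-frame neighbour > 600 nm
        matched = total = 0
        for f in np.unique(frames):
            te = np.flatnonzero(frames == f)
            if len(te) > 1:
                tree = cKDTree(pos[te])
                dd, _ = tree.query(pos[te], k=2)
                te = te[dd[:, 1] > 600]
            lo = np.flatnonzero(fr == f)
            total += len(te)
            if len(te) == 0 or len(lo) == 0:
                continue
            dd, _ = cKDTree(loc[lo]).query(pos[te], k=1)
            matched += int((dd < 50).sum())
        assert total > 50
        assert matched / total >= 0.95

    def test_tables_are_frame_ordered_and_deterministic(self, medium_handle):
        a = localize_frames(medium_handle, engine="phasor")
        b = localize_frames(medium_handle, engine="phasor")
        assert a.df.equals(b.df)
        frames = a.df["frame"].to_numpy()
        assert np.all(np.diff(frames) >= 0)
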